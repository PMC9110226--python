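"""Parallel-beam forward projection and projection-domain conversions.

A sinogram is the (n_views x n_bins) grid of line integrals of the
attenuation image, one row per view angle. The same grid can carry
transmitted intensities via Beer-Lambert: I = P0 * exp(-a), where P0 is
the incident-ray intensity and a the line integral; conversions between
the two domains are exact inverses.

Ray discretization is delegated to scikit-image's Radon transform
(parallel geometry, views in [0, 180)); values are scaled by the physical
pixel size so line integrals are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import radon

LINE_INTEGRAL = "line_integral"
INTENSITY = "intensity"

#: water attenuation coefficient used for the HU <-> mu conversion (1/cm)
MU_WATER_CM = 0.19


@dataclass
class Sinogram:
    """Projection data for one frame.

    values : (n_views, n_bins) array
    angles_deg : strictly increasing view angles in [0, 180)
    domain : "line_integral" or "intensity"
    frame_index : time index of the frame this sinogram belongs to
    pixel_size : physical pixel size (cm) used to scale the line integrals
    """

    values: np.ndarray
    angles_deg: np.ndarray
    domain: str = LINE_INTEGRAL
    frame_index: int = 0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2-D (views x bins)")
        if self.angles_deg.ndim != 1 or len(self.angles_deg) != self.values.shape[0]:
            raise ValueError("one angle per view required")
        if len(self.angles_deg) < 1:
            raise ValueError("at least one view required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 180:
            raise ValueError("angles must lie in [0, 180)")
        if self.domain not in (LINE_INTEGRAL, INTENSITY):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain == INTENSITY and np.any(self.values <= 0):
            raise ValueError("intensity-domain values must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_views(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def copy_with(self, **kw) -> "Sinogram":
        return replace(self, **kw)


def default_angles(n_views: int = 180) -> np.ndarray:
    """Evenly spaced view angles covering [0, 180)."""
    return np.arange(n_views) * (180.0 / n_views)


def hu_to_mu(hu: np.ndarray, mu_water_cm: float = MU_WATER_CM) -> np.ndarray:
    """Hounsfield-like units to linear attenuation (1/cm); air (-1000) -> 0."""
    return mu_water_cm * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def mu_to_hu(mu: np.ndarray, mu_water_cm: float = MU_WATER_CM) -> np.ndarray:
    return 1000.0 * (np.asarray(mu, dtype=float) / mu_water_cm - 1.0)


def forward_project(frame: np.ndarray, angles_deg=None, *,
                    pixel_size: float = 1.0, frame_index: int = 0) -> Sinogram:
    """Discrete line integrals of a square frame along parallel rays.

    ``frame`` is the attenuation image (e.g. mu in 1/cm); integrals are
    multiplied by ``pixel_size`` so the result is dimensionless. The frame
    is assumed supported on the inscribed circle (air outside).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] != frame.shape[1]:
        raise ValueError("frame must be a square 2-D image")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if angles_deg is None:
        angles_deg = default_angles()
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        raise ValueError("empty angle list")
    # skimage returns (n_bins, n_views); transpose to view-major
    sino = radon(frame, theta=angles_deg, circle=True, preserve_range=True).T
    return Sinogram(values=sino * pixel_size, angles_deg=angles_deg,
                    domain=LINE_INTEGRAL, frame_index=frame_index,
                    pixel_size=pixel_size)


def to_intensity(s: Sinogram, P0: float) -> Sinogram:
    """Beer-Lambert: I_i = P0 * exp(-a_i)."""
    if s.domain != LINE_INTEGRAL:
        raise ValueError("expected a line-integral sinogram")
    if P0 <= 0:
        raise ValueError("incident intensity P0 must be positive")
    return s.copy_with(values=P0 * np.exp(-s.values), domain=INTENSITY)


def to_line_integral(s: Sinogram, P0: float) -> Sinogram:
    """Inverse Beer-Lambert: a_i = ln(P0 / I_i), clipped below at 0."""
    if s.domain != INTENSITY:
        raise ValueError("expected an intensity sinogram")
    if P0 <= 0:
        raise ValueError("incident intensity P0 must be positive")
    if np.any(s.values <= 0):
        raise ValueError("nonpositive intensities must be clipped upstream")
    vals = np.clip(np.log(P0 / s.values), 0.0, None)
    return s.copy_with(values=vals, domain=LINE_INTEGRAL)
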