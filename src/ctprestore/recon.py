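"""Filtered back-projection of (restored) sinograms.

Standard parallel-beam FBP: frequency-domain ramp filtering of each view
(optionally apodized) followed by back-projection onto the output grid.
The physical pixel size recorded on the sinogram is divided out so the
reconstruction is in the same attenuation units as the projected image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon

from .phantom import DynamicImage
from .projection import LINE_INTEGRAL, Sinogram

FILTERS = ("ramp", "hann", "shepp-logan")


@dataclass(frozen=True)
class ReconParams:
    """FBP filter choice, output grid size and circular field-of-view mask."""

    filter_name: str = "ramp"
    output_size: int | None = None  # None: n_bins of the sinogram
    circle_mask: bool = True

    def __post_init__(self) -> None:
        if self.filter_name not in FILTERS:
            raise ValueError(f"filter_name must be one of {FILTERS}")
        if self.output_size is not None and self.output_size <= 0:
            raise ValueError("output_size must be positive")


def fbp_reconstruct(s: Sinogram, params: ReconParams | None = None) -> np.ndarray:
    """Reconstruct one 2-D attenuation frame from a line-integral sinogram."""
    if params is None:
        params = ReconParams()
    if s.domain != LINE_INTEGRAL:
        raise ValueError("FBP expects a line-integral sinogram")
    if s.n_views == 1:
        warnings.warn("single-view sinogram: reconstruction is severely "
                      "ill-posed", stacklevel=2)
    size = params.output_size or s.n_bins
    img = iradon(s.values.T / s.pixel_size, theta=s.angles_deg,
                 output_size=size, filter_name=params.filter_name,
                 circle=True, preserve_range=True)
    if params.circle_mask:
        rr, cc = np.mgrid[0:size, 0:size]
        center = (size - 1) / 2.0
        mask = (rr - center) ** 2 + (cc - center) ** 2 > (size / 2.0) ** 2
        img = np.where(mask, 0.0, img)
    return img


def reconstruct_series(sinograms: list[Sinogram],
                       params: ReconParams | None = None,
                       frame_interval_s: float = 1.0) -> DynamicImage:
    """Per-frame FBP of a sinogram stack, ordered by ``frame_index``."""
    if not sinograms:
        raise ValueError("empty sinogram stack")
    geom = {(s.n_views, s.n_bins, tuple(s.angles_deg), s.pixel_size)
            for s in sinograms}
    if len(geom) != 1:
        raise ValueError("all frames must share one acquisition geometry")
    ordered = sorted(sinograms, key=lambda s: s.frame_index)
    frames = np.stack([fbp_reconstruct(s, params) for s in ordered])
    return DynamicImage(frames, frame_interval_s)
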