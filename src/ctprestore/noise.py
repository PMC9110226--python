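"""Low-dose projection noise: the mean-variance model and noise injection.

Low-dose CT projection noise is modeled as Gaussian in the line-integral
domain with a signal-dependent variance

    sigma_i^2 = (1/P0) exp(a_i) * [1 + (1/P0) exp(a_i) (sigma_e^2 - 1.25)]

where P0 is the incident-ray intensity, a_i the (noise-free) line integral
along ray i and sigma_e^2 the background electronic-noise variance. The
leading term is the photon (quantum) contribution; the bracket corrects for
electronic noise at low detected counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .projection import LINE_INTEGRAL, Sinogram

logger = logging.getLogger(__name__)

#: variance floor applied when the electronic-noise bracket turns negative
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class NoiseParams:
    """Incident intensity P0 (photons), electronic variance, RNG seed.

    Defaults correspond to a low-dose acquisition: P0 = 5e4, sigma_e^2 = 10.
    """

    P0: float = 5.0e4
    sigma_e2: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P0 <= 0:
            raise ValueError("P0 must be positive")
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be nonnegative")


def noise_variance(a_bar, params: NoiseParams):
    """Line-integral noise variance for mean value(s) ``a_bar``.

    Clipped at a small positive floor (with a warning) should the
    electronic-noise bracket go negative at extreme parameters.
    """
    a = np.asarray(a_bar, dtype=float)
    if np.any(a < 0):
        raise ValueError("mean line integral must be nonnegative")
    q = np.exp(a) / params.P0  # inverse detected counts
    var = q * (1.0 + q * (params.sigma_e2 - 1.25))
    if np.any(var <= 0):
        logger.warning("noise variance clipped at floor %.1e", VARIANCE_FLOOR)
        var = np.clip(var, VARIANCE_FLOOR, None)
    return float(var) if np.ndim(a_bar) == 0 else var


def add_noise(s: Sinogram, params: NoiseParams,
              rng: np.random.Generator | None = None
              ) -> tuple[Sinogram, np.ndarray]:
    """Inject signal-dependent Gaussian noise into a line-integral sinogram.

    Each datum becomes y_i = a_i + N(0, noise_variance(a_i)); negative
    results are clipped to 0. Returns the noisy sinogram and the per-ray
    variance map (evaluated at the clean values) for downstream weighting.
    Deterministic for a fixed seed.
    """
    if s.domain != LINE_INTEGRAL:
        raise ValueError("noise is injected in the line-integral domain")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    var = noise_variance(s.values, params)
    var = np.atleast_2d(np.asarray(var, dtype=float))
    noisy = s.values + rng.standard_normal(s.values.shape) * np.sqrt(var)
    noisy = np.clip(noisy, 0.0, None)
    return s.copy_with(values=noisy), var
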