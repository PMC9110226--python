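"""Image-quality indices: RMSE, PSNR and the universal quality index (UQI).

Conventions: PSNR = 20 log10(max(reference) / RMSE) in dB, with the RMSE of
the compared images standing in for the noise standard deviation; UQI is
the Wang-Bovik universal quality index

    UQI = 4 Cov(f, g) mu_f mu_g / [(var_f + var_g)(mu_f^2 + mu_g^2)]

with population (1/n) moments, bounded in [-1, 1] and equal to 1 iff the
images are identical. All three accept an optional region-of-interest mask;
NaN pixels present in either image are always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perfusion import PerfusionMaps


@dataclass
class QualityReport:
    """PSNR (dB), RMSE (image units), UQI for one image against a reference."""

    psnr: float
    rmse: float
    uqi: float
    n_pixels: int
    roi: str | None = None

    def as_dict(self) -> dict:
        return {"psnr": self.psnr, "rmse": self.rmse, "uqi": self.uqi,
                "n_pixels": self.n_pixels, "roi": self.roi}


def _flatten(f, f_ref, roi):
    f = np.asarray(f, dtype=float)
    g = np.asarray(f_ref, dtype=float)
    if f.shape != g.shape:
        raise ValueError("image shapes must agree")
    if roi is None:
        mask = np.ones(f.shape, dtype=bool)
    else:
        mask = np.asarray(roi, dtype=bool)
        if mask.shape != f.shape:
            raise ValueError("ROI shape must match the images")
        if not mask.any():
            raise ValueError("ROI is empty")
    mask = mask & np.isfinite(f) & np.isfinite(g)
    if not mask.any():
        raise ValueError("no finite pixels to compare")
    return f[mask], g[mask]


def rmse(f, f_ref, roi=None) -> float:
    """Root mean squared error over the ROI."""
    fv, gv = _flatten(f, f_ref, roi)
    return float(np.sqrt(np.mean((fv - gv) ** 2)))


def psnr(f, f_ref, roi=None) -> float:
    """Peak signal-to-noise ratio: 20 log10(max(f_ref over ROI) / RMSE)."""
    fv, gv = _flatten(f, f_ref, roi)
    peak = float(np.max(gv))
    if peak <= 0:
        raise ValueError("reference peak must be positive for PSNR")
    err = float(np.sqrt(np.mean((fv - gv) ** 2)))
    if err == 0:
        return float("inf")
    return float(20.0 * np.log10(peak / err))


def uqi(f, f_ref, roi=None) -> float:
    """Universal quality index over the ROI (population moments)."""
    fv, gv = _flatten(f, f_ref, roi)
    mu_f, mu_g = float(fv.mean()), float(gv.mean())
    var_f = float(np.mean((fv - mu_f) ** 2))
    var_g = float(np.mean((gv - mu_g) ** 2))
    cov = float(np.mean((fv - mu_f) * (gv - mu_g)))
    denom = (var_f + var_g) * (mu_f ** 2 + mu_g ** 2)
    if denom == 0:
        raise ValueError("UQI undefined: both images constant zero")
    return float(4.0 * cov * mu_f * mu_g / denom)


def quality_report(f, f_ref, roi=None, roi_name: str | None = None) -> QualityReport:
    fv, _ = _flatten(f, f_ref, roi)
    return QualityReport(psnr=psnr(f, f_ref, roi), rmse=rmse(f, f_ref, roi),
                         uqi=uqi(f, f_ref, roi), n_pixels=int(fv.size),
                         roi=roi_name)


def evaluate(maps: PerfusionMaps, ref_maps: PerfusionMaps, roi=None,
             roi_name: str | None = None) -> dict[str, QualityReport]:
    """All three indices for each of the four perfusion maps."""
    out = {}
    for name in PerfusionMaps.MAP_NAMES:
        out[name] = quality_report(getattr(maps, name), getattr(ref_maps, name),
                                   roi=roi, roi_name=roi_name)
    return out
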