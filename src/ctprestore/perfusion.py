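"""Perfusion parameter maps from a dynamic attenuation series.

Simple, well-defined single-compartment conventions:

* CBV — 100 x area under the tissue enhancement curve divided by the area
  under the arterial input function (AIF) enhancement, trapezoidal over the
  full scan.
* CBF — maximum finite-difference upslope of the tissue enhancement divided
  by the AIF peak enhancement (maximum-slope method).
* MTT — CBV / CBF by the central volume theorem, only where CBF exceeds a
  relative floor; invalid elsewhere (NaN).
* TTP — time of the enhancement maximum; ties broken by the earliest frame.

Deconvolution-based CBF and delay/dispersion correction are deliberately
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: CBF values below this fraction of the map maximum make MTT undefined.
DEFAULT_CBF_FLOOR = 0.01


@dataclass
class PerfusionMaps:
    """CBV (dimensionless x100), CBF (1/s), MTT (s), TTP (s) maps.

    Invalid pixels (MTT where CBF is below the floor, or pixels never
    computed) are NaN.
    """

    cbv: np.ndarray
    cbf: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray

    def __post_init__(self) -> None:
        shapes = {np.shape(m) for m in (self.cbv, self.cbf, self.mtt, self.ttp)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"cbv": self.cbv, "cbf": self.cbf,
                "mtt": self.mtt, "ttp": self.ttp}

    MAP_NAMES = ("cbv", "cbf", "mtt", "ttp")


@dataclass
class RegionReport:
    """Class-wise map means and values relative to the normal-tissue mean."""

    means: dict[str, dict[str, float]]  # class -> map -> mean
    relative: dict[str, dict[str, float]]  # class -> map -> mean / normal mean


def _series(frames, frame_interval_s):
    """Accept a DynamicImage-like object or a raw (T, n, n) array."""
    if hasattr(frames, "frames") and hasattr(frames, "frame_interval_s"):
        return np.asarray(frames.frames, dtype=float), float(frames.frame_interval_s)
    if frame_interval_s is None:
        raise ValueError("frame_interval_s required for a raw array stack")
    return np.asarray(frames, dtype=float), float(frame_interval_s)


def baseline_subtract(tac: np.ndarray, n_baseline: int) -> np.ndarray:
    """Subtract the mean of the first ``n_baseline`` frames along axis 0."""
    tac = np.asarray(tac, dtype=float)
    if not 1 <= n_baseline < tac.shape[0]:
        raise ValueError("n_baseline must be in [1, series length)")
    return tac - tac[:n_baseline].mean(axis=0)


def compute_ttp(enh: np.ndarray, frame_interval_s: float) -> np.ndarray | float:
    """Time-to-peak: frame interval times the argmax (earliest on ties)."""
    enh = np.asarray(enh, dtype=float)
    out = frame_interval_s * np.argmax(enh, axis=0)
    return float(out) if np.ndim(out) == 0 else out.astype(float)


def compute_maps(frames, aif_mask: np.ndarray, n_baseline: int = 2,
                 frame_interval_s: float | None = None,
                 cbf_floor: float = DEFAULT_CBF_FLOOR) -> PerfusionMaps:
    """Per-pixel perfusion maps from a dynamic series and an AIF pixel mask.

    Parameters
    ----------
    frames : DynamicImage or (T, n, n) array
    aif_mask : boolean mask of artery pixels whose mean curve is the AIF
    n_baseline : frames averaged for the pre-contrast baseline
    cbf_floor : relative CBF floor below which MTT is NaN
    """
    stack, dt = _series(frames, frame_interval_s)
    aif_mask = np.asarray(aif_mask, dtype=bool)
    if not aif_mask.any():
        raise ValueError("AIF region is empty")

    enh = baseline_subtract(stack, n_baseline)
    aif = enh[:, aif_mask].mean(axis=1)
    aif_peak = float(aif.max())
    if aif_peak <= 0:
        raise ValueError("AIF enhancement has no positive peak")
    aif_auc = float(np.trapezoid(aif, dx=dt))

    auc = np.trapezoid(enh, dx=dt, axis=0)
    cbv = 100.0 * auc / aif_auc
    upslope = np.diff(enh, axis=0) / dt
    cbf = upslope.max(axis=0) / aif_peak
    cbv = np.clip(cbv, 0.0, None)
    cbf = np.clip(cbf, 0.0, None)

    floor = cbf_floor * float(cbf.max()) if cbf.max() > 0 else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf > floor, cbv / cbf, np.nan)
    ttp = compute_ttp(enh, dt)

    return PerfusionMaps(cbv=cbv, cbf=cbf, mtt=mtt, ttp=ttp)


def region_report(maps: PerfusionMaps, label_map: np.ndarray,
                  class_names: dict[int, str] | None = None,
                  normal_class: str = "normal") -> RegionReport:
    """Class-wise map means and ratios to the normal class.

    NaN (invalid) pixels are excluded from means; classes absent from the
    label map are omitted rather than reported as zero.
    """
    label_map = np.asarray(label_map)
    if class_names is None:
        class_names = {int(c): str(int(c)) for c in np.unique(label_map)}
        normal_class = class_names.get(1, normal_class)
    means: dict[str, dict[str, float]] = {}
    for code, name in class_names.items():
        sel = label_map == code
        if not sel.any():
            continue
        means[name] = {key: float(np.nanmean(m[sel])) if np.isfinite(m[sel]).any()
                       else float("nan")
                       for key, m in maps.as_dict().items()}
    if normal_class not in means:
        raise ValueError(f"normal class {normal_class!r} absent from label map")
    ref = means[normal_class]
    relative = {name: {key: (val / ref[key] if ref[key] != 0 else float("nan"))
                       for key, val in permap.items()}
                for name, permap in means.items()}
    return RegionReport(means=means, relative=relative)
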