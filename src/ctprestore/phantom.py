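"""Dynamic brain-like CT-perfusion phantom.

Builds a 2-D head phantom composed of ellipses (normal tissue, ischemic
penumbra, infarct core, a feeding artery) whose pixels follow tissue-class
time-attenuation curves (TACs) shaped as peak-normalized gamma-variate
bolus curves. Because every curve is analytic, the ground-truth perfusion
maps (CBV, CBF, MTT, TTP) are known in closed form, which is what makes
recovery tests exact.

Attenuation is expressed in Hounsfield-like units (air = -1000, water = 0);
absolute iodine calibration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gamma as gamma_fn

from .perfusion import PerfusionMaps

TISSUE_CLASSES = ("background", "normal", "penumbra", "core", "artery")

# integer codes used in label maps, painter's order independent
CLASS_CODES = {name: i for i, name in enumerate(TISSUE_CLASSES)}


@dataclass(frozen=True)
class TissueKinetics:
    """Peak-normalized gamma-variate enhancement curve for one tissue class.

    The curve is ``baseline_hu`` for ``t <= delay_s`` and afterwards rises to
    a maximum of exactly ``baseline_hu + amplitude`` at
    ``t = delay_s + alpha * beta``.
    """

    baseline_hu: float
    amplitude: float
    delay_s: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")

    @property
    def t_peak(self) -> float:
        """Time-to-peak measured from bolus arrival (alpha * beta)."""
        return self.alpha * self.beta

    @property
    def ttp(self) -> float:
        """Absolute time-to-peak: delay_s + alpha * beta."""
        return self.delay_s + self.t_peak


@dataclass(frozen=True)
class EllipseRegion:
    """Ellipse (center, semi-axes, rotation) painted with one tissue class."""

    center: tuple[float, float]  # (row, col) in pixels
    axes: tuple[float, float]  # semi-axes (a, b) in pixels
    rotation_deg: float
    tissue_class: str

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if min(self.axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def mask(self, grid_size: int) -> np.ndarray:
        rr, cc = np.mgrid[0:grid_size, 0:grid_size].astype(float)
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        th = np.deg2rad(self.rotation_deg)
        u = dr * np.cos(th) + dc * np.sin(th)
        v = -dr * np.sin(th) + dc * np.cos(th)
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and time-sampling of the dynamic phantom.

    Defaults follow a 45-second acquisition sampled in 20 cycles
    (frame interval 2.25 s).
    """

    grid_size: int = 128
    regions: tuple[EllipseRegion, ...] = ()
    frame_count: int = 20
    frame_interval_s: float = 2.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.grid_size > 512:
            raise ValueError("grid_size capped at 512")
        if self.frame_count < 3:
            raise ValueError("frame_count must be >= 3")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        for reg in self.regions:
            r0, c0 = reg.center
            amax = max(reg.axes)
            if not (0 <= r0 - amax and r0 + amax <= self.grid_size
                    and 0 <= c0 - amax and c0 + amax <= self.grid_size):
                raise ValueError(f"region {reg.tissue_class} exceeds the grid")

    @property
    def duration_s(self) -> float:
        return (self.frame_count - 1) * self.frame_interval_s

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frame_count) * self.frame_interval_s


@dataclass
class DynamicImage:
    """Time-ordered stack of 2-D attenuation frames."""

    frames: np.ndarray  # (n_frames, n, n)
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, n, n) stack")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class GroundTruth:
    """Phantom output: label map, dynamic frames and analytic perfusion maps."""

    label_map: np.ndarray  # (n, n) int codes per CLASS_CODES
    frames: DynamicImage
    true_maps: PerfusionMaps
    spec: PhantomSpec = field(repr=False, default=None)
    kinetics: dict[str, TissueKinetics] = field(repr=False, default=None)


def gamma_variate(t, kinetics: TissueKinetics):
    """Evaluate the peak-normalized gamma-variate TAC at time(s) ``t``.

    Returns ``baseline_hu`` for ``t <= delay_s``, else

        baseline + amplitude * (u ** alpha) * exp(alpha * (1 - u)),
        u = (t - delay_s) / (alpha * beta)

    so the maximum above baseline is exactly ``amplitude`` at
    ``t = delay_s + alpha * beta``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    k = kinetics
    u = (t_arr - k.delay_s) / k.t_peak
    with np.errstate(invalid="ignore"):
        rise = np.where(u > 0, np.power(np.clip(u, 0, None), k.alpha)
                        * np.exp(k.alpha * (1.0 - np.clip(u, 0, None))), 0.0)
    out = k.baseline_hu + k.amplitude * rise
    out = np.where(t_arr <= k.delay_s, k.baseline_hu, out)
    return out if out.ndim else float(out)


def _analytic_auc(k: TissueKinetics, t_end: float) -> float:
    """Closed-form area under the enhancement (curve - baseline) on [0, t_end].

    With u = (t - delay)/t_peak the enhancement is A u^a e^{a(1-u)}, whose
    integral over [0, T] is A e^a t_peak a^{-(a+1)} * lower_gamma(a+1, a*U),
    U = (T - delay)/t_peak.
    """
    if t_end <= k.delay_s or k.amplitude == 0:
        return 0.0
    a = k.alpha
    u_end = (t_end - k.delay_s) / k.t_peak
    lower = gammainc(a + 1.0, a * u_end) * gamma_fn(a + 1.0)
    return float(k.amplitude * np.exp(a) * k.t_peak * a ** (-(a + 1.0)) * lower)


def _analytic_max_slope(k: TissueKinetics) -> float:
    """Maximum upslope of the enhancement curve (per second).

    For alpha > 1 the inflection of the rising limb is at
    u* = 1 - 1/sqrt(alpha); otherwise falls back to dense evaluation.
    """
    if k.amplitude == 0:
        return 0.0
    a, tp = k.alpha, k.t_peak
    if a > 1.0:
        u = 1.0 - 1.0 / np.sqrt(a)
        return float(k.amplitude * a / tp * u ** (a - 1.0) * (1.0 - u)
                     * np.exp(a * (1.0 - u)))
    tt = np.linspace(k.delay_s, k.delay_s + 6 * tp, 20001)
    vals = gamma_variate(tt, k) - k.baseline_hu
    return float(np.max(np.diff(vals) / np.diff(tt)))


def analytic_perfusion(kinetics: dict[str, TissueKinetics], spec: PhantomSpec,
                       aif_class: str = "artery") -> dict[str, dict[str, float]]:
    """Per-class ground-truth CBV/CBF/MTT/TTP from the closed-form curves.

    CBV = 100 * AUC(class) / AUC(AIF) over the scan window; CBF is the
    continuous-time maximum upslope normalized by the AIF peak enhancement;
    MTT = CBV / CBF (central volume theorem); TTP = delay + alpha * beta.
    """
    if aif_class not in kinetics:
        raise KeyError(f"no kinetics for AIF class {aif_class!r}")
    aif = kinetics[aif_class]
    if aif.amplitude <= 0:
        raise ValueError("AIF must have positive peak enhancement")
    auc_aif = _analytic_auc(aif, spec.duration_s)
    out: dict[str, dict[str, float]] = {}
    for name, k in kinetics.items():
        cbv = 100.0 * _analytic_auc(k, spec.duration_s) / auc_aif
        cbf = _analytic_max_slope(k) / aif.amplitude
        mtt = cbv / cbf if cbf > 0 else np.nan
        out[name] = {"cbv": cbv, "cbf": cbf, "mtt": mtt, "ttp": k.ttp}
    return out


def default_kinetics() -> dict[str, TissueKinetics]:
    """Default TACs: artery with a tall early bolus; enhancement amplitude
    decreasing (and arrival/TTP increasing) from normal tissue through
    penumbra to the infarct core, which barely enhances."""
    return {
        "background": TissueKinetics(-1000.0, 0.0, 0.0, 2.0, 1.0),
        "artery": TissueKinetics(45.0, 200.0, 2.25, 3.0, 1.0),
        "normal": TissueKinetics(40.0, 30.0, 4.5, 2.0, 2.0),
        "penumbra": TissueKinetics(38.0, 15.0, 6.75, 2.0, 3.0),
        "core": TissueKinetics(35.0, 5.0, 9.0, 2.0, 4.0),
    }


def default_regions(grid_size: int) -> tuple[EllipseRegion, ...]:
    """Conventional lesion geometry: brain ellipse, a penumbra in one
    hemisphere with a core inside it, and a small central artery."""
    g = grid_size
    return (
        EllipseRegion((g / 2, g / 2), (0.42 * g, 0.36 * g), 0.0, "normal"),
        EllipseRegion((0.56 * g, 0.34 * g), (0.16 * g, 0.12 * g), 20.0, "penumbra"),
        EllipseRegion((0.58 * g, 0.32 * g), (0.08 * g, 0.055 * g), 20.0, "core"),
        EllipseRegion((0.38 * g, 0.52 * g), (0.035 * g, 0.035 * g), 0.0, "artery"),
    )


def default_spec(grid_size: int = 128, frame_count: int = 20,
                 frame_interval_s: float = 2.25, seed: int = 0) -> PhantomSpec:
    return PhantomSpec(grid_size=grid_size,
                       regions=default_regions(grid_size),
                       frame_count=frame_count,
                       frame_interval_s=frame_interval_s,
                       seed=seed)


def build_phantom(spec: PhantomSpec,
                  kinetics: dict[str, TissueKinetics] | None = None) -> GroundTruth:
    """Paint the label map (painter's order: later regions overwrite earlier),
    evaluate each class TAC on the frame grid, and attach analytic truth maps.
    """
    if kinetics is None:
        kinetics = default_kinetics()
    used = {"background"} | {r.tissue_class for r in spec.regions}
    missing = used - set(kinetics)
    if missing:
        raise KeyError(f"missing kinetics for classes: {sorted(missing)}")

    g = spec.grid_size
    label = np.full((g, g), CLASS_CODES["background"], dtype=np.int8)
    for reg in spec.regions:
        label[reg.mask(g)] = CLASS_CODES[reg.tissue_class]

    times = spec.times
    frames = np.empty((spec.frame_count, g, g), dtype=float)
    class_curves = {name: gamma_variate(times, k) for name, k in kinetics.items()
                    if name in used}
    for name in used:
        code = CLASS_CODES[name]
        sel = label == code
        frames[:, sel] = class_curves[name][:, None]

    truth = analytic_perfusion({n: kinetics[n] for n in used}, spec) \
        if "artery" in used else None
    maps = {}
    for key in ("cbv", "cbf", "mtt", "ttp"):
        m = np.full((g, g), np.nan)
        if truth is not None:
            for name in used:
                m[label == CLASS_CODES[name]] = truth[name][key]
        maps[key] = m
    true_maps = PerfusionMaps(cbv=maps["cbv"], cbf=maps["cbf"],
                              mtt=maps["mtt"], ttp=maps["ttp"])

    return GroundTruth(label_map=label,
                       frames=DynamicImage(frames, spec.frame_interval_s),
                       true_maps=true_maps, spec=spec, kinetics=dict(kinetics))
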