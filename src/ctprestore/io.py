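"""Run container (HDF5) and image export helpers.

One hierarchical container file per run:

    /phantom/frames, /phantom/label_map, /phantom/true_maps/{cbv,cbf,mtt,ttp}
    /sinograms/<stage>/frame_###      (stage: clean, noisy, restored, weighted)
    /noise/variance_###
    /recon/<arm>/frames
    /perfusion/<arm>/{cbv,cbf,mtt,ttp}

Sinogram datasets carry their angles, domain and pixel size as attributes.
Frames export to multi-page TIFF; maps to TIFF plus pseudocolor PNG with a
fixed colormap and per-map ranges recorded in the run report metadata.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .perfusion import PerfusionMaps
from .phantom import DynamicImage, GroundTruth
from .projection import Sinogram

#: fixed colormaps for reproducible pseudocolor renders
MAP_COLORMAPS = {"cbv": "jet", "cbf": "jet", "mtt": "jet", "ttp": "jet"}


def save_ground_truth(f: h5py.Group, gt: GroundTruth) -> None:
    grp = f.require_group("phantom")
    grp.create_dataset("frames", data=gt.frames.frames)
    grp.create_dataset("label_map", data=gt.label_map)
    grp.attrs["frame_interval_s"] = gt.frames.frame_interval_s
    if gt.spec is not None:
        grp.attrs["grid_size"] = gt.spec.grid_size
        grp.attrs["frame_count"] = gt.spec.frame_count
        grp.attrs["seed"] = gt.spec.seed
    tm = grp.require_group("true_maps")
    for name, arr in gt.true_maps.as_dict().items():
        tm.create_dataset(name, data=arr)


def save_sinogram_stack(f: h5py.Group, stage: str,
                        sinograms: list[Sinogram]) -> None:
    grp = f.require_group(f"sinograms/{stage}")
    for s in sinograms:
        ds = grp.create_dataset(f"frame_{s.frame_index:03d}", data=s.values)
        ds.attrs["angles_deg"] = s.angles_deg
        ds.attrs["domain"] = s.domain
        ds.attrs["pixel_size"] = s.pixel_size
        ds.attrs["frame_index"] = s.frame_index


def load_sinogram_stack(f: h5py.Group, stage: str) -> list[Sinogram]:
    grp = f[f"sinograms/{stage}"]
    out = []
    for key in sorted(grp):
        ds = grp[key]
        out.append(Sinogram(values=ds[()], angles_deg=ds.attrs["angles_deg"],
                            domain=ds.attrs["domain"],
                            frame_index=int(ds.attrs["frame_index"]),
                            pixel_size=float(ds.attrs["pixel_size"])))
    return out


def save_variance_maps(f: h5py.Group, variances: list[np.ndarray]) -> None:
    grp = f.require_group("noise")
    for idx, var in enumerate(variances):
        grp.create_dataset(f"variance_{idx:03d}", data=var)


def load_variance_maps(f: h5py.Group) -> list[np.ndarray]:
    grp = f["noise"]
    return [grp[k][()] for k in sorted(grp)]


def save_recon(f: h5py.Group, arm: str, img: DynamicImage) -> None:
    grp = f.require_group(f"recon/{arm}")
    grp.create_dataset("frames", data=img.frames)
    grp.attrs["frame_interval_s"] = img.frame_interval_s


def load_recon(f: h5py.Group, arm: str) -> DynamicImage:
    grp = f[f"recon/{arm}"]
    return DynamicImage(grp["frames"][()], float(grp.attrs["frame_interval_s"]))


def save_maps(f: h5py.Group, arm: str, maps: PerfusionMaps) -> None:
    grp = f.require_group(f"perfusion/{arm}")
    for name, arr in maps.as_dict().items():
        grp.create_dataset(name, data=arr)


def load_maps(f: h5py.Group, arm: str) -> PerfusionMaps:
    grp = f[f"perfusion/{arm}"]
    return PerfusionMaps(**{name: grp[name][()] for name in PerfusionMaps.MAP_NAMES})


def export_tiff(frames: np.ndarray, path: str | Path) -> None:
    """Multi-page float TIFF export of a frame stack or single image."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))


def export_png(map2d: np.ndarray, path: str | Path, cmap: str = "jet",
               vmin: float | None = None, vmax: float | None = None
               ) -> dict[str, float]:
    """Pseudocolor PNG of a 2-D map; returns the value range rendered.

    NaN (invalid) pixels render black. The returned range belongs in run
    metadata so renders are reproducible.
    """
    import imageio.v3 as iio
    from matplotlib import colormaps

    arr = np.asarray(map2d, dtype=float)
    finite = np.isfinite(arr)
    lo = float(np.nanmin(arr)) if vmin is None else vmin
    hi = float(np.nanmax(arr)) if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((arr - lo) / span, 0.0, 1.0)
    rgba = colormaps[cmap](np.where(finite, norm, 0.0))
    rgba[~finite] = (0.0, 0.0, 0.0, 1.0)
    iio.imwrite(str(path), (rgba[..., :3] * 255).astype(np.uint8))
    return {"vmin": lo, "vmax": hi, "cmap": cmap}
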