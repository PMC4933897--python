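"""NIfTI / CSV / JSON serialisation of pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionMeta
from .synthetic import DynamicSeries, TruthPhantom
from .t1 import T1Map
from .tofts import ParameterMap

__all__ = [
    "save_map", "load_map", "save_series", "load_series",
    "save_phantom", "save_t1map", "save_parameter_map", "load_parameter_map",
    "save_table", "load_table",
]

_IDENTITY = np.eye(4)


def save_map(arr, path) -> None:
    """Write a 2-D/3-D/4-D array as NIfTI-1 (identity affine)."""
    nib.save(nib.Nifti1Image(np.asarray(arr, np.float64), _IDENTITY), str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_series(series: DynamicSeries, stem) -> None:
    """Dynamic frames + VFA stack as 4-D NIfTI, metadata as JSON sidecar."""
    stem = Path(stem)
    save_map(series.frames, stem.with_suffix(".dyn.nii"))
    save_map(series.vfa_signals, stem.with_suffix(".vfa.nii"))
    series.meta.to_json(stem.with_suffix(".json"))


def load_series(stem) -> DynamicSeries:
    stem = Path(stem)
    return DynamicSeries(
        frames=load_map(stem.with_suffix(".dyn.nii")),
        vfa_signals=load_map(stem.with_suffix(".vfa.nii")),
        meta=AcquisitionMeta.from_json(stem.with_suffix(".json")),
    )


def save_phantom(phantom: TruthPhantom, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("ktrans_map", "ve_map", "vp_map", "t10_map", "m0_map"):
        save_map(getattr(phantom, name), outdir / f"truth_{name}.nii")
    save_map(np.asarray(phantom.roi_mask, np.float64), outdir / "truth_roi_mask.nii")


def save_t1map(t1map: T1Map, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_map(t1map.t1, outdir / "t1.nii")
    save_map(t1map.m0, outdir / "m0.nii")
    save_map(np.asarray(t1map.success, np.float64), outdir / "t1_success.nii")


def save_parameter_map(pmap: ParameterMap, outdir) -> None:
    """One NIfTI per parameter plus a per-pixel CSV table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("ktrans", "ve", "vp", "kep", "rss"):
        save_map(getattr(pmap, name), outdir / f"{name}.nii")
    save_map(np.asarray(pmap.converged, np.float64), outdir / "converged.nii")
    ii, jj = np.nonzero(np.isfinite(pmap.ktrans))
    pd.DataFrame({
        "row": ii, "col": jj,
        "ktrans": pmap.ktrans[ii, jj], "ve": pmap.ve[ii, jj],
        "vp": pmap.vp[ii, jj], "kep": pmap.kep[ii, jj],
        "rss": pmap.rss[ii, jj], "converged": pmap.converged[ii, jj],
    }).to_csv(outdir / "parameters.csv", index=False)


def load_parameter_map(outdir) -> ParameterMap:
    outdir = Path(outdir)
    maps = {n: load_map(outdir / f"{n}.nii") for n in ("ktrans", "ve", "vp", "kep", "rss")}
    return ParameterMap(converged=load_map(outdir / "converged.nii").astype(bool), **maps)


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
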