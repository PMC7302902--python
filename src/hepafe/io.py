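"""Standard-format I/O: NIfTI image stacks with JSON sidecars, CSV tables.

Image stacks travel as a single NIfTI file (echoes/inversion times along the
last axis) plus a JSON sidecar carrying the acquisition metadata (TR, TE
list, flip angle, TI list, seed).  Rating tables and echo-series tables are
plain UTF-8 comma-separated CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .relaxometry import EchoSeries, T2StarMap
from .units import MG_PER_UMOL

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_t2s_map",
    "read_echo_series_csv",
    "write_ratings",
    "read_ratings",
    "write_report",
]

log = logging.getLogger("hepafe")


def write_image_stack(stack: np.ndarray, meta: dict, path: str | Path) -> Path:
    """Write an image stack as NIfTI (frames on the last axis) + JSON sidecar.

    ``path`` is the NIfTI filename (``.nii`` appended if absent); the sidecar
    shares the stem with a ``.json`` suffix.
    """
    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        path = path.with_suffix(".nii")
    data = np.moveaxis(np.asarray(stack, dtype=np.float64), 0, -1)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_image_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a NIfTI stack + sidecar; validates frame count against metadata."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar}: {exc}") from exc
    frames = meta.get("echo_times_ms") or meta.get("ti_ms")
    if frames is not None and len(frames) != data.shape[0]:
        raise ValueError(
            f"sidecar lists {len(frames)} frames but stack has {data.shape[0]}"
        )
    return data, meta


def write_t2s_map(t2s_map: T2StarMap, out_dir: str | Path) -> Path:
    """Write T2*/R2* maps and validity mask as NIfTI files + fit metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    nib.save(nib.Nifti1Image(t2s_map.t2star_ms.astype(np.float64), aff), str(out / "t2star_ms.nii"))
    nib.save(nib.Nifti1Image(t2s_map.r2star_hz.astype(np.float64), aff), str(out / "r2star_hz.nii"))
    nib.save(nib.Nifti1Image(t2s_map.valid.astype(np.uint8), aff), str(out / "valid.nii"))
    (out / "map_meta.json").write_text(json.dumps(t2s_map.meta, indent=2))
    return out


def read_echo_series_csv(path: str | Path) -> EchoSeries:
    """Read an ROI echo series from CSV columns ``te_ms`` and ``si``."""
    df = pd.read_csv(path)
    for col in ("te_ms", "si"):
        if col not in df.columns:
            raise ValueError(f"echo series CSV needs column {col!r}")
    floor = float(df["noise_floor"].iloc[0]) if "noise_floor" in df.columns else None
    return EchoSeries(tuple(df["te_ms"]), tuple(df["si"]), noise_floor=floor)


def write_ratings(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_ratings(path: str | Path, harmonize: bool = True) -> pd.DataFrame:
    """Read a rating table CSV; optionally harmonize LIC units to mg/g.

    Estimates carrying ``umol_per_g_dry`` units are converted to mg/g (the
    conversion is logged); non-LIC scales (e.g. R1 in Hz) pass through.
    """
    df = pd.read_csv(path)
    if "units" in df.columns and harmonize:
        known = {"mg_per_g_dry", "umol_per_g_dry", "hz"}
        unknown = set(df["units"].unique()) - known
        if unknown:
            raise ValueError(f"unknown units in ratings: {sorted(unknown)}")
        sel = df["units"] == "umol_per_g_dry"
        if sel.any():
            log.info("converting %d estimates from umol/g to mg/g", int(sel.sum()))
            df.loc[sel, "estimate"] = df.loc[sel, "estimate"] * MG_PER_UMOL
            df.loc[sel, "units"] = "mg_per_g_dry"
    return df


def write_report(report, out_dir: str | Path) -> Path:
    """Write a study report: tidy CSV tables plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.ratings.to_csv(out / "ratings.csv", index=False)
    report.agreement.to_csv(out / "agreement.csv", index=False)
    report.roc.to_csv(out / "roc.csv", index=False)
    report.auc_contrasts.to_csv(out / "auc_contrasts.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    (out / "report.json").write_text(json.dumps(report.summary_dict(), indent=2))
    return out
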