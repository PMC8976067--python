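"""Readers and writers for the pipeline's on-disk formats.

Decay stacks are multi-page TIFFs (one page per micro-time bin) with a JSON
metadata sidecar; phasor images are 3-plane float32 TIFFs (g, s, intensity)
plus a validity-mask TIFF; masks are 16-bit label TIFFs; tables are CSV;
pathway sets are GMT or two-column CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .btnr import RoiMeasurement
from .phasor import PhasorImage, PhasorPoint, TCSPCStack

__all__ = [
    "write_stack", "read_stack",
    "write_phasor", "read_phasor",
    "write_mask", "read_mask",
    "write_roi_csv", "read_roi_csv",
    "read_gmt", "read_pathway_csv",
]

ROI_COLUMNS = ["roi", "frame", "pixels", "photons", "g", "s", "btnr", "state",
               "centroid_y", "centroid_x"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: TCSPCStack, path: str | Path) -> None:
    path = Path(path)
    pages = np.moveaxis(stack.counts.astype(np.uint16), 2, 0)
    tifffile.imwrite(path, pages)
    meta = {
        "period_ns": stack.period_ns,
        "bin_width_ns": stack.bin_width_ns,
        "n_bins": stack.n_bins,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> TCSPCStack:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("period_ns", "bin_width_ns", "n_bins"):
        if key not in meta:
            raise KeyError(f"metadata sidecar {sidecar} missing key {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != meta["n_bins"]:
        raise ValueError(f"{path}: expected {meta['n_bins']} pages")
    return TCSPCStack(
        np.moveaxis(pages, 0, 2), meta["period_ns"], meta["bin_width_ns"]
    )


def write_phasor(image: PhasorImage, path: str | Path) -> None:
    path = Path(path)
    planes = np.stack(
        [image.g, image.s, image.intensity]
    ).astype(np.float32)
    tifffile.imwrite(path, planes, photometric="minisblack")
    tifffile.imwrite(
        path.with_name(path.stem + "_valid.tif"),
        image.valid.astype(np.uint8),
    )
    meta = {"omega": None if not np.isfinite(image.omega) else image.omega}
    _sidecar(path).write_text(json.dumps(meta))


def read_phasor(path: str | Path) -> PhasorImage:
    path = Path(path)
    planes = tifffile.imread(path).astype(np.float64)
    if planes.ndim != 3 or planes.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-plane (g, s, intensity) TIFF")
    valid = tifffile.imread(path.with_name(path.stem + "_valid.tif")).astype(bool)
    omega = np.nan
    sidecar = _sidecar(path)
    if sidecar.exists():
        om = json.loads(sidecar.read_text()).get("omega")
        omega = np.nan if om is None else float(om)
    return PhasorImage(planes[0], planes[1], planes[2], valid, omega)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)


def write_roi_csv(measurements: list[RoiMeasurement], path: str | Path) -> None:
    rows = [
        {
            "roi": m.roi, "frame": m.frame, "pixels": m.pixels,
            "photons": m.photons, "g": m.com.g, "s": m.com.s,
            "btnr": m.btnr, "state": m.state,
            "centroid_y": m.centroid[0], "centroid_x": m.centroid[1],
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, index=False)


def read_roi_csv(path: str | Path) -> list[RoiMeasurement]:
    df = pd.read_csv(path)
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return [
        RoiMeasurement(
            roi=int(r.roi), frame=int(r.frame), pixels=int(r.pixels),
            photons=float(r.photons), com=PhasorPoint(float(r.g), float(r.s)),
            btnr=float(r.btnr), state=str(r.state),
            centroid=(float(r.centroid_y), float(r.centroid_x)),
        )
        for r in df.itertuples()
    ]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT pathway sets: name <tab> description <tab> member...

    Lines with fewer than 2 members are skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        name, members = parts[0], [m for m in parts[2:] if m]
        if len(members) < 2:
            warnings.warn(f"GMT set {name!r} has < 2 members; skipped")
            continue
        sets[name] = members
    return sets


def read_pathway_csv(path: str | Path) -> dict[str, list[str]]:
    """Read two-column (pathway, metabolite) pathway sets."""
    df = pd.read_csv(path)
    for col in ("pathway", "metabolite"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return {
        name: sub["metabolite"].tolist()
        for name, sub in df.groupby("pathway")
    }
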