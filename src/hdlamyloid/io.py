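"""Plain-text I/O: TSV height maps with JSON sidecars, CSV time series.

Height maps travel as tab-separated numeric matrices (nm) next to a JSON
sidecar carrying at least ``pixel_size_nm``; coordinate models use standard
PDB (see :mod:`hdlamyloid.structure`); concentration and fluorescence time
series are CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import HeightMap, ThTTrace, TranswellExperiment


def _sidecar_path(map_path: str | Path) -> Path:
    p = Path(map_path)
    return p.with_suffix(p.suffix + ".json")


def write_heightmap(hmap: HeightMap, path: str | Path,
                    extra_meta: Optional[dict] = None) -> None:
    """Write a height map as TSV plus a JSON sidecar with its metadata."""
    path = Path(path)
    np.savetxt(path, hmap.heights, delimiter="\t", fmt="%.6g")
    meta = {"pixel_size_nm": hmap.pixel_size,
            "field_size_nm": list(hmap.field_size),
            "label": hmap.label}
    if hmap.time is not None:
        meta["time_h"] = hmap.time
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_heightmap(path: str | Path) -> HeightMap:
    """Read a TSV height map; pixel size and label come from the sidecar."""
    heights = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return HeightMap(heights, pixel_size=float(meta["pixel_size_nm"]),
                     label=meta.get("label", ""), time=meta.get("time_h"))


def write_transwell(exp: TranswellExperiment, csv_path: str | Path,
                    meta_path: str | Path) -> None:
    pd.DataFrame({"time_min": exp.times,
                  "receiver_conc": exp.receiver_conc}).to_csv(csv_path, index=False)
    meta = {"donor_volume_ml": exp.donor_volume,
            "receiver_volume_ml": exp.receiver_volume,
            "area_cm2": exp.area,
            "donor_conc0": exp.donor_conc0,
            "direction": exp.direction}
    if exp.teer is not None:
        meta["teer_ohm_cm2"] = exp.teer
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_transwell(csv_path: str | Path, meta_path: str | Path) -> TranswellExperiment:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(meta_path).read_text())
    return TranswellExperiment(
        donor_volume=float(meta["donor_volume_ml"]),
        receiver_volume=float(meta["receiver_volume_ml"]),
        area=float(meta["area_cm2"]),
        times=df["time_min"].to_numpy(),
        receiver_conc=df["receiver_conc"].to_numpy(),
        donor_conc0=float(meta["donor_conc0"]),
        direction=meta.get("direction", "b2a"),
        teer=meta.get("teer_ohm_cm2"))


def write_tht(trace: ThTTrace, path: str | Path) -> None:
    pd.DataFrame({"time_h": trace.times,
                  "intensity": trace.intensity}).to_csv(path, index=False)


def read_tht(path: str | Path) -> ThTTrace:
    df = pd.read_csv(path)
    return ThTTrace(df["time_h"].to_numpy(), df["intensity"].to_numpy())
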