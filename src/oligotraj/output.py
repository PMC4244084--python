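"""Tabular result output: TSV with a one-line header plus a JSON metadata
sidecar carrying the run configuration, its hash and the package version."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import SpeciesTimeSeries
from .contactmaps import ContactProbabilityMap
from .kinetics import SurvivalCurve
from .landscape import PMFGrid

__all__ = [
    "config_hash",
    "write_tsv",
    "species_frame",
    "survival_frame",
    "pmf_frame",
    "map_frame",
]


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_tsv(df: pd.DataFrame, path: str | Path,
              metadata: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = dict(metadata or {})
    meta.setdefault("version", __version__)
    if "config" in meta:
        meta.setdefault("config_hash", config_hash(meta["config"]))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")


def species_frame(series: SpeciesTimeSeries) -> pd.DataFrame:
    df = series.table.reset_index(drop=True).copy()
    df.insert(0, "bin_start_ns", series.bin_edges[:-1])
    df.insert(1, "bin_end_ns", series.bin_edges[1:])
    df.insert(2, "n_frames", series.n_frames)
    return df


def survival_frame(curve: SurvivalCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "lag_ns": curve.lags,
        "S": curve.S,
        "S_normalized": curve.S_normalized,
        "n_origins": curve.n_origins,
    })


def pmf_frame(grid: PMFGrid) -> pd.DataFrame:
    xs, ys = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    return pd.DataFrame({
        "inhibitor_contacts": xs.ravel(),
        "interpeptide_contacts": ys.ravel(),
        "P": grid.P.ravel(),
        "W_kcal_mol": grid.W.ravel(),
        "masked": grid.mask.ravel().astype(int),
    })


def map_frame(cmap: ContactProbabilityMap) -> pd.DataFrame:
    rows = []
    for i, rl in enumerate(cmap.row_labels):
        for j, cl in enumerate(cmap.col_labels):
            rows.append((rl, cl, cmap.probability[i, j], cmap.counts[i, j]))
    return pd.DataFrame(rows, columns=["row", "col", "probability", "n"])
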