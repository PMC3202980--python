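"""Readers and writers for plate tables, parameter files, and results.

The canonical data format is a CSV plate table with header-keyed columns
receptor / mixture_id / point_index / replicate / plate / log10_total_conc /
intensity — one row per normalized fluorescence measurement.  (Supplementary
spreadsheets of normalized intensities map onto this layout one sheet row
per well; the CSV is the package's canonical form.)  Array parameters and
inference results are JSON.  All logging goes to stderr so that stdout
stays pipeline-safe.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import PriorSpec, SamplerSettings
from .model import (
    ArrayParams,
    DATA_COLUMNS,
    DilutionSeries,
    ModelConstants,
    ResponseDataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_plate_table",
    "write_plate_table",
    "read_params",
    "write_params",
    "write_results",
    "load_run_config",
]


def read_plate_table(path, const: ModelConstants | None = None) -> ResponseDataset:
    """Load a plate-table CSV into a validated ResponseDataset.

    Columns are matched by header name, so column order is free.  Rows with
    non-numeric or missing intensity are rejected with their row numbers.
    Per-receptor dilution series are reconstructed from log10_total_conc
    (the nominal ladder); decoding treats only the increments as known and
    infers the absolute anchor.  A plate whose maximum intensity is far from
    1 draws a normalization warning, not an error.
    """
    const = const or ModelConstants()
    df = pd.read_csv(path)
    missing = [c for c in DATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[DATA_COLUMNS].copy()
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = intensity.isna() | ~np.isfinite(intensity)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:5]]  # 1-based incl. header
        raise ValueError(f"{path}: non-numeric intensity at file rows {rows}")
    df["intensity"] = intensity

    for plate, sub in df.groupby("plate"):
        peak = sub["intensity"].max()
        if abs(peak - 1.0) > 0.25:
            logger.warning("plate %r: max intensity %.3f far from 1; "
                           "check per-plate normalization", plate, peak)

    series: dict[str, DilutionSeries] = {}
    for r, sub in df.groupby("receptor"):
        pts = sub.drop_duplicates("point_index").sort_values("point_index")
        log10c = pts["log10_total_conc"].to_numpy(dtype=float)
        if np.isfinite(log10c).all():
            series[r] = DilutionSeries.from_log10_concentrations(log10c, const)
        else:
            raise ValueError(
                f"{path}: receptor {r!r} lacks a complete log10_total_conc ladder")
    return ResponseDataset(df, series)


def write_plate_table(dataset: ResponseDataset, path) -> None:
    dataset.df.to_csv(path, index=False)


def read_params(path) -> ArrayParams:
    with open(path) as fh:
        return ArrayParams.from_dict(json.load(fh))


def write_params(params: ArrayParams, path, stds: dict | None = None) -> None:
    doc = params.to_dict()
    if stds:
        doc["stds"] = stds
    doc["software"] = {"name": "arraysense", "version": __version__}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def write_results(result, path, seed: int | None = None, extra: dict | None = None) -> None:
    """Write an inference/design result as schema-stable JSON (no timestamps)."""
    doc = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    doc["software"] = {"name": "arraysense", "version": __version__}
    if seed is not None:
        doc["seed"] = int(seed)
    if extra:
        doc.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def load_run_config(path) -> dict:
    """Load a YAML run config with optional priors / sampler / model sections."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = dict(cfg)
    if "priors" in cfg:
        out["priors"] = PriorSpec.from_dict(cfg["priors"])
    if "sampler" in cfg:
        out["sampler"] = SamplerSettings(**cfg["sampler"])
    if "model" in cfg:
        out["model"] = ModelConstants(**cfg["model"])
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    return out
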