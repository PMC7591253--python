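"""Readers and writers for the pipeline's plain-text formats.

All formats are UTF-8 CSV/TSV with required headers; lines starting with
``#`` are comments (writers record the simulation seed there when known).
Every reader validates its container's invariants and raises
:class:`~curlquant.de.ValidationError` with located messages; every
reader/writer pair is a round-trip identity on valid data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import CellActivity, PopulationComparison, TraceSet
from .de import CountExperiment, DeReport, ValidationError
from .morphometry import ClutchCounts, LandmarkSet
from .qpcr import CtTable

__all__ = [
    "read_clutches",
    "read_counts",
    "read_ct",
    "read_landmarks",
    "read_traces",
    "write_activities",
    "write_clutches",
    "write_comparison",
    "write_counts",
    "write_ct",
    "write_landmarks",
    "write_report",
    "write_traces",
]


def _read_table(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValidationError(f"{path}: blank or NaN cells (first offending rows: {rows})")
    return df


def _seed_header(seed: int | None) -> str:
    return f"# seed={seed}\n" if seed is not None else ""


# --- counts ---------------------------------------------------------------


def read_counts(counts_path, sheet_path) -> CountExperiment:
    """Read a gene x sample count TSV and its sample-sheet CSV."""
    counts = _read_table(counts_path, sep="\t")
    gene_col = counts.columns[0]
    counts = counts.set_index(gene_col)
    counts.index.name = "gene"
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.allclose(
        vals, np.rint(vals), atol=0
    ):
        bad = np.argwhere(vals != np.rint(vals))
        loc = (
            f" at gene {counts.index[bad[0][0]]!r}, sample {counts.columns[bad[0][1]]!r}"
            if len(bad)
            else ""
        )
        raise ValidationError(f"{counts_path}: non-integer count{loc}")
    sheet = _read_table(sheet_path, sep=",").set_index("sample")
    return CountExperiment(counts=counts.astype(np.int64), sheet=sheet)


def write_counts(experiment: CountExperiment, counts_path, sheet_path, seed=None) -> None:
    with open(counts_path, "w") as fh:
        fh.write(_seed_header(seed))
        experiment.counts.to_csv(fh, sep="\t")
    with open(sheet_path, "w") as fh:
        fh.write(_seed_header(seed))
        experiment.sheet.to_csv(fh, index_label="sample")


def write_report(report: DeReport, path) -> None:
    """Write the ranked DE table as TSV with a provenance comment header."""
    with open(path, "w") as fh:
        cfg = report.config
        fh.write(
            f"# q={cfg.q} fc_down={cfg.fc_down} fc_up={cfg.fc_up} "
            f"min_cpm={cfg.min_cpm} reliable_k={cfg.reliable_k}\n"
        )
        if report.dropped_replicates:
            fh.write(f"# dropped_replicates={','.join(report.dropped_replicates)}\n")
        report.table.to_csv(fh, sep="\t")


# --- traces ---------------------------------------------------------------


def read_traces(path, meta_path) -> TraceSet:
    """Read a trace CSV (``time_s`` column plus one column per ROI) and ROI metadata."""
    df = _read_table(path, sep=",")
    if "time_s" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'time_s'")
    df = df.set_index("time_s")
    meta = _read_table(meta_path, sep=",").set_index("roi")
    return TraceSet(traces=df, roi_meta=meta)


def write_traces(traceset: TraceSet, path, meta_path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_seed_header(seed))
        traceset.traces.to_csv(fh)
    with open(meta_path, "w") as fh:
        fh.write(_seed_header(seed))
        traceset.roi_meta.to_csv(fh)


def write_activities(activities: list[CellActivity], path) -> None:
    pd.DataFrame(
        [
            {"roi": a.roi, "group": a.group, "integral_per_min": a.integral_per_min}
            for a in activities
        ]
    ).to_csv(path, index=False)


def write_comparison(cmp: PopulationComparison, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(cmp), fh, indent=2)
        fh.write("\n")


# --- qPCR -----------------------------------------------------------------


def read_ct(path) -> CtTable:
    df = _read_table(path, sep=",")
    return CtTable(df)


def write_ct(table: CtTable, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_seed_header(seed))
        table.data.to_csv(fh, index=False)


# --- landmarks ------------------------------------------------------------

_LANDMARK_COLS = ["embryo", "group", "ear_x", "ear_y", "yolk_x", "yolk_y", "tail_x", "tail_y"]


def read_landmarks(path) -> list[LandmarkSet]:
    df = _read_table(path, sep=",")
    missing = set(_LANDMARK_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: landmark CSV missing columns {sorted(missing)}")
    return [
        LandmarkSet(
            embryo=str(r["embryo"]),
            group=str(r["group"]),
            ear=(float(r["ear_x"]), float(r["ear_y"])),
            yolk_vertex=(float(r["yolk_x"]), float(r["yolk_y"])),
            tail_tip=(float(r["tail_x"]), float(r["tail_y"])),
        )
        for _, r in df.iterrows()
    ]


def write_landmarks(landmarks: list[LandmarkSet], path, seed=None) -> None:
    rows = [
        {
            "embryo": lm.embryo,
            "group": lm.group,
            "ear_x": lm.ear[0],
            "ear_y": lm.ear[1],
            "yolk_x": lm.yolk_vertex[0],
            "yolk_y": lm.yolk_vertex[1],
            "tail_x": lm.tail_tip[0],
            "tail_y": lm.tail_tip[1],
        }
        for lm in landmarks
    ]
    with open(path, "w") as fh:
        fh.write(_seed_header(seed))
        pd.DataFrame(rows, columns=_LANDMARK_COLS).to_csv(fh, index=False)


# --- clutches -------------------------------------------------------------


def read_clutches(path) -> list[ClutchCounts]:
    df = _read_table(path, sep=",")
    missing = {"clutch", "treatment", "n_curled", "n_total"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: clutch CSV missing columns {sorted(missing)}")
    return [
        ClutchCounts(
            clutch=str(r["clutch"]),
            treatment=str(r["treatment"]),
            n_curled=int(r["n_curled"]),
            n_total=int(r["n_total"]),
        )
        for _, r in df.iterrows()
    ]


def write_clutches(counts: list[ClutchCounts], path, seed=None) -> None:
    rows = [
        {
            "clutch": c.clutch,
            "treatment": c.treatment,
            "n_curled": c.n_curled,
            "n_total": c.n_total,
        }
        for c in counts
    ]
    with open(path, "w") as fh:
        fh.write(_seed_header(seed))
        pd.DataFrame(rows).to_csv(fh, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
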