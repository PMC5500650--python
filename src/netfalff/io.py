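"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: gzip-compressed delimited matrices with JSON
sidecars (shape, tr, stage tags), whitespace 6-column motion files, TSV
cohort/QC/result tables, and TSV template matrices with a one-line label
header.  Numeric formatting is fixed so reruns under the same seed are
byte-identical.
"""
from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .types import ICNTemplateSet, MotionTrace, QCRecord, VertexTimeSeries

__all__ = [
    "save_scan",
    "load_scan",
    "save_motion",
    "load_motion",
    "MOTION_PRESETS",
    "save_cohort",
    "load_cohort",
    "save_templates",
    "load_templates",
    "save_table",
    "qc_records_to_table",
]

FLOAT_FMT = "%.10g"

# column orders for motion-file dialects: values are the permutation taking
# file columns to the internal order (tx ty tz rx ry rz)
MOTION_PRESETS = {
    "translations-first-mm-then-radians": [0, 1, 2, 3, 4, 5],
    "rotations-first-radians-then-mm": [3, 4, 5, 0, 1, 2],
}


def save_scan(path: str | Path, ts: VertexTimeSeries) -> None:
    """Write a scan as gzip TSV (rows = time points, columns = vertices)
    with a JSON sidecar recording tr, subject and stage tags."""
    path = Path(path)
    with gzip.open(path, "wt") as fh:
        np.savetxt(fh, ts.data, fmt=FLOAT_FMT, delimiter="\t")
    sidecar = {
        "n_timepoints": ts.n_timepoints,
        "n_vertices": ts.n_vertices,
        "tr": ts.tr,
        "subject_id": ts.subject_id,
        "stage_tag": list(ts.stage_tag),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_scan(path: str | Path) -> VertexTimeSeries:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    with gzip.open(path, "rt") as fh:
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape != (meta["n_timepoints"], meta["n_vertices"]):
        raise DataError(
            f"scan {path} has shape {data.shape}, sidecar says "
            f"({meta['n_timepoints']}, {meta['n_vertices']})"
        )
    return VertexTimeSeries(
        data,
        tr=meta["tr"],
        subject_id=meta.get("subject_id", "subject"),
        stage_tag=tuple(meta.get("stage_tag", ())),
    )


def save_motion(path: str | Path, motion: MotionTrace) -> None:
    """Whitespace-delimited T x 6 motion file, translations (mm) first then
    rotations (radians)."""
    np.savetxt(path, motion.params, fmt=FLOAT_FMT)


def load_motion(
    path: str | Path, preset: str = "translations-first-mm-then-radians"
) -> MotionTrace:
    if preset not in MOTION_PRESETS:
        raise ConfigError(
            f"unknown motion dialect {preset!r}; expected one of {sorted(MOTION_PRESETS)} "
            "(T rows x 6 whitespace-separated columns)"
        )
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape[1] != 6:
        raise DataError(f"motion file {path} has {raw.shape[1]} columns, expected 6")
    perm = MOTION_PRESETS[preset]
    return MotionTrace(raw[:, perm])


COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "tcc_years",
    "tcc_hours_per_week",
    "conflict_rt",
    "conflict_acc",
]


def save_cohort(path: str | Path, table: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"cohort table missing columns {missing}")
    table[COHORT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"cohort file {path} missing columns {missing}")
    return table


def save_templates(
    path: str | Path, templates: ICNTemplateSet, config_hash: str | None = None
) -> None:
    """V x K delimited matrix with a one-line label header (and an optional
    leading comment carrying the run's config hash)."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write("\t".join(templates.labels) + "\n")
        np.savetxt(fh, templates.maps, fmt=FLOAT_FMT, delimiter="\t")


def load_templates(path: str | Path) -> ICNTemplateSet:
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
        labels = tuple(header.strip().split("\t"))
        maps = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if maps.shape[1] != len(labels):
        raise DataError(
            f"template file {path}: {len(labels)} labels for {maps.shape[1]} columns"
        )
    return ICNTemplateSet(maps=maps, labels=labels)


def save_table(
    path: str | Path, table: pd.DataFrame, comment_lines: list[str] | None = None
) -> None:
    """TSV writer with optional '#' comment header lines (config hash etc.)
    and fixed float formatting for bit-stable reruns."""
    with open(path, "w") as fh:
        for line in comment_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def qc_records_to_table(records: list[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "max_tran": r.max_tran,
                "max_rot": r.max_rot,
                "mean_fd": r.mean_fd,
                "rms_fd": r.rms_fd,
                "pass": r.passed,
            }
            for r in records
        ]
    )
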