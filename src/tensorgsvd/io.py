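"""Readers and writers for the tab-delimited profile, annotation and clinical formats.

Profile tables are probes x patients matrices, one file per platform, with a
header row of patient identifiers and the probe identifier as the first
column.  The annotation table maps probes to chromosome arms and genomic
positions; the clinical table carries patient_id, time_months, event and
optional covariates.  All writes are deterministic with floats at 17
significant digits, so every numeric round trip is lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .tensor import ThirdOrderTensor

__all__ = [
    "read_tensor",
    "read_profile",
    "write_profile",
    "read_clinical",
    "write_clinical",
    "read_annotation",
    "write_segments_bed",
    "write_classification",
]

log = logging.getLogger("tensorgsvd")

_FLOAT_FMT = "%.17g"


def write_profile(path, matrix, probe_ids, patient_ids) -> None:
    """Write a probes x patients profile table."""
    df = pd.DataFrame(np.asarray(matrix, dtype=float), index=list(probe_ids), columns=list(patient_ids))
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_profile(path) -> pd.DataFrame:
    """Read a profile table; rejects duplicate probes and missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id '{dup}'")
    if df.isna().any().any():
        raise ValueError(f"{path}: profile contains missing values")
    return df


def drop_incomplete_probes(df: pd.DataFrame) -> pd.DataFrame:
    """Remove probes with any missing entry (logged), for pre-cleaning."""
    bad = df.isna().any(axis=1)
    if bad.any():
        log.info("dropping %d probes with missing values", int(bad.sum()))
    return df.loc[~bad]


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "arm": str})
    required = {"probe_id", "arm", "position"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {sorted(missing)}")
    return ann


def read_tensor(profile_paths, annotation_path=None, arms=None, platform_ids=None) -> ThirdOrderTensor:
    """Assemble a tensor from one profile table per platform.

    Patient columns must agree (same ids, same order) across platforms.  With
    an annotation and an arm selection (e.g. ``["6p", "12p"]``), probes are
    restricted to the selected arms, concatenated in the requested order with
    positions ascending within each arm.  Verifies K >= L*M.
    """
    tables = [read_profile(p) for p in profile_paths]
    ref = tables[0]
    for path, tab in zip(profile_paths[1:], tables[1:]):
        if list(tab.columns) != list(ref.columns):
            for j, (a, b) in enumerate(zip(ref.columns, tab.columns)):
                if a != b:
                    raise ValueError(
                        f"{path}: patient column {j + 1} is '{b}', expected '{a}'"
                    )
            raise ValueError(f"{path}: patient columns differ in number")
        if list(tab.index) != list(ref.index):
            raise ValueError(f"{path}: probe rows differ from {profile_paths[0]}")

    probe_ids = list(ref.index)
    if arms:
        if annotation_path is None:
            raise ValueError("arm selection requires an annotation table")
        ann = read_annotation(annotation_path)
        selected = []
        for arm in arms:
            sub = ann[ann["arm"] == arm].sort_values("position", kind="stable")
            if sub.empty:
                raise ValueError(f"arm '{arm}' not present in {annotation_path}")
            selected.extend(sub["probe_id"].tolist())
        missing = [p for p in selected if p not in ref.index]
        if missing:
            raise ValueError(f"annotation probe '{missing[0]}' absent from profiles")
        tables = [t.loc[selected] for t in tables]
        probe_ids = selected

    values = np.stack([t.to_numpy(dtype=float) for t in tables], axis=2)
    k, l, m = values.shape
    if k < l * m:
        raise ValueError(f"K = {k} probes < L*M = {l * m}; tensor GSVD precondition violated")
    if platform_ids is None:
        platform_ids = [f"platform{j + 1}" for j in range(m)]
    return ThirdOrderTensor(
        values, probe_ids=probe_ids, patient_ids=list(ref.columns), platform_ids=platform_ids
    )


def write_clinical(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table, validating times and events row by row."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"patient_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table lacks columns {sorted(missing)}")
    times = pd.to_numeric(df["time_months"], errors="coerce")
    bad = times.isna() | (times < 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: invalid survival time at line {line}")
    events = pd.to_numeric(df["event"], errors="coerce")
    bad = events.isna() | ~events.isin([0, 1])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: event indicator must be 0/1 (line {line})")
    optional = [c for c in ("stage", "grade", "therapy") if c not in df.columns]
    if optional:
        log.info("clinical table lacks optional fields: %s", ", ".join(optional))
    df["time_months"] = times
    df["event"] = events.astype(int)
    return df


def write_segments_bed(path, segments, positions, chromosome: str = ".") -> None:
    """Write called segments as a BED-like table.

    ``positions`` are the 1-based genomic positions of the probes underlying
    the segmented arraylet; BED coordinates are 0-based half-open
    (start = first probe position - 1, end = last probe position).
    """
    positions = np.asarray(positions)
    rows = []
    for s in segments:
        rows.append(
            {
                "chrom": chromosome,
                "start": int(positions[s.start_probe - 1]) - 1,
                "end": int(positions[s.end_probe - 1]),
                "n_probes": s.n_probes,
                "mean_level": s.mean_level,
                "call": s.call,
                "focal": s.focal,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_classification(path, result, groups=None) -> None:
    """Write per-patient scores and labels (optionally with A/B/C groups)."""
    df = result.to_frame()
    if groups is not None:
        df["group"] = list(groups)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
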