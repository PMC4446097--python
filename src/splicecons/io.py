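"""TSV/JSON file formats for every pipeline artifact.

All tables are plain tab-separated text with a header row; identifiers are
opaque strings.  Malformed files are rejected with diagnostics naming the
offending row/column.  Result JSON carries a ``schema_version`` field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventCallSet, EventCountSummary
from .exceptions import ValidationError
from .firma import FirmaScoreMatrix, ProbeIntensityMatrix

__all__ = [
    "SCHEMA_VERSION",
    "write_probe_matrix",
    "read_probe_matrix",
    "write_groups",
    "read_groups",
    "write_scores",
    "read_scores",
    "write_callsets",
    "read_callsets",
    "write_results_json",
    "read_results_json",
]

SCHEMA_VERSION = 1

_ANNOT_COLS = ["probe_id", "transcript_id", "exon_id"]


def write_probe_matrix(matrix: ProbeIntensityMatrix, path) -> None:
    ann = matrix.annotation.loc[matrix.values.index]
    out = pd.concat(
        [ann[["transcript_id", "exon_id"]], matrix.values], axis=1
    )
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_probe_matrix(path, log2_scale: bool = False) -> ProbeIntensityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing!r}")
    df = df.set_index("probe_id")
    sample_cols = [c for c in df.columns if c not in ("transcript_id", "exon_id")]
    if not sample_cols:
        raise ValidationError(f"{path.name}: no sample columns")
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path.name}: non-numeric intensity at row {i + 2} "
            f"(probe {values.index[i]!r}), column {sample_cols[j]!r}"
        )
    if not log2_scale:
        nonpos = values.to_numpy() <= 0
        if nonpos.any():
            i, j = np.argwhere(nonpos)[0]
            raise ValidationError(
                f"{path.name}: non-positive intensity at row {i + 2} "
                f"(probe {values.index[i]!r}), column {sample_cols[j]!r}"
            )
    return ProbeIntensityMatrix(
        values, df[["transcript_id", "exon_id"]], log2_scale=log2_scale
    )


def write_groups(groups: pd.Series, path) -> None:
    groups.rename("group").rename_axis("sample_id").to_csv(path, sep="\t")


def read_groups(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path.name}: duplicate sample id {dup!r}")
    return df.set_index("sample_id")["group"]


def write_scores(scores: FirmaScoreMatrix, path) -> None:
    scores.scores.to_csv(path, sep="\t", float_format="%.17g")


def read_scores(path) -> FirmaScoreMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    for col in ("transcript_id", "exon_id"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing column {col!r}")
    df = df.set_index(["transcript_id", "exon_id"])
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        i, j = np.argwhere(vals.isna().to_numpy())[0]
        raise ValidationError(
            f"{path.name}: non-numeric score at row {i + 2}, column {df.columns[j]!r}"
        )
    return FirmaScoreMatrix(vals)


def write_callsets(callsets: list[EventCallSet], path) -> None:
    rows = []
    for cs in callsets:
        for (t, e, direction), score in sorted(cs.events.items()):
            rows.append((cs.sample_id, t, e, direction, score))
    pd.DataFrame(
        rows, columns=["sample_id", "transcript_id", "exon_id", "direction", "score"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_callsets(path, known_samples=None) -> list[EventCallSet]:
    """Read calls; ``known_samples`` (e.g. the group map's ids) enables the
    referential check that every call belongs to a known sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"score": float})
    needed = ["sample_id", "transcript_id", "exon_id", "direction", "score"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing!r}")
    bad_dir = ~df["direction"].isin(["inclusion", "exclusion"])
    if bad_dir.any():
        i = int(np.flatnonzero(bad_dir)[0])
        raise ValidationError(
            f"{path.name}: row {i + 2}: unknown direction {df['direction'].iloc[i]!r}"
        )
    if known_samples is not None:
        unknown = set(df["sample_id"]) - set(known_samples)
        if unknown:
            raise ValidationError(
                f"{path.name}: unknown sample ids {sorted(unknown)[:5]!r}"
            )
        sample_ids = list(known_samples)
    else:
        sample_ids = list(dict.fromkeys(df["sample_id"]))
    callsets = {s: EventCallSet(str(s)) for s in sample_ids}
    for row in df.itertuples(index=False):
        callsets[row.sample_id].events[
            (str(row.transcript_id), str(row.exon_id), str(row.direction))
        ] = float(row.score)
    return list(callsets.values())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, EventCountSummary):
        return _jsonable(
            {
                "group": obj.group,
                "direction": obj.direction,
                "n": len(obj.counts),
                "counts": obj.counts,
                "median": obj.median,
                "ci": [obj.ci_low, obj.ci_high],
                "p_value": obj.p_value,
            }
        )
    return obj


def write_results_json(payload: dict, path) -> None:
    body = {"schema_version": SCHEMA_VERSION}
    body.update(_jsonable(payload))
    with open(path, "w") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results_json(path) -> dict:
    with open(path) as fh:
        body = json.load(fh)
    if body.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema_version {body.get('schema_version')!r}"
        )
    return body
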