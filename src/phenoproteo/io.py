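"""Readers and writers for the pipeline's tabular formats.

Wide TSV matrices (samples as rows), CSV clinical/survival tables, CSV
phenogroup assignments with a JSON provenance sidecar, and a minimal
ADAT-like text dialect (caret-prefixed header block, tab-separated body)
sufficient for round-tripping this tool's own output.

All readers reject malformed input rather than coercing it; there is no
silent NA-filling.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MatrixFormatError, MatrixValidationError, ProteinMatrix


def _check_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Parse all cells as floats; name the first offending cell on failure."""
    try:
        return df.astype(float)
    except (ValueError, TypeError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if df[col].isna().any():
                row = df.index[df[col].isna()][0]
                raise MatrixFormatError(
                    f"{path}: missing value at row {row!r}, column {col!r}"
                )
            if bad.any():
                row = df.index[bad][0]
                raise MatrixFormatError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
        raise


def read_matrix(
    path: str | Path,
    dialect: str = "tsv_wide",
    transform_state: str = "raw",
    feature_meta: pd.DataFrame | None = None,
) -> ProteinMatrix:
    """Read a samples x features matrix.

    ``tsv_wide``: header row of feature IDs, first column sample IDs.
    ``adat_like``: the same body preceded by ``^key\\tvalue`` header lines.
    """
    path = Path(path)
    if dialect not in ("tsv_wide", "adat_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header_meta: dict[str, str] = {}
    if dialect == "adat_like":
        lines = path.read_text().splitlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("^"):
                key, _, val = line[1:].partition("\t")
                header_meta[key] = val
                body_start = i + 1
            else:
                break
        from io import StringIO

        raw = pd.read_csv(
            StringIO("\n".join(lines[body_start:])), sep="\t", index_col=0, dtype=str
        )
        if "TransformState" in header_meta:
            transform_state = header_meta["TransformState"]
    else:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)

    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise MatrixFormatError(f"{path}: duplicate sample ID {dup!r}")
    # pandas auto-renames duplicate headers, so detect them from the raw header
    dup_cols = _duplicated_header_names(path, dialect)
    if dup_cols:
        raise MatrixFormatError(f"{path}: duplicate feature ID {dup_cols[0]!r}")
    values = _check_numeric(raw, str(path))
    values.index = values.index.astype(str)
    values.index.name = "sample_id"
    try:
        return ProteinMatrix(
            values=values,
            feature_meta=feature_meta,
            transform_state=transform_state,
        )
    except MatrixValidationError:
        raise


def _duplicated_header_names(path: Path, dialect: str) -> list[str]:
    with open(path) as fh:
        for line in fh:
            if dialect == "adat_like" and line.startswith("^"):
                continue
            names = line.rstrip("\n").split("\t")[1:]
            seen: set[str] = set()
            dups = []
            for n in names:
                if n in seen:
                    dups.append(n)
                seen.add(n)
            return dups
    return []


def write_matrix(
    matrix: ProteinMatrix, path: str | Path, dialect: str = "tsv_wide"
) -> None:
    """Write a matrix in the named dialect, preserving row/column order."""
    path = Path(path)
    body = matrix.values.to_csv(sep="\t", index_label="sample_id")
    if dialect == "tsv_wide":
        path.write_text(body)
    elif dialect == "adat_like":
        header = (
            f"^FileFormat\tphenoproteo-adat-like-1\n"
            f"^TransformState\t{matrix.transform_state}\n"
            f"^NSamples\t{matrix.n_samples}\n"
            f"^NFeatures\t{matrix.n_features}\n"
        )
        path.write_text(header + body)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def feature_set_hash(feature_ids: list[str]) -> str:
    """Stable short hash of an ordered feature-ID list, for provenance."""
    h = hashlib.sha256("\n".join(feature_ids).encode())
    return h.hexdigest()[:16]


def write_assignment(assignment, path: str | Path) -> None:
    """Write a phenogroup assignment as CSV plus a JSON provenance sidecar.

    Labels are written 1-based (phenogroup 1 is the largest group by
    convention). The sidecar records the feature-set hash, seed, and
    pipeline parameters carried in ``assignment.provenance``.
    """
    path = Path(path)
    labels = assignment.labels
    if len(labels) == 0:
        raise ValueError("empty assignment")
    df = pd.DataFrame(
        {"sample_id": labels.index, "phenogroup": labels.to_numpy(dtype=int)}
    )
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"k": int(assignment.k), "provenance": _jsonable(assignment.provenance)},
            fh,
            indent=2,
        )


def read_assignment(path: str | Path):
    """Read an assignment CSV (and sidecar if present) back into memory."""
    from .cluster import PhenogroupAssignment

    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "phenogroup": int})
    labels = pd.Series(
        df["phenogroup"].to_numpy(), index=df["sample_id"], name="phenogroup"
    )
    provenance: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", {})
    return PhenogroupAssignment(
        labels=labels, k=int(labels.nunique()), provenance=provenance
    )


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical covariate CSV keyed by ``sample_id``."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise MatrixFormatError(f"{path}: missing sample_id column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MatrixFormatError(f"{path}: duplicate sample_id {dup!r}")
    return df


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival CSV with columns sample_id, time_years, event."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "time_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise MatrixFormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["time_years"] <= 0).any():
        raise MatrixValidationError(f"{path}: nonpositive survival time")
    if not df["event"].isin([0, 1]).all():
        raise MatrixValidationError(f"{path}: event must be 0/1")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
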