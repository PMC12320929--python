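"""Central matrix container for aptamer-style protein abundance data.

The :class:`ProteinMatrix` holds a samples x features table of positive
abundances (relative fluorescence units or similar), together with feature
metadata, per-sample QC flags, and a record of which transform has been
applied.  All pipeline stages consume and produce this type; alignment with
clinical and survival tables is always by sample ID, never by row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Allowed transform states, in pipeline order.
TRANSFORM_STATES = ("raw", "log2", "standardized")


class MatrixFormatError(ValueError):
    """Malformed or inconsistent matrix input (duplicates, non-numeric cells)."""


class MatrixValidationError(ValueError):
    """Structurally valid input violating a domain invariant (e.g. nonpositive RFU)."""


@dataclass
class ProteinMatrix:
    """Samples x features abundance matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample ID with feature IDs as columns. Strictly
        positive when ``transform_state == "raw"``.
    feature_meta
        Optional DataFrame indexed by feature ID; a ``target_name`` column is
        conventional but not required.
    sample_flags
        Mapping of sample ID -> QC flag string for flagged samples.
    transform_state
        One of ``"raw"``, ``"log2"``, ``"standardized"``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    sample_flags: dict[str, str] = field(default_factory=dict)
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        """Check container invariants; raise on violation."""
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample ID: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise MatrixFormatError(f"duplicate feature ID: {dup!r}")
        if self.transform_state not in TRANSFORM_STATES:
            raise MatrixValidationError(
                f"unknown transform_state {self.transform_state!r}"
            )
        arr = self.values.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise MatrixFormatError("matrix values must be numeric")
            if not np.all(np.isfinite(arr)):
                i, j = np.argwhere(~np.isfinite(arr))[0]
                raise MatrixValidationError(
                    f"non-finite value at sample {idx[i]!r}, feature {cols[j]!r}"
                )
            if self.transform_state == "raw" and not np.all(arr > 0):
                i, j = np.argwhere(arr <= 0)[0]
                raise MatrixValidationError(
                    f"nonpositive raw abundance at sample {idx[i]!r}, "
                    f"feature {cols[j]!r}"
                )

    # ------------------------------------------------------------------ #

    def subset_samples(self, sample_ids: Iterable[str]) -> "ProteinMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order given)."""
        ids = list(sample_ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown sample IDs: {sorted(missing)[:5]}")
        return ProteinMatrix(
            values=self.values.loc[ids].copy(),
            feature_meta=self.feature_meta,
            sample_flags={s: f for s, f in self.sample_flags.items() if s in set(ids)},
            transform_state=self.transform_state,
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "ProteinMatrix":
        """Return a new matrix restricted to ``feature_ids`` (order given)."""
        ids = list(feature_ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown feature IDs: {sorted(missing)[:5]}")
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.loc[
                [f for f in ids if f in self.feature_meta.index]
            ]
        return ProteinMatrix(
            values=self.values[ids].copy(),
            feature_meta=meta,
            sample_flags=dict(self.sample_flags),
            transform_state=self.transform_state,
        )

    def to_log2(self) -> "ProteinMatrix":
        """Return the log2-transformed matrix (requires raw scale)."""
        if self.transform_state != "raw":
            raise MatrixValidationError(
                f"log2 transform requires raw matrix, got {self.transform_state!r}"
            )
        return ProteinMatrix(
            values=np.log2(self.values),
            feature_meta=self.feature_meta,
            sample_flags=dict(self.sample_flags),
            transform_state="log2",
        )


def check_sample_alignment(
    matrix: ProteinMatrix, *tables: pd.DataFrame, id_column: str = "sample_id"
) -> None:
    """Verify that every table covers exactly the matrix's sample-ID set.

    Tables may be indexed by sample ID or carry an ``id_column``. Raises
    ``MatrixValidationError`` listing missing/extra IDs on mismatch.
    """
    ref = set(matrix.sample_ids)
    for t in tables:
        ids = set(t[id_column]) if id_column in t.columns else set(t.index)
        missing = ref - ids
        extra = ids - ref
        if missing or extra:
            raise MatrixValidationError(
                f"sample mismatch: {len(missing)} missing "
                f"(e.g. {sorted(missing)[:3]}), {len(extra)} extra "
                f"(e.g. {sorted(extra)[:3]})"
            )


def align_by_sample_id(
    matrix: ProteinMatrix, table: pd.DataFrame, id_column: str = "sample_id"
) -> pd.DataFrame:
    """Return ``table`` reindexed to the matrix's sample order (by ID)."""
    check_sample_alignment(matrix, table, id_column=id_column)
    if id_column in table.columns:
        table = table.set_index(id_column)
    return table.loc[matrix.sample_ids]
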