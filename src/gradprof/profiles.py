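"""Fraction-profile matrices: the universal carrier for gradient data.

A sedimentation experiment measures each entity (RNA, protein, or isoform
event) across an ordered series of density-gradient fractions, light to
dense.  This module holds the matrix type, TSV readers/writers,
row-normalization into relative (sum-to-one) profiles, and Pearson
correlation between profiles or between whole fractions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyResultError,
    ParseError,
    UndefinedCorrelationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ENTITY_KINDS = ("rna", "protein", "isoform")

_FRACTION_HEADER = re.compile(r"^(?:frac(?:tion)?[_\s]?)?(\d+)$", re.IGNORECASE)


@dataclass
class FractionProfileMatrix:
    """Entities x ordered gradient fractions, nonnegative abundances.

    ``fraction_indices`` are the *physical* fraction numbers (e.g. 3..24 for
    the RNA gradient, 3..19 for the proteomic fractions), strictly
    increasing.  Values are TPM-like or normalized peptide quantities;
    negative values are rejected, missing cells are imputed as zero at load
    time with a warning.
    """

    entity_ids: list[str]
    fraction_indices: np.ndarray
    values: np.ndarray
    entity_kind: str = "rna"

    def __post_init__(self) -> None:
        self.fraction_indices = np.asarray(self.fraction_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.entity_kind not in ENTITY_KINDS:
            raise ValidationError(f"unknown entity_kind {self.entity_kind!r}")
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.entity_ids), len(self.fraction_indices)):
            raise ValidationError(
                f"shape mismatch: {self.values.shape} vs "
                f"{len(self.entity_ids)} ids x {len(self.fraction_indices)} fractions"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            dupes = sorted({e for e in self.entity_ids if self.entity_ids.count(e) > 1})
            raise ValidationError(f"duplicate entity ids: {dupes[:5]}")
        if len(self.fraction_indices) >= 1 and np.any(np.diff(self.fraction_indices) <= 0):
            raise ValidationError("fraction_indices must be strictly increasing")
        if np.any(self.fraction_indices <= 0):
            raise ValidationError("fraction indices must be positive integers")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("non-finite values in matrix")
        if np.any(self.values < 0):
            raise ValidationError("negative abundances are a hard error")
        self._row_index = {e: i for i, e in enumerate(self.entity_ids)}

    # -- convenience accessors -------------------------------------------------

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_indices)

    def row(self, entity_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[entity_id]]
        except KeyError:
            raise KeyError(f"entity {entity_id!r} not in matrix") from None

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._row_index

    def subset_entities(self, ids: Sequence[str]) -> "FractionProfileMatrix":
        missing = [e for e in ids if e not in self._row_index]
        if missing:
            raise ValidationError(f"entities missing from matrix: {missing[:5]}")
        rows = [self._row_index[e] for e in ids]
        return type(self)(
            entity_ids=list(ids),
            fraction_indices=self.fraction_indices.copy(),
            values=self.values[rows].copy(),
            entity_kind=self.entity_kind,
        )

    def subset_fractions(self, fractions: Iterable[int]) -> "FractionProfileMatrix":
        wanted = sorted(set(int(f) for f in fractions))
        have = {int(f): j for j, f in enumerate(self.fraction_indices)}
        missing = [f for f in wanted if f not in have]
        if missing:
            raise ValidationError(f"fractions not in matrix: {missing}")
        cols = [have[f] for f in wanted]
        return FractionProfileMatrix(
            entity_ids=list(self.entity_ids),
            fraction_indices=np.array(wanted, dtype=int),
            values=self.values[:, cols].copy(),
            entity_kind=self.entity_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.entity_ids, name="entity_id"),
            columns=[f"frac{f}" for f in self.fraction_indices],
        )


class NormalizedProfileMatrix(FractionProfileMatrix):
    """A FractionProfileMatrix whose rows each sum to one."""

    def __post_init__(self) -> None:
        super().__post_init__()
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = [self.entity_ids[i] for i in np.nonzero(~np.isclose(sums, 1.0, atol=1e-9))[0][:5]]
            raise ValidationError(f"rows do not sum to 1: {bad}")


# -- I/O ---------------------------------------------------------------------


def _parse_fraction_header(name: str) -> int:
    m = _FRACTION_HEADER.match(name.strip())
    if not m:
        raise ParseError(f"column header {name!r} is not a fraction index")
    return int(m.group(1))


def load_profile_table(path, entity_kind: str = "rna") -> FractionProfileMatrix:
    """Load a tab-separated entity x fraction table.

    First column holds entity ids; remaining headers must parse as fraction
    integers (``frac3``, ``fraction_3`` or plain ``3``).  Columns are sorted
    by fraction index regardless of file order; duplicate ids and negative
    or non-numeric cells are errors; empty cells become 0 with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: need an id column plus >=2 fraction columns")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({e for e in ids if ids.count(e) > 1})
        raise ValidationError(f"{path}: duplicate entity ids {dupes[:5]}")
    fractions = [(_parse_fraction_header(c), c) for c in df.columns[1:]]
    fractions.sort(key=lambda t: t[0])
    idx = [f for f, _ in fractions]
    if len(set(idx)) != len(idx):
        raise ValidationError(f"{path}: duplicate fraction columns {idx}")
    n_missing = 0
    cols = []
    for f, c in fractions:
        stripped = df[c].fillna("").astype(str).str.strip()
        empty = stripped == ""
        n_missing += int(empty.sum())
        num = pd.to_numeric(stripped.mask(empty, "0"), errors="coerce")
        if num.isna().any():
            row = int(num.index[num.isna()][0])
            raise ParseError(
                f"{path}: non-numeric cell {stripped[row]!r} in column {c!r}, "
                f"row {row} (entity {ids[row]})"
            )
        cols.append(num.to_numpy(dtype=float))
    if n_missing:
        logger.warning("%s: %d missing cells imputed as 0", path, n_missing)
    values = np.column_stack(cols)
    return FractionProfileMatrix(
        entity_ids=ids,
        fraction_indices=np.array(idx, dtype=int),
        values=values,
        entity_kind=entity_kind,
    )


def write_profile_table(m: FractionProfileMatrix, path, header_comment: str | None = None) -> None:
    """Write the reader's dialect: id column + ``fracN`` columns, tab-separated."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df = m.to_frame()
        df.to_csv(fh, sep="\t", float_format="%.10g")


# -- normalization -----------------------------------------------------------


def normalize_profiles(
    m: FractionProfileMatrix, min_total: float = 1.0
) -> NormalizedProfileMatrix:
    """Scale each row to a relative profile summing to one.

    Rows whose raw sum falls below ``min_total`` (the expression floor) are
    dropped, never zero-padded: a profile with no signal has no shape.  The
    default floor of 1 total TPM suits RNA tables; pass 0 for curated
    protein tables.
    """
    if min_total < 0:
        raise ValidationError("min_total must be >= 0")
    sums = m.values.sum(axis=1)
    keep = (sums >= min_total) & (sums > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "normalize_profiles: dropped %d/%d rows below expression floor %g",
            n_dropped, m.n_entities, min_total,
        )
    if not keep.any():
        raise EmptyResultError("all rows fell below the expression floor")
    values = m.values[keep] / sums[keep, None]
    return NormalizedProfileMatrix(
        entity_ids=[e for e, k in zip(m.entity_ids, keep) if k],
        fraction_indices=m.fraction_indices.copy(),
        values=values,
        entity_kind=m.entity_kind,
    )


# -- correlation -------------------------------------------------------------


def pearson(a, b) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises rather than silently returning NaN when either vector is
    constant, since a profile with no shape cannot co-sediment with
    anything.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("pearson: vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValidationError("pearson: need at least 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("pearson: constant vector has undefined correlation")
    r = float(np.corrcoef(a, b)[0, 1])
    return max(-1.0, min(1.0, r))


def fraction_correlation_matrix(
    m: FractionProfileMatrix, log2_transform: bool = True
) -> pd.DataFrame:
    """All-pairs Pearson correlation between gradient fractions.

    Entry (j, k) correlates the fraction-j and fraction-k columns over all
    entities.  Neighbouring fractions of a well-behaved gradient correlate
    more strongly than distant ones.  By default raw abundances are
    log2(v+1)-transformed first, which keeps a handful of very abundant
    transcripts from dominating the correlation.
    """
    if m.n_entities < 3:
        raise ValidationError("need >=3 entities to correlate fractions")
    vals = np.log2(m.values + 1.0) if log2_transform else m.values
    const = np.nonzero(np.ptp(vals, axis=0) == 0)[0]
    if const.size:
        frs = [int(m.fraction_indices[j]) for j in const]
        raise UndefinedCorrelationError(f"constant fraction column(s): {frs}")
    corr = np.corrcoef(vals.T)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    labels = [int(f) for f in m.fraction_indices]
    return pd.DataFrame(corr, index=labels, columns=labels)
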