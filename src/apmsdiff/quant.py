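"""iBAQ computation, per-sample normalisation and the log2 transform.

iBAQ (intensity-based absolute quantification) divides the summed peptide
intensities of a protein by its number of theoretically observable peptides,
yielding a value proportional to molar amount. Each sample is then scaled to
its total so replicates of different pull-down depth become comparable; the
"holistic" route additionally works on log2-transformed values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import DataError, PeptideTable, QuantTable

logger = logging.getLogger(__name__)

ZERO_POLICIES = ("floor", "drop")


def compute_ibaq(peptides: PeptideTable) -> QuantTable:
    """Sum peptide intensities per protein and divide by observable peptides."""
    sums = peptides.values.groupby(peptides.accession).sum()
    denom = peptides.n_observable.reindex(sums.index)
    ibaq = sums.div(denom, axis=0)
    ibaq.index.name = "accession"
    return QuantTable(ibaq, mode="raw_ibaq")


def normalize_total(q: QuantTable) -> QuantTable:
    """Scale every (condition, replicate) column to unit total.

    Accepts raw summed intensities or raw iBAQ values; the output mode is
    always ``total_normalized``.
    """
    if q.mode not in ("raw_intensity", "raw_ibaq"):
        raise DataError(f"normalize_total expects an intensity-scale table, got {q.mode!r}")
    totals = q.values.sum(axis=0)
    zero_cols = totals[totals == 0].index.tolist()
    if zero_cols:
        raise DataError(f"all-zero replicate columns cannot be normalized: {zero_cols}")
    return QuantTable(q.values.div(totals, axis=1), mode="total_normalized")


def column_floors(values: pd.DataFrame) -> pd.Series:
    """Per-column floor: half the smallest nonzero value of that column."""
    masked = values.where(values > 0)
    mins = masked.min(axis=0)
    if mins.isna().any():
        bad = mins[mins.isna()].index.tolist()
        raise DataError(f"column with no nonzero values, floor undefined: {bad}")
    return mins / 2.0


def apply_zero_policy(q: QuantTable, zero_policy: str = "floor") -> QuantTable:
    """Resolve zero (missing) cells ahead of ratios or log2.

    ``floor`` substitutes half the column's smallest nonzero value, keeping
    every ratio finite while preserving within-column rank. ``drop`` marks
    zeros as missing (NaN); downstream combination values touching them are
    omitted and proteins missing from a whole side are excluded from that
    comparison.
    """
    if zero_policy not in ZERO_POLICIES:
        raise DataError(f"unknown zero_policy {zero_policy!r}; expected one of {ZERO_POLICIES}")
    zeros = int((q.values == 0).to_numpy().sum())
    if zero_policy == "floor":
        floors = column_floors(q.values)
        out = q.values.mask(q.values == 0, floors, axis=1)
    else:
        out = q.values.where(q.values != 0)
    if zeros:
        logger.info("zero_policy=%s resolved %d zero cells", zero_policy, zeros)
    return QuantTable(out, mode=q.mode)


def to_log2(q: QuantTable, zero_policy: str = "floor") -> QuantTable:
    """Elementwise log2 of a total-normalised table.

    Zeros are resolved by ``zero_policy`` first; negative inputs are a data
    error.
    """
    if q.mode != "total_normalized":
        raise DataError(f"to_log2 expects a total_normalized table, got {q.mode!r}")
    if (q.values.fillna(0.0).to_numpy() < 0).any():
        raise DataError("negative values cannot be log2-transformed")
    resolved = apply_zero_policy(q, zero_policy)
    return QuantTable(np.log2(resolved.values), mode="log2")
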