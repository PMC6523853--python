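"""Core tabular carriers for the pipeline.

Quantification tables are pandas DataFrames indexed by protein accession with
a two-level column index ``(condition, replicate)``; a mode tag records which
processing stage the values represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Recognised value modes, in pipeline order.
MODES = ("raw_intensity", "raw_ibaq", "total_normalized", "log2")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid run or simulation configuration."""


def make_columns(conditions: dict[str, int]) -> pd.MultiIndex:
    """Build a (condition, replicate) column index.

    ``conditions`` maps condition name to its replicate count; replicates are
    numbered from 1.
    """
    tuples = [(c, r) for c, n in conditions.items() for r in range(1, n + 1)]
    return pd.MultiIndex.from_tuples(tuples, names=["condition", "replicate"])


@dataclass
class QuantTable:
    """Protein-level quantification matrix.

    Attributes
    ----------
    values : DataFrame
        Rows are protein accessions, columns a (condition, replicate)
        MultiIndex.
    mode : str
        One of :data:`MODES`; intensity-scale modes must be non-negative.
    """

    values: pd.DataFrame
    mode: str = "raw_ibaq"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DataError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        cols = self.values.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise DataError("QuantTable columns must be a (condition, replicate) MultiIndex")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].tolist()
            raise DataError(f"duplicate (condition, replicate) columns: {dupes}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DataError(f"duplicate accessions: {dupes}")
        if self.mode != "log2" and (self.values.fillna(0.0).to_numpy() < 0).any():
            raise DataError(f"negative values not allowed in mode {self.mode!r}")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values("condition")))

    def condition(self, name: str) -> pd.DataFrame:
        """Replicate sub-matrix of one condition (columns = replicate index)."""
        if name not in self.conditions:
            raise KeyError(f"condition {name!r} not present; have {self.conditions}")
        return self.values.xs(name, axis=1, level="condition")

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cond, _ in self.values.columns:
            counts[cond] = counts.get(cond, 0) + 1
        return counts


@dataclass
class PeptideTable:
    """Peptide-level intensities with the peptide-to-protein map.

    ``values`` is indexed by peptide id with (condition, replicate) columns;
    ``accession`` maps each peptide to its single parent protein and
    ``n_observable`` gives the theoretical observable-peptide count per
    accession (the iBAQ denominator).
    """

    values: pd.DataFrame
    accession: pd.Series
    n_observable: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.accession.index):
            raise DataError("peptide intensity rows and accession map must share the index")
        missing = set(self.accession.unique()) - set(self.n_observable.index)
        if missing:
            raise DataError(f"no observable-peptide count for accessions: {sorted(missing)[:5]}")
        if (self.n_observable < 1).any():
            bad = self.n_observable[self.n_observable < 1].index.tolist()
            raise DataError(f"n_observable must be >= 1; offending accessions: {bad[:5]}")
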