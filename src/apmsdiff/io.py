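"""Readers and writers for the TSV dialects, plus the run configuration.

Quantification input is a tab-separated table with one accession column and
one intensity column per (condition, replicate). The reader is tolerant of
the common proteinGroups-style export: intensity columns can be selected by a
prefix (e.g. ``iBAQ ``), and contaminant / reverse-hit flag columns are
honoured (flagged rows dropped, counts logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .tables import ConfigurationError, DataError, QuantTable

logger = logging.getLogger(__name__)

ACCESSION_COLUMNS = ("accession", "Accession", "Majority protein IDs", "Protein IDs")
FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Contaminant",
                "Only identified by site")


@dataclass
class RunConfig:
    """Everything that affects the numbers of an end-to-end run.

    Defaults are the published analysis constants: classification threshold
    +/-5 log2, volcano bounds |delta| >= 6 and p < 0.025 with 10,000
    permutations, and interactome membership at >= 2 replicates.
    """

    route: str = "holistic"             # "ibaq_ratio" | "holistic"
    zero_policy: str = "floor"          # "floor" | "drop"
    background_condition: str = "background"
    classification_threshold: float = 5.0
    delta_threshold: float = 6.0
    p_threshold: float = 0.025
    b_perm: int = 10_000
    min_replicates: int = 2
    overlap_method: str = "allway"
    permutation_statistic: str = "median"
    permutation_unit: str = "values"
    cluster_k: int = 8
    cluster_k_range: tuple[int, int] = (3, 12)
    cluster_on_scores: bool = False
    seed: int = 0
    outdir: str | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.route not in ("ibaq_ratio", "holistic"):
            raise ConfigurationError(f"unknown route {self.route!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "cluster_k_range" in raw:
            raw["cluster_k_range"] = tuple(raw["cluster_k_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cluster_k_range"] = list(self.cluster_k_range)
        return d


def _find_accession_column(columns) -> str:
    for cand in ACCESSION_COLUMNS:
        if cand in columns:
            return cand
    raise DataError(
        f"no accession column found; expected one of {ACCESSION_COLUMNS}, "
        f"got {list(columns)[:8]}")


def read_quant_tsv(path, condition_map: dict[str, tuple[str, int]],
                   mode: str = "raw_ibaq") -> QuantTable:
    """Read a protein quantification TSV.

    ``condition_map`` maps input column names to (condition, replicate)
    pairs. Rows flagged in any recognised contaminant/reverse column are
    dropped (count logged). Duplicate accessions and non-numeric cells are
    errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    acc_col = _find_accession_column(df.columns)

    n_flagged = 0
    for flag in FLAG_COLUMNS:
        if flag in df.columns:
            mask = df[flag].fillna("").str.strip() == "+"
            n_flagged += int(mask.sum())
            df = df[~mask]
    if n_flagged:
        logger.info("read_quant_tsv: dropped %d contaminant/reverse-flagged rows", n_flagged)

    missing = [c for c in condition_map if c not in df.columns]
    if missing:
        raise DataError(f"condition_map columns absent from {path}: {missing}")

    df = df.set_index(acc_col)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate accessions in {path}: {dupes}")

    values = {}
    for col, (cond, rep) in condition_map.items():
        try:
            values[(cond, rep)] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            where = bad.index[0] if len(bad) else "?"
            raise DataError(
                f"non-numeric value in column {col!r}, row {where!r}") from None
    out = pd.DataFrame(values)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "replicate"])
    out.index.name = "accession"
    return QuantTable(out.fillna(0.0), mode=mode)


def quant_columns_by_prefix(path, prefix: str = "iBAQ ") -> list[str]:
    """Column names in a TSV header starting with ``prefix`` (helper for
    proteinGroups-style files)."""
    header = pd.read_csv(path, sep="\t", nrows=0, comment="#").columns
    return [c for c in header if c.startswith(prefix)]


def write_quant_tsv(q: QuantTable, path) -> None:
    """Write a QuantTable with ``condition.replicate`` flat headers."""
    flat = q.values.copy()
    flat.columns = [f"{c}.{r}" for c, r in q.values.columns]
    flat.index.name = "accession"
    flat.to_csv(path, sep="\t")


def condition_map_from_flat_headers(path) -> dict[str, tuple[str, int]]:
    """Recover the condition map from ``condition.replicate`` flat headers."""
    header = pd.read_csv(path, sep="\t", nrows=0, comment="#").columns
    cmap = {}
    for col in header:
        if col in ACCESSION_COLUMNS or col in FLAG_COLUMNS:
            continue
        cond, _, rep = col.rpartition(".")
        if cond and rep.isdigit():
            cmap[col] = (cond, int(rep))
    return cmap


def read_accession_list(path) -> set[str]:
    """One accession per line, UTF-8; blank lines and # comments ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.add(token)
    return out


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def write_peptide_tsv(peptides, path) -> None:
    flat = peptides.values.copy()
    flat.columns = [f"{c}.{r}" for c, r in peptides.values.columns]
    flat.insert(0, "accession", peptides.accession)
    flat.insert(1, "n_observable",
                peptides.n_observable.reindex(peptides.accession).to_numpy())
    flat.to_csv(path, sep="\t")
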