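"""Hypergeometric over-representation analysis against a user-supplied annotation.

A generic stand-in for web-service GO enrichment: one-sided hypergeometric
upper-tail p per term, fold enrichment relative to the background, and
Benjamini-Hochberg adjusted p-values. The background universe is the set of
proteins quantified in the run, not the whole annotation universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .tables import DataError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationTable:
    """Term-to-accession map with optional term names and namespaces."""

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]],
                   names: dict[str, str] | None = None) -> "AnnotationTable":
        terms: dict[str, set[str]] = {}
        for term, acc in pairs:
            if not acc:
                raise DataError("empty accession string in annotation pairs")
            terms.setdefault(term, set()).add(acc)
        return cls(terms={t: frozenset(s) for t, s in terms.items()},
                   names=dict(names or {}))

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        """Two-column TSV: term_id <tab> accession (optional third: term name)."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise DataError("annotation TSV needs at least term_id and accession columns")
        names = {}
        if df.shape[1] >= 3:
            names = dict(zip(df[0], df[2]))
        return cls.from_pairs(list(zip(df[0], df[1])), names)

    @classmethod
    def read_gmt(cls, path) -> "AnnotationTable":
        """GMT: term_id <tab> description <tab> accession ..."""
        terms, names = {}, {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                term, desc, accs = parts[0], parts[1], [a for a in parts[2:] if a]
                terms[term] = frozenset(accs)
                names[term] = desc
        return cls(terms=terms, names=names)


def hypergeom_enrich(study: set[str], background: set[str],
                     ann: AnnotationTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term over-representation of ``study`` within ``background``.

    For a term covering K of the N background accessions, of which the
    n-element study set hits k, the upper-tail p is P(X >= k) with
    X ~ Hypergeometric(N, K, n), and fold enrichment is (k/n) / (K/N).
    """
    study, background = set(study), set(background)
    if not study <= background:
        extra = sorted(study - background)[:5]
        raise DataError(f"study set is not contained in the background: e.g. {extra}")
    n, big_n = len(study), len(background)
    rows = []
    for term, accs in ann.terms.items():
        term_bg = accs & background
        big_k = len(term_bg)
        if big_k == 0:
            continue
        k = len(study & term_bg)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        fold = (k / n) / (big_k / big_n) if n else float("nan")
        rows.append((term, ann.names.get(term, term), k, n, big_k, big_n, fold, p))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "n", "K", "N",
                                      "fold_enrichment", "p"]).set_index("term_id")
    if len(out):
        out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["p_bh"] < alpha
        out = out.sort_values("p")
    return out
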