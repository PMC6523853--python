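"""Qualitative interactome sets: Jaccard similarity, Venn partitions, lists.

An interactome set is the accessions deemed interactors of one bait condition
under an explicit membership rule — by default, detection (value > 0) in at
least two replicates. Sets built under different rules are never compared
silently.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .tables import DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractomeSet:
    """Accessions interacting with one bait under a stated membership rule."""

    condition: str
    accessions: frozenset[str]
    membership_rule: tuple = field(default=("min_replicates", 2, "detection", "value>0"))

    def __len__(self) -> int:
        return len(self.accessions)


def build_interactome(replicates: pd.DataFrame, condition: str,
                      min_replicates: int = 2) -> InteractomeSet:
    """Accessions detected (value > 0) in at least ``min_replicates`` replicates."""
    if replicates.shape[1] < min_replicates:
        raise DataError(
            f"{condition!r} has {replicates.shape[1]} replicates, fewer than "
            f"min_replicates={min_replicates}")
    n_det = (replicates > 0).sum(axis=1)
    members = frozenset(replicates.index[n_det >= min_replicates])
    return InteractomeSet(
        condition=condition,
        accessions=members,
        membership_rule=("min_replicates", min_replicates, "detection", "value>0"),
    )


def jaccard(a: InteractomeSet, b: InteractomeSet) -> float:
    """|intersection| / |union| of two interactome sets, in [0, 1]."""
    if a.membership_rule != b.membership_rule:
        logger.warning("comparing sets built under different membership rules: %s vs %s",
                       a.membership_rule, b.membership_rule)
    union = a.accessions | b.accessions
    if not union:
        logger.warning("jaccard of two empty sets defined as 0")
        return 0.0
    return len(a.accessions & b.accessions) / len(union)


def similarity_matrix(sets: list[InteractomeSet]) -> pd.DataFrame:
    """All pairwise Jaccard indices as a symmetric matrix with unit diagonal."""
    if len(sets) < 2:
        raise DataError("similarity_matrix needs at least 2 sets")
    names = [s.condition for s in sets]
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for (i, a), (j, b) in itertools.combinations(enumerate(sets), 2):
        mat.iloc[i, j] = mat.iloc[j, i] = jaccard(a, b)
    return mat


def exclusive_partition(sets: list[InteractomeSet]
                        ) -> dict[tuple[str, ...], set[str]]:
    """Venn regions: every accession of the union assigned to exactly one region.

    Region keys are the sorted tuple of conditions containing the accession.
    Supports 2-4 sets (higher-order Venn diagrams are not meaningful to draw
    or report).
    """
    if not 2 <= len(sets) <= 4:
        raise DataError("exclusive_partition supports 2 to 4 sets")
    regions: dict[tuple[str, ...], set[str]] = {}
    union = set().union(*(s.accessions for s in sets))
    for acc in union:
        key = tuple(sorted(s.condition for s in sets if acc in s.accessions))
        regions.setdefault(key, set()).add(acc)
    return regions


def exclusive_to(sets: list[InteractomeSet], condition: str) -> set[str]:
    """Accessions present only in ``condition``'s interactome."""
    regions = exclusive_partition(sets)
    return set(regions.get((condition,), set()))


def cross_reference(interactome: InteractomeSet,
                    annotation_list: set[str]) -> tuple[int, list[str]]:
    """Intersection of an interactome with an external accession list."""
    if not annotation_list:
        logger.warning("cross_reference against an empty annotation list")
    hits = sorted(interactome.accessions & set(annotation_list))
    return len(hits), hits
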