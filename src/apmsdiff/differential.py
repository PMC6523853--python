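"""Differential affinity between two bait conditions and the permutation volcano.

The affinity difference per protein is the log2 ratio of its two
background-referenced combination medians (ratio route) or the difference of
the medians of log2 combinations (holistic route); the two coincide through
the 2^x identity on all-positive inputs. Significance comes from a per-protein
permutation test on the pooled combination values, and volcano calls require
both a large difference and a small permutation p-value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import CombinationSet
from .tables import DataError

logger = logging.getLogger(__name__)

STATISTICS = ("median", "mean")
PERMUTATION_UNITS = ("values", "replicates")


@dataclass
class VolcanoConfig:
    """Thresholds and permutation settings for a pairwise comparison.

    Defaults follow the published analysis: 10,000 random permutations,
    significance at p < 0.025 (-log10 p > 1.60), a volcano fold-change bound
    |delta| >= 6 log2 units, and a +/-5 log2 threshold for the simple
    classification route.
    """

    b_perm: int = 10_000
    p_threshold: float = 0.025
    delta_threshold: float = 6.0
    classification_threshold: float = 5.0
    statistic: str = "median"
    permutation_unit: str = "values"
    exhaustive_max: int = 0  # pooled-size cap below which enumeration replaces sampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise DataError(f"unknown statistic {self.statistic!r}")
        if self.permutation_unit not in PERMUTATION_UNITS:
            raise DataError(f"unknown permutation unit {self.permutation_unit!r}")
        if self.b_perm < 1:
            raise DataError("b_perm must be >= 1")

    @property
    def p_threshold_log(self) -> float:
        return -np.log10(self.p_threshold)


def differential_affinity(med_a: pd.Series, med_b: pd.Series,
                          route: str = "holistic") -> pd.Series:
    """Per-protein affinity difference, positive when higher in A.

    ``ibaq_ratio`` route: log2(medA / medB) on intensity-scale medians.
    ``holistic`` route: medA - medB on log2-scale medians.
    Proteins missing a median on either side are excluded (logged).
    """
    if route not in ("ibaq_ratio", "holistic"):
        raise DataError(f"unknown route {route!r}")
    a, b = med_a.align(med_b, join="inner")
    keep = a.notna() & b.notna()
    n_dropped = len(med_a.index.union(med_b.index)) - int(keep.sum())
    if n_dropped:
        logger.info("differential_affinity: excluded %d proteins missing a median", n_dropped)
    a, b = a[keep], b[keep]
    if route == "ibaq_ratio":
        if (b <= 0).any() or (a <= 0).any():
            raise DataError("ibaq_ratio route requires positive medians; "
                            "apply a zero policy first")
        delta = np.log2(a / b)
    else:
        delta = a - b
    return pd.Series(delta, name="delta")


def classify_threshold(deltas: pd.Series, t: float = 5.0
                       ) -> tuple[pd.Series, dict[str, int]]:
    """Classify proteins by a symmetric log2 threshold.

    Returns per-protein calls (``higher_A`` / ``higher_B`` / ``nonspecific``)
    and the three counts, which always partition the input.
    """
    call = pd.Series("nonspecific", index=deltas.index, name="call")
    call[deltas > t] = "higher_A"
    call[deltas < -t] = "higher_B"
    counts = {
        "higher_A": int((call == "higher_A").sum()),
        "higher_B": int((call == "higher_B").sum()),
        "nonspecific": int((call == "nonspecific").sum()),
    }
    return call, counts


def _stat_fn(name: str):
    return np.median if name == "median" else np.mean


def _perm_p_values(va: np.ndarray, vb: np.ndarray, b_perm: int, statistic: str,
                   rng: np.random.Generator) -> float:
    """Monte-Carlo permutation p for one protein, value-level reassignment."""
    fn = _stat_fn(statistic)
    pool = np.concatenate([va, vb])
    n, na = len(pool), len(va)
    obs = abs(fn(va) - fn(vb))
    order = np.argsort(rng.random((b_perm, n)), axis=1)
    perm = pool[order]
    null = np.abs(fn(perm[:, :na], axis=1) - fn(perm[:, na:], axis=1))
    return (int(np.sum(null >= obs)) + 1) / (b_perm + 1)


def _perm_p_exhaustive(va: np.ndarray, vb: np.ndarray, statistic: str) -> float:
    """Exact permutation p by enumerating every reassignment of the pool."""
    fn = _stat_fn(statistic)
    pool = np.concatenate([va, vb])
    n, na = len(pool), len(va)
    obs = abs(fn(va) - fn(vb))
    idx = np.arange(n)
    n_ge = n_total = 0
    for group_a in itertools.combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(group_a)] = True
        stat = abs(fn(pool[mask]) - fn(pool[~mask]))
        n_total += 1
        if stat >= obs - 1e-12:
            n_ge += 1
    return n_ge / n_total


def _perm_p_replicates(sample_a: np.ndarray, sample_b: np.ndarray,
                       control: np.ndarray, statistic: str) -> float:
    """Exact replicate-level permutation p.

    Reassigns the bait replicate values of the protein to the two conditions
    in every possible way, recomputing combination values against the fixed
    control replicates. Exchangeability of bait replicates holds exactly
    under the null, but with 3+3 replicates only C(6,3)=20 reassignments
    exist, so p-values are coarse (minimum 0.1 for a symmetric statistic).
    """
    fn = _stat_fn(statistic)
    pool = np.concatenate([sample_a, sample_b])
    na = len(sample_a)
    obs = None
    stats = []
    for group_a in itertools.combinations(range(len(pool)), na):
        mask = np.zeros(len(pool), dtype=bool)
        mask[list(group_a)] = True
        ca = (pool[mask][:, None] - control[None, :]).ravel()
        cb = (pool[~mask][:, None] - control[None, :]).ravel()
        stat = abs(fn(ca) - fn(cb))
        stats.append(stat)
        if group_a == tuple(range(na)):
            obs = stat
    stats = np.asarray(stats)
    return float(np.sum(stats >= obs - 1e-12)) / len(stats)


def permutation_test(cs_a: CombinationSet, cs_b: CombinationSet,
                     cfg: VolcanoConfig | None = None) -> pd.Series:
    """Per-protein permutation p-value for proteins present in both sets.

    The observed statistic is |median(A combinations) - median(B
    combinations)| on the log2 scale; the null pools the two combination
    vectors and randomly reassigns values to groups of the original sizes,
    ``b_perm`` times, with p = (#{null >= observed} + 1) / (b_perm + 1).
    Proteins with fewer than two finite values on either side are excluded
    (logged). Deterministic given ``cfg.seed``.

    With ``permutation_unit='replicates'`` the exact but coarse
    replicate-level scheme is used instead (see ``_perm_p_replicates``); it
    requires complete 1-to-1 pair structure and is mainly a validity
    cross-check.
    """
    cfg = cfg or VolcanoConfig()
    if cs_a.mode != cs_b.mode:
        raise DataError("combination sets must share a mode")
    # The statistic is symmetric in the two conditions; order them
    # canonically so p(A, B) == p(B, A) bit for bit at the same seed.
    if cs_b.condition < cs_a.condition:
        cs_a, cs_b = cs_b, cs_a
    common = cs_a.values.index.intersection(cs_b.values.index)
    rng = np.random.default_rng(cfg.seed)
    out = {}
    n_excluded = 0
    a_mat = cs_a.values.loc[common].to_numpy()
    b_mat = cs_b.values.loc[common].to_numpy()
    for i, acc in enumerate(common):
        va = a_mat[i][np.isfinite(a_mat[i])]
        vb = b_mat[i][np.isfinite(b_mat[i])]
        if len(va) < 2 or len(vb) < 2:
            n_excluded += 1
            continue
        if cfg.permutation_unit == "replicates":
            sa, ctrl_a = _replicate_values(cs_a, acc)
            sb, ctrl_b = _replicate_values(cs_b, acc)
            if not np.allclose(ctrl_a, ctrl_b):
                raise DataError("replicate-level permutation needs a shared control")
            out[acc] = _perm_p_replicates(sa, sb, ctrl_a, cfg.statistic)
        elif cfg.exhaustive_max and len(va) + len(vb) <= cfg.exhaustive_max:
            out[acc] = _perm_p_exhaustive(va, vb, cfg.statistic)
        else:
            out[acc] = _perm_p_values(va, vb, cfg.b_perm, cfg.statistic, rng)
    if n_excluded:
        logger.info("permutation_test: excluded %d proteins with <2 values on a side",
                    n_excluded)
    return pd.Series(out, name="p_perm", dtype=float)


def _replicate_values(cs: CombinationSet, acc) -> tuple[np.ndarray, np.ndarray]:
    """Recover per-replicate sample and control log2 values from a log2diff set.

    Only defined for complete log2diff combination grids: the value of sample
    replicate i against control replicate j is s_i - c_j, so rows/columns of
    the grid determine s and c up to a common additive constant, which the
    permutation statistic cancels.
    """
    if cs.mode != "log2diff":
        raise DataError("replicate-level permutation requires log2diff mode")
    grid = cs.values.loc[acc].unstack("control_replicate").to_numpy()
    if not np.all(np.isfinite(grid)):
        raise DataError("replicate-level permutation requires a complete grid")
    # s_i - c_j with c anchored at c_1 = 0.
    c = grid[0, 0] - grid[0, :]
    s = grid[:, 0] + c[0]
    return s, c


def volcano_calls(deltas: pd.Series, p_perms: pd.Series,
                  cfg: VolcanoConfig | None = None) -> pd.DataFrame:
    """Assemble the differential table with volcano significance calls.

    A protein is a volcano hit iff |delta| >= delta_threshold and
    p < p_threshold (equivalently -log10 p above the log cutoff).
    """
    cfg = cfg or VolcanoConfig()
    common = deltas.index.intersection(p_perms.index)
    if len(common) != len(deltas) or len(common) != len(p_perms):
        logger.info("volcano_calls: restricting to %d proteins present in both inputs",
                    len(common))
    d = deltas.loc[common]
    p = p_perms.loc[common]
    call, _ = classify_threshold(d, cfg.classification_threshold)
    table = pd.DataFrame({
        "delta": d,
        "p_perm": p,
        "neg_log10_p": -np.log10(p),
        "call": call,
        "volcano_hit": (d.abs() >= cfg.delta_threshold) & (p < cfg.p_threshold),
    })
    table.index.name = "accession"
    return table
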