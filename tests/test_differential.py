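"""Differential affinity, threshold classification and the permutation volcano."""

import numpy as np
import pandas as pd
import pytest

import apmsdiff as a
from apmsdiff.differential import _perm_p_exhaustive
from conftest import combo_set, exhaustive_perm_p


def _series(d):
    return pd.Series(d, dtype=float)


def test_differential_affinity_routes_and_log_identity():
    med_a = _series({"P1": 32.0, "P2": 5.0})
    med_b = _series({"P1": 1.0, "P2": 5.0})
    ratio = a.differential_affinity(med_a, med_b, route="ibaq_ratio")
    assert ratio["P1"] == pytest.approx(5.0) and ratio["P2"] == 0.0
    holistic = a.differential_affinity(np.log2(med_a), np.log2(med_b), route="holistic")
    np.testing.assert_allclose(ratio, holistic, atol=1e-12)


def test_differential_affinity_antisymmetry_exact():
    rng = np.random.default_rng(0)
    med_a = pd.Series(rng.normal(size=50), index=[f"P{i}" for i in range(50)])
    med_b = pd.Series(rng.normal(size=50), index=med_a.index)
    fwd = a.differential_affinity(med_a, med_b, route="holistic")
    rev = a.differential_affinity(med_b, med_a, route="holistic")
    assert (fwd == -rev).all()


def test_missing_medians_are_excluded():
    med_a = _series({"P1": 1.0, "P2": np.nan, "P3": 2.0})
    med_b = _series({"P1": 1.0, "P2": 1.0})
    out = a.differential_affinity(med_a, med_b, route="holistic")
    # P2 has a missing median, P3 is absent from one side entirely
    assert list(out.index) == ["P1"]


def test_classify_threshold_partitions_counts():
    deltas = _series({"P1": 6.0, "P2": -6.0, "P3": 0.0})
    call, counts = a.classify_threshold(deltas, t=5.0)
    assert counts == {"higher_A": 1, "higher_B": 1, "nonspecific": 1}
    zero_call, zero_counts = a.classify_threshold(_series({"P1": 0.0, "P2": 0.0}))
    assert zero_counts == {"higher_A": 0, "higher_B": 0, "nonspecific": 2}
    assert sum(counts.values()) == 3 and (call.index == deltas.index).all()


def test_identical_combination_sets_give_p_near_one():
    rows = {"P1": [0.1, 0.5, -0.2, 0.7, 0.0, -0.4, 0.3, 0.2, -0.1]}
    cs = combo_set(rows, condition="A")
    cs_b = combo_set(rows, condition="B")
    p = a.permutation_test(cs, cs_b, a.VolcanoConfig(b_perm=500, seed=1))
    assert p["P1"] == 1.0  # observed statistic 0, every null >= it


def test_monte_carlo_matches_independent_exhaustive_enumeration():
    # tiny 2v2 instance: all C(4,2)=6 reassignments enumerable by hand
    va, vb = np.array([0.0, 1.0]), np.array([5.0, 6.0])
    p_oracle = exhaustive_perm_p(va, vb)
    assert p_oracle == pytest.approx(2 / 6)
    rows_a = {"P1": list(va)}
    rows_b = {"P1": list(vb)}
    cs_a = combo_set(rows_a, "A", n_sample=2, n_control=1)
    cs_b = combo_set(rows_b, "B", n_sample=2, n_control=1)
    b_perm = 4000
    p_mc = a.permutation_test(cs_a, cs_b, a.VolcanoConfig(b_perm=b_perm, seed=2))["P1"]
    se = np.sqrt(p_oracle * (1 - p_oracle) / b_perm)
    assert abs(p_mc - p_oracle) < 3 * se + 1 / b_perm
    # package exhaustive mode agrees with the independent oracle exactly
    p_ex = a.permutation_test(
        cs_a, cs_b, a.VolcanoConfig(b_perm=10, exhaustive_max=10, seed=2))["P1"]
    assert p_ex == pytest.approx(p_oracle)


@pytest.mark.parametrize("seed", [3, 4])
def test_monte_carlo_converges_on_larger_pools(seed):
    rng = np.random.default_rng(seed)
    va, vb = rng.normal(0, 1, 4), rng.normal(1.5, 1, 5)
    p_oracle = exhaustive_perm_p(va, vb)
    cs_a = combo_set({"P1": list(va)}, "A", n_sample=2, n_control=2)
    cs_b = combo_set({"P1": list(vb)}, "B", n_sample=5, n_control=1)
    p_mc = a.permutation_test(cs_a, cs_b, a.VolcanoConfig(b_perm=4000, seed=seed))["P1"]
    se = np.sqrt(p_oracle * (1 - p_oracle) / 4000)
    assert abs(p_mc - p_oracle) < 3 * se + 1 / 4000


def test_permutation_p_symmetric_under_condition_swap():
    rng = np.random.default_rng(9)
    rows_a = {f"P{i}": list(rng.normal(0, 1, 9)) for i in range(5)}
    rows_b = {f"P{i}": list(rng.normal(1, 1, 9)) for i in range(5)}
    cs_a, cs_b = combo_set(rows_a, "A"), combo_set(rows_b, "B")
    cfg = a.VolcanoConfig(b_perm=300, seed=5)
    fwd = a.permutation_test(cs_a, cs_b, cfg)
    rev = a.permutation_test(cs_b, cs_a, cfg)
    pd.testing.assert_series_equal(fwd, rev)


def test_proteins_with_too_few_values_excluded():
    cs_a = combo_set({"P1": [np.nan] * 8 + [1.0], "P2": [0.5] * 9}, "A")
    cs_b = combo_set({"P1": [0.0] * 9, "P2": [0.0] * 9}, "B")
    p = a.permutation_test(cs_a, cs_b, a.VolcanoConfig(b_perm=100, seed=1))
    assert "P1" not in p.index and "P2" in p.index


def test_replicate_level_permutation_is_coarse_but_exact():
    # 3v3 bait replicates admit only C(6,3)=20 reassignments; the minimum
    # two-sided p is 2/20 for a symmetric statistic.
    rng = np.random.default_rng(2)
    s_a, s_b, c = np.array([8.0, 8.2, 7.9]), np.array([0.1, -0.2, 0.0]), rng.normal(0, 0.5, 3)
    va = (s_a[:, None] - c[None, :]).ravel()
    vb = (s_b[:, None] - c[None, :]).ravel()
    cs_a = combo_set({"P1": list(va)}, "A")
    cs_b = combo_set({"P1": list(vb)}, "B")
    p = a.permutation_test(cs_a, cs_b,
                           a.VolcanoConfig(permutation_unit="replicates", seed=0))["P1"]
    assert p == pytest.approx(2 / 20)


def test_volcano_calls_threshold_conjunction():
    deltas = _series({"P1": 7.0, "P2": 7.0, "P3": 5.9, "P4": -6.5})
    ps = _series({"P1": 0.01, "P2": 0.05, "P3": 0.001, "P4": 0.002})
    table = a.volcano_calls(deltas, ps)
    assert table.loc["P1", "volcano_hit"]
    assert not table.loc["P2", "volcano_hit"]   # p fails
    assert not table.loc["P3", "volcano_hit"]   # fold change fails
    assert table.loc["P4", "volcano_hit"]
    np.testing.assert_allclose(table["neg_log10_p"], -np.log10(ps))
    hits = table[table["volcano_hit"]]
    assert ((hits["delta"].abs() >= 6) & (hits["neg_log10_p"] >= 1.60)).all()


def test_null_level_on_exchangeable_values():
    # With genuinely exchangeable (iid) value vectors the permutation test
    # holds its level; the combination-structure inflation is tested (and
    # documented) in the acceptance suite.
    rng = np.random.default_rng(12)
    n = 400
    rows_a = {f"P{i}": list(rng.normal(0, 1, 9)) for i in range(n)}
    rows_b = {f"P{i}": list(rng.normal(0, 1, 9)) for i in range(n)}
    p = a.permutation_test(combo_set(rows_a, "A"), combo_set(rows_b, "B"),
                           a.VolcanoConfig(b_perm=1000, seed=13))
    level = 0.025
    se = np.sqrt(level * (1 - level) / n)
    assert (p < level).mean() <= level + 3 * se
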