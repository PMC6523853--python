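import numpy as np
import pandas as pd
import pytest

import apmsdiff as a


def pair_columns(n_sample: int = 3, n_control: int = 3) -> pd.MultiIndex:
    """(sample_replicate, control_replicate) column index for combination sets."""
    return pd.MultiIndex.from_product(
        [[("s", i) for i in range(1, n_sample + 1)],
         [("c", j) for j in range(1, n_control + 1)]],
        names=["sample_replicate", "control_replicate"])


def combo_set(rows: dict[str, list[float]], condition: str = "A",
              mode: str = "log2diff", n_sample: int = 3, n_control: int = 3
              ) -> a.CombinationSet:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = pair_columns(n_sample, n_control)
    return a.CombinationSet(condition, df, mode)


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic experiment shared across read-only tests."""
    sim = a.SimConfig(n_conditions=2, n_replicates=3, n_background_binders=150,
                      n_specific_per_condition=15, n_shared_specific=10,
                      enrichment_log2=8.0, noise_sigma=0.5, dropout_rate=0.1, seed=11)
    peptides, proteins, truth = a.generate_experiment(sim)
    return sim, peptides, proteins, truth


@pytest.fixture(scope="session")
def small_run(small_sim):
    sim, _, _, _ = small_sim
    cfg = a.RunConfig(b_perm=500, make_plots=False, seed=11)
    return cfg, a.run_pipeline(cfg, sim_config=sim)


def exhaustive_perm_p(va, vb, stat=np.median) -> float:
    """Independent brute-force permutation p: enumerate every reassignment."""
    import itertools
    pool = np.concatenate([va, vb])
    na, n = len(va), len(va) + len(vb)
    obs = abs(stat(va) - stat(vb))
    n_ge = n_tot = 0
    for ga in itertools.combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(ga)] = True
        n_tot += 1
        if abs(stat(pool[mask]) - stat(pool[~mask])) >= obs - 1e-12:
            n_ge += 1
    return n_ge / n_tot
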