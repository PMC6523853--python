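"""Synthetic co-immunoprecipitation / pull-down experiment generator.

Emulates label-free AP-MS quantification tables: several bait conditions plus
one background pull-down, a few replicates each, log-normally distributed
intensities over a wide dynamic range, a majority class of nonspecific
(background) binders, planted condition-specific interactors at a configurable
log2 enrichment over the background capture, and stochastic dropout recorded
as true zeros. A matching peptide-level table decomposes every protein
intensity across its observable peptides so the iBAQ computation downstream is
exercised end to end.

Ground truth for every generated protein is returned alongside the tables, so
recovery of planted interactors can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ConfigurationError, PeptideTable, QuantTable, make_columns

BACKGROUND = "background"

#: log2 range of per-protein base abundance (arbitrary intensity units).
BASE_LOG2_RANGE = (18.0, 30.0)


@dataclass
class SimConfig:
    """Study design of a synthetic experiment.

    Parameters
    ----------
    n_conditions : int
        Number of bait conditions (a background condition is always added).
    n_replicates : int
        Replicates per condition; 3 or 4, as in typical co-IP designs.
    n_background_binders : int
        Nonspecific binders present at equal expected level in every
        pull-down, the majority class in real experiments.
    n_specific_per_condition : int
        Interactors planted in exactly one bait condition.
    n_shared_specific : int
        Interactors enriched in every bait condition (bait-generic binders).
    enrichment_log2 : float
        Mean planted log2 enrichment of specific interactors over their
        background-capture level.
    noise_sigma : float
        Replicate-to-replicate standard deviation on the log2 scale.
    dropout_rate : float
        Probability that a protein is missing (recorded as 0) in a replicate.
    peptides_per_protein_range : tuple[int, int]
        Inclusive range for the theoretical observable-peptide count.
    seed : int
        RNG seed; identical configs produce byte-identical tables.
    condition_names : tuple[str, ...] | None
        Optional bait condition names; defaults to bait1..baitN.
    """

    n_conditions: int = 4
    n_replicates: int = 3
    n_background_binders: int = 800
    n_specific_per_condition: int = 50
    n_shared_specific: int = 30
    enrichment_log2: float = 8.0
    noise_sigma: float = 0.5
    dropout_rate: float = 0.1
    peptides_per_protein_range: tuple[int, int] = (5, 30)
    seed: int = 0
    condition_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_conditions < 1:
            raise ConfigurationError("need at least one bait condition")
        if self.n_replicates not in (3, 4):
            raise ConfigurationError("n_replicates must be 3 or 4")
        if min(self.n_background_binders, self.n_specific_per_condition,
               self.n_shared_specific) < 0:
            raise ConfigurationError("protein counts must be >= 0")
        if self.n_background_binders + self.n_specific_per_condition + self.n_shared_specific == 0:
            raise ConfigurationError("experiment would contain zero proteins")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.noise_sigma <= 0:
            raise ConfigurationError("noise_sigma must be > 0")
        lo, hi = self.peptides_per_protein_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("peptides_per_protein_range must be 1 <= lo <= hi")
        if self.condition_names is not None and len(self.condition_names) != self.n_conditions:
            raise ConfigurationError("condition_names length must equal n_conditions")

    @property
    def conditions(self) -> list[str]:
        if self.condition_names is not None:
            return list(self.condition_names)
        return [f"bait{i + 1}" for i in range(self.n_conditions)]


def _truth(config: SimConfig) -> pd.DataFrame:
    """Per-protein class and planted log2 enrichment per bait condition."""
    conds = config.conditions
    rows = []
    for i in range(config.n_background_binders):
        rows.append((f"BG{i:05d}", "background", {c: 0.0 for c in conds}))
    for cond in conds:
        for i in range(config.n_specific_per_condition):
            enr = {c: (config.enrichment_log2 if c == cond else 0.0) for c in conds}
            rows.append((f"SP_{cond}_{i:04d}", f"specific:{cond}", enr))
    for i in range(config.n_shared_specific):
        rows.append((f"SH{i:04d}", "shared_specific",
                     {c: config.enrichment_log2 for c in conds}))
    truth = pd.DataFrame(
        {
            "accession": [r[0] for r in rows],
            "class": [r[1] for r in rows],
            **{f"enrichment_{c}": [r[2][c] for r in rows] for c in conds},
        }
    ).set_index("accession")
    return truth


def generate_experiment(config: SimConfig) -> tuple[PeptideTable, QuantTable, pd.DataFrame]:
    """Simulate one experiment.

    Returns
    -------
    peptides : PeptideTable
        Peptide-level intensities whose per-protein sums reproduce the
        protein table exactly.
    proteins : QuantTable
        Protein-level summed intensities (mode ``raw_intensity``), one column
        per (condition, replicate) including the background condition.
    truth : DataFrame
        One row per accession with its class and planted enrichments.
    """
    truth = _truth(config)
    accessions = truth.index.to_numpy()
    n_prot = len(accessions)
    all_conds = [BACKGROUND] + config.conditions

    root = np.random.SeedSequence(config.seed)
    base_ss, pept_ss, *cond_ss = root.spawn(2 + len(all_conds))
    base_rng = np.random.default_rng(base_ss)

    # Background binders span the full dynamic range. Specific interactors
    # are captured near the low end in the background pull-down so that their
    # enriched level stays within the same range: otherwise a single planted
    # protein could dominate a bait sample's total and total-protein
    # normalisation would shift every ratio in that sample.
    lo, hi = BASE_LOG2_RANGE
    spec_hi = max(lo + 0.5, hi - max(config.enrichment_log2, 0.0))
    is_bg = (truth["class"] == "background").to_numpy()
    base_log2 = np.where(
        is_bg,
        base_rng.uniform(lo, hi, size=n_prot),
        base_rng.uniform(lo, spec_hi, size=n_prot),
    )

    # Expected log2 level per protein and condition: base everywhere, plus the
    # planted enrichment in the protein's own bait condition(s).
    expected = {BACKGROUND: base_log2}
    for cond in config.conditions:
        expected[cond] = base_log2 + truth[f"enrichment_{cond}"].to_numpy()

    cols = make_columns({c: config.n_replicates for c in all_conds})
    mat = np.empty((n_prot, len(cols)))
    for ci, (cond, ss) in enumerate(zip(all_conds, cond_ss)):
        rng = np.random.default_rng(ss)
        noise = rng.normal(0.0, config.noise_sigma, size=(n_prot, config.n_replicates))
        block = np.exp2(expected[cond][:, None] + noise)
        if config.dropout_rate > 0:
            drop = rng.random((n_prot, config.n_replicates)) < config.dropout_rate
            block[drop] = 0.0
        mat[:, ci * config.n_replicates:(ci + 1) * config.n_replicates] = block

    proteins = QuantTable(pd.DataFrame(mat, index=accessions, columns=cols),
                          mode="raw_intensity")

    peptides = _decompose_peptides(proteins, config, np.random.default_rng(pept_ss))
    return peptides, proteins, truth


def _decompose_peptides(proteins: QuantTable, config: SimConfig,
                        rng: np.random.Generator) -> PeptideTable:
    """Split each protein intensity across its observable peptides.

    Peptide ionisation weights are fixed per peptide (Dirichlet draw) and
    shared across replicates, so per-protein peptide sums equal the protein
    intensity exactly in every replicate.
    """
    lo, hi = config.peptides_per_protein_range
    accs = proteins.values.index.to_numpy()
    n_obs = rng.integers(lo, hi + 1, size=len(accs))

    pep_ids, pep_acc, weights = [], [], []
    for acc, k in zip(accs, n_obs):
        w = rng.dirichlet(np.ones(k))
        for j in range(k):
            pep_ids.append(f"{acc}_pep{j + 1}")
            pep_acc.append(acc)
            weights.append(w[j])

    w = np.asarray(weights)[:, None]
    prot_rows = proteins.values.loc[pep_acc].to_numpy()
    values = pd.DataFrame(w * prot_rows, index=pd.Index(pep_ids, name="peptide_id"),
                          columns=proteins.values.columns)
    return PeptideTable(
        values=values,
        accession=pd.Series(pep_acc, index=values.index, name="accession"),
        n_observable=pd.Series(n_obs, index=accs, name="n_observable"),
    )
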