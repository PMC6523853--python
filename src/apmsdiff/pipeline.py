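"""End-to-end pipeline driver.

Runs the whole differential interactomics analysis in order: quantification
(iBAQ, per-sample normalisation, optional log2), the background-referenced
combination test with per-protein medians, pairwise differential affinity
with permutation-test volcano calls, qualitative interactome comparison
(Jaccard, Venn regions), uncentered PCA with agglomerative clustering, and
optional over-representation analysis. Every decision flag and threshold is
recorded in a run manifest; identical config and seed reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plots
from .background import CombinationSet, combination_values, median_combination, replicate_overlap
from .compare import InteractomeSet, build_interactome, exclusive_partition, similarity_matrix
from .differential import VolcanoConfig, differential_affinity, permutation_test, volcano_calls
from .enrich import AnnotationTable, hypergeom_enrich
from .io import RunConfig, write_quant_tsv
from .project import ProjectionResult, hac_cluster, median_profile_matrix, pca_uncentered, sweep_partitions
from .quant import apply_zero_policy, compute_ibaq, normalize_total, to_log2
from .simulate import SimConfig, generate_experiment
from .tables import ConfigurationError, PeptideTable, QuantTable

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """Everything an end-to-end run produces, plus the manifest."""

    quant: QuantTable
    combinations: dict[str, CombinationSet]
    medians: dict[str, pd.Series]
    replicate_overlap: dict[str, float]
    differential: dict[tuple[str, str], pd.DataFrame]
    interactomes: dict[str, InteractomeSet]
    similarity: pd.DataFrame | None
    exclusive_regions: dict[tuple[str, ...], set[str]] | None
    projection: ProjectionResult | None
    partitions: dict[int, pd.Series] | None
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig,
                 proteins: QuantTable | None = None,
                 peptides: PeptideTable | None = None,
                 sim_config: SimConfig | None = None,
                 annotations: AnnotationTable | None = None) -> RunResult:
    """Execute the full analysis on provided tables or a fresh simulation."""
    # outdir is a pure sink location and never affects any number; leaving
    # it out keeps manifests of identical analyses byte-identical.
    manifest: dict = {"config": {k: v for k, v in cfg.to_dict().items()
                                 if k != "outdir"},
                      "stages": {}}
    truth = None

    if proteins is None and peptides is None:
        if sim_config is None:
            raise ConfigurationError("provide input tables or a SimConfig to simulate")
        peptides, proteins, truth = generate_experiment(sim_config)
        manifest["simulation"] = {k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in vars(sim_config).items()}
    if peptides is not None:
        ibaq = compute_ibaq(peptides)
    elif proteins.mode == "raw_intensity":
        ibaq = QuantTable(proteins.values, mode="raw_ibaq")  # already protein-level
    else:
        ibaq = proteins
    manifest["stages"]["ibaq"] = {"n_proteins": int(ibaq.values.shape[0]),
                                  "n_columns": int(ibaq.values.shape[1])}

    bg = cfg.background_condition
    if bg not in ibaq.conditions:
        raise ConfigurationError(
            f"background condition {bg!r} missing from input; have {ibaq.conditions}")
    baits = [c for c in ibaq.conditions if c != bg]

    norm = normalize_total(ibaq)
    detected = norm.values > 0  # pre-policy detection mask

    if cfg.route == "holistic":
        working = to_log2(norm, cfg.zero_policy)
        comb_mode = "log2diff"
    else:
        working = apply_zero_policy(norm, cfg.zero_policy)
        comb_mode = "ratio"

    combos: dict[str, CombinationSet] = {}
    medians: dict[str, pd.Series] = {}
    overlaps: dict[str, float] = {}
    control = working.condition(bg)
    for cond in baits:
        cs = combination_values(working.condition(cond), control, comb_mode, condition=cond)
        # Under the floor policy a protein absent from every bait replicate
        # still carries floor values; it has no evidence for this condition,
        # so restrict the set to proteins detected at least once.
        det = detected.xs(cond, axis=1, level="condition").any(axis=1)
        keep = cs.values.index[det.reindex(cs.values.index, fill_value=False)]
        cs = CombinationSet(cond, cs.values.loc[keep], cs.mode)
        combos[cond] = cs
        medians[cond] = median_combination(cs)
        overlaps[cond] = replicate_overlap(ibaq.condition(cond), cfg.overlap_method)
        manifest["stages"].setdefault("combinations", {})[cond] = {
            "n_proteins": int(cs.values.shape[0]), "n_pairs": int(cs.n_pairs())}
    manifest["stages"]["replicate_overlap_pct"] = {
        c: round(v, 3) for c, v in overlaps.items()}

    vcfg = VolcanoConfig(
        b_perm=cfg.b_perm, p_threshold=cfg.p_threshold,
        delta_threshold=cfg.delta_threshold,
        classification_threshold=cfg.classification_threshold,
        statistic=cfg.permutation_statistic, permutation_unit=cfg.permutation_unit,
        seed=cfg.seed)

    differential: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in itertools.combinations(baits, 2):
        if cfg.route == "holistic":
            delta = differential_affinity(medians[a], medians[b], route="holistic")
            cs_a, cs_b = combos[a], combos[b]
        else:
            delta = differential_affinity(medians[a], medians[b], route="ibaq_ratio")
            # The permutation statistic operates on the log2 scale.
            cs_a = CombinationSet(a, np.log2(combos[a].values), "log2diff")
            cs_b = CombinationSet(b, np.log2(combos[b].values), "log2diff")
        p = permutation_test(cs_a, cs_b, vcfg)
        table = volcano_calls(delta, p, vcfg)
        differential[(a, b)] = table
        manifest["stages"].setdefault("differential", {})[f"{a}_vs_{b}"] = {
            "n_tested": int(table.shape[0]),
            "n_volcano_hits": int(table["volcano_hit"].sum()),
            "n_higher_A": int((table["call"] == "higher_A").sum()),
            "n_higher_B": int((table["call"] == "higher_B").sum()),
        }

    interactomes = {c: build_interactome(ibaq.condition(c), c, cfg.min_replicates)
                    for c in baits}
    manifest["stages"]["interactomes"] = {c: len(s) for c, s in interactomes.items()}
    sim_mat = similarity_matrix(list(interactomes.values())) if len(baits) >= 2 else None
    regions = (exclusive_partition(list(interactomes.values()))
               if 2 <= len(baits) <= 4 else None)
    if regions is not None:
        manifest["stages"]["venn_regions"] = {
            "+".join(k): len(v) for k, v in sorted(regions.items())}

    projection = partitions = None
    if len(baits) >= 2:
        profiles = median_profile_matrix(medians, fill="floor")
        projection = pca_uncentered(profiles)
        cluster_input = (projection.scores.iloc[:, :3]
                         if cfg.cluster_on_scores else profiles)
        lo, hi = cfg.cluster_k_range
        partitions = sweep_partitions(cluster_input, range(lo, hi + 1))
        k = min(max(cfg.cluster_k, 2), cluster_input.shape[0])
        labels = (partitions[k] if k in partitions
                  else hac_cluster(cluster_input, k))
        projection.cluster_labels = labels
        projection.k = k
        manifest["stages"]["projection"] = {
            "explained_fraction": [round(float(f), 6)
                                   for f in projection.explained_fraction[:4]],
            "k": k,
            "cluster_sizes": labels.value_counts().sort_index().tolist(),
        }

    enrichment: dict[str, pd.DataFrame] = {}
    if annotations is not None:
        universe = set(ibaq.values.index)
        for (a, b), table in differential.items():
            hits = set(table.index[table["volcano_hit"]])
            if hits:
                enrichment[f"{a}_vs_{b}"] = hypergeom_enrich(hits, universe, annotations)
        manifest["stages"]["enrichment"] = {
            name: int(df["significant"].sum()) for name, df in enrichment.items()}

    result = RunResult(quant=ibaq, combinations=combos, medians=medians,
                       replicate_overlap=overlaps, differential=differential,
                       interactomes=interactomes, similarity=sim_mat,
                       exclusive_regions=regions, projection=projection,
                       partitions=partitions, enrichment=enrichment,
                       truth=truth, manifest=manifest)
    if cfg.outdir:
        _write_outputs(result, cfg)
    return result


def _write_outputs(result: RunResult, cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_quant_tsv(result.quant, out / "ibaq.tsv")
    for cond, cs in result.combinations.items():
        flat = cs.values.copy()
        flat.columns = [f"s{s}_c{c}" for s, c in cs.values.columns]
        flat.to_csv(out / f"combinations_{cond}.tsv", sep="\t")
    for (a, b), table in result.differential.items():
        table.to_csv(out / f"differential_{a}_vs_{b}.tsv", sep="\t")
        if cfg.make_plots:
            plots.volcano_plot(table, out / f"volcano_{a}_vs_{b}.png",
                               cfg.delta_threshold, cfg.p_threshold,
                               title=f"{a} vs {b}")
    if result.similarity is not None:
        result.similarity.to_csv(out / "jaccard.tsv", sep="\t")
        if cfg.make_plots:
            plots.similarity_heatmap(result.similarity, out / "jaccard_heatmap.png")
    if result.projection is not None:
        result.projection.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        if result.projection.cluster_labels is not None:
            result.projection.cluster_labels.to_csv(out / "clusters.tsv", sep="\t")
        if cfg.make_plots and result.projection.scores.shape[1] >= 3:
            plots.projection_scatter3d(result.projection, out / "pca_3d.png")
    for name, df in result.enrichment.items():
        df.to_csv(out / f"enrichment_{name}.tsv", sep="\t")
    if result.truth is not None:
        result.truth.to_csv(out / "truth.tsv", sep="\t")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    logger.info("outputs written to %s", out)
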