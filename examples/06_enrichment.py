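"""Hypergeometric over-representation of an interactor set.

A generic stand-in for web-service GO enrichment: the study set is tested
against annotation terms within the background of all quantified proteins.
Here one term is constructed to cover the planted interactors, so it comes
out strongly enriched while random terms do not.
"""

import numpy as np

import apmsdiff as a

rng = np.random.default_rng(3)
sim = a.SimConfig(n_conditions=1, n_background_binders=400,
                  n_specific_per_condition=30, n_shared_specific=0, seed=3)
_, proteins, truth = a.generate_experiment(sim)

universe = set(truth.index)
planted = set(truth.index[truth["class"] == "specific:bait1"])

terms = {"planted_interactors": planted | set(rng.choice(sorted(universe), 10))}
for t in range(20):  # random decoy terms
    terms[f"decoy_{t}"] = set(rng.choice(sorted(universe), 25, replace=False))
ann = a.AnnotationTable(terms={k: frozenset(v) for k, v in terms.items()})

study = planted  # e.g. the volcano hits of a comparison
result = a.hypergeom_enrich(study, universe, ann)
print(result[["k", "K", "fold_enrichment", "p", "p_bh"]].head(5).round(4))
print(f"\nsignificant terms after Benjamini-Hochberg: "
      f"{int(result['significant'].sum())} of {len(result)}")
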