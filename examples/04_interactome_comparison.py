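"""Qualitative interactome sets: Jaccard similarity and exclusive interactors.

Membership follows the >=2-replicate rule: a protein belongs to a bait's
interactome if it is detected in at least two of its replicates. Sets are
compared by Jaccard index and partitioned into Venn regions; an external
annotation list (e.g. ER-membrane proteins) can be cross-referenced.
"""

import apmsdiff as a

sim = a.SimConfig(n_conditions=3, n_replicates=3, n_background_binders=250,
                  n_specific_per_condition=25, n_shared_specific=10,
                  dropout_rate=0.15, seed=5)
_, proteins, truth = a.generate_experiment(sim)

sets = [a.build_interactome(proteins.condition(c), c, min_replicates=2)
        for c in ("bait1", "bait2", "bait3")]
for s in sets:
    print(f"{s.condition}: {len(s)} interactors (>=2 of 3 replicates)")

mat = a.similarity_matrix(sets)
print("\nJaccard similarity (%):")
print((mat * 100).round(1).to_string())

regions = a.exclusive_partition(sets)
print("\nexclusive to bait1:", len(a.exclusive_to(sets, "bait1")), "proteins")
print("shared by all three:", len(regions.get(("bait1", "bait2", "bait3"), set())))

# cross-reference against an external accession list (here: the planted
# bait1-specific interactors, standing in for e.g. an ER-membrane catalogue)
er_like = set(truth.index[truth["class"] == "specific:bait1"])
n, _ = a.cross_reference(sets[0], er_like)
print(f"bait1 interactome hits {n} of {len(er_like)} proteins on the external list")
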