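"""Hypergeometric term enrichment of a module against the network universe.

A term collection in which one term ("cell wall") coincides with a
planted module: over-representation is tested with the upper-tail
hypergeometric probability and Benjamini-Hochberg control.
"""

import numpy as np

import hausnet as h

nm, truth = h.simulate_module_expression(seed=1)
universe = set(nm.gene_ids)
module1 = set(truth.module_labels.index[truth.module_labels == "module1"])

rng = np.random.default_rng(1)
terms = {"CW": ("cell wall organization", frozenset(module1))}
for t in range(6):
    members = rng.choice(sorted(universe), 40, replace=False)
    terms[f"T{t}"] = (f"random term {t}", frozenset(members))

res = h.enrich_terms(module1, universe, terms)
print(res[["term_id", "term_name", "k", "K", "n", "N",
           "p_value", "fdr"]].to_string(index=False,
                                        float_format=lambda x: f"{x:.3g}"))
# The planted term overlaps the target completely (k = K = n = 30) and
# dominates the ranking; random terms sit near their null expectation.
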