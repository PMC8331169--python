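"""Filter variable genes and cluster their tissue profiles on a 6x2 map.

High-CV genes are z-scored over tissue-class means and fed to a hexagonal
self-organizing map; the planted invasive-stage cluster (up-regulated in
both prehaustoria and haustoria) should collapse into a single unit.
"""

import hausnet as h

cm, truth = h.simulate_tissue_counts(n_genes=1000, seed=1)
nm = h.tmm_normalize(cm)

kept = h.cv_filter(nm, "threshold", 0.85)
print(f"{len(kept)} of {len(nm.gene_ids)} genes pass CV > 0.85")

sm = h.scale_genes(nm, by="tissue_mean", genes=kept)
fit = h.som_train(sm, 6, 2, epochs=100, seed=1)
summary = h.som_summarize(fit, sm)
print("genes per unit:", summary.gene_counts.to_dict())

focal = [g for g in truth.cluster_labels.index[
    truth.cluster_labels == "cluster1"] if g in fit.assignment.index]
unit = int(fit.assignment.loc[focal].mode().iloc[0])
inside = int((fit.assignment.loc[focal] == unit).sum())
print(f"planted invasive-stage cluster: {inside}/{len(focal)} genes in "
      f"unit {unit}")
print("unit profile (mean z per tissue):")
print(summary.means.loc[unit].round(2).to_string())
# The unit's profile should peak in prehaustoria and haustoria, the
# expression signature the planted cluster was given.
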