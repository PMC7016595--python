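"""Derive cell type-specific metagenes from a sorted-cell experiment.

Simulates a 4-compartment sorted-cell design (luminal, basal, fibromuscular,
endothelial; 5 replicates each), runs one-vs-rest differential expression
with permutation p-values and BH FDR control, and reports how well the
extracted signatures recover the planted markers.
"""

import prostasig as ps
from prostasig.io import annotation_series

cfg = ps.SimulationConfig(markers_per_type=20, n_background_genes=120, seed=0)
expr, annotations, truth = ps.simulate_sorted_experiment(cfg)
design = annotation_series(annotations, "cell_type")
print(f"sorted experiment: {expr.n_genes} genes x {expr.n_samples} samples")

panel = ps.extract_metagenes(expr, design, n_genes=20, n_perm=1000, seed=0)
for cell_type, genes in panel.panel:
    planted = set(truth.marker_sets.sets[cell_type])
    hit = len(planted & set(genes))
    print(f"  {cell_type:>13} metagene: {len(genes)} genes, "
          f"{hit}/{len(planted)} planted markers recovered")

recovered = {g for _, gs in panel.panel for g in gs}
planted = {g for _, gs in truth.marker_sets for g in gs}
jaccard = len(recovered & planted) / len(recovered | planted)
print(f"panel-level Jaccard vs planted truth: {jaccard:.3f}")
print("(1.0 would be perfect recovery; FDR control at a 3-SD effect size "
      "leaves a few borderline markers behind)")
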