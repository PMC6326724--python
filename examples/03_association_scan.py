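"""Structure-corrected functional allele-state association scan.

Runs the per-gene logistic scan of LoF state on the drought-timing index
and on flowering time, with three kinship principal components as fixed
covariates, Bonferroni adjustment, gene classification, and the
permutation negative control.
"""

import tempfile

import pandas as pd

import lofscan as L

cfg = L.SimulationConfig(seed=1)  # 500 ecotypes x 200 genes
grid = L.simulate_vhi_grid(cfg)
panel, truth = L.simulate_panel(cfg, grid)
with tempfile.TemporaryDirectory() as tmp:
    paths = panel.write(tmp, include_raster=False)
    matrix = L.call_lof(paths["vcf"], paths["gff3"], paths["fasta"])

# predictors: drought-timing index from the raster, phenotype, geography
profile = L.seasonal_frequency(grid)
index = L.drought_timing_index(profile)
vals, _ = L.extract_at_locations(index, panel.ecotypes, profile)
eco = panel.ecotypes.set_index("id")
predictors = pd.DataFrame(
    {"drought_timing": vals, "flowering": eco["flowering_days"]}
).reindex(matrix.states.index)

pcs = L.structure_pcs(L.kinship(panel.background), k=3)
print(f"kinship PCs explain {pcs.variance_explained.sum():.0%} of relatedness variance")

scans = L.scan_all_predictors(matrix.states, predictors, pcs)
classes = L.classify_genes(scans["drought_timing"], scans["flowering"])
print("\ngene classification (Bonferroni-adjusted P < 0.05):")
print("  drought axis:  ", dict(classes["drought_class"].value_counts()))
print("  flowering axis:", dict(classes["flowering_class"].value_counts()))

hits = classes.index[classes["drought_class"] != "none"]
correct = sum(truth.gene_class[g] != "null" for g in hits)
print(f"\n{correct}/{len(hits)} drought hits are true causal genes "
      f"(of {cfg.n_causal_spring_late + cfg.n_causal_summer_early} simulated)")

_, n_perm = L.permutation_scan(matrix.states, predictors, pcs, seed=99)
print(f"after one random permutation of ecotype labels: {n_perm} significant genes")
print("(permutation preserves allele frequencies but breaks genotype-environment links)")

qq = L.qq_diagnostics(scans["drought_timing"]["p_raw"])
print(f"\nQQ genomic inflation lambda = {qq.attrs['lambda_gc']:.2f} "
      "(causal enrichment inflates the tail; the bulk should sit near 1)")
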