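"""Knockout-experiment analysis: block-adjusted line means and sign test.

Simulates a shelf-stratified randomized experiment (59 knockout lines x 10
replicates, 30 wild-type replicates), fits the mixed model with shelf and
tray as random intercepts, and tests whether knockout lines flower later
than the wild type.
"""

import lofscan as L

cfg = L.SimulationConfig(seed=5, n_ecotypes=50, n_genes=70,
                         n_causal_spring_late=59, n_causal_summer_early=0)
grid = L.simulate_vhi_grid(cfg)
_, truth = L.simulate_panel(cfg, grid)

table = L.simulate_knockout_experiment(cfg, truth)
print(f"experiment: {table['line'].nunique() - 1} knockout lines + wild type, "
      f"{len(table)} plants on {table['shelf'].nunique()} shelves")

means = L.adjusted_line_means(table, wild_type=cfg.wild_type)
wt = means.loc[cfg.wild_type]
print(f"wild-type adjusted mean: {wt['adjusted_mean']:.1f} days "
      f"(n = {wt['n_reps']:.0f})")

result = L.sign_test(means, wild_type=cfg.wild_type)
print(f"\n{result['n_later']} of {result['n_lines']} lines flowered later "
      f"than the wild type")
print(f"sign test vs 50:50: chi2 = {result['chi2']:.2f}, p = {result['p']:.3g}")
print("\nA lopsided split confirms the prediction that knocking out candidate"
      "\ngenes (those whose natural LoF alleles associate with spring drought"
      "\nand/or later flowering) delays flowering.")

true_pos = sum(1 for ln, e in truth.line_effects.items()
               if ln != cfg.wild_type and e > 0)
print(f"\nground truth: {true_pos} lines had a positive simulated effect; "
      f"the sign test recovered {result['n_later']}.")
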