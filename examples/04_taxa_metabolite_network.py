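"""Correlate taxa with metabolites and export a significance-filtered edge list.

Metabolites are simulated with a Gaussian copula so chosen taxon-metabolite
pairs carry a known Spearman rank correlation; the analysis recovers them
with Benjamini-Hochberg control over all pairs.
"""

from normodi import (
    AbundanceTable,
    TrialDesign,
    generate_correlated_metabolites,
    generate_trial,
    results_to_frame,
    spearman_matrix,
    to_relative_abundance,
)

trial = generate_trial(TrialDesign(seed=1))
linked = [
    ("taxon_0003", "metabolite_0000", 0.8),
    ("taxon_0010", "metabolite_0001", -0.6),
]
metabolites = generate_correlated_metabolites(trial, 15, linked, seed=1)

rel = to_relative_abundance(trial.combined())
taxa = AbundanceTable(rel.data.iloc[:, :20], state="raw")

results = spearman_matrix(taxa, metabolites, threshold=0.05, adjust=True)
frame = results_to_frame(results)
kept = frame[frame.kept].sort_values("p_adj")

print(f"{len(frame)} taxon-metabolite pairs tested, {len(kept)} kept "
      "(BH-adjusted p < 0.05):\n")
print(kept.head(8).to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nthe two planted links (taxon_0003~metabolite_0000 at rho=0.8,")
print("taxon_0010~metabolite_0001 at rho=-0.6) top the list; everything else")
print("is noise and is screened out by the BH step-up.")
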