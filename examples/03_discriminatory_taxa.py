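"""Find taxa that discriminate between trial arms (LEfSe-style).

Each taxon is gated by a Kruskal-Wallis test across arms; survivors get a
log10 linear-discriminant effect size on the per-million abundance axis.
A taxon is discriminatory when kw_p < 0.05 and the LDA score exceeds 2.
"""

from normodi import TrialDesign, generate_trial, lda_effect_size, to_relative_abundance

trial = generate_trial(TrialDesign(seed=1))
combined = trial.combined(("HC_test", "NIP", "Placebo", "Synbiotic"))
rel = to_relative_abundance(combined)

results = lda_effect_size(
    rel, trial.metadata, kw_alpha=0.05, lda_threshold=2.0, n_boot=30, seed=1
)

hits = sorted((r for r in results if r.passed), key=lambda r: -r.lda_log10)
print(f"{len(hits)} of {len(results)} taxa are discriminatory "
      "(KW p < 0.05, LDA log10 > 2):\n")
print(f"{'taxon':<14} {'kw_p':>9} {'LDA log10':>10}  enriched in")
for r in hits[:12]:
    print(f"{r.feature_id:<14} {r.kw_p:>9.2e} {r.lda_log10:>10.2f}  {r.enriched_group}")

truth = set(trial.truth["taxon"])
recovered = sum(r.feature_id in truth for r in hits)
print(f"\n{recovered}/{len(hits)} of the reported taxa are genuinely shifted "
      f"(generator injected {len(truth)} shifts); the LDA score ranks the")
print("strongest compositional differences first.")
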