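"""Full pipeline on a simulated fibroblast population.

Simulates the built-in 21-locus panel (11 partially silenced Z-like loci
plus 10 autosomal controls), then runs the complete inference: diploid
filtering, per-probe efficiency from the heterogametic sex, error bound from
the autosomal controls, and the error-adjusted inactivation test with
Bonferroni correction.
"""
import allelefish as af

config = af.study_panel_config("chicken", seed=1)
config = af.SimConfig(**{**config.__dict__, "n_homogametic": 400, "n_heterogametic": 400})
records = af.simulate_population(config)
panel = af.panel_from_config(config)

scores = af.score_panel(records, panel)
truth = {l.probe_id: l.silencing_prob for l in config.loci}

print(f"excluded non-diploid nuclei: {scores.n_excluded_nondiploid}")
print(f"error bound from controls:   {scores.error.max_error_rate * 100:.2f}%")
print(f"Bonferroni family size:      {scores.family_size}")
print()
print("probe    true_s  pct_1_active  p_adjusted   significant")
for r in sorted(scores.results, key=lambda r: r.probe_id):
    print(
        f"{r.probe_id:8s} {truth[r.probe_id]:5.2f}   {r.pct_1_active:8.1f}%    "
        f"{r.p_adj_bonferroni:10.3g}   {r.significant}"
    )
print()
print("Every truly inactivated locus should be flagged; the one-signal")
print("percentage exceeds the ~5-10% detection-failure background roughly in")
print("proportion to the locus's silencing probability.")
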