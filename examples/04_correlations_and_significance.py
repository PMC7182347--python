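"""Full pipeline: feature table, correlations, resampling significance.

Runs the complete analysis on a 40-member synthetic family and prints the
Pearson correlations of delta with the key fluctuation features, plus the
subset-resampling majority-vote significance test (10 rounds x 15 subsets;
unanimous signs give p = 2^-10).
"""

from pathlib import Path

from disorderlink import FamilyConfig, RunConfig, run_pipeline

cfg = RunConfig(outdir=Path("example_run"),
                family=FamilyConfig(n_proteins=40, length=120, seed=42),
                stats_seed=42)
res = run_pipeline(cfg)

print("family summary:", res.summary, "\n")
rows = res.report.delta_vs_feature.set_index("feature")
print("Pearson r(delta, feature):")
for feat in ("dav", "dsd", "ra1av", "ra1sd", "s2", "ss1e", "sss1", "phi1sd", "phi2sd"):
    print(f"  {feat:7s} {rows.loc[feat, 'r']:+.3f}   (n={rows.loc[feat, 'n_pairs']:.0f})")

rs = res.resampling["delta_vs_dav"]
print(f"\nresampling delta vs dav: round signs {rs['round_signs']}, "
      f"p = {rs['p_value']:.6f} ({rs['note']})")
print("\nPositive r for dav/dsd/RSA: disordered sites are exposed, with larger"
      "\nand noisier long-range contact distances. Negative r for sheet"
      "\npropensity: disorder avoids strands.")
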