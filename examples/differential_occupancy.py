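"""Position-wise and region-wise differential occupancy between strains.

Runs the per-position Student's t-test (the significance-bar analysis)
and the per-spacer Kolmogorov-Smirnov tests on a simulated experiment in
which the perturbed strain pauses 5x more strongly at planted motifs.
"""

from netpause import SimConfig
from netpause.pipeline import analyze_tracks, tracks_from_read_sets
from netpause.simulate import simulate_reads

config = SimConfig(seed=7, reads_per_replicate=50_000)
read_sets, template, truth = simulate_reads(config)
tracks, _ = tracks_from_read_sets(read_sets, template)
analysis = analyze_tracks(template, tracks, "ref", "perturbed")

calls = analysis.significance.counts()
testable = analysis.ttest_table[analysis.ttest_table.testable]
print(f"t-test at {len(testable)} testable positions (alpha = 0.05):")
print(f"  up in perturbed:   {calls['up']:5d} positions")
print(f"  down in perturbed: {calls['down']:5d} positions")
print(f"  no call:           {calls['none']:5d} positions")

print("\nKolmogorov-Smirnov test per spacer region "
      "(median occupancy value distributions):")
for ks in analysis.ks_results:
    print(f"  {ks.region:5s}  D = {ks.D:.3f}  p = {ks.p_value:.3g}")

print("\n'up' positions are where the perturbed strain accumulates polymerase "
      "(pausing); a small KS p-value says the whole occupancy distribution of "
      "that spacer differs between strains, not just isolated positions.")
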