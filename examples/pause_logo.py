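"""Call pause sites and build the Jensen-Shannon difference logo.

On a simulation with 20 planted TTTT->GGGG pause motifs, calls the top
2.5% occupied spacer positions per strain, checks how many planted sites
each strain's pause set recovers, and prints the LNT-centered difference
logo columns around the pause site.
"""

from netpause import SimConfig
from netpause.pipeline import analyze_tracks, tracks_from_read_sets
from netpause.simulate import simulate_reads

config = SimConfig(seed=11)  # full default depth: 2e5 reads x 3 replicates
read_sets, template, truth = simulate_reads(config)
tracks, _ = tracks_from_read_sets(read_sets, template)
analysis = analyze_tracks(template, tracks, "ref", "perturbed")

planted = set(truth.motif_positions)
for condition in ("ref", "perturbed"):
    pause_set = analysis.pause_sets[condition]
    hit = len(set(pause_set.positions.tolist()) & planted)
    print(f"{condition:9s}: {len(pause_set.positions)} pause positions "
          f"(top {pause_set.quantile:.1%} of {pause_set.n_eligible} eligible), "
          f"{hit}/{len(planted)} planted motifs recovered")

print("\ndifference logo (perturbed minus reference), offsets -8..+2 "
      "relative to the LNT:")
frame = analysis.logo.to_frame().set_index("offset")
print(frame.loc[-8:2].round(4).to_string())

print("\nPositive heights mark bases enriched around perturbed-strain pauses; "
      "the planted signature is a T-run at offsets -7..-4 and a G-run at "
      "-3..0, with the pause LNT on the last G (offset 0).")
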