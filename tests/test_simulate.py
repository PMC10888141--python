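"""Generator behaviour: planted motifs, occupancy model, reproducibility."""

import numpy as np
import pytest

from netpause import (
    MotifSpec,
    SimConfig,
    make_template,
    occupancy_distribution,
    simulate_reads,
)
from netpause.rdna import spacer_mask
from netpause.simulate import PERTURBED, REF


class TestMakeTemplate:
    def test_no_motifs_requested(self):
        config = SimConfig(seed=0, motif_spec=MotifSpec(n_motifs=0))
        template, truth = make_template(config)
        assert truth.motif_positions == []
        assert len(template) == config.template_length
        assert [r.name for r in template.regions] == [
            "ETS1", "18S", "ITS1", "5.8S", "ITS2", "25S", "ETS2",
        ]

    def test_exactly_n_motif_occurrences_at_truth_positions(self):
        config = SimConfig(seed=4, motif_spec=MotifSpec(4, 4, 5))
        template, truth = make_template(config)
        hits = []
        i = template.sequence.find("TTTTGGGG")
        while i != -1:
            hits.append(i + 7)  # LNT = last G
            i = template.sequence.find("TTTTGGGG", i + 1)
        assert hits == truth.motif_positions
        assert len(hits) == 5
        mask = spacer_mask(template)
        assert all(mask[p] for p in truth.motif_positions)

    def test_infeasible_placement_raises(self):
        config = SimConfig(
            seed=0,
            template_length=400,
            motif_spec=MotifSpec(4, 4, 50),
        )
        with pytest.raises(ValueError, match="cannot place"):
            make_template(config)

    def test_motifs_are_separated(self):
        _, truth = make_template(SimConfig(seed=9))
        positions = sorted(truth.motif_positions)
        gaps = np.diff(positions)
        assert (gaps >= 25 + 8).all()


class TestOccupancyDistribution:
    def test_flat_baseline_no_motifs_is_uniform(self):
        config = SimConfig(
            seed=0, baseline_amplitude=0.0, motif_spec=MotifSpec(n_motifs=0)
        )
        template, truth = make_template(config)
        dist = occupancy_distribution(template, truth, REF, config)
        assert np.allclose(dist, 1.0 / len(template))

    def test_unit_multiplier_makes_conditions_identical(self):
        config = SimConfig(seed=2, condition_multiplier=1.0)
        _, truth = make_template(config)
        assert np.array_equal(truth.occupancy[REF], truth.occupancy[PERTURBED])

    def test_hand_computed_four_position_distribution(self):
        # L = 4, flat baseline, one motif boosted 3x at position 2:
        # weights (1, 1, 3, 1) -> probabilities (1/6, 1/6, 1/2, 1/6)
        from netpause.rdna import RdnaTemplate, Region
        from netpause.simulate import TruthRecord

        config = SimConfig(
            seed=0,
            template_length=4,
            baseline_amplitude=0.0,
            base_pause_boost=3.0,
            motif_spec=MotifSpec(n_motifs=0),
        )
        template = RdnaTemplate("t", "ACGT", [Region("ETS1", 0, 4, "spacer")])
        truth = TruthRecord(motif_positions=[2])
        dist = occupancy_distribution(template, truth, REF, config)
        assert np.allclose(dist, [1 / 6, 1 / 6, 1 / 2, 1 / 6])

    def test_distribution_sums_to_one_and_multiplier_is_monotone(self):
        config = SimConfig(seed=6)
        template, truth = make_template(config)
        low = occupancy_distribution(template, truth, PERTURBED, config)
        high_cfg = SimConfig(seed=6, condition_multiplier=10.0)
        high = occupancy_distribution(template, truth, PERTURBED, high_cfg)
        motifs = np.array(truth.motif_positions)
        others = np.setdiff1d(np.arange(len(template)), motifs)
        assert abs(low.sum() - 1) < 1e-9 and abs(high.sum() - 1) < 1e-9
        assert (high[motifs] > low[motifs]).all()
        assert (high[others] < low[others]).all()


class TestSimulateReads:
    CHEAP = dict(reads_per_replicate=5000, n_replicates=2)

    def test_zero_contamination_bookkeeping(self):
        config = SimConfig(seed=1, contamination_fraction=0.0, **self.CHEAP)
        _, _, truth = simulate_reads(config)
        assert all(v == 0 for v in truth.contamination_counts.values())

    def test_zero_duplicate_rate_gives_unique_triples(self):
        config = SimConfig(seed=1, pcr_duplicate_rate=0.0, **self.CHEAP)
        read_sets, _, truth = simulate_reads(config)
        for key, frame in read_sets.items():
            n_unique = frame.drop_duplicates(
                subset=["start", "end", "strand", "umi"]
            ).shape[0]
            assert truth.duplicate_counts[key] == 0
            assert n_unique == len(frame) - truth.umi_collision_counts[key]

    def test_uniform_model_frequencies_within_binomial_error(self):
        # flat baseline, no motifs: each position's 3'-end frequency should
        # sit within 5 standard errors of 1/L
        config = SimConfig(
            seed=8,
            template_length=500,
            baseline_amplitude=0.0,
            motif_spec=MotifSpec(n_motifs=0),
            contamination_fraction=0.0,
            pcr_duplicate_rate=0.0,
            reads_per_replicate=100_000,
            n_replicates=2,
        )
        read_sets, template, _ = simulate_reads(config)
        frame = read_sets[(REF, 0)]
        L = len(template)
        n = len(frame)
        counts = np.bincount(frame["end"].to_numpy() - 1, minlength=L)
        p = 1.0 / L
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(counts / n - p) < 5 * se).all()

    def test_same_seed_is_byte_identical(self, tmp_path):
        from netpause import write_simulation

        config = SimConfig(seed=13, **self.CHEAP)
        outputs = []
        for name in ("a", "b"):
            read_sets, template, truth = simulate_reads(config)
            paths = write_simulation(tmp_path / name, read_sets, template, truth)
            outputs.append(paths)
        for key in outputs[0]:
            assert (
                outputs[0][key].read_bytes() == outputs[1][key].read_bytes()
            ), f"{key} differs between identically seeded runs"

    def test_read_geometry_matches_lnt(self):
        config = SimConfig(seed=1, **self.CHEAP)
        read_sets, template, _ = simulate_reads(config)
        frame = read_sets[(PERTURBED, 1)]
        lengths = frame["end"] - frame["start"]
        lo, hi = config.read_length_range
        assert (frame["start"] >= 0).all()
        assert (frame["end"] <= len(template)).all()
        # starts clipped at 0 may shorten reads; all others in range
        unclipped = frame["start"] > 0
        assert lengths[unclipped].between(lo, hi).all()
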