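"""Pause calling, context extraction, PWMs, and the JS difference logo."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpause import (
    ContextPwm,
    MedianProfile,
    build_pwm,
    call_pauses,
    difflogo,
    extract_contexts,
)
from netpause.pauses import PauseSet
from netpause.rdna import RdnaTemplate, Region


def entropy_oracle(p):
    """Plain-sum Shannon entropy in bits (0 log 0 = 0)."""
    return -sum(pi * np.log2(pi) for pi in p if pi > 0)


def make_template(length=1000, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return RdnaTemplate("t", seq, [Region("ETS1", 0, length, "spacer")])


class TestCallPauses:
    def test_quantile_count_is_forced_arithmetic(self):
        template = make_template(1000)
        values = np.linspace(1e-6, 1e-3, 1000)
        pauses = call_pauses(MedianProfile("ref", values), template, q=0.025)
        assert len(pauses.positions) == 25  # ceil(0.025 * 1000)
        assert pauses.n_eligible == 1000

    def test_ties_break_by_ascending_coordinate(self):
        template = make_template(100)
        pauses = call_pauses(MedianProfile("ref", np.full(100, 0.01)), template, 0.1)
        assert pauses.positions.tolist() == list(range(10))

    def test_zero_median_positions_are_ineligible(self):
        template = make_template(100)
        values = np.zeros(100)
        values[40:60] = np.arange(1, 21)
        pauses = call_pauses(MedianProfile("ref", values), template, q=0.1)
        assert pauses.n_eligible == 20
        assert pauses.positions.tolist() == [58, 59]  # two largest medians

    def test_pauses_respect_spacer_mask(self):
        seq = "A" * 100
        template = RdnaTemplate(
            "t", seq,
            [Region("ETS1", 0, 50, "spacer"), Region("18S", 50, 100, "mature")],
        )
        values = np.linspace(1, 2, 100)  # maxima all in the mature half
        pauses = call_pauses(MedianProfile("ref", values), template, q=0.1)
        assert (pauses.positions < 50).all()

    def test_no_eligible_positions_raises(self):
        template = make_template(50)
        with pytest.raises(ValueError, match="no spacer position"):
            call_pauses(MedianProfile("ref", np.zeros(50)), template)

    def test_recovers_planted_motifs_in_perturbed_condition(self, strong_sim):
        truth_positions = set(strong_sim.truth.motif_positions)
        pert = set(strong_sim.analysis.pause_sets["perturbed"].positions.tolist())
        recovered = len(pert & truth_positions) / len(truth_positions)
        assert recovered >= 0.9


class TestExtractContexts:
    def test_window_is_lnt_centered(self):
        template = make_template(200, seed=5)
        pauses = PauseSet("ref", 0.025, np.array([50]), 1.0, 100)
        contexts, dropped = extract_contexts(pauses, template, window=5)
        assert dropped == 0
        assert contexts == [template.sequence[48:53]]
        assert contexts[0][2] == template.sequence[50]

    def test_out_of_bounds_windows_dropped_and_counted(self):
        template = make_template(100)
        pauses = PauseSet("ref", 0.025, np.array([1, 50, 99]), 1.0, 100)
        contexts, dropped = extract_contexts(pauses, template, window=21)
        assert dropped == 2 and len(contexts) == 1

    def test_in_bounds_set_is_conserved(self):
        template = make_template(500, seed=2)
        positions = np.arange(100, 125)
        pauses = PauseSet("ref", 0.025, positions, 1.0, 400)
        contexts, dropped = extract_contexts(pauses, template, window=3)
        assert dropped == 0 and len(contexts) == 25
        assert all(len(c) == 3 for c in contexts)

    def test_even_window_rejected(self):
        template = make_template(100)
        pauses = PauseSet("ref", 0.025, np.array([50]), 1.0, 100)
        with pytest.raises(ValueError, match="odd"):
            extract_contexts(pauses, template, window=4)


class TestBuildPwm:
    def test_pure_column_without_pseudocount(self):
        pwm = build_pwm(["AA", "AA"], pseudocount=0.0)
        assert np.allclose(pwm.matrix, [[1, 0, 0, 0], [1, 0, 0, 0]])

    def test_uniform_column(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
        assert np.allclose(pwm.matrix, [[0.25, 0.25, 0.25, 0.25]])

    def test_pseudocount_arithmetic(self):
        pwm = build_pwm(["A", "A", "C"], pseudocount=0.5)
        assert np.allclose(pwm.matrix, [[0.5, 0.3, 0.1, 0.1]])

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        contexts = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(30)]
        pwm = build_pwm(contexts)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)

    def test_empty_and_ragged_inputs_rejected(self):
        with pytest.raises(ValueError, match="no contexts"):
            build_pwm([])
        with pytest.raises(ValueError, match="unequal lengths"):
            build_pwm(["AA", "AAA"])


def _pwm(columns, condition=""):
    return ContextPwm(condition, np.asarray(columns, float), 1, 0.0)


class TestDifflogo:
    def test_identical_columns_are_silent(self):
        pwm = _pwm([[0.25, 0.25, 0.25, 0.25]])
        result = difflogo(pwm, pwm)
        assert result.jsd[0] == 0.0
        assert not result.heights.any()

    def test_maximal_divergence_closed_form(self):
        result = difflogo(_pwm([[1, 0, 0, 0]]), _pwm([[0, 1, 0, 0]]))
        assert result.jsd[0] == pytest.approx(1.0)
        assert result.heights[0, 0] == pytest.approx(0.5)   # A enriched, perturbed
        assert result.heights[0, 1] == pytest.approx(-0.5)  # C enriched, reference

    def test_numeric_entropy_oracle(self):
        p = [0.5, 0.5, 0.0, 0.0]
        r = [0.25, 0.25, 0.25, 0.25]
        expected = entropy_oracle([0.375, 0.375, 0.125, 0.125]) - (
            entropy_oracle(p) + entropy_oracle(r)
        ) / 2.0
        result = difflogo(_pwm([p]), _pwm([r]))
        assert result.jsd[0] == pytest.approx(expected, abs=1e-12)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="widths differ"):
            difflogo(_pwm([[1, 0, 0, 0]]), _pwm([[1, 0, 0, 0]] * 2))

    @settings(derandomize=True, max_examples=100)
    @given(
        raw=st.lists(
            st.floats(min_value=0.01, max_value=1.0), min_size=8, max_size=8
        )
    )
    def test_antisymmetry_and_height_conservation(self, raw):
        p = np.asarray(raw[:4]) / np.sum(raw[:4])
        r = np.asarray(raw[4:]) / np.sum(raw[4:])
        forward = difflogo(_pwm([p]), _pwm([r]))
        backward = difflogo(_pwm([r]), _pwm([p]))
        assert 0.0 <= forward.jsd[0] <= 1.0
        assert np.abs(forward.heights[0]).sum() == pytest.approx(
            forward.jsd[0], abs=1e-9
        )
        assert backward.jsd[0] == pytest.approx(forward.jsd[0], abs=1e-12)
        assert np.allclose(backward.heights[0], -forward.heights[0], atol=1e-12)
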