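"""Shared fixtures: simulated experiments at the default study scale.

The session-scoped simulations are the expensive shared inputs: a
strong-effect experiment (planted pauses boosted 5x, perturbed a further
5x) used for recovery/separation checks, and a null experiment
(condition_multiplier = 1) used for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from netpause import SimConfig, simulate_reads
from netpause.pipeline import analyze_tracks, tracks_from_read_sets


@dataclass
class SimBundle:
    config: "SimConfig"
    read_sets: dict
    template: object
    truth: object
    tracks: dict
    analysis: object


def run_simulation(config: SimConfig) -> SimBundle:
    read_sets, template, truth = simulate_reads(config)
    tracks, _ = tracks_from_read_sets(read_sets, template)
    analysis = analyze_tracks(template, tracks, "ref", "perturbed")
    return SimBundle(config, read_sets, template, truth, tracks, analysis)


@pytest.fixture(scope="session")
def strong_sim() -> SimBundle:
    """Default study conditions: 20 planted motifs, boost 5, multiplier 5."""
    return run_simulation(SimConfig(seed=11))


@pytest.fixture(scope="session")
def null_sim() -> SimBundle:
    """Identical conditions (multiplier 1): every difference is noise."""
    return run_simulation(SimConfig(seed=7, condition_multiplier=1.0))


@pytest.fixture(scope="session")
def small_sim() -> SimBundle:
    """A light simulation for structural (non-statistical) checks."""
    return run_simulation(
        SimConfig(seed=3, reads_per_replicate=20_000)
    )


@pytest.fixture()
def toy_template_files(tmp_path):
    """100 nt template with ETS1(spacer) 0-40, 18S(mature) 40-80, ITS1(spacer) 80-100."""
    fasta = tmp_path / "toy.fa"
    fasta.write_text(">toy\n" + "ACGT" * 25 + "\n")
    bed = tmp_path / "toy.bed"
    bed.write_text(
        "toy\t0\t40\tETS1:spacer\n"
        "toy\t40\t80\t18S:mature\n"
        "toy\t80\t100\tITS1:spacer\n"
    )
    return fasta, bed
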