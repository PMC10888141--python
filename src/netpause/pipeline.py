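"""End-to-end orchestration: dedup -> occupancy -> QC -> tests -> logo.

:func:`analyze_tracks` is the in-memory core shared by the CLI, the
examples, and the acceptance machinery: given normalized replicate tracks
for two conditions it runs replicate QC, the per-position t-test, the
per-region KS tests, pause calling, and the difference logo.
:func:`run_pipeline` wraps it with file I/O and a run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffstats import (
    PcaResult,
    RegionKsResult,
    SignificanceTrack,
    ks_region_test,
    pca_samples,
    per_position_ttest,
    spearman_matrix,
)
from .io import positions_table, write_bedgraph, write_tsv
from .occupancy import MedianProfile, NormalizedTrack, median_profile, moving_average
from .pauses import (
    ContextPwm,
    DiffLogoResult,
    PauseSet,
    build_pwm,
    call_pauses,
    difflogo,
    extract_contexts,
)
from .rdna import RdnaTemplate, load_template
from .reads import deduplicate_umis, raw_occupancy, read_bed6
from .occupancy import normalize


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    condition: str
    replicate: int
    path: str


@dataclass
class RunConfig:
    """Validated configuration for a two-condition pipeline run."""

    fasta: str
    regions_bed: str
    samples: list[SampleSpec]
    reference_condition: str
    perturbed_condition: str
    outdir: str
    alpha: float = 0.05
    pause_quantile: float = 0.025
    window_unit: int = 200
    window_spacer: int = 75
    logo_window: int = 21
    umi_delim: str = "#"
    seed: int = 0

    def validate(self) -> None:
        conditions = {s.condition for s in self.samples}
        expected = {self.reference_condition, self.perturbed_condition}
        if conditions != expected:
            raise ValueError(
                f"sample sheet conditions {sorted(conditions)} do not match "
                f"configured conditions {sorted(expected)}"
            )
        for condition in expected:
            n = sum(1 for s in self.samples if s.condition == condition)
            if n < 2:
                raise ValueError(
                    f"condition {condition!r} has {n} replicate(s); need >= 2"
                )
        for path in [self.fasta, self.regions_bed] + [s.path for s in self.samples]:
            if not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")


@dataclass
class AnalysisResult:
    """Bundle of every analysis-stage output for one two-condition run."""

    spearman: pd.DataFrame
    pca: PcaResult
    ttest_table: pd.DataFrame
    significance: SignificanceTrack
    ks_results: list[RegionKsResult]
    profiles: dict[str, MedianProfile]
    smoothed_unit: dict[str, np.ndarray]
    pause_sets: dict[str, PauseSet]
    pwms: dict[str, ContextPwm]
    logo: DiffLogoResult
    dropped_contexts: dict[str, int] = field(default_factory=dict)


def analyze_tracks(
    template: RdnaTemplate,
    tracks: dict[str, list[NormalizedTrack]],
    reference_condition: str,
    perturbed_condition: str,
    *,
    alpha: float = 0.05,
    pause_quantile: float = 0.025,
    logo_window: int = 21,
    window_unit: int = 200,
) -> AnalysisResult:
    ref_tracks = tracks[reference_condition]
    pert_tracks = tracks[perturbed_condition]
    all_tracks = ref_tracks + pert_tracks

    spearman = spearman_matrix(all_tracks)
    pca = pca_samples(all_tracks)
    ttest_table, significance = per_position_ttest(
        ref_tracks, pert_tracks, alpha=alpha
    )

    profiles = {
        reference_condition: median_profile(ref_tracks),
        perturbed_condition: median_profile(pert_tracks),
    }
    smoothed = {
        condition: moving_average(profile.values, window_unit)
        for condition, profile in profiles.items()
    }
    ks_results = [
        ks_region_test(
            profiles[reference_condition], profiles[perturbed_condition], region
        )
        for region in template.regions_of_class("spacer")
    ]

    pause_sets, pwms, dropped = {}, {}, {}
    for condition, profile in profiles.items():
        pause_set = call_pauses(profile, template, q=pause_quantile)
        contexts, n_dropped = extract_contexts(pause_set, template, logo_window)
        pause_sets[condition] = pause_set
        pwms[condition] = build_pwm(contexts, condition=condition)
        dropped[condition] = n_dropped
    logo = difflogo(pwms[perturbed_condition], pwms[reference_condition])

    return AnalysisResult(
        spearman=spearman,
        pca=pca,
        ttest_table=ttest_table,
        significance=significance,
        ks_results=ks_results,
        profiles=profiles,
        smoothed_unit=smoothed,
        pause_sets=pause_sets,
        pwms=pwms,
        logo=logo,
        dropped_contexts=dropped,
    )


def tracks_from_read_sets(
    read_sets: dict[tuple[str, int], pd.DataFrame],
    template: RdnaTemplate,
) -> tuple[dict[str, list[NormalizedTrack]], dict[str, dict[str, int]]]:
    """Dedup + count + normalize in-memory read sets, keyed by condition.

    Returns the normalized tracks grouped by condition and a per-sample
    log of record counts (reads in/out, duplicates removed, drops).
    """
    tracks: dict[str, list[NormalizedTrack]] = {}
    log: dict[str, dict[str, int]] = {}
    for (condition, replicate), frame in sorted(read_sets.items()):
        sample_id = f"{condition}_rep{replicate}"
        unique, n_removed = deduplicate_umis(frame)
        track = raw_occupancy(unique, template, sample_id, condition)
        tracks.setdefault(condition, []).append(normalize(track))
        log[sample_id] = {
            "reads_in": len(frame),
            "reads_after_dedup": len(unique),
            "duplicates_removed": n_removed,
            "dropped_antisense": track.n_dropped_strand,
            "dropped_out_of_bounds": track.n_dropped_out_of_bounds,
        }
    return tracks, log


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-based end-to-end run; writes all stage outputs plus a manifest."""
    config.validate()
    template = load_template(config.fasta, config.regions_bed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    read_sets = {
        (s.condition, s.replicate): read_bed6(s.path, umi_delim=config.umi_delim)
        for s in config.samples
    }
    tracks, sample_log = tracks_from_read_sets(read_sets, template)
    result = analyze_tracks(
        template,
        tracks,
        config.reference_condition,
        config.perturbed_condition,
        alpha=config.alpha,
        pause_quantile=config.pause_quantile,
        logo_window=config.logo_window,
        window_unit=config.window_unit,
    )

    all_tracks = [t for condition in sorted(tracks) for t in tracks[condition]]
    for track in all_tracks:
        write_bedgraph(
            track.values, template.name, outdir / f"{track.sample_id}.norm.bedgraph"
        )
    for condition, profile in result.profiles.items():
        write_bedgraph(
            profile.values, template.name, outdir / f"median_{condition}.bedgraph"
        )
        write_bedgraph(
            result.smoothed_unit[condition],
            template.name,
            outdir / f"smoothed_{condition}.bedgraph",
        )

    write_tsv(
        positions_table(template, all_tracks, result.profiles),
        outdir / "positions.tsv",
    )
    write_tsv(result.spearman, outdir / "spearman.tsv", index=True)
    write_tsv(result.pca.coordinates, outdir / "pca.tsv", index=True)
    write_tsv(result.ttest_table, outdir / "ttest.tsv")
    write_tsv(
        pd.DataFrame(
            {
                "position": np.arange(len(template)) + 1,
                "call": result.significance.calls,
            }
        ),
        outdir / "significance_track.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {"region": ks.region, "D": ks.D, "p_value": ks.p_value}
                for ks in result.ks_results
            ]
        ),
        outdir / "ks.tsv",
    )
    for condition, pause_set in result.pause_sets.items():
        rows = []
        profile = result.profiles[condition]
        ranked = sorted(
            pause_set.positions.tolist(),
            key=lambda p: (-profile.values[p], p),
        )
        for rank, position in enumerate(ranked, start=1):
            region = template.region_at(position)
            rows.append(
                {
                    "position": position + 1,
                    "coordinate_0based": position,
                    "region": region.name if region else "",
                    "median_occupancy": profile.values[position],
                    "rank": rank,
                }
            )
        write_tsv(pd.DataFrame(rows), outdir / f"pauses_{condition}.tsv")
        write_tsv(
            pd.DataFrame(
                result.pwms[condition].matrix, columns=list("ACGT")
            ).assign(offset=result.logo.offsets),
            outdir / f"pwm_{condition}.tsv",
        )
    write_tsv(result.logo.to_frame(), outdir / "difflogo.tsv")

    manifest = {
        "netpause_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "pause_quantile": config.pause_quantile,
            "window_unit": config.window_unit,
            "window_spacer": config.window_spacer,
            "logo_window": config.logo_window,
        },
        "template": {"name": template.name, "length": len(template)},
        "samples": sample_log,
        "untestable_positions": int((~result.ttest_table["testable"]).sum()),
        "dropped_logo_contexts": result.dropped_contexts,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
    return result
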