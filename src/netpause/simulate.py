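"""Synthetic NET-seq data generator with planted pause sites.

The generator emulates the statistical structure the downstream analysis
assumes: a ~7 kb transcription unit tiled by four spacer and three mature
regions, a periodic baseline occupancy, T-run->G-run pause motifs whose
last G (the LNT) carries a multiplicative occupancy boost — stronger in
the perturbed condition — multinomial sampling of read 3' ends across
replicates, uniform mature-rRNA contamination, and PCR duplicates that
share coordinates and UMI so deduplication can provably remove them.

Everything is reproducible from the config seed, and a
:class:`TruthRecord` carries the planted positions and bookkeeping counts
that downstream tests check conservation against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rdna import RdnaTemplate, Region
from .reads import READ_COLUMNS, write_bed6

#: default region layout as (name, class, fraction of template length)
DEFAULT_REGION_LAYOUT = (
    ("ETS1", "spacer", 0.10),
    ("18S", "mature", 0.25),
    ("ITS1", "spacer", 0.05),
    ("5.8S", "mature", 0.03),
    ("ITS2", "spacer", 0.07),
    ("25S", "mature", 0.40),
    ("ETS2", "spacer", 0.10),
)

#: minimum gap between planted motifs (nt)
MOTIF_SEPARATION = 25

REF = "ref"
PERTURBED = "perturbed"
CONDITIONS = (REF, PERTURBED)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifSpec:
    """T-run -> G-run pause motif to plant in spacer regions."""

    t_run_length: int = 4
    g_run_length: int = 4
    n_motifs: int = 20
    spacer_only: bool = True

    @property
    def length(self) -> int:
        return self.t_run_length + self.g_run_length

    @property
    def sequence(self) -> str:
        return "T" * self.t_run_length + "G" * self.g_run_length


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated two-strain experiment.

    Defaults model triplicate libraries of 2x10^5 aligned reads over a
    7 kb unit with a 200 nt periodic baseline spanning a 17-fold
    peak-to-trough range, 20 planted TTTT->GGGG motifs boosted 5-fold in
    the reference strain and a further 5-fold in the perturbed strain,
    10% PCR duplicates and 30% mature-rRNA contamination.
    """

    seed: int = 0
    template_length: int = 7000
    motif_spec: MotifSpec = field(default_factory=MotifSpec)
    baseline_period: int = 200
    baseline_amplitude: float = 16.0
    base_pause_boost: float = 5.0
    condition_multiplier: float = 5.0
    n_replicates: int = 3
    reads_per_replicate: int = 200_000
    pcr_duplicate_rate: float = 0.1
    contamination_fraction: float = 0.3
    umi_length: int = 8
    read_length_range: tuple[int, int] = (20, 100)

    def __post_init__(self) -> None:
        if self.template_length < 1:
            raise ValueError("template_length must be >= 1")
        for name in ("pcr_duplicate_rate", "contamination_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.reads_per_replicate < 1:
            raise ValueError("reads_per_replicate must be >= 1")
        if self.baseline_amplitude < 0:
            raise ValueError("baseline_amplitude must be >= 0")
        if self.base_pause_boost < 1 or self.condition_multiplier < 1:
            raise ValueError("pause boost factors must be >= 1")
        lo, hi = self.read_length_range
        if not 1 <= lo <= hi:
            raise ValueError("read_length_range must satisfy 1 <= min <= max")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth and bookkeeping for one simulation."""

    motif_positions: list[int]
    occupancy: dict[str, np.ndarray] = field(default_factory=dict)
    pre_duplication_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    duplicate_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    contamination_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    umi_collision_counts: dict[tuple[str, int], int] = field(default_factory=dict)


def make_template(config: SimConfig) -> tuple[RdnaTemplate, TruthRecord]:
    """Random background sequence + region tiling + planted motifs.

    The motif LNT (truth position) is the last base of the G-run. Any
    accidental occurrence of the motif string elsewhere in the background
    is disrupted, so the planted positions are exactly the motif matches.
    """
    rng = np.random.default_rng(config.seed)
    length = config.template_length
    sequence = rng.choice(BASES, size=length)

    regions = _layout_regions(length)
    spacers = [r for r in regions if r.region_class == "spacer"]

    spec = config.motif_spec
    motif = np.array(list(spec.sequence))
    starts = _place_motifs(rng, spec, spacers if spec.spacer_only else regions)
    for start in starts:
        sequence[start : start + spec.length] = motif
    if spec.n_motifs > 0:
        _disrupt_spurious(rng, sequence, spec, starts)

    template = RdnaTemplate(
        name="synthetic_35S",
        sequence="".join(sequence),
        regions=tuple(regions),
    )
    lnt_positions = sorted(int(s + spec.length - 1) for s in starts)
    truth = TruthRecord(motif_positions=lnt_positions)
    for condition in CONDITIONS:
        truth.occupancy[condition] = occupancy_distribution(
            template, truth, condition, config
        )
    return template, truth


def _layout_regions(length: int) -> list[Region]:
    bounds = [0]
    acc = 0.0
    for _, _, fraction in DEFAULT_REGION_LAYOUT[:-1]:
        acc += fraction
        bounds.append(int(round(acc * length)))
    bounds.append(length)
    regions = []
    for (name, region_class, _), start, end in zip(
        DEFAULT_REGION_LAYOUT, bounds[:-1], bounds[1:]
    ):
        if end <= start:
            raise ValueError(
                f"template_length {length} too short to tile the default regions"
            )
        regions.append(Region(name, start, end, region_class))
    return regions


def _place_motifs(
    rng: np.random.Generator, spec: MotifSpec, regions: list[Region]
) -> list[int]:
    if spec.n_motifs == 0:
        return []
    candidates = np.concatenate(
        [
            np.arange(r.start, r.end - spec.length + 1)
            for r in regions
            if r.length >= spec.length
        ]
        or [np.array([], dtype=int)]
    )
    rng.shuffle(candidates)
    min_gap = spec.length + MOTIF_SEPARATION
    chosen: list[int] = []
    for start in candidates:
        if all(abs(start - other) >= min_gap for other in chosen):
            chosen.append(int(start))
            if len(chosen) == spec.n_motifs:
                return chosen
    raise ValueError(
        f"cannot place {spec.n_motifs} motifs of length {spec.length} with "
        f">={MOTIF_SEPARATION} nt separation inside the available regions"
    )


def _disrupt_spurious(
    rng: np.random.Generator,
    sequence: np.ndarray,
    spec: MotifSpec,
    planted_starts: list[int],
) -> None:
    """Mutate accidental motif matches so truth positions are exact."""
    planted = set(planted_starts)
    footprint = np.zeros(sequence.shape[0], dtype=bool)
    for start in planted_starts:
        footprint[start : start + spec.length] = True
    motif = spec.sequence
    while True:
        text = "".join(sequence)
        spurious = [
            i
            for i in _find_all(text, motif)
            if i not in planted
        ]
        if not spurious:
            return
        for start in spurious:
            # mutate a base of the match that lies outside every planted motif
            offsets = [
                k for k in range(spec.length) if not footprint[start + k]
            ]
            k = offsets[0]
            current = sequence[start + k]
            sequence[start + k] = rng.choice(BASES[BASES != current])


def _find_all(text: str, pattern: str) -> list[int]:
    hits, i = [], text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def occupancy_distribution(
    template: RdnaTemplate,
    truth: TruthRecord,
    condition: str,
    config: SimConfig,
) -> np.ndarray:
    """Probability of a nascent 3' end at each position.

    Unnormalized weight ``w(i) = 1 + A*(1 + sin(2*pi*i/T))/2`` (periodic
    baseline), times ``base_pause_boost`` at motif LNT positions, times
    ``condition_multiplier`` additionally in the perturbed condition;
    normalized to sum to 1. Occupancy is read as dwell time: a paused
    polymerase deposits proportionally more 3' ends at its active site.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    positions = np.arange(len(template))
    weights = 1.0 + config.baseline_amplitude * (
        1.0 + np.sin(2.0 * np.pi * positions / config.baseline_period)
    ) / 2.0
    motif_idx = np.asarray(truth.motif_positions, dtype=int)
    if motif_idx.size:
        weights[motif_idx] *= config.base_pause_boost
        if condition == PERTURBED:
            weights[motif_idx] *= config.condition_multiplier
    return weights / weights.sum()


def simulate_reads(
    config: SimConfig,
    template: RdnaTemplate | None = None,
    truth: TruthRecord | None = None,
) -> tuple[dict[tuple[str, int], pd.DataFrame], RdnaTemplate, TruthRecord]:
    """Draw per-replicate read sets for both conditions.

    Returns ``(read_sets, template, truth)`` where ``read_sets`` maps
    ``(condition, replicate_index)`` to a read DataFrame. Nascent 3' ends
    are multinomial draws from the condition's occupancy distribution; a
    ``contamination_fraction`` of reads instead land uniformly on mature
    regions; read starts extend a uniform-random length upstream (clipped
    at 0); every unique read gets a random UMI; finally a
    ``pcr_duplicate_rate`` share of the emitted list are verbatim copies
    of already-emitted reads.
    """
    if template is None or truth is None:
        template, truth = make_template(config)
    mature_positions = np.concatenate(
        [
            np.arange(r.start, r.end)
            for r in template.regions_of_class("mature")
        ]
        or [np.array([], dtype=int)]
    )
    if config.contamination_fraction > 0 and mature_positions.size == 0:
        raise ValueError(
            "contamination requested but the template has no mature regions"
        )
    rng = np.random.default_rng(config.seed + 1)
    read_sets: dict[tuple[str, int], pd.DataFrame] = {}
    for condition in CONDITIONS:
        probabilities = truth.occupancy[condition]
        for replicate in range(config.n_replicates):
            frame = _simulate_replicate(
                rng, config, template, probabilities, mature_positions,
                condition, replicate, truth,
            )
            read_sets[(condition, replicate)] = frame
    return read_sets, template, truth


def _simulate_replicate(
    rng: np.random.Generator,
    config: SimConfig,
    template: RdnaTemplate,
    probabilities: np.ndarray,
    mature_positions: np.ndarray,
    condition: str,
    replicate: int,
    truth: TruthRecord,
) -> pd.DataFrame:
    n_total = config.reads_per_replicate
    n_duplicates = int(round(config.pcr_duplicate_rate * n_total))
    n_unique = n_total - n_duplicates
    n_contaminant = (
        rng.binomial(n_unique, config.contamination_fraction)
        if config.contamination_fraction > 0
        else 0
    )

    nascent_counts = rng.multinomial(n_unique - n_contaminant, probabilities)
    lnt = np.repeat(np.arange(len(template)), nascent_counts)
    if n_contaminant:
        lnt = np.concatenate([lnt, rng.choice(mature_positions, n_contaminant)])
    rng.shuffle(lnt)

    lo, hi = config.read_length_range
    lengths = rng.integers(lo, hi + 1, size=n_unique)
    starts = np.maximum(lnt - lengths + 1, 0)
    ends = lnt + 1
    umis = _random_umis(rng, n_unique, config.umi_length)
    ids = np.array(
        [f"{condition}_r{replicate}_{i}" for i in range(n_unique)], dtype=object
    )

    frame = pd.DataFrame(
        {
            "reference": template.name,
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "strand": "+",
            "umi": umis,
            "read_id": ids,
        },
        columns=READ_COLUMNS,
    )
    if n_duplicates:
        copies = frame.iloc[rng.integers(0, n_unique, size=n_duplicates)]
        frame = pd.concat([frame, copies], ignore_index=True)

    key = (condition, replicate)
    truth.pre_duplication_counts[key] = n_unique
    truth.duplicate_counts[key] = n_duplicates
    truth.contamination_counts[key] = int(n_contaminant)
    truth.umi_collision_counts[key] = int(
        n_unique - frame.iloc[:n_unique].drop_duplicates(
            subset=["start", "end", "strand", "umi"]
        ).shape[0]
    )
    return frame


def _random_umis(
    rng: np.random.Generator, n: int, length: int
) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(row) for row in BASES[codes]], dtype=object)


def write_simulation(
    outdir: str | Path,
    read_sets: dict[tuple[str, int], pd.DataFrame],
    template: RdnaTemplate,
    truth: TruthRecord,
) -> dict[str, Path]:
    """Write template FASTA, region BED, per-replicate BED6, and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "template.fa"
    with open(fasta, "w") as handle:
        handle.write(f">{template.name}\n")
        seq = template.sequence
        for i in range(0, len(seq), 70):
            handle.write(seq[i : i + 70] + "\n")
    paths["fasta"] = fasta

    bed = outdir / "regions.bed"
    with open(bed, "w") as handle:
        for region in template.regions:
            handle.write(
                f"{template.name}\t{region.start}\t{region.end}\t"
                f"{region.name}:{region.region_class}\n"
            )
    paths["regions"] = bed

    for (condition, replicate), frame in sorted(read_sets.items()):
        path = outdir / f"{condition}_rep{replicate}.bed"
        write_bed6(frame, path)
        paths[f"{condition}_rep{replicate}"] = path

    truth_path = outdir / "truth.tsv"
    rows = [
        {
            "motif_lnt_position": p,
            "ref_probability": truth.occupancy[REF][p],
            "perturbed_probability": truth.occupancy[PERTURBED][p],
        }
        for p in truth.motif_positions
    ]
    pd.DataFrame(
        rows,
        columns=["motif_lnt_position", "ref_probability", "perturbed_probability"],
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
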