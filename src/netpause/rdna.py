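"""Transcription-unit template and region annotation.

The analysis operates on a single transcription unit (the yeast 35S
pre-rRNA in the motivating application), stored 5'->3' in the direction of
transcription. The unit is partitioned into named regions of two classes:
``mature`` (18S, 5.8S, 25S — positions where mature-rRNA contamination can
land) and ``spacer`` (ETS1, ITS1, ITS2, ETS2 — transcribed-spacer positions
carrying pure nascent signal). All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical region names whose class is fixed by the biology
CANONICAL_CLASS = {
    "ETS1": "spacer",
    "ITS1": "spacer",
    "ITS2": "spacer",
    "ETS2": "spacer",
    "18S": "mature",
    "5.8S": "mature",
    "25S": "mature",
}

REGION_CLASSES = ("spacer", "mature")


@dataclass(frozen=True)
class Region:
    """A named, classed interval of the template (0-based, half-open)."""

    name: str
    start: int
    end: int
    region_class: str

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"region {self.name!r}: class must be one of {REGION_CLASSES}, "
                f"got {self.region_class!r}"
            )
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"region {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        expected = CANONICAL_CLASS.get(self.name)
        if expected is not None and expected != self.region_class:
            raise ValueError(
                f"region {self.name!r} must be class {expected!r}, "
                f"got {self.region_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RdnaTemplate:
    """A transcription-unit sequence plus its ordered region annotation.

    The strand is fixed '+': the sequence is given in the direction of
    transcription, so downstream arithmetic never reverse-complements.
    """

    name: str
    sequence: str
    regions: tuple[Region, ...] = field(default_factory=tuple)
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("template sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(
                f"template sequence contains non-ACGT characters: {sorted(bad)}"
            )
        if self.strand != "+":
            raise ValueError("template strand is fixed '+'")
        object.__setattr__(self, "regions", tuple(self.regions))
        prev_end = None
        for region in self.regions:
            if region.end > len(self.sequence):
                raise ValueError(
                    f"region {region.name!r} end {region.end} exceeds template "
                    f"length {len(self.sequence)}"
                )
            if prev_end is not None and region.start < prev_end:
                raise ValueError(
                    f"regions overlap or are unsorted at {region.name!r}"
                )
            prev_end = region.end

    def __len__(self) -> int:
        return len(self.sequence)

    def region(self, name: str) -> Region:
        for region in self.regions:
            if region.name == name:
                return region
        raise KeyError(f"no region named {name!r}")

    def regions_of_class(self, region_class: str) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.region_class == region_class)

    def region_at(self, position: int) -> Region | None:
        """The region containing ``position``, or None if in a gap."""
        for region in self.regions:
            if region.start <= position < region.end:
                return region
        return None


def load_template(
    fasta_path: str | Path,
    regions_path: str | Path,
    *,
    allow_gaps: bool = False,
) -> RdnaTemplate:
    """Load a template from a single-record FASTA and a BED4 region file.

    The BED name column carries the region class as ``"NAME:CLASS"``
    (e.g. ``ETS1:spacer``). Unless ``allow_gaps`` is set, the regions must
    tile the sequence from its first to its last base with no holes.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"ambiguous reference: {fasta_path} holds {len(records)} records, "
            "expected exactly 1"
        )
    record = records[0]
    sequence = str(record.seq)
    if sequence != sequence.upper():
        logger.info("template %s: lowercase bases uppercased on load", record.id)
        sequence = sequence.upper()
    if "N" in sequence:
        raise ValueError(f"template {record.id!r} contains N bases; refusing to load")

    regions = _read_region_bed(regions_path)
    template = RdnaTemplate(name=record.id, sequence=sequence, regions=regions)
    if not allow_gaps:
        _check_tiling(template)
    return template


def _read_region_bed(path: str | Path) -> tuple[Region, ...]:
    regions: list[Region] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 BED columns, got {len(fields)}"
                )
            _, start, end, name_class = fields[:4]
            if ":" not in name_class:
                raise ValueError(
                    f"{path}:{lineno}: region name column must be 'NAME:CLASS', "
                    f"got {name_class!r}"
                )
            name, _, region_class = name_class.rpartition(":")
            try:
                regions.append(Region(name, int(start), int(end), region_class))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
    regions.sort(key=lambda r: r.start)
    return tuple(regions)


def _check_tiling(template: RdnaTemplate) -> None:
    if not template.regions:
        raise ValueError("template has no regions and gaps are not allowed")
    cursor = template.regions[0].start
    if cursor != 0:
        raise ValueError("regions do not start at position 0 (pass allow_gaps=True)")
    for region in template.regions:
        if region.start != cursor:
            raise ValueError(
                f"gap in region annotation before {region.name!r} at {region.start} "
                "(pass allow_gaps=True to permit)"
            )
        cursor = region.end
    if cursor != len(template):
        raise ValueError(
            f"regions end at {cursor} but template length is {len(template)} "
            "(pass allow_gaps=True to permit)"
        )


def spacer_mask(template: RdnaTemplate) -> np.ndarray:
    """Boolean vector, true exactly inside spacer-class regions."""
    mask = np.zeros(len(template), dtype=bool)
    for region in template.regions_of_class("spacer"):
        mask[region.start : region.end] = True
    return mask


def slice_region(values: np.ndarray, region: Region) -> np.ndarray:
    """``values[start:end]`` for a full-template per-position vector."""
    values = np.asarray(values)
    if values.shape[0] < region.end:
        raise ValueError(
            f"vector of length {values.shape[0]} does not cover region "
            f"{region.name!r} ending at {region.end}"
        )
    return values[region.start : region.end]
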