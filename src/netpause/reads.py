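"""Aligned-read handling: BED6 I/O, UMI deduplication, LNT counting.

NET-seq reads arrive as aligned intervals whose name field carries the
unique molecular identifier (``READID#UMI``). The 3' end of the alignment
is the last incorporated nucleotide (LNT) — the polymerase active-site
position — so a per-position occupancy track is simply a histogram of
read 3' ends after PCR-duplicate removal.

Read sets are held as pandas DataFrames with columns
``reference, start, end, strand, umi, read_id`` (:data:`READ_COLUMNS`);
the scalar :class:`AlignedRead` record is provided for convenience and
small inputs, and every operation accepts either form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rdna import RdnaTemplate

logger = logging.getLogger(__name__)

READ_COLUMNS = ["reference", "start", "end", "strand", "umi", "read_id"]

#: fields identifying one sequenced molecule: PCR duplicates share all four
DEDUP_KEY = ["start", "end", "strand", "umi"]


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read (0-based, half-open) with its UMI tag."""

    reference: str
    start: int
    end: int
    strand: str
    umi: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read {self.read_id!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: strand must be '+' or '-'")


def reads_to_frame(reads) -> pd.DataFrame:
    """Normalize a read list / DataFrame to the canonical DataFrame form."""
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in reads.columns]
        if missing:
            raise ValueError(f"read table is missing columns {missing}")
        return reads
    rows = [
        (r.reference, r.start, r.end, r.strand, r.umi, r.read_id) for r in reads
    ]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def frame_to_reads(frame: pd.DataFrame) -> list[AlignedRead]:
    return [
        AlignedRead(
            row.reference, int(row.start), int(row.end), row.strand, row.umi,
            row.read_id,
        )
        for row in frame.itertuples(index=False)
    ]


def read_bed6(path: str | Path, *, umi_delim: str = "#") -> pd.DataFrame:
    """Read a BED6 file whose name field is ``READID<delim>UMI``."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, start, end, name, _, strand = fields[:6]
            read_id, delim, umi = name.rpartition(umi_delim)
            if not delim:
                raise ValueError(
                    f"{path}:{lineno}: name field {name!r} lacks UMI delimiter "
                    f"{umi_delim!r}"
                )
            try:
                rows.append((chrom, int(start), int(end), strand, umi, read_id))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_bed6(frame: pd.DataFrame, path: str | Path, *, umi_delim: str = "#") -> None:
    frame = reads_to_frame(frame)
    with open(path, "w") as handle:
        for row in frame.itertuples(index=False):
            name = f"{row.read_id}{umi_delim}{row.umi}"
            handle.write(
                f"{row.reference}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n"
            )


def deduplicate_umis(reads):
    """Collapse PCR duplicates: one read kept per (start, end, strand, UMI).

    Retention is first-seen in input order. Reads at the same coordinates
    with different UMIs are distinct molecules and both survive.

    Returns ``(unique_reads, n_removed)`` with ``unique_reads`` in the same
    form (list or DataFrame) as the input.
    """
    as_list = not isinstance(reads, pd.DataFrame)
    frame = reads_to_frame(reads)
    if frame["reference"].nunique() > 1:
        raise ValueError(
            "reads map to multiple references: "
            f"{sorted(frame['reference'].unique())}"
        )
    unique = frame.drop_duplicates(subset=DEDUP_KEY, keep="first")
    n_removed = len(frame) - len(unique)
    unique = unique.reset_index(drop=True)
    return (frame_to_reads(unique) if as_list else unique), n_removed


def lnt_position(read: AlignedRead) -> int:
    """Last-incorporated-nucleotide position: the read's 3'-most base.

    Only sense-strand reads are meaningful on the single-strand template;
    an antisense read is an error here (the track builder filters and
    logs them instead of failing).
    """
    if read.strand != "+":
        raise ValueError(
            f"read {read.read_id!r} is on strand {read.strand!r}; LNT is defined "
            "only for reads on the transcription strand"
        )
    return read.end - 1


@dataclass
class OccupancyTrack:
    """Integer LNT counts per template position for one sample."""

    sample_id: str
    condition: str
    counts: np.ndarray
    n_dropped_strand: int = 0
    n_dropped_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("occupancy counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def raw_occupancy(
    reads,
    template: RdnaTemplate,
    sample_id: str = "",
    condition: str = "",
) -> OccupancyTrack:
    """Histogram deduplicated reads by LNT position.

    Antisense reads and reads whose 3' end falls outside the template are
    dropped with logged counts rather than raising, so mixed real-world
    BED files flow through.
    """
    frame = reads_to_frame(reads)
    length = len(template)
    sense = frame["strand"].to_numpy() == "+"
    lnt = frame["end"].to_numpy(dtype=np.int64) - 1
    in_bounds = (lnt >= 0) & (lnt < length)
    keep = sense & in_bounds
    n_strand = int((~sense).sum())
    n_oob = int((sense & ~in_bounds).sum())
    if n_strand or n_oob:
        logger.info(
            "sample %s: dropped %d antisense and %d out-of-bounds reads",
            sample_id, n_strand, n_oob,
        )
    counts = np.bincount(lnt[keep], minlength=length)
    return OccupancyTrack(
        sample_id=sample_id,
        condition=condition,
        counts=counts,
        n_dropped_strand=n_strand,
        n_dropped_out_of_bounds=n_oob,
    )
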