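"""Shared writers for bedGraph and TSV outputs.

FASTA and BED readers live next to the types they produce
(:func:`netpause.rdna.load_template`, :func:`netpause.reads.read_bed6`);
this module collects the output side used by several pipeline stages.
Coordinates in bedGraph/BED files are 0-based half-open; human-readable
report tables emit 1-based inclusive positions alongside.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .occupancy import MedianProfile, NormalizedTrack
from .rdna import RdnaTemplate


def write_bedgraph(
    values: np.ndarray, chrom: str, path: str | Path
) -> None:
    """Write per-position values as bedGraph, one line per nonzero run."""
    values = np.asarray(values)
    with open(path, "w") as handle:
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[start]:
                if values[start] != 0:
                    handle.write(
                        f"{chrom}\t{start}\t{i}\t{values[start]:g}\n"
                    )
                start = i


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Expand a bedGraph back into a dense per-position vector."""
    values = np.zeros(length)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 bedGraph columns"
                )
            _, start, end, value = fields
            values[int(start) : int(end)] = float(value)
    return values


def positions_table(
    template: RdnaTemplate,
    tracks: list[NormalizedTrack],
    profiles: dict[str, MedianProfile],
) -> pd.DataFrame:
    """Per-position table: coordinate, region, replicate values, medians.

    Mirrors the per-unit data frame the pipeline's outputs are organized
    around. ``position`` is 1-based inclusive for human readers; the
    0-based coordinate is kept alongside.
    """
    length = len(template)
    region_names = np.array(["" for _ in range(length)], dtype=object)
    for region in template.regions:
        region_names[region.start : region.end] = region.name
    data: dict[str, object] = {
        "coordinate_0based": np.arange(length),
        "position": np.arange(1, length + 1),
        "region": region_names,
    }
    for track in tracks:
        data[f"norm_{track.sample_id}"] = track.values
    for condition, profile in profiles.items():
        data[f"median_{condition}"] = profile.values
    return pd.DataFrame(data)


def write_tsv(frame: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")
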