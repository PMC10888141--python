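"""Library-size normalization, median profiles, and moving averages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reads import OccupancyTrack


@dataclass
class NormalizedTrack:
    """Per-position occupancy as a fraction of the sample's total counts.

    Values sum to 1 for any non-empty sample; an all-zero input yields an
    all-zero track flagged ``degenerate``.
    """

    sample_id: str
    condition: str
    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("normalized values must be non-negative")


@dataclass
class MedianProfile:
    """Position-wise median across a condition's normalized replicates."""

    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def normalize(track: OccupancyTrack, total: int | None = None) -> NormalizedTrack:
    """Divide each position's count by the sample total.

    ``total`` overrides the denominator (e.g. a library-wide read count
    when the track covers only the analyzed unit); by default the sum of
    the track itself is used.
    """
    denom = track.total if total is None else int(total)
    if denom <= 0:
        return NormalizedTrack(
            sample_id=track.sample_id,
            condition=track.condition,
            values=np.zeros_like(track.counts, dtype=float),
            degenerate=True,
        )
    return NormalizedTrack(
        sample_id=track.sample_id,
        condition=track.condition,
        values=track.counts / denom,
    )


def median_profile(tracks: list[NormalizedTrack]) -> MedianProfile:
    """Position-wise median over >=2 same-condition replicates.

    For an even replicate count the median is the mean of the two central
    order statistics (the usual convention).
    """
    if len(tracks) < 2:
        raise ValueError("median profile needs at least 2 replicate tracks")
    conditions = {t.condition for t in tracks}
    if len(conditions) != 1:
        raise ValueError(f"tracks mix conditions {sorted(conditions)}")
    lengths = {t.values.shape[0] for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"tracks have mismatched lengths {sorted(lengths)}")
    stacked = np.vstack([t.values for t in tracks])
    return MedianProfile(condition=conditions.pop(), values=np.median(stacked, axis=0))


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar mean with shrinking edges; output length = input length.

    At positions where the full window does not fit, the mean of the
    available positions is taken. For even windows the window extends
    ``(window-1)//2`` positions left and ``window//2`` right of center.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > values.shape[0]:
        raise ValueError(
            f"window {window} exceeds vector length {values.shape[0]}"
        )
    n = values.shape[0]
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - left)
    hi = np.minimum(n, idx + right + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)
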