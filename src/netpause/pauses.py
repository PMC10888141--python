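"""Pause-site calling and sequence-context difference logos.

Pause sites are the top quantile (default 2.5%) of spacer positions by
median normalized occupancy. Each pause contributes an LNT-centered
sequence window; per-condition base-frequency matrices over those windows
are compared column-by-column with the Jensen-Shannon divergence (bits),
and per-base signed heights apportion each column's divergence by the
base-frequency differences — positive heights mark bases enriched in the
perturbed condition, negative ones bases enriched in the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy import MedianProfile
from .rdna import RdnaTemplate, spacer_mask

ALPHABET = "ACGT"


@dataclass
class PauseSet:
    """Top-quantile occupied spacer positions for one condition."""

    condition: str
    quantile: float
    positions: np.ndarray  # sorted ascending, 0-based
    threshold_value: float  # smallest selected median occupancy
    n_eligible: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)


@dataclass
class ContextPwm:
    """Base-frequency matrix over LNT-centered pause contexts.

    ``matrix`` has shape (window, 4) in A, C, G, T order; every row sums
    to 1. A per-cell pseudocount keeps frequencies positive on small
    pause sets.
    """

    condition: str
    matrix: np.ndarray
    n_contexts: int
    pseudocount: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def window(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DiffLogoResult:
    """Per-column JS divergence and signed per-base letter heights.

    ``offsets`` are column positions relative to the LNT (center = 0).
    At every column the absolute heights sum to the column's divergence;
    a positive height means the base is more frequent in the perturbed
    condition.
    """

    offsets: np.ndarray
    jsd: np.ndarray  # bits, shape (window,)
    heights: np.ndarray  # shape (window, 4), A C G T

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"offset": self.offsets, "jsd_bits": self.jsd}
        )
        for k, base in enumerate(ALPHABET):
            frame[f"height_{base}"] = self.heights[:, k]
        return frame


def call_pauses(
    profile: MedianProfile,
    template: RdnaTemplate,
    q: float = 0.025,
) -> PauseSet:
    """Select the top-q fraction of occupied spacer positions.

    Eligible positions are spacer positions with median occupancy > 0
    (zeros carry no occupancy evidence and would dilute the quantile).
    Ranking is by median descending with ties broken by ascending
    coordinate; ceil(q * n_eligible) positions are selected.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    if profile.values.shape[0] != len(template):
        raise ValueError("profile length does not match template length")
    mask = spacer_mask(template)
    eligible = np.flatnonzero(mask & (profile.values > 0))
    if eligible.size == 0:
        raise ValueError("no spacer position has nonzero median occupancy")
    k = math.ceil(q * eligible.size)
    order = np.lexsort((eligible, -profile.values[eligible]))
    selected = eligible[order[:k]]
    threshold = float(profile.values[selected].min())
    return PauseSet(
        condition=profile.condition,
        quantile=q,
        positions=np.sort(selected),
        threshold_value=threshold,
        n_eligible=int(eligible.size),
    )


def extract_contexts(
    pauses: PauseSet,
    template: RdnaTemplate,
    window: int = 21,
) -> tuple[list[str], int]:
    """LNT-centered sense-strand windows around each pause position.

    Returns ``(contexts, n_dropped)``; windows running past either
    template end are dropped and counted.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    half = (window - 1) // 2
    contexts: list[str] = []
    n_dropped = 0
    for position in pauses.positions:
        start, end = position - half, position + half + 1
        if start < 0 or end > len(template):
            n_dropped += 1
            continue
        contexts.append(template.sequence[start:end])
    return contexts, n_dropped


def build_pwm(
    contexts: list[str],
    pseudocount: float = 0.5,
    condition: str = "",
) -> ContextPwm:
    """Column-wise base frequencies with an additive pseudocount per cell."""
    if not contexts:
        raise ValueError("no contexts to build a PWM from")
    lengths = {len(c) for c in contexts}
    if len(lengths) != 1:
        raise ValueError(f"contexts have unequal lengths {sorted(lengths)}")
    window = lengths.pop()
    counts = np.zeros((window, 4))
    index = {base: k for k, base in enumerate(ALPHABET)}
    for context in contexts:
        for j, base in enumerate(context):
            counts[j, index[base]] += 1
    matrix = (counts + pseudocount) / (len(contexts) + 4 * pseudocount)
    return ContextPwm(
        condition=condition,
        matrix=matrix,
        n_contexts=len(contexts),
        pseudocount=pseudocount,
    )


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits along the last axis, with 0*log0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def difflogo(pwm_perturbed: ContextPwm, pwm_ref: ContextPwm) -> DiffLogoResult:
    """Column-wise Jensen-Shannon difference logo, perturbed minus reference.

    For column distributions p (perturbed) and r (reference) with
    m = (p + r) / 2, the stack height is
    ``JSD = H(m) - (H(p) + H(r)) / 2`` in bits, and each base's signed
    height is ``sign(p_b - r_b) * JSD * |p_b - r_b| / sum|p - r|``.
    Identical columns get zero divergence and zero heights.
    """
    if pwm_perturbed.window != pwm_ref.window:
        raise ValueError(
            f"PWM widths differ: {pwm_perturbed.window} vs {pwm_ref.window}"
        )
    p = pwm_perturbed.matrix
    r = pwm_ref.matrix
    m = (p + r) / 2.0
    jsd = _entropy_bits(m) - (_entropy_bits(p) + _entropy_bits(r)) / 2.0
    jsd = np.clip(jsd, 0.0, None)  # guard tiny negative round-off
    delta = p - r
    total = np.abs(delta).sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(total > 0, np.abs(delta) / total, 0.0)
    heights = np.sign(delta) * jsd[:, None] * share
    half = pwm_ref.window // 2
    offsets = np.arange(pwm_ref.window) - half
    return DiffLogoResult(offsets=offsets, jsd=jsd, heights=heights)
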