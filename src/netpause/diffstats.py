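"""Replicate QC and between-condition differential tests.

QC: pairwise Spearman rank correlation between normalized replicates and
a sample-level PCA (samples are observations, positions features). The
differential layer runs a pooled-variance Student's t-test at every
template position, emitting an up/down/none significance track at
``alpha``, and a two-sample Kolmogorov-Smirnov test on the per-position
median occupancy values within each region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .occupancy import MedianProfile, NormalizedTrack
from .rdna import Region

DIRECTIONS = ("up", "down", "none")


@dataclass
class SignificanceTrack:
    """Per-position call: occupancy up, down, or unchanged in perturbed vs ref."""

    alpha: float
    calls: np.ndarray  # array of 'up' / 'down' / 'none'

    def counts(self) -> dict[str, int]:
        values, counts = np.unique(self.calls, return_counts=True)
        out = {d: 0 for d in DIRECTIONS}
        out.update(dict(zip(values.tolist(), counts.tolist())))
        return out


@dataclass
class RegionKsResult:
    region: str
    D: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 1.0:
            raise ValueError(f"KS statistic must be in [0, 1], got {self.D}")


def spearman_matrix(tracks: list[NormalizedTrack]) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between normalized tracks.

    Ties receive average ranks. A constant track has no rank variance, so
    its correlations are undefined and reported as NaN with a warning.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    lengths = {t.values.shape[0] for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"tracks have mismatched lengths {sorted(lengths)}")
    labels = [t.sample_id for t in tracks]
    n = len(tracks)
    matrix = np.eye(n)
    constant = [np.ptp(t.values) == 0 for t in tracks]
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                warnings.warn(
                    f"Spearman undefined for constant track pair "
                    f"({labels[i]}, {labels[j]}); reported as NaN",
                    stacklevel=2,
                )
                rho = np.nan
            else:
                rho = stats.spearmanr(tracks[i].values, tracks[j].values).statistic
            matrix[i, j] = matrix[j, i] = rho
    return pd.DataFrame(matrix, index=labels, columns=labels)


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x (PC1, PC2), with a condition column
    explained_variance_ratio: np.ndarray
    degenerate: bool = False


def pca_samples(tracks: list[NormalizedTrack], n_components: int = 2) -> PcaResult:
    """PCA over samples with positions as centered (unscaled) features."""
    if len(tracks) < 2:
        raise ValueError("PCA needs at least 2 samples")
    matrix = np.vstack([t.values for t in tracks])
    n_components = min(n_components, len(tracks) - 1, matrix.shape[1])
    if np.allclose(matrix, matrix[0]):
        coords = pd.DataFrame(
            np.zeros((len(tracks), n_components)),
            index=[t.sample_id for t in tracks],
            columns=[f"PC{k + 1}" for k in range(n_components)],
        )
        coords["condition"] = [t.condition for t in tracks]
        return PcaResult(coords, np.zeros(n_components), degenerate=True)
    model = PCA(n_components=n_components, svd_solver="full")
    transformed = model.fit_transform(matrix)
    coords = pd.DataFrame(
        transformed,
        index=[t.sample_id for t in tracks],
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    coords["condition"] = [t.condition for t in tracks]
    return PcaResult(coords, model.explained_variance_ratio_)


def per_position_ttest(
    ref_tracks: list[NormalizedTrack],
    pert_tracks: list[NormalizedTrack],
    alpha: float = 0.05,
    *,
    welch: bool = False,
) -> tuple[pd.DataFrame, SignificanceTrack]:
    """Two-sided Student's t-test at every position, perturbed vs reference.

    Pooled-variance by default (``welch=True`` switches to unequal
    variances). Degenerate positions where both groups have zero variance
    get p = 1 when the means agree and p = 0 otherwise, flagged in the
    table. Positions with all-zero values in both conditions are marked
    untestable (call 'none') and are meant to be excluded from any
    calibration denominator.
    """
    if len(ref_tracks) < 2 or len(pert_tracks) < 2:
        raise ValueError("need >=2 replicates per condition")
    ref = np.vstack([t.values for t in ref_tracks])
    pert = np.vstack([t.values for t in pert_tracks])
    if ref.shape[1] != pert.shape[1]:
        raise ValueError("conditions have mismatched track lengths")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_value = stats.ttest_ind(
            ref, pert, axis=0, equal_var=not welch
        )

    mean_ref = ref.mean(axis=0)
    mean_pert = pert.mean(axis=0)
    zero_var = (ref.var(axis=0) == 0) & (pert.var(axis=0) == 0)
    equal_means = mean_ref == mean_pert
    degenerate = zero_var
    p_value = np.where(zero_var, np.where(equal_means, 1.0, 0.0), p_value)
    t_stat = np.where(zero_var, 0.0, t_stat)
    untestable = (ref.sum(axis=0) == 0) & (pert.sum(axis=0) == 0)

    significant = (p_value < alpha) & ~equal_means & ~untestable
    calls = np.where(
        significant, np.where(mean_pert > mean_ref, "up", "down"), "none"
    ).astype(object)

    table = pd.DataFrame(
        {
            "position": np.arange(ref.shape[1]),
            "mean_ref": mean_ref,
            "mean_perturbed": mean_pert,
            "t_stat": t_stat,
            "p_value": p_value,
            "direction": calls,
            "degenerate": degenerate,
            "testable": ~untestable,
        }
    )
    return table, SignificanceTrack(alpha=alpha, calls=calls)


def ks_region_test(
    ref_profile: MedianProfile,
    pert_profile: MedianProfile,
    region: Region,
) -> RegionKsResult:
    """Two-sample KS on the distribution of median occupancy values in a region.

    Each condition contributes one observation per region position; D is
    the supremum ECDF difference and p comes from the asymptotic
    Kolmogorov distribution at the standard two-sample effective n.
    """
    if region.length < 2:
        raise ValueError(f"region {region.name!r} has length < 2")
    ref_values = ref_profile.values[region.start : region.end]
    pert_values = pert_profile.values[region.start : region.end]
    result = stats.ks_2samp(ref_values, pert_values, method="asymp")
    return RegionKsResult(
        region=region.name, D=float(result.statistic), p_value=float(result.pvalue)
    )
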