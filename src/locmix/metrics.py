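"""Distance-based behavioral metrics and their chance corrections.

These are the model-free summaries traditionally used on spatial recall
tasks: mean distance to the target (all error sources combined), distance
to the nearest displayed item (misbinding removed), their difference (a
misbinding proxy), and swap-error proportions (responses landing within a
threshold of a nontarget), optionally corrected for the chance rate implied
by the response's distance from the target.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .data import TrialDataset
from .geometry import deg_to_px

__all__ = [
    "target_distance",
    "nearest_neighbor_distance",
    "swap_errors",
    "swap_errors_mean_threshold",
    "split_half_reliability",
]


def target_distance(data: TrialDataset) -> np.ndarray:
    """Per-trial Euclidean distance from response to target."""
    return np.linalg.norm(data.responses - data.targets, axis=1)


def nearest_neighbor_distance(data: TrialDataset) -> np.ndarray:
    """Per-trial distance to the nearest displayed item (target included).

    Ties between the target and a nontarget resolve to the same value either
    way; the minimum is taken over the target and all finite nontargets.
    """
    d0 = target_distance(data)
    if data.nontargets.shape[1] == 0:
        return d0
    dnt = np.linalg.norm(data.responses[:, None, :] - data.nontargets, axis=2)
    dnt = np.where(data.nontarget_mask, dnt, np.inf)
    return np.minimum(d0, dnt.min(axis=1))


def _chance_swap_fraction(data: TrialDataset, threshold: float, n_circle: int = 360) -> np.ndarray:
    """Per-trial chance rate of a 'swap' at the response's target distance.

    Candidate response locations are ``n_circle`` evenly spaced points on
    the circle of radius = the trial's target distance, centred on the
    target; points off the screen are dropped, and the fraction of the
    remaining candidates lying within ``threshold`` of any nontarget is the
    chance rate subtracted by the corrected swap metric.
    """
    r = target_distance(data)
    ang = np.arange(n_circle) * (2 * np.pi / n_circle)
    circ = np.column_stack([np.cos(ang), np.sin(ang)])
    cand = data.targets[:, None, :] + r[:, None, None] * circ[None, :, :]  # (n, c, 2)
    onscreen = data.screen.contains(cand)
    dnt = np.linalg.norm(cand[:, :, None, :] - data.nontargets[:, None, :, :], axis=3)
    dnt = np.where(data.nontarget_mask[:, None, :], dnt, np.inf)
    hit = (dnt.min(axis=2) < threshold) & onscreen
    denom = onscreen.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, hit.sum(axis=1) / np.maximum(denom, 1), 0.0)


def swap_errors(
    data: TrialDataset,
    threshold: float | None = None,
    chance_corrected: bool = True,
    n_circle: int = 360,
) -> float:
    """Proportion of responses within ``threshold`` of a nontarget.

    The default threshold is 1.5 visual degrees (~44 px at a 40 cm viewing
    distance and 42 px/cm).  With ``chance_corrected`` the per-trial chance
    fraction of equally distant candidate locations that would count as
    swaps is subtracted before averaging, removing the imprecision
    confound.  Trials without nontargets are excluded; if no trial has a
    nontarget the metric is undefined and NaN is returned with a warning.
    """
    if threshold is None:
        threshold = deg_to_px(1.5)
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    has_nt = data.n_nontargets > 0
    if not has_nt.any():
        warnings.warn("swap errors undefined: no trial has a nontarget")
        return float("nan")
    dnt = np.linalg.norm(data.responses[:, None, :] - data.nontargets, axis=2)
    dnt = np.where(data.nontarget_mask, dnt, np.inf)
    swap = (dnt.min(axis=1) < threshold).astype(float)
    if chance_corrected:
        swap = swap - _chance_swap_fraction(data, threshold, n_circle)
    return float(swap[has_nt].mean())


def swap_errors_mean_threshold(data: TrialDataset, chance_corrected: bool = True, n_circle: int = 360) -> float:
    """Swap errors using the participant's mean target distance as threshold."""
    thr = float(target_distance(data).mean())
    if thr == 0.0:
        return 0.0  # all responses exactly on target: nothing can be a swap
    return swap_errors(data, threshold=thr, chance_corrected=chance_corrected, n_circle=n_circle)


def split_half_reliability(
    datasets: list,
    measure,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> float:
    """Split-half reliability of a per-participant measure.

    Each iteration randomly halves every participant's trials, applies
    ``measure`` (a callable dataset -> float) to each half, and Spearman-
    correlates the two resulting vectors across participants; the mean
    correlation over iterations is returned.  A measure that is constant
    across participants makes the correlation undefined (NaN, with a
    warning).
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 participants")
    if any(len(d) < 4 for d in datasets):
        raise ValueError("each participant needs at least 4 trials")
    rng = rng or np.random.default_rng(seed)
    rhos = []
    for _ in range(n_iterations):
        a_vals, b_vals = [], []
        for ds in datasets:
            perm = rng.permutation(len(ds))
            half = len(ds) // 2
            a_vals.append(measure(ds.subset(perm[:half])))
            b_vals.append(measure(ds.subset(perm[half:])))
        if np.std(a_vals) == 0 or np.std(b_vals) == 0:
            warnings.warn("measure constant across participants; reliability undefined")
            rhos.append(np.nan)
            continue
        rho = stats.spearmanr(a_vals, b_vals).statistic
        rhos.append(rho)
    return float(np.nanmean(rhos))
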