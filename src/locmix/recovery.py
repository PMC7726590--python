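"""Parameter-recovery experiments: sweep -> simulate -> fit -> summarise.

The principal validation device for the mixture models: simulate data from
known parameters over a sweep, refit, and examine recovery errors
(recovered - true), rank correlations between true and recovered values,
and how those degrade with design factors (trials, nontargets, placement
constraints, response biases).
"""

from __future__ import annotations

import os
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .bias import BiasSpec
from .components import kappa_to_sd, sd_to_kappa
from .model import CircularMixtureModel, SpatialMixtureModel
from .simulate import TaskDesign, simulate_dataset, simulate_dataset_1d, sweep_grid

__all__ = [
    "run_recovery",
    "recovery_correlations",
    "tradeoff_correlations",
    "compare_designs",
    "metric_sweep",
    "metric_parameter_correlations",
]

_PARAMS = ("sigma", "alpha", "beta", "gamma")


def _fit_one_2d(ds, fit_kw, bias_spec=None):
    model = SpatialMixtureModel(ds, misbinding=True, bias=bias_spec or "none")
    res = model.fit(**fit_kw)
    p = res.params
    return dict(
        est_beta=float(p["beta"]), est_gamma=float(p["gamma"]), est_sigma=float(p["sigma"]),
        est_alpha=res.alpha, llf=res.llf, converged=res.converged,
    )


def _fit_one_1d(ds, fit_kw):
    model = CircularMixtureModel(ds, misbinding=True)
    res = model.fit(**fit_kw)
    p = res.params
    sd_deg = np.rad2deg(kappa_to_sd(float(p["kappa"])))
    return dict(
        est_beta=float(p["beta"]), est_gamma=float(p["gamma"]), est_sigma=sd_deg,
        est_alpha=res.alpha, llf=res.llf, converged=res.converged,
    )


def run_recovery(
    cells: np.ndarray | None = None,
    design: TaskDesign | None = None,
    iterations: int = 10,
    seed: int = 0,
    model: str = "2d",
    fit_kw: dict | None = None,
    checkpoint: str | None = None,
    checkpoint_every: int = 50,
) -> pd.DataFrame:
    """Simulate and refit every sweep cell x iteration.

    ``cells`` is an array of (beta, gamma, sigma) rows (default: the full
    11x11x11 grid with ``gamma + beta <= 1``); for ``model="1d"`` the sigma
    column is circular SD in degrees.  Individual fit failures are recorded
    (``converged=False``, NaN estimates), not fatal.  With ``checkpoint``
    set, partial results are written to CSV and re-used on restart.

    Returns one row per record: true parameters (``true_*``), estimates
    (``est_*``), signed errors (``err_* = est - true``) and absolute errors.
    """
    if cells is None:
        cells = sweep_grid()
    design = design or TaskDesign()
    fit_kw = dict(fit_kw or {})
    rng = np.random.default_rng(seed)
    done = None
    if checkpoint and os.path.exists(checkpoint):
        done = pd.read_csv(checkpoint)
    rows: list[dict] = []
    n_done = 0 if done is None else len(done)
    count = 0
    for beta, gamma, sigma in np.asarray(cells, dtype=float):
        for it in range(iterations):
            count += 1
            if model == "1d":
                kappa = sd_to_kappa(np.deg2rad(sigma))
                ds = simulate_dataset_1d(design.n_trials, design.n_items, beta, gamma, kappa, rng)
            else:
                ds = simulate_dataset(design, beta, gamma, sigma, rng)
            if count <= n_done:
                continue  # RNG consumed to keep the stream aligned with the checkpoint
            rec = dict(
                true_beta=beta, true_gamma=gamma, true_sigma=sigma,
                true_alpha=1.0 - beta - gamma, iteration=it,
            )
            try:
                rec.update(_fit_one_1d(ds, fit_kw) if model == "1d" else _fit_one_2d(ds, fit_kw))
            except Exception as e:  # fit failures are recorded, not fatal
                rec.update(
                    est_beta=np.nan, est_gamma=np.nan, est_sigma=np.nan, est_alpha=np.nan,
                    llf=np.nan, converged=False, error=str(e),
                )
            rows.append(rec)
            if checkpoint and len(rows) % checkpoint_every == 0:
                _flush_checkpoint(done, rows, checkpoint)
    df = pd.DataFrame(rows)
    if done is not None:
        df = pd.concat([done, df], ignore_index=True)
    for p in _PARAMS:
        df[f"err_{p}"] = df[f"est_{p}"] - df[f"true_{p}"]
        df[f"abs_err_{p}"] = df[f"err_{p}"].abs()
    if checkpoint:
        df.to_csv(checkpoint, index=False)
    return df


def _flush_checkpoint(done, rows, path):
    df = pd.DataFrame(rows)
    if done is not None:
        df = pd.concat([done, df], ignore_index=True)
    df.to_csv(path, index=False)


def recovery_correlations(records: pd.DataFrame) -> pd.Series:
    """Pooled Spearman correlation between true and recovered parameters.

    Pools all records (cells x iterations) per parameter; a constant column
    yields NaN with the usual scipy warning.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    ok = records[[f"est_{p}" for p in _PARAMS]].notna().all(axis=1)
    out = {}
    for p in _PARAMS:
        out[p] = stats.spearmanr(
            records.loc[ok, f"true_{p}"], records.loc[ok, f"est_{p}"]
        ).statistic
    return pd.Series(out)


def tradeoff_correlations(posterior) -> pd.DataFrame:
    """Pairwise Pearson correlations among posterior draws of (beta, gamma, spread)."""
    samples = posterior.samples if hasattr(posterior, "samples") else pd.DataFrame(posterior)
    if len(samples) < 2:
        raise ValueError("need more than one posterior draw")
    return samples.corr(method="pearson")


def compare_designs(
    factor: str,
    levels,
    base_design: TaskDesign | None = None,
    cells: np.ndarray | None = None,
    iterations: int = 10,
    seed: int = 0,
    fit_kw: dict | None = None,
    bias_spec: BiasSpec | None = None,
    bias_values_by_level=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recovery-error summaries across levels of one design factor.

    ``factor`` is one of ``trials``, ``nontargets``, ``constraints`` or
    ``bias``.  For ``bias``, levels are generative bias magnitudes (the fits
    stay uncorrected; pair with a bias-corrected run for the correction
    contrast).  Returns ``(records, trends)`` where ``trends`` holds, per
    parameter, the linear-regression slope of |recovery error| on the level
    index and its p-value.
    """
    base_design = base_design or TaskDesign()
    if cells is None:
        cells = np.array([[0.3, 0.3, 30.0], [0.1, 0.1, 50.0], [0.2, 0.4, 10.0]])
    fit_kw = dict(fit_kw or {})
    frames = []
    for li, level in enumerate(levels):
        rng = np.random.default_rng(seed + 1000 * li)
        design = base_design
        bias_values = None
        if factor == "trials":
            design = replace(base_design, n_trials=int(level))
        elif factor == "nontargets":
            design = replace(base_design, n_items=int(level) + 1)
        elif factor == "constraints":
            design = replace(base_design, **level) if isinstance(level, dict) else base_design
        elif factor == "bias":
            bias_values = bias_values_by_level[li] if bias_values_by_level else level
        else:
            raise ValueError(f"unknown factor {factor!r}")
        rows = []
        for beta, gamma, sigma in np.asarray(cells, dtype=float):
            for it in range(iterations):
                ds = simulate_dataset(
                    design, beta, gamma, sigma, rng,
                    bias_spec=bias_spec if factor == "bias" else None,
                    bias_values=bias_values,
                )
                rec = dict(level=li, level_value=str(level), iteration=it,
                           true_beta=beta, true_gamma=gamma, true_sigma=sigma,
                           true_alpha=1 - beta - gamma)
                try:
                    rec.update(_fit_one_2d(ds, fit_kw))
                except Exception:
                    rec.update(est_beta=np.nan, est_gamma=np.nan, est_sigma=np.nan,
                               est_alpha=np.nan, llf=np.nan, converged=False)
                rows.append(rec)
        frames.append(pd.DataFrame(rows))
    records = pd.concat(frames, ignore_index=True)
    for p in _PARAMS:
        records[f"abs_err_{p}"] = (records[f"est_{p}"] - records[f"true_{p}"]).abs()
    trends = {}
    ok = records[[f"abs_err_{p}" for p in _PARAMS]].notna().all(axis=1)
    for p in _PARAMS:
        lr = stats.linregress(records.loc[ok, "level"], records.loc[ok, f"abs_err_{p}"])
        trends[p] = dict(slope=lr.slope, pvalue=lr.pvalue)
    return records, pd.DataFrame(trends).T


def metric_sweep(
    cells: np.ndarray | None = None,
    design: TaskDesign | None = None,
    iterations: int = 10,
    seed: int = 0,
    swap_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-run behavioral-metric means over a simulation sweep (no fitting).

    One row per (cell, iteration): the true parameters plus mean target
    distance, mean nearest-neighbor distance, their difference, and the
    fixed-threshold swap-error proportion (raw and chance-corrected).
    """
    if cells is None:
        cells = sweep_grid()
    design = design or TaskDesign()
    rng = np.random.default_rng(seed)
    rows = []
    for beta, gamma, sigma in np.asarray(cells, dtype=float):
        for it in range(iterations):
            ds = simulate_dataset(design, beta, gamma, sigma, rng)
            td = metrics.target_distance(ds)
            nn = metrics.nearest_neighbor_distance(ds)
            rows.append(dict(
                true_beta=beta, true_gamma=gamma, true_sigma=sigma,
                true_alpha=1 - beta - gamma, iteration=it,
                target_dist=float(td.mean()),
                nn_dist=float(nn.mean()),
                target_minus_nn=float(td.mean() - nn.mean()),
                swaps=metrics.swap_errors(ds, threshold=swap_threshold, chance_corrected=False),
                swaps_corrected=metrics.swap_errors(ds, threshold=swap_threshold, chance_corrected=True),
            ))
    return pd.DataFrame(rows)


def metric_parameter_correlations(runs: pd.DataFrame) -> pd.Series:
    """The headline metric-validity correlations (Spearman, pooled runs).

    target distance vs alpha, nearest-neighbor distance vs gamma,
    (target - NN) vs beta, corrected fixed-threshold swaps vs sigma, and
    NN distance vs sigma.
    """
    pairs = {
        "target_dist~alpha": ("target_dist", "true_alpha"),
        "nn_dist~gamma": ("nn_dist", "true_gamma"),
        "target_minus_nn~beta": ("target_minus_nn", "true_beta"),
        "swaps_corrected~sigma": ("swaps_corrected", "true_sigma"),
        "nn_dist~sigma": ("nn_dist", "true_sigma"),
    }
    out = {}
    for name, (m, p) in pairs.items():
        out[name] = stats.spearmanr(runs[m], runs[p]).statistic
    return pd.Series(out)
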