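"""Generative simulation of continuous-report and change-detection tasks.

The default design is the 3-item task used throughout the package's
validation work: three stimuli placed on a 1366x768 px screen, one randomly
designated the target, 100 trials.  Stimulus placement is uniform, optionally
subject to spacing constraints (minimum inter-item distance, distance from
the screen center, and margin from the screen edges) enforced by rejection
sampling.

Response generation follows the mixture model exactly: each trial's response
type is drawn with probabilities (alpha, beta, gamma); target and misbinding
responses are Gaussian around the chosen item with per-axis SD sigma,
*resampled* until they land on screen; misbinding picks uniformly among the
trial's nontargets; guesses are uniform over the screen (or drawn from a
supplied sampler).  An optional bias transform is applied to the finished
responses and then clipped to the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bias import BiasSpec, apply_bias
from .components import sd_to_kappa, wrap_angle
from .data import ChangeDataset, CircularDataset, TrialDataset
from .geometry import DEFAULT_SCREEN, ScreenGeometry

__all__ = [
    "TaskDesign",
    "generate_stimuli",
    "simulate_dataset",
    "simulate_dataset_1d",
    "simulate_change_dataset",
    "sweep_grid",
    "simulate_sweep",
    "PAPER_CONSTRAINTS",
    "ignore_update_design",
]

#: Spacing constraints used by the constrained-placement simulations:
#: >= 88 px between items and from the screen center (3 visual degrees at
#: 40 cm / 42 px-per-cm), >= 29 px from the screen edges (1 degree).
PAPER_CONSTRAINTS = dict(min_item_dist=88.0, min_center_dist=88.0, min_edge_dist=29.0)

_MAX_ATTEMPTS = 10_000  # rejection-sampling cap, per batch of trials


@dataclass(frozen=True)
class TaskDesign:
    """Geometry and structure of a simulated continuous-report task."""

    n_trials: int = 100
    n_items: int = 3  # 1 target + (n_items - 1) nontargets
    screen: ScreenGeometry = DEFAULT_SCREEN
    min_item_dist: float | None = None
    min_center_dist: float | None = None
    min_edge_dist: float | None = None
    nt_class_sizes: tuple[int, ...] | None = None  # e.g. (1, 2): one class-1 + two class-2 nontargets

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_items < 1:
            raise ValueError("need at least one trial and one item")
        if self.nt_class_sizes is not None and sum(self.nt_class_sizes) != self.n_items - 1:
            raise ValueError("nt_class_sizes must partition the nontargets")

    @property
    def n_nontargets(self) -> int:
        return self.n_items - 1

    def with_constraints(self, **kw) -> "TaskDesign":
        return replace(self, **kw)


def ignore_update_design(n_trials: int = 100, screen: ScreenGeometry = DEFAULT_SCREEN) -> TaskDesign:
    """Synthetic two-class layout: 1 nonprobed test shape + 2 distractors.

    Mirrors the structure of an ignore/update trial (four items, three
    nonprobed) for exercising the two-class misbinding model; it is a
    synthetic fixture, not a reconstruction of any experiment's trial list.
    """
    return TaskDesign(n_trials=n_trials, n_items=4, screen=screen, nt_class_sizes=(1, 2))


def _satisfies(items: np.ndarray, design: TaskDesign) -> np.ndarray:
    """Per-trial boolean: does this item set satisfy all placement constraints?"""
    ok = np.ones(items.shape[0], dtype=bool)
    scr = design.screen
    if design.min_edge_dist is not None:
        e = design.min_edge_dist
        x, y = items[..., 0], items[..., 1]
        ok &= ((x >= e) & (x <= scr.width - e) & (y >= e) & (y <= scr.height - e)).all(axis=1)
    if design.min_center_dist is not None:
        d = np.linalg.norm(items - scr.center, axis=-1)
        ok &= (d >= design.min_center_dist).all(axis=1)
    if design.min_item_dist is not None and items.shape[1] > 1:
        diff = items[:, :, None, :] - items[:, None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        iu = np.triu_indices(items.shape[1], k=1)
        ok &= (dist[:, iu[0], iu[1]] >= design.min_item_dist).all(axis=1)
    return ok


def generate_stimuli(design: TaskDesign, rng: np.random.Generator) -> np.ndarray:
    """Place items for every trial; returns (n_trials, n_items, 2).

    Item 0 is the target.  Placement is uniform over the screen, filtered by
    rejection sampling when constraints are set; exceeding the attempt cap
    raises with the name of the (infeasible) constraint set.
    """
    n, k, scr = design.n_trials, design.n_items, design.screen
    out = np.empty((n, k, 2))
    todo = np.arange(n)
    for _ in range(_MAX_ATTEMPTS):
        cand = scr.sample_uniform(todo.size * k, rng).reshape(todo.size, k, 2)
        ok = _satisfies(cand, design)
        out[todo[ok]] = cand[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise RuntimeError(
        "stimulus placement failed after "
        f"{_MAX_ATTEMPTS} attempts; constraints (item>={design.min_item_dist}, "
        f"center>={design.min_center_dist}, edge>={design.min_edge_dist}) look infeasible "
        f"for {k} items on a {scr.width:g}x{scr.height:g} screen"
    )


def _sample_gaussian_onscreen(centers: np.ndarray, sigma: float, screen: ScreenGeometry, rng: np.random.Generator) -> np.ndarray:
    """Gaussian draws around per-row centers, resampled until on-screen."""
    n = centers.shape[0]
    out = np.empty((n, 2))
    todo = np.arange(n)
    for _ in range(_MAX_ATTEMPTS):
        cand = centers[todo] + rng.standard_normal((todo.size, 2)) * sigma
        ok = screen.contains(cand)
        out[todo[ok]] = cand[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise RuntimeError("response resampling failed to land on screen")


def simulate_dataset(
    design: TaskDesign,
    beta: float,
    gamma: float,
    sigma: float,
    rng: np.random.Generator,
    bias_spec: BiasSpec | None = None,
    bias_values=None,
    guess_sampler=None,
    beta_by_class: dict[int, float] | None = None,
    stimuli: np.ndarray | None = None,
) -> TrialDataset:
    """Simulate one continuous-report dataset from known mixture parameters.

    ``beta_by_class`` optionally splits misbinding across nontarget classes
    (requires ``design.nt_class_sizes``); ``guess_sampler(n, rng)`` overrides
    the uniform guess distribution; ``stimuli`` bypasses placement.
    """
    scr = design.screen
    n = design.n_trials
    if stimuli is None:
        stimuli = generate_stimuli(design, rng)
    targets = stimuli[:, 0, :]
    nontargets = stimuli[:, 1:, :].copy()
    m = design.n_nontargets

    if design.nt_class_sizes is not None:
        cls_row = np.concatenate([np.full(sz, i + 1) for i, sz in enumerate(design.nt_class_sizes)])
        nt_class = np.tile(cls_row, (n, 1)).astype(int)
    else:
        nt_class = np.ones((n, m), dtype=int)

    if beta_by_class is not None:
        probs = [1.0 - sum(beta_by_class.values()) - gamma]
        labels = sorted(beta_by_class)
        probs += [beta_by_class[c] for c in labels] + [gamma]
    else:
        probs = [1.0 - beta - gamma, beta, gamma]
        labels = [None]
    probs_arr = np.asarray(probs)
    if (probs_arr < -1e-12).any():
        raise ValueError("mixture proportions must be nonnegative and sum to <= 1")

    kind = rng.choice(len(probs), size=n, p=np.clip(probs_arr, 0, None) / probs_arr.clip(0, None).sum())
    responses = np.empty((n, 2))

    is_target = kind == 0
    if is_target.any():
        responses[is_target] = _sample_gaussian_onscreen(targets[is_target], sigma, scr, rng)
    is_guess = kind == len(probs) - 1
    for j, label in enumerate(labels, start=1):
        sel = kind == j
        if not sel.any():
            continue
        if label is None:
            cols = np.arange(m)
            choice = rng.integers(0, m, size=sel.sum())
            centers = nontargets[np.where(sel)[0], choice]
        else:
            cols = np.where(cls_row == label)[0]
            choice = cols[rng.integers(0, cols.size, size=sel.sum())]
            centers = nontargets[np.where(sel)[0], choice]
        responses[sel] = _sample_gaussian_onscreen(centers, sigma, scr, rng)
    if is_guess.any():
        ng = int(is_guess.sum())
        if guess_sampler is None:
            responses[is_guess] = scr.sample_uniform(ng, rng)
        else:
            responses[is_guess] = guess_sampler(ng, rng)

    if bias_spec is not None and bias_spec.kind != "none":
        trial_centers = nontargets[:, 0, :] if bias_spec.center == "nontarget" else None
        responses = apply_bias(responses, bias_spec, bias_values, scr, trial_centers=trial_centers)

    return TrialDataset(responses, targets, nontargets, scr, nt_class=nt_class)


def simulate_dataset_1d(
    n_trials: int,
    n_items: int,
    beta: float,
    gamma: float,
    kappa: float,
    rng: np.random.Generator,
) -> CircularDataset:
    """Simulate the circular (orientation) analogue of the 3-item task.

    Stimulus orientations are uniform on the circle; responses wrap (no
    boundary, so no resampling is needed).
    """
    angles = rng.uniform(-np.pi, np.pi, size=(n_trials, n_items))
    targets = angles[:, 0]
    nontargets = angles[:, 1:]
    m = n_items - 1
    probs = np.array([1.0 - beta - gamma, beta, gamma])
    kind = rng.choice(3, size=n_trials, p=probs / probs.sum())
    responses = np.empty(n_trials)
    sel = kind == 0
    responses[sel] = targets[sel] + rng.vonmises(0.0, kappa, size=int(sel.sum()))
    sel = kind == 1
    if sel.any():
        if m == 0:
            raise ValueError("beta > 0 requires at least one nontarget")
        choice = rng.integers(0, m, size=int(sel.sum()))
        responses[sel] = nontargets[np.where(sel)[0], choice] + rng.vonmises(0.0, kappa, size=int(sel.sum()))
    sel = kind == 2
    responses[sel] = rng.uniform(-np.pi, np.pi, size=int(sel.sum()))
    return CircularDataset(wrap_angle(responses), targets, nontargets)


def simulate_change_dataset(
    design: TaskDesign,
    beta: float,
    gamma: float,
    sigma: float,
    rng: np.random.Generator,
    probe_distances=(20.0, 40.0, 80.0, 160.0, 320.0),
) -> ChangeDataset:
    """Simulate 2AFC change-detection data from the continuous mixture.

    Each trial shows the probe displaced from the target by a distance drawn
    from ``probe_distances`` in a uniformly random direction (redrawn until
    the probe is on screen).  The simulated observer internally generates a
    continuous response from the mixture and rejects the probe ("changed",
    response 1) whenever that response falls closer to the target than the
    probe is — the same rule the fitted likelihood integrates over.
    """
    stimuli = generate_stimuli(design, rng)
    targets = stimuli[:, 0, :]
    nontargets = stimuli[:, 1:, :]
    n = design.n_trials
    d = rng.choice(np.asarray(probe_distances, dtype=float), size=n)
    probes = np.empty((n, 2))
    todo = np.arange(n)
    for _ in range(_MAX_ATTEMPTS):
        ang = rng.uniform(0, 2 * np.pi, size=todo.size)
        cand = targets[todo] + np.column_stack([np.cos(ang), np.sin(ang)]) * d[todo, None]
        ok = design.screen.contains(cand)
        probes[todo[ok]] = cand[ok]
        todo = todo[~ok]
        if todo.size == 0:
            break
    else:
        raise RuntimeError("probe placement failed; displacement too large for screen")

    internal = simulate_dataset(design, beta, gamma, sigma, rng, stimuli=stimuli)
    gen_dist = np.linalg.norm(internal.responses - targets, axis=1)
    responses = (gen_dist < d).astype(int)  # closer than the probe -> reject as changed
    return ChangeDataset(targets, probes, nontargets, responses, design.screen)


def sweep_grid(
    n_values: int = 11,
    gamma_range: tuple[float, float] = (0.01, 0.98),
    beta_range: tuple[float, float] = (0.01, 0.98),
    sigma_range: tuple[float, float] = (0.1, 100.0),
):
    """Full factorial parameter grid with the simplex cells dropped.

    Returns an array of (beta, gamma, sigma) rows covering ``n_values``
    evenly spaced values per parameter, keeping only cells with
    ``gamma + beta <= 1``.
    """
    gammas = np.linspace(*gamma_range, n_values)
    betas = np.linspace(*beta_range, n_values)
    sigmas = np.linspace(*sigma_range, n_values)
    cells = [
        (b, g, s)
        for g in gammas
        for b in betas
        if g + b <= 1.0
        for s in sigmas
    ]
    return np.array(cells)


def simulate_sweep(
    cells: np.ndarray,
    design: TaskDesign,
    iterations: int,
    rng: np.random.Generator,
    circular: bool = False,
    sigma_in_degrees: bool = True,
):
    """Yield ``(beta, gamma, sigma, iteration, dataset)`` over a sweep.

    For ``circular=True`` the sigma column is interpreted as circular SD (in
    degrees when ``sigma_in_degrees``) and converted to a von Mises
    concentration for simulation.
    """
    for beta, gamma, sigma in np.asarray(cells):
        if circular:
            sd_rad = np.deg2rad(sigma) if sigma_in_degrees else sigma
            kappa = sd_to_kappa(sd_rad)
        for it in range(iterations):
            if circular:
                ds = simulate_dataset_1d(design.n_trials, design.n_items, beta, gamma, kappa, rng)
            else:
                ds = simulate_dataset(design, beta, gamma, sigma, rng)
            yield float(beta), float(gamma), float(sigma), it, ds
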