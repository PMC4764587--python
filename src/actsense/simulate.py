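"""Synthetic data: GP stimulus images, simulated trials, saccade-calibration data.

Everything the pipeline consumes can be generated here: images sampled from the
three pattern types' Gaussian processes on the 77 x 77 stimulus grid (rejecting
functions leaving [-4, 4]), complete trials for any revealing strategy and
observer, balanced datasets mirroring the task design (5-25 revealings in steps
of 5, equiprobable categories), and endpoint tables emulating the saccade
calibration experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from . import strategies as strat
from .bas import SaccadeNoiseModel, apply_saccade_noise, choose_fixation
from .kernels import (
    DEFAULT_TYPE_SET,
    IMAGE_HALF_EXTENT,
    ObservationSet,
    TypeSet,
    kernel_matrix,
)
from .observer import IdealObserver, ObserverParams, choice_probability, perceive

#: Side length of the stimulus generation grid.
IMAGE_GRID_N = 77

#: Side length of the rendered (supersampled) raster.
RENDER_N = 770

#: Pixel values outside this range trigger resampling of the whole function.
VALUE_CLIP = 4.0

#: Revealing counts used in the task, balanced across trials.
REVEALING_COUNTS = (5, 10, 15, 20, 25)

STRATEGY_NAMES = (
    "bas",
    "max_entropy",
    "random",
    "anti_bas",
    "heuristic:order",
    "heuristic:posterior",
    "heuristic:both",
)

_SACCADE_STRATEGIES = ("bas", "max_entropy", "anti_bas")


def image_grid(n: int = IMAGE_GRID_N) -> np.ndarray:
    """Node coordinates of the generation grid (endpoints at +/-13.9 deg)."""
    return np.linspace(-IMAGE_HALF_EXTENT, IMAGE_HALF_EXTENT, n)


@lru_cache(maxsize=32)
def _axis_factor(lam: float, n: int) -> np.ndarray:
    """Matrix B with B B^T = K for a 1D SE kernel on the grid (eigen square root).

    SE Gram matrices are numerically rank deficient at these length scales, so
    eigenvalues are clipped at zero; the distortion is below 1e-7 in covariance.
    """
    from .kernels import LengthScales

    xs = image_grid(n)
    X = np.column_stack([xs, np.zeros(n)])
    K = kernel_matrix(X, LengthScales(lam, 1.0))
    w, U = np.linalg.eigh(K)
    return U * np.sqrt(np.clip(w, 0.0, None))


@dataclass(frozen=True)
class StimulusImage:
    """One GP stimulus: values[iy, ix] on the generation grid, with labels.

    ``values`` is indexed row = vertical coordinate, column = horizontal, both
    ascending along :func:`image_grid`.
    """

    values: np.ndarray = field(repr=False)
    type_name: str
    category: str
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("image values must be square")
        if np.max(np.abs(v)) > VALUE_CLIP:
            raise ValueError(f"image values must lie in [-{VALUE_CLIP}, {VALUE_CLIP}]")
        object.__setattr__(self, "values", v)

    @property
    def grid(self) -> np.ndarray:
        return image_grid(self.values.shape[0])


def sample_image(
    type_name: str,
    type_set: TypeSet = DEFAULT_TYPE_SET,
    rng: np.random.Generator | None = None,
    max_tries: int = 1000,
    grid_n: int = IMAGE_GRID_N,
    seed: int | None = None,
) -> StimulusImage:
    """Draw a stimulus of the given pattern type, rejecting values outside [-4, 4].

    Sampling exploits the separability of the SE kernel on the grid: with
    Bh Bh^T = K_h and Bv Bv^T = K_v, Z = Bv G Bh^T (G iid standard normal) has
    covariance K_v (x) K_h, i.e. the full 2D SE covariance.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ptype = type_set[type_name]
    bh = _axis_factor(float(ptype.scales.lambda_h), grid_n)
    bv = _axis_factor(float(ptype.scales.lambda_v), grid_n)
    for _ in range(max_tries):
        g = rng.standard_normal((grid_n, grid_n))
        z = bv @ g @ bh.T
        if np.max(np.abs(z)) <= VALUE_CLIP:
            return StimulusImage(z, ptype.name, ptype.category, seed=seed)
    raise RuntimeError(
        f"rejection sampling failed {max_tries} times; check the kernel variance"
    )


def pixel_value(image: StimulusImage, location) -> float:
    """Displayed pixel value at a location: the nearest generation-grid node.

    Exact midpoints between nodes resolve to the lower index.  Locations
    outside the image extent raise ValueError.
    """
    loc = np.asarray(location, dtype=float)
    if np.any(np.abs(loc) > IMAGE_HALF_EXTENT + 1e-9):
        raise ValueError(f"location {loc} outside the image extent")
    xs = image.grid
    step = xs[1] - xs[0]
    u = (loc - xs[0]) / step
    idx = np.ceil(u - 0.5).astype(int)  # ties toward the lower index
    idx = np.clip(idx, 0, len(xs) - 1)
    return float(image.values[idx[1], idx[0]])


def render_image(image: StimulusImage, out_n: int = RENDER_N, negative_color: str = "red") -> np.ndarray:
    """Supersample to an RGB raster with 2D splines.

    Values are mapped linearly so that -4 is pure ``negative_color`` (red by
    convention, switchable) and +4 the opposite primary (blue); returns an
    (out_n, out_n, 3) float array in [0, 1] with rows = vertical coordinate.
    """
    xs = image.grid
    fine = np.linspace(xs[0], xs[-1], out_n)
    spline = RectBivariateSpline(xs, xs, image.values, kx=3, ky=3)
    z = spline(fine, fine)  # rows follow the first (vertical) axis
    t = np.clip((z + VALUE_CLIP) / (2 * VALUE_CLIP), 0.0, 1.0)
    rgb = np.zeros(z.shape + (3,))
    if negative_color == "red":
        rgb[..., 0] = 1.0 - t
        rgb[..., 2] = t
    elif negative_color == "blue":
        rgb[..., 0] = t
        rgb[..., 2] = 1.0 - t
    else:
        raise ValueError("negative_color must be 'red' or 'blue'")
    return rgb


@dataclass(frozen=True)
class Revealing:
    """One revealing event within a trial."""

    index: int
    intended: tuple[float, float]
    executed: tuple[float, float]
    z_displayed: float
    z_perceived: float


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial: revealing sequence, category choice and bookkeeping."""

    type_name: str
    category: str
    strategy: str
    n_revealings: int
    revealings: tuple[Revealing, ...]
    choice: str
    correct: bool
    trial_id: int | None = None
    seed: int | None = None
    image_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_revealings not in REVEALING_COUNTS:
            raise ValueError(f"n_revealings must be one of {REVEALING_COUNTS}")
        if len(self.revealings) != self.n_revealings:
            raise ValueError("revealing count must equal n_revealings")
        if self.choice not in ("P", "S"):
            raise ValueError("choice must be 'P' or 'S'")

    def executed_locations(self) -> np.ndarray:
        return np.array([r.executed for r in self.revealings], dtype=float)

    def displayed_values(self) -> np.ndarray:
        return np.array([r.z_displayed for r in self.revealings], dtype=float)

    def observations(self, perceived: bool = True) -> ObservationSet:
        vals = [r.z_perceived if perceived else r.z_displayed for r in self.revealings]
        return ObservationSet(self.executed_locations(), vals)


def _wrong_type(type_name: str, type_set: TypeSet, rng: np.random.Generator) -> str:
    others = [t.name for t in type_set.types if t.name != type_name]
    return others[rng.integers(len(others))]


def simulate_trial(
    image: StimulusImage,
    strategy: str,
    observer_params: ObserverParams,
    n_revealings: int,
    rng: np.random.Generator,
    *,
    type_set: TypeSet = DEFAULT_TYPE_SET,
    noise_model: SaccadeNoiseModel | None = None,
    pool: strat.FixationPool | None = None,
    observe_displayed: bool = False,
    decoy_image: StimulusImage | None = None,
    start_location=(0.0, 0.0),
    score_mode: str = "jensen",
    grid_n: int | None = None,
    trial_id: int | None = None,
    seed: int | None = None,
) -> TrialRecord:
    """Simulate one trial of the revealing task.

    Each step proposes an intended location under the strategy, corrupts it
    with saccade noise (active strategies only, when a ``noise_model`` is
    given), reveals the displayed pixel value, perceives it (Gaussian noise of
    SD sigma_p, skipped when ``observe_displayed`` — the idealized sensor), and
    updates the observer.  The final category choice is sampled from the
    softmax/lapse decision model on the final log posterior ratio.

    The anti-BAS control runs the active sensor against a decoy image of a
    (randomly chosen) wrong type: its selection loop observes decoy pixel
    values while the recorded trial reveals the real image.
    """
    if strategy not in STRATEGY_NAMES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGY_NAMES}")
    if strategy.startswith("heuristic:") and pool is None:
        raise ValueError("heuristic strategies require a fixation pool")
    if strategy == "anti_bas" and decoy_image is None:
        decoy_image = sample_image(_wrong_type(image.type_name, type_set, rng), type_set, rng)

    observer = IdealObserver(observer_params, type_set)
    kwargs = dict(type_set=type_set, score_kind="bas", rng=rng, mode=score_mode)
    if grid_n is not None:
        kwargs["grid_n"] = grid_n

    D = ObservationSet()  # what the observer perceives (real image)
    D_select = ObservationSet() if strategy == "anti_bas" else D  # what drives selection
    prev = np.asarray(start_location, dtype=float)
    revealings = []
    for i in range(1, n_revealings + 1):
        if strategy in ("bas", "max_entropy"):
            kwargs["score_kind"] = "bas" if strategy == "bas" else "max_entropy"
            _, intended = choose_fixation(D, observer_params, **kwargs)
        elif strategy == "anti_bas":
            kwargs["score_kind"] = "bas"
            _, intended = choose_fixation(D_select, observer_params, **kwargs)
        elif strategy == "random":
            intended = strat.random_location(rng)
        else:
            mode = strategy.split(":", 1)[1]
            intended = strat.heuristic_sample(
                mode, pool, D, i, observer.type_set, observer_params.sigma_p, rng
            )
        if noise_model is not None and strategy in _SACCADE_STRATEGIES:
            executed = apply_saccade_noise(prev, intended, noise_model, rng)
        else:
            executed = np.asarray(intended, dtype=float)
        z_disp = pixel_value(image, executed)
        z_perc = z_disp if observe_displayed else perceive(z_disp, observer_params.sigma_p, rng)
        D.append(executed, z_perc)
        if strategy == "anti_bas":
            z_decoy = pixel_value(decoy_image, executed)
            if not observe_displayed:
                z_decoy = perceive(z_decoy, observer_params.sigma_p, rng)
            D_select.append(executed, z_decoy)
        revealings.append(
            Revealing(i, tuple(map(float, intended)), tuple(map(float, executed)), z_disp, z_perc)
        )
        prev = executed

    lpr = observer.posterior(D).lpr
    p_patchy = choice_probability(lpr, observer_params.beta, observer_params.kappa)
    choice = "P" if rng.random() < p_patchy else "S"
    return TrialRecord(
        type_name=image.type_name,
        category=image.category,
        strategy=strategy,
        n_revealings=n_revealings,
        revealings=tuple(revealings),
        choice=choice,
        correct=(choice == image.category),
        trial_id=trial_id,
        seed=seed,
        image_seed=image.seed,
    )


def _balanced_plan(n_trials, counts, type_set, type_balance):
    """Deterministic (n_revealings, type) assignment, balanced as in the task."""
    if type_balance == "category":
        cycle = [type_set.patchy.name, type_set.patchy.name] + [t.name for t in type_set.stripy]
    elif type_balance == "uniform":
        cycle = [t.name for t in type_set.types]
    else:
        raise ValueError("type_balance must be 'category' or 'uniform'")
    block = len(counts) * len(cycle)
    if n_trials % block != 0:
        raise ValueError(
            f"n_trials={n_trials} cannot be balanced over {len(counts)} revealing "
            f"counts and the type cycle {cycle} (needs a multiple of {block})"
        )
    plan = []
    per_count = n_trials // len(counts)
    for c in counts:
        for j in range(per_count):
            plan.append((c, cycle[j % len(cycle)]))
    return plan


def simulate_dataset(
    n_trials: int,
    strategy: str,
    observer_params: ObserverParams,
    rng: np.random.Generator,
    *,
    type_set: TypeSet = DEFAULT_TYPE_SET,
    counts=REVEALING_COUNTS,
    type_balance: str = "category",
    noise_model: SaccadeNoiseModel | None = None,
    pool: strat.FixationPool | None = None,
    observe_displayed: bool = False,
    images: list[StimulusImage] | None = None,
    score_mode: str = "jensen",
) -> list[TrialRecord]:
    """Simulate a balanced dataset of trials.

    Trials are balanced over revealing counts and — with
    ``type_balance='category'`` — over categories (1/2 patchy, 1/4 each stripy,
    as in the task); ``'uniform'`` balances the three types equally.  Per-trial
    seeds are drawn from ``rng`` and recorded so any trial can be re-simulated.
    Pass ``images`` (one per trial) to pair strategies on identical stimuli.
    """
    plan = _balanced_plan(n_trials, tuple(counts), type_set, type_balance)
    if images is not None and len(images) != len(plan):
        raise ValueError("images, when given, must have one entry per trial")
    trials = []
    for tid, (n_rev, tname) in enumerate(plan):
        image_seed = int(rng.integers(2**31))
        trial_seed = int(rng.integers(2**31))
        if images is not None:
            image = images[tid]
        else:
            image = sample_image(tname, type_set, np.random.default_rng(image_seed), seed=image_seed)
        trials.append(
            simulate_trial(
                image,
                strategy,
                observer_params,
                n_rev,
                np.random.default_rng(trial_seed),
                type_set=type_set,
                noise_model=noise_model,
                pool=pool,
                observe_displayed=observe_displayed,
                score_mode=score_mode,
                trial_id=tid,
                seed=trial_seed,
            )
        )
    return trials


#: Target eccentricities of the saccade calibration experiment, degrees.
CALIBRATION_ECCENTRICITIES = (1.39, 2.78, 5.56, 8.34)


def simulate_saccade_calibration(
    model: SaccadeNoiseModel,
    n_per_eccentricity: int,
    rng: np.random.Generator,
    *,
    eccentricities=CALIBRATION_ECCENTRICITIES,
    decoy_fraction: float = 0.0,
    drift_sd: float = 0.15,
) -> pd.DataFrame:
    """First-saccade endpoints of the calibration task, from a known noise model.

    Two targets per eccentricity (right and up from fixation); the cued one is
    chosen at random each trial.  A ``decoy_fraction`` of saccades is
    mis-directed toward the non-cued target, and each row carries a fixation
    drift magnitude — both exercise the exclusion rules of the calibration fit.
    """
    rows = []
    for ecc in eccentricities:
        targets = {"right": np.array([ecc, 0.0]), "up": np.array([0.0, ecc])}
        for _ in range(n_per_eccentricity):
            cued = "right" if rng.random() < 0.5 else "up"
            other = "up" if cued == "right" else "right"
            is_decoy = rng.random() < decoy_fraction
            aim = targets[other] if is_decoy else targets[cued]
            endpoint = apply_saccade_noise((0.0, 0.0), aim, model, rng, clip=False)
            drift = abs(rng.normal(0.0, drift_sd)) if drift_sd > 0 else 0.0
            rows.append(
                {
                    "eccentricity": ecc,
                    "cued": cued,
                    "target_x": targets[cued][0],
                    "target_y": targets[cued][1],
                    "other_x": targets[other][0],
                    "other_y": targets[other][1],
                    "endpoint_x": endpoint[0],
                    "endpoint_y": endpoint[1],
                    "drift": drift,
                    "decoy": is_decoy,
                }
            )
    return pd.DataFrame(rows)
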