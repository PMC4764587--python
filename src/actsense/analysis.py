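"""Analysis of revealing patterns and information gain.

Density maps of trial-centered revealing locations (smoothed, reweighted to a
balanced design), split-half correlations of mean-corrected per-type maps,
cumulative information-gain curves with MC marginalization over perceived
values, and shared-shape cumulative-Weibull efficiency fits with bootstrap
confidence intervals over the simulation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .kernels import DEFAULT_TYPE_SET, IMAGE_HALF_EXTENT, IMAGE_SPAN, TypeSet, chol_with_jitter, kernel_matrix
from .observer import ObserverParams, biased_scales, binary_entropy_bits

LOG2PI = np.log(2 * np.pi)

#: Grid resolution of the revealing density maps (matches the rendered raster).
DENSITY_GRID_N = 770

#: Grid resolution used for split-half correlation maps (0.18 deg bins, ~8x
#: finer than the 1.5 deg correlation smoothing kernel).
CORRELATION_GRID_N = 154


@dataclass(frozen=True)
class DensityMap:
    """Revealing density on a square grid over the image extent.

    ``values[iy, ix]``; sums to 1 unless mean-corrected (then ~0).
    """

    values: np.ndarray = field(repr=False)
    smoothing_sd_bins: float
    meta: dict = field(default_factory=dict)

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    @property
    def bin_width(self) -> float:
        return IMAGE_SPAN / self.grid_n


def _centered_locations(trial) -> np.ndarray:
    locs = trial.executed_locations()
    return locs - locs.mean(axis=0)


def _bin_and_smooth(locs, weights, grid_n, smoothing_sd_bins) -> np.ndarray:
    edges = np.linspace(-IMAGE_HALF_EXTENT, IMAGE_HALF_EXTENT, grid_n + 1)
    x = np.clip(locs[:, 0], -IMAGE_HALF_EXTENT, IMAGE_HALF_EXTENT)
    y = np.clip(locs[:, 1], -IMAGE_HALF_EXTENT, IMAGE_HALF_EXTENT)
    hist, _, _ = np.histogram2d(y, x, bins=[edges, edges], weights=weights)
    if smoothing_sd_bins > 0:
        hist = gaussian_filter(hist, smoothing_sd_bins, mode="constant")
    return hist


def density_map(
    trials,
    grid_n: int = DENSITY_GRID_N,
    smoothing_sd: float = 20.0,
    reweight: bool = True,
    center: bool = True,
    meta: dict | None = None,
) -> DensityMap:
    """Smoothed density of trial-centered revealing locations.

    Each trial's revealings are first translated so their centroid sits at the
    image center (the stimulus statistics are translation invariant).  With
    ``reweight``, the count of the n-th revealing is multiplied by the relative
    frequency of 1st to n-th revealings and by the inverse frequency of the
    trial's image type, so the map represents a balanced design (every trial as
    if 25 revealings; types equally frequent).  Smoothing SD is in bins; the
    map is normalized to sum to 1.
    """
    if not trials:
        raise ValueError("density_map requires at least one trial")
    n_trials = len(trials)
    order_count = {}
    type_count = {}
    for t in trials:
        type_count[t.type_name] = type_count.get(t.type_name, 0) + 1
        for r in t.revealings:
            order_count[r.index] = order_count.get(r.index, 0) + 1
    locs, weights = [], []
    for t in trials:
        pts = _centered_locations(t) if center else t.executed_locations()
        for r, p in zip(t.revealings, pts):
            w = 1.0
            if reweight:
                w = (n_trials / order_count[r.index]) * (n_trials / (3.0 * type_count[t.type_name]))
            locs.append(p)
            weights.append(w)
    hist = _bin_and_smooth(np.asarray(locs), np.asarray(weights), grid_n, smoothing_sd)
    hist = hist / hist.sum()
    return DensityMap(hist, smoothing_sd, meta or {})


def mean_corrected_maps(maps: dict[str, DensityMap]) -> tuple[dict[str, DensityMap], DensityMap]:
    """Subtract the unweighted mean of the per-type maps from each.

    Returns (corrected maps, the mean map).  Corrected values sum to ~0 per map
    and to 0 across types per bin; relative scaling conventionally reports a
    density of 1 at the peak of the mean map (see :func:`peak_scale`).
    """
    arrs = [m.values for m in maps.values()]
    mean = np.mean(arrs, axis=0)
    sd = next(iter(maps.values())).smoothing_sd_bins
    corrected = {
        name: DensityMap(m.values - mean, m.smoothing_sd_bins, {**m.meta, "mean_corrected": True})
        for name, m in maps.items()
    }
    return corrected, DensityMap(mean, sd, {"mean": True})


def peak_scale(mean_map: DensityMap) -> float:
    """Scale factor mapping densities so the peak mean density equals 1."""
    return float(mean_map.values.max())


def map_correlation(a: DensityMap | np.ndarray, b: DensityMap | np.ndarray) -> float:
    """Pearson correlation between two maps (flattened)."""
    va = (a.values if isinstance(a, DensityMap) else a).ravel()
    vb = (b.values if isinstance(b, DensityMap) else b).ravel()
    return float(np.corrcoef(va, vb)[0, 1])


@dataclass
class SplitHalfResult:
    """Split-half correlation statistics: within- and across-type map correlations."""

    within_mean: float
    within_sd: float
    within_ci: tuple[float, float]
    across_mean: float
    across_sd: float
    across_ci: tuple[float, float]
    p_within_positive: float  # fraction of repetitions with within <= 0
    p_across_negative: float  # fraction of repetitions with across >= 0
    reps: np.ndarray = field(repr=False, default=None)  # (n_rep, 2)


def _pooled_revealings(trials, type_names):
    """Trial-centered revealing locations and orders pooled per type."""
    pooled = {t: {"loc": [], "order": []} for t in type_names}
    for trial in trials:
        pts = _centered_locations(trial)
        d = pooled[trial.type_name]
        for r, p in zip(trial.revealings, pts):
            d["loc"].append(p)
            d["order"].append(r.index)
    out = {}
    for t, d in pooled.items():
        if not d["loc"]:
            raise ValueError(f"no trials of type {t!r} to split")
        out[t] = (np.asarray(d["loc"]), np.asarray(d["order"]))
    return out


def _order_weights(orders: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights equalizing the contribution of revealing numbers."""
    uniq, counts = np.unique(orders, return_counts=True)
    w = dict(zip(uniq, 1.0 / counts))
    return np.array([w[o] for o in orders])


def split_half_correlations(
    trials_a,
    trials_b=None,
    n_rep: int = 1000,
    kernel_sd: float = 1.5,
    grid_n: int = CORRELATION_GRID_N,
    rng: np.random.Generator | None = None,
    type_set: TypeSet = DEFAULT_TYPE_SET,
    weight_by_order: bool = True,
) -> SplitHalfResult:
    """Split-half correlations of mean-corrected per-type revealing maps.

    Per repetition, the pooled revealing locations of each type are split
    randomly into two equal halves (subsampled so every type contributes the
    same number of locations).  When ``trials_b`` is given the two halves come
    from the two datasets (e.g. participant vs. active-sensor simulations);
    otherwise both come from ``trials_a``.  Within = mean of the 3 same-type
    correlations between halves, across = mean of the 6 different-type
    correlations.  Maps are smoothed with a Gaussian kernel of ``kernel_sd``
    degrees; revealings are weighted so each revealing number contributes
    equally.  Confidence intervals are 2.5/97.5 percentiles over repetitions.
    """
    rng = np.random.default_rng() if rng is None else rng
    names = list(type_set.names)
    pool_a = _pooled_revealings(trials_a, names)
    pool_b = pool_a if trials_b is None else _pooled_revealings(trials_b, names)
    same = trials_b is None
    m = min(min(len(pool_a[t][0]) for t in names), min(len(pool_b[t][0]) for t in names))
    half = m // 2
    if half < 1:
        raise ValueError("not enough revealings per type to split")
    sd_bins = kernel_sd / (IMAGE_SPAN / grid_n)

    reps = np.empty((n_rep, 2))
    for r in range(n_rep):
        maps = {1: {}, 2: {}}
        for t in names:
            if same:
                perm = rng.permutation(len(pool_a[t][0]))
                idx = {1: perm[:half], 2: perm[half : 2 * half]}
                src = {1: pool_a[t], 2: pool_a[t]}
            else:
                idx = {
                    1: rng.permutation(len(pool_a[t][0]))[:half],
                    2: rng.permutation(len(pool_b[t][0]))[:half],
                }
                src = {1: pool_a[t], 2: pool_b[t]}
            for h in (1, 2):
                locs, orders = src[h]
                w = _order_weights(orders[idx[h]]) if weight_by_order else None
                maps[h][t] = _bin_and_smooth(locs[idx[h]], w, grid_n, sd_bins)
        for h in (1, 2):
            mean = np.mean([maps[h][t] for t in names], axis=0)
            for t in names:
                maps[h][t] = maps[h][t] - mean
        within = np.mean([np.corrcoef(maps[1][t].ravel(), maps[2][t].ravel())[0, 1] for t in names])
        across = np.mean(
            [
                np.corrcoef(maps[1][t1].ravel(), maps[2][t2].ravel())[0, 1]
                for t1 in names
                for t2 in names
                if t1 != t2
            ]
        )
        reps[r] = (within, across)

    ci = lambda v: tuple(np.percentile(v, [2.5, 97.5]))
    return SplitHalfResult(
        within_mean=float(reps[:, 0].mean()),
        within_sd=float(reps[:, 0].std(ddof=1)),
        within_ci=ci(reps[:, 0]),
        across_mean=float(reps[:, 1].mean()),
        across_sd=float(reps[:, 1].std(ddof=1)),
        across_ci=ci(reps[:, 1]),
        p_within_positive=float((reps[:, 0] <= 0).mean()),
        p_across_negative=float((reps[:, 1] >= 0).mean()),
        reps=reps,
    )


def split_half_curves(
    trials_a,
    trials_b=None,
    revealing_numbers=(5, 10, 15, 20, 25),
    n_rep: int = 200,
    kernel_sd: float = 1.5,
    grid_n: int = CORRELATION_GRID_N,
    rng: np.random.Generator | None = None,
    type_set: TypeSet = DEFAULT_TYPE_SET,
) -> pd.DataFrame:
    """Split-half correlations as a function of revealing number.

    At each revealing number n the maps are built from revealings of order
    <= n, subsampled to a constant count per (type, half) across all n — the
    count available at the smallest n — so the curve reflects differentiation
    of the revealing patterns, not growing sample size.  Returns a tidy frame
    with columns n, within_mean, within_sd, across_mean, across_sd.
    """
    rng = np.random.default_rng() if rng is None else rng
    names = list(type_set.names)
    pool_a = _pooled_revealings(trials_a, names)
    pool_b = pool_a if trials_b is None else _pooled_revealings(trials_b, names)
    same = trials_b is None
    n_min = min(revealing_numbers)
    m = min(
        min((pool_a[t][1] <= n_min).sum() for t in names),
        min((pool_b[t][1] <= n_min).sum() for t in names),
    )
    half = m // 2
    if half < 1:
        raise ValueError("not enough early revealings per type to split")
    sd_bins = kernel_sd / (IMAGE_SPAN / grid_n)

    rows = []
    for n in revealing_numbers:
        reps = np.empty((n_rep, 2))
        for r in range(n_rep):
            maps = {1: {}, 2: {}}
            for t in names:
                sel_a = np.nonzero(pool_a[t][1] <= n)[0]
                if same:
                    perm = sel_a[rng.permutation(len(sel_a))]
                    idx = {1: perm[:half], 2: perm[half : 2 * half]}
                    src = {1: pool_a[t], 2: pool_a[t]}
                else:
                    sel_b = np.nonzero(pool_b[t][1] <= n)[0]
                    idx = {
                        1: sel_a[rng.permutation(len(sel_a))[:half]],
                        2: sel_b[rng.permutation(len(sel_b))[:half]],
                    }
                    src = {1: pool_a[t], 2: pool_b[t]}
                for h in (1, 2):
                    locs, _ = src[h]
                    maps[h][t] = _bin_and_smooth(locs[idx[h]], None, grid_n, sd_bins)
            for h in (1, 2):
                mean = np.mean([maps[h][t] for t in names], axis=0)
                for t in names:
                    maps[h][t] = maps[h][t] - mean
            within = np.mean(
                [np.corrcoef(maps[1][t].ravel(), maps[2][t].ravel())[0, 1] for t in names]
            )
            across = np.mean(
                [
                    np.corrcoef(maps[1][t1].ravel(), maps[2][t2].ravel())[0, 1]
                    for t1 in names
                    for t2 in names
                    if t1 != t2
                ]
            )
            reps[r] = (within, across)
        rows.append(
            {
                "n": n,
                "within_mean": reps[:, 0].mean(),
                "within_sd": reps[:, 0].std(ddof=1),
                "across_mean": reps[:, 1].mean(),
                "across_sd": reps[:, 1].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class InfoCurve:
    """Cumulative category information vs revealing number for one strategy.

    ``mean[k-1]`` is the across-trial, across-simulation mean of 1 - H2(p) after
    k revealings; ``sem`` is the SEM across trials; ``replicates[s]`` is the
    across-trial mean curve of simulation s (the bootstrap unit).
    """

    strategy: str
    n: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_trials: np.ndarray
    replicates: np.ndarray = field(repr=False, default=None)


def info_curve(
    trials,
    observer_params: ObserverParams,
    n_sims: int = 200,
    rng: np.random.Generator | None = None,
    type_set: TypeSet = DEFAULT_TYPE_SET,
    strategy: str | None = None,
) -> InfoCurve:
    """Cumulative information gain 1 - H[c|D] along each trial's revealing sequence.

    Perceived values are unknown, so each trial is re-simulated ``n_sims``
    times, redrawing perception noise around the displayed values, and the
    information is averaged over redraws.  Prefix marginal likelihoods for all
    revealing numbers come from one Cholesky factor per (trial, type): with
    whitened residuals a = L^-1 z, the k-prefix quadratic form is the running
    sum of a_j^2 and the log-determinant the running sum of log diag(L)^2.
    """
    if not trials:
        raise ValueError("info_curve requires at least one trial")
    rng = np.random.default_rng() if rng is None else rng
    sigma_p = observer_params.sigma_p
    eff_types = biased_scales(type_set, observer_params.prior_bias)
    is_p = np.array([t.category == "P" for t in eff_types.types])
    log_prior = np.log(eff_types.type_prior())

    max_n = max(t.n_revealings for t in trials)
    trial_info = np.full((len(trials), max_n), np.nan)  # sim-averaged per trial
    rep_sum = np.zeros((n_sims, max_n))
    rep_cnt = np.zeros(max_n)

    for ti, trial in enumerate(trials):
        locs = trial.executed_locations()
        z_disp = trial.displayed_values()
        n = len(z_disp)
        Z = z_disp[:, None] + sigma_p * rng.standard_normal((n, n_sims))
        log_l = np.empty((3, n, n_sims))
        for j, ptype in enumerate(eff_types.types):
            K = kernel_matrix(locs, ptype.scales) + sigma_p**2 * np.eye(n)
            L = chol_with_jitter(K)
            a = np.linalg.solve(L, Z)
            quad = np.cumsum(a**2, axis=0)  # (n, S) prefix quadratic forms
            logdet = np.cumsum(2.0 * np.log(np.diag(L)))
            ks = np.arange(1, n + 1)
            log_l[j] = -0.5 * (quad + (logdet + ks * LOG2PI)[:, None])
        logw = log_l + log_prior[:, None, None]
        log_p = _lse0(logw[is_p])
        log_s = _lse0(logw[~is_p])
        p_patchy = 1.0 / (1.0 + np.exp(-(log_p - log_s)))
        info = 1.0 - binary_entropy_bits(p_patchy)  # (n, S)
        trial_info[ti, :n] = info.mean(axis=1)
        rep_sum[:, :n] += info.T
        rep_cnt[:n] += 1

    mean = np.nanmean(trial_info, axis=0)
    counts = np.sum(~np.isnan(trial_info), axis=0)
    sem = np.nanstd(trial_info, axis=0, ddof=1) / np.sqrt(np.maximum(counts, 1))
    return InfoCurve(
        strategy=strategy or (trials[0].strategy if trials else ""),
        n=np.arange(1, max_n + 1),
        mean=mean,
        sem=sem,
        n_trials=counts,
        replicates=rep_sum / np.maximum(rep_cnt, 1)[None, :],
    )


def _lse0(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m).sum(axis=0))


def info_curves(trials, observer_params, n_sims: int = 200, rng=None, type_set=DEFAULT_TYPE_SET):
    """Group trials by strategy label and compute one InfoCurve per strategy."""
    rng = np.random.default_rng() if rng is None else rng
    groups: dict[str, list] = {}
    for t in trials:
        groups.setdefault(t.strategy, []).append(t)
    return {
        s: info_curve(g, observer_params, n_sims=n_sims, rng=rng, type_set=type_set, strategy=s)
        for s, g in groups.items()
    }


def _weibull(n, a, b):
    return 1.0 - np.exp(-((n / a) ** b))


def _fit_weibull_shared(curve_arrays: dict[str, tuple[np.ndarray, np.ndarray]], x0=None):
    """Joint least squares of I(n) = 1 - exp(-(n/a_s)^b) with shared shape b.

    ``curve_arrays`` maps strategy -> (n, values).  Parameters are log a_s and
    log b for positivity.  Returns (a dict, b, optimality result).
    """
    names = list(curve_arrays)
    if x0 is None:
        a0 = []
        for s in names:
            n, v = curve_arrays[s]
            crossing = n[np.argmin(np.abs(v - 0.632))]
            a0.append(max(float(crossing), 1.0))
        x0 = np.log(np.concatenate([a0, [1.0]]))

    def residuals(x):
        log_a, log_b = x[:-1], x[-1]
        out = []
        for s, la in zip(names, log_a):
            n, v = curve_arrays[s]
            out.append(_weibull(n, np.exp(la), np.exp(log_b)) - v)
        return np.concatenate(out)

    res = least_squares(residuals, x0, method="lm", max_nfev=2000)
    if not res.success:
        raise RuntimeError(f"Weibull fit did not converge: {res.message}")
    a = {s: float(np.exp(v)) for s, v in zip(names, res.x[:-1])}
    return a, float(np.exp(res.x[-1])), res


@dataclass
class EfficiencyFit:
    """Shared-shape Weibull efficiency fit over strategies."""

    a: dict[str, float]
    b: float
    boot_a: pd.DataFrame = field(repr=False, default=None)

    def ratio(self, s1: str, s2: str) -> tuple[float, float, float]:
        """Efficiency of s1 relative to s2 = a_s2 / a_s1, with bootstrap 95% CI."""
        est = self.a[s2] / self.a[s1]
        if self.boot_a is None or len(self.boot_a) == 0:
            return est, np.nan, np.nan
        samples = (self.boot_a[s2] / self.boot_a[s1]).to_numpy()
        lo, hi = np.percentile(samples, [2.5, 97.5])
        return float(est), float(lo), float(hi)


class WeibullEfficiency(BaseEstimator):
    """Sklearn-style estimator for strategy information efficiency.

    fit({strategy: InfoCurve}) jointly fits cumulative Weibulls with a shared
    shape parameter b and per-strategy scales a_s to the mean curves, then
    bootstraps the fit over the simulation replicates for confidence intervals
    on efficiency ratios a_s2 / a_s1.
    """

    def __init__(self, n_boot: int = 200, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, curves: dict[str, InfoCurve], y=None):
        if len(curves) < 2:
            raise ValueError("need at least two strategies to compare")
        arrays = {
            s: (c.n[c.n_trials > 0].astype(float), c.mean[c.n_trials > 0]) for s, c in curves.items()
        }
        a, b, res = _fit_weibull_shared(arrays)
        rng = np.random.default_rng(self.random_state)
        boot = []
        x_warm = res.x
        for _ in range(self.n_boot):
            rep_arrays = {}
            for s, c in curves.items():
                reps = c.replicates
                idx = rng.integers(len(reps), size=len(reps))
                mask = c.n_trials > 0
                rep_arrays[s] = (c.n[mask].astype(float), reps[idx].mean(axis=0)[mask])
            try:
                a_r, _, _ = _fit_weibull_shared(rep_arrays, x0=x_warm)
                boot.append(a_r)
            except RuntimeError:  # pragma: no cover - degenerate bootstrap draw
                continue
        self.a_ = a
        self.b_ = b
        self.boot_a_ = pd.DataFrame(boot)
        self.result_ = EfficiencyFit(a, b, self.boot_a_)
        return self

    def ratio(self, s1: str, s2: str):
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the estimator before querying ratios")
        return self.result_.ratio(s1, s2)


def weibull_efficiency(
    curves: dict[str, InfoCurve], n_boot: int = 200, random_state: int | None = None
) -> EfficiencyFit:
    """Functional wrapper over :class:`WeibullEfficiency`."""
    return WeibullEfficiency(n_boot=n_boot, random_state=random_state).fit(curves).result_
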