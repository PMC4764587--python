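"""Observer-model fitting: MC choice likelihood, grid x gradient MLE, BIC table,
and the robust saccade-noise regression.

The observer is conditioned on *perceived* pixel values, which are unknown to
the experimenter; the choice likelihood therefore marginalizes them out by
Monte Carlo, redrawing perception noise around the displayed values.  Common
random numbers (one fixed noise tensor reused at every parameter setting) make
the simulated likelihood a smooth, deterministic function of the parameters, so
a grid search over (sigma_p, prior bias) can be combined with gradient-based
optimization of the decision-noise parameters (beta, kappa) at every grid node.
Model variants are compared by BIC with n = number of trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .bas import SaccadeNoiseModel
from .kernels import DEFAULT_TYPE_SET, TypeSet
from .observer import ObserverParams, PriorBias, biased_scales

logger = logging.getLogger(__name__)

LOG2PI = np.log(2 * np.pi)

#: Fixation-drift threshold (degrees) above which calibration trials are excluded.
DRIFT_EXCLUSION = 0.56

#: Gaussian consistency factor converting MAD into an SD estimate.
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class ModelVariant:
    """One of the six observer variants: a prior-bias kind x lapse included or not.

    sigma_p and beta are always free.
    """

    bias_kind: str  # 'none' | 'scale' | 'offset'
    include_lapse: bool

    def __post_init__(self) -> None:
        if self.bias_kind not in ("none", "scale", "offset"):
            raise ValueError(f"unknown bias kind {self.bias_kind!r}")

    @property
    def n_params(self) -> int:
        return 2 + (self.bias_kind != "none") + int(self.include_lapse)

    @property
    def label(self) -> str:
        bias = {"none": "no-bias", "scale": "alpha", "offset": "delta"}[self.bias_kind]
        return f"{bias}{'+lapse' if self.include_lapse else ''}"


def all_variants() -> tuple[ModelVariant, ...]:
    """The six model variants of the comparison, lapse-free variants first."""
    return tuple(
        ModelVariant(kind, lapse)
        for kind in ("none", "scale", "offset")
        for lapse in (False, True)
    )


def default_grids() -> dict[str, np.ndarray]:
    """Grid-search nodes for sigma_p and the prior-bias parameters."""
    return {
        "sigma_p": np.round(np.arange(0.1, 1.5001, 0.1), 10),
        "alpha": np.round(np.arange(0.5, 2.0001, 0.1), 10),
        "delta": np.round(np.arange(-0.5, 1.5001, 0.05), 10),
    }


class _TrialMatrix:
    """Trials regrouped by revealing count into dense arrays for batched GP math.

    Squared horizontal/vertical displacement tensors are cached per group so a
    new (sigma_p, length-scale) setting only costs elementwise kernel
    evaluation plus one batched Cholesky per type.
    """

    def __init__(self, trials):
        if not trials:
            raise ValueError("no trials to fit")
        self.n_trials = len(trials)
        self.choice_is_p = np.array([t.choice == "P" for t in trials])
        groups: dict[int, list[int]] = {}
        for idx, t in enumerate(trials):
            groups.setdefault(t.n_revealings, []).append(idx)
        self.groups = []
        for n_rev, idxs in sorted(groups.items()):
            locs = np.stack([trials[i].executed_locations() for i in idxs])  # (T, n, 2)
            z = np.stack([trials[i].displayed_values() for i in idxs])  # (T, n)
            dx2 = (locs[:, :, None, 0] - locs[:, None, :, 0]) ** 2
            dy2 = (locs[:, :, None, 1] - locs[:, None, :, 1]) ** 2
            self.groups.append(
                {"idx": np.array(idxs), "n": n_rev, "z": z, "dx2": dx2, "dy2": dy2}
            )

    def draw_eps(self, n_sims: int, rng: np.random.Generator):
        """Common random numbers: one standard-normal tensor per group, (T, n, S)."""
        return [rng.standard_normal(g["z"].shape + (n_sims,)) for g in self.groups]

    def lpr(self, sigma_p: float, type_set: TypeSet, eps) -> np.ndarray:
        """Log posterior ratios, (n_trials, n_sims), trials in original order."""
        n_sims = eps[0].shape[-1]
        out = np.empty((self.n_trials, n_sims))
        prior = type_set.type_prior()
        for g, e in zip(self.groups, eps):
            tcount, n = g["z"].shape
            z = g["z"][:, :, None] + sigma_p * e  # (T, n, S)
            log_l = np.empty((len(type_set.types), tcount, n_sims))
            for j, ptype in enumerate(type_set.types):
                lam_h, lam_v = ptype.scales.lambda_h, ptype.scales.lambda_v
                K = np.exp(-0.5 * (g["dx2"] / lam_h**2 + g["dy2"] / lam_v**2))
                K[:, np.arange(n), np.arange(n)] += sigma_p**2
                try:
                    chol = np.linalg.cholesky(K)
                except np.linalg.LinAlgError:
                    K[:, np.arange(n), np.arange(n)] += 1e-8
                    chol = np.linalg.cholesky(K)
                a = np.linalg.solve(chol, z)
                quad = np.einsum("tns,tns->ts", a, a)
                logdet = 2.0 * np.log(
                    chol[:, np.arange(n), np.arange(n)]
                ).sum(axis=1)
                log_l[j] = -0.5 * (quad + (logdet + n * LOG2PI)[:, None])
            is_p = np.array([t.category == "P" for t in type_set.types])
            logw = log_l + np.log(prior)[:, None, None]
            log_p = _logsumexp0(logw[is_p])
            log_s = _logsumexp0(logw[~is_p])
            out[g["idx"]] = log_p - log_s
        return out


def _logsumexp0(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m).sum(axis=0))


def _nll_and_grad(lpr, choice_is_p, beta, kappa, floor):
    """Negative log-likelihood of the choices and its gradient wrt (beta, kappa).

    The per-trial choice probability is the MC average over perception-noise
    draws of the softmax/lapse model; probabilities are floored at ``floor``.
    """
    s = 0.5 * (1.0 + np.tanh(0.5 * beta * lpr))  # sigmoid(beta * lpr), (N, S)
    p_p = (1.0 - kappa) * s.mean(axis=1) + kappa / 2.0
    dp_dbeta = (1.0 - kappa) * (s * (1.0 - s) * lpr).mean(axis=1)
    dp_dkappa = 0.5 - s.mean(axis=1)
    sign = np.where(choice_is_p, 1.0, -1.0)
    p_choice = np.where(choice_is_p, p_p, 1.0 - p_p)
    floored = p_choice < floor
    p_eff = np.where(floored, floor, p_choice)
    nll = -np.log(p_eff).sum()
    w = np.where(floored, 0.0, sign / p_eff)
    grad = np.array([-(w * dp_dbeta).sum(), -(w * dp_dkappa).sum()])
    return nll, grad


def mc_choice_loglik(
    trials,
    params: ObserverParams,
    n_sims: int = 100,
    rng: np.random.Generator | None = None,
    type_set: TypeSet = DEFAULT_TYPE_SET,
    *,
    _matrix=None,
    _eps=None,
) -> float:
    """MC-marginalized log-likelihood of the recorded choices under ``params``.

    Perceived values are integrated out with ``n_sims`` redraws per trial; zero
    estimated probabilities are floored at 1/(10 n_sims).  With a fixed seed the
    value is a deterministic function of the parameters (common random numbers).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    tm = _matrix if _matrix is not None else _TrialMatrix(trials)
    if _eps is None:
        rng = np.random.default_rng() if rng is None else rng
        _eps = tm.draw_eps(n_sims, rng)
    eff_types = biased_scales(type_set, params.prior_bias)
    lpr = tm.lpr(params.sigma_p, eff_types, _eps)
    floor = 1.0 / (10.0 * lpr.shape[1])
    nll, _ = _nll_and_grad(lpr, tm.choice_is_p, params.beta, params.kappa, floor)
    return float(-nll)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model variant."""

    variant: ModelVariant
    params: ObserverParams
    loglik: float
    bic: float
    n_trials: int
    diagnostics: dict = field(default_factory=dict)
    delta_bic: float | None = None

    def to_row(self) -> dict:
        return {
            "model": self.variant.label,
            "sigma_p": self.params.sigma_p,
            "bias_kind": self.params.prior_bias.kind,
            "bias_value": self.params.prior_bias.value,
            "beta": self.params.beta,
            "kappa": self.params.kappa,
            "loglik": self.loglik,
            "bic": self.bic,
            "delta_bic": self.delta_bic,
        }


def _optimize_decision_noise(lpr, choice_is_p, include_lapse, floor, starts):
    """Box-constrained quasi-Newton fit of (beta, kappa) on cached LPRs."""
    best = (np.inf, None)
    bounds = [(0.0, 100.0)] + ([(0.0, 1.0)] if include_lapse else [])
    for x0 in starts:
        x0 = np.asarray(x0[: len(bounds)], dtype=float)

        def objective(x):
            beta = x[0]
            kappa = x[1] if include_lapse else 0.0
            nll, grad = _nll_and_grad(lpr, choice_is_p, beta, kappa, floor)
            return nll, grad[: len(x)]

        res = minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds, tol=1e-6
        )
        if res.fun < best[0]:
            best = (res.fun, res.x)
    beta = float(best[1][0])
    kappa = float(best[1][1]) if include_lapse else 0.0
    return best[0], beta, kappa


def fit_variant(
    trials,
    variant: ModelVariant,
    *,
    grids: dict | None = None,
    n_sims: int = 100,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    n_starts: int = 3,
    type_set: TypeSet = DEFAULT_TYPE_SET,
    _matrix=None,
    _eps=None,
    _lpr_cache: dict | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one variant: grid over (sigma_p, bias), gradient
    over (beta, kappa), jointly optimal over the product.

    Reproducible given ``seed`` (or ``rng``); the same perception-noise draws
    are reused at every grid node.  A warning lands in the diagnostics when the
    optimum sits on a grid boundary.
    """
    grids = {**default_grids(), **(grids or {})}
    rng = np.random.default_rng(seed) if rng is None else rng
    tm = _matrix if _matrix is not None else _TrialMatrix(trials)
    eps = tm.draw_eps(n_sims, rng) if _eps is None else _eps
    floor = 1.0 / (10.0 * n_sims)

    if variant.bias_kind == "none":
        bias_values = [0.0]
    else:
        bias_values = grids["alpha" if variant.bias_kind == "scale" else "delta"]

    best = None
    warm = (1.0, 0.05)
    for sigma_p in grids["sigma_p"]:
        for bval in bias_values:
            key = (float(sigma_p), variant.bias_kind, float(bval))
            if _lpr_cache is not None and key in _lpr_cache:
                lpr = _lpr_cache[key]
            else:
                eff = biased_scales(type_set, PriorBias(variant.bias_kind, float(bval)))
                lpr = tm.lpr(float(sigma_p), eff, eps)
                if _lpr_cache is not None:
                    _lpr_cache[key] = lpr
            nll, beta, kappa = _optimize_decision_noise(
                lpr, tm.choice_is_p, variant.include_lapse, floor, [warm]
            )
            warm = (max(beta, 1e-3), kappa)
            if best is None or nll < best["nll"]:
                best = {
                    "nll": nll, "sigma_p": float(sigma_p), "bias": float(bval),
                    "beta": beta, "kappa": kappa, "lpr": lpr,
                }

    # multi-start refinement of (beta, kappa) at the winning grid node
    starts = [(best["beta"], best["kappa"]), (0.5, 0.02), (3.0, 0.2)][:n_starts]
    nll, beta, kappa = _optimize_decision_noise(
        best["lpr"], tm.choice_is_p, variant.include_lapse, floor, starts
    )
    diagnostics = {"n_sims": n_sims, "grid_points": len(grids["sigma_p"]) * len(bias_values)}
    sg = grids["sigma_p"]
    if best["sigma_p"] in (sg[0], sg[-1]):
        diagnostics["sigma_p_on_boundary"] = True
        logger.warning("sigma_p optimum %.2f on the grid boundary", best["sigma_p"])
    if variant.bias_kind != "none" and best["bias"] in (bias_values[0], bias_values[-1]):
        diagnostics["bias_on_boundary"] = True
        logger.warning("prior-bias optimum %.3f on the grid boundary", best["bias"])

    params = ObserverParams(
        sigma_p=best["sigma_p"],
        prior_bias=PriorBias(variant.bias_kind, best["bias"]) if variant.bias_kind != "none" else PriorBias(),
        beta=beta,
        kappa=kappa,
    )
    loglik = -nll
    bic = variant.n_params * np.log(tm.n_trials) - 2.0 * loglik
    return FitResult(variant, params, float(loglik), float(bic), tm.n_trials, diagnostics)


def bic_table(
    trials,
    variants=None,
    *,
    grids: dict | None = None,
    n_sims: int = 100,
    seed: int | None = None,
    type_set: TypeSet = DEFAULT_TYPE_SET,
) -> list[FitResult]:
    """Fit all variants on the same trials (and the same noise draws) and rank by BIC.

    delta_bic is relative to the best (lowest-BIC) variant, which gets 0.
    """
    variants = all_variants() if variants is None else tuple(variants)
    tm = _TrialMatrix(trials)
    eps = tm.draw_eps(n_sims, np.random.default_rng(seed))
    cache: dict = {}  # lapse-in/out variant pairs share the grid of LPR arrays
    results = [
        fit_variant(
            trials, v, grids=grids, n_sims=n_sims, type_set=type_set,
            _matrix=tm, _eps=eps, _lpr_cache=cache,
        )
        for v in variants
    ]
    best = min(r.bic for r in results)
    for r in results:
        r.delta_bic = r.bic - best
    return results


def results_table(results) -> pd.DataFrame:
    """Fit results as a tidy table (one row per variant)."""
    return pd.DataFrame([r.to_row() for r in results])


class ObserverDecisionModel(BaseEstimator):
    """Sklearn-style estimator for the observer decision model.

    fit(trials) runs the grid x gradient maximum-likelihood procedure for one
    variant; fitted parameters land in trailing-underscore attributes and the
    estimator can then emit per-trial choice probabilities.
    """

    def __init__(
        self,
        bias_kind: str = "offset",
        include_lapse: bool = True,
        n_sims: int = 100,
        grids: dict | None = None,
        n_starts: int = 3,
        random_state: int | None = None,
    ):
        self.bias_kind = bias_kind
        self.include_lapse = include_lapse
        self.n_sims = n_sims
        self.grids = grids
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, trials, y=None):
        result = fit_variant(
            trials,
            ModelVariant(self.bias_kind, self.include_lapse),
            grids=self.grids,
            n_sims=self.n_sims,
            seed=self.random_state,
            n_starts=self.n_starts,
        )
        self.result_ = result
        self.sigma_p_ = result.params.sigma_p
        self.prior_bias_ = result.params.prior_bias
        self.beta_ = result.params.beta
        self.kappa_ = result.params.kappa
        self.loglik_ = result.loglik
        self.bic_ = result.bic
        self.classes_ = np.array(["P", "S"])
        return self

    def predict_proba(self, trials):
        """MC choice probabilities per trial, columns ordered as ``classes_``."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the model before calling predict_proba")
        tm = _TrialMatrix(trials)
        eps = tm.draw_eps(self.n_sims, np.random.default_rng(self.random_state))
        eff = biased_scales(DEFAULT_TYPE_SET, self.prior_bias_)
        lpr = tm.lpr(self.sigma_p_, eff, eps)
        s = 0.5 * (1.0 + np.tanh(0.5 * self.beta_ * lpr))
        p_p = (1.0 - self.kappa_) * s.mean(axis=1) + self.kappa_ / 2.0
        return np.column_stack([p_p, 1.0 - p_p])

    def predict(self, trials):
        proba = self.predict_proba(trials)
        return self.classes_[(proba[:, 0] < 0.5).astype(int)]


class SaccadeCalibration(BaseEstimator):
    """Robust regression of saccadic variability and bias on target distance.

    fit(endpoints) applies the calibration exclusions (fixation drift >
    0.56 deg; saccades landing closer to the non-cued target), estimates
    per-eccentricity tangential/orthogonal SDs as 1.4826 x MAD and the
    tangential bias as the median tangential error, then regresses each
    linearly on target distance.
    """

    def __init__(self, drift_threshold: float = DRIFT_EXCLUSION):
        self.drift_threshold = drift_threshold

    def fit(self, endpoints: pd.DataFrame, y=None):
        df = endpoints.copy()
        required = {"eccentricity", "target_x", "target_y", "other_x", "other_y",
                    "endpoint_x", "endpoint_y"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"endpoint table missing columns {sorted(missing)}")
        if "drift" not in df.columns:
            df["drift"] = 0.0

        n0 = len(df)
        df = df[df["drift"] <= self.drift_threshold]
        self.n_excluded_drift_ = n0 - len(df)
        d_cued = np.hypot(df["endpoint_x"] - df["target_x"], df["endpoint_y"] - df["target_y"])
        d_other = np.hypot(df["endpoint_x"] - df["other_x"], df["endpoint_y"] - df["other_y"])
        keep = d_cued.to_numpy() <= d_other.to_numpy()
        self.n_excluded_misdirected_ = int((~keep).sum())
        df = df[keep]

        rows = []
        for ecc, sub in df.groupby("eccentricity"):
            target = sub[["target_x", "target_y"]].to_numpy()
            d = np.hypot(target[:, 0], target[:, 1])
            u = target / d[:, None]
            e = sub[["endpoint_x", "endpoint_y"]].to_numpy()
            tan = np.einsum("ij,ij->i", e, u) - d
            orth = e[:, 0] * (-u[:, 1]) + e[:, 1] * u[:, 0]
            rows.append(
                {
                    "eccentricity": float(ecc),
                    "n": len(sub),
                    "bias": float(np.median(tan)),
                    "sd_tan": float(MAD_TO_SD * np.median(np.abs(tan - np.median(tan)))),
                    "sd_orth": float(MAD_TO_SD * np.median(np.abs(orth - np.median(orth)))),
                }
            )
        table = pd.DataFrame(rows).sort_values("eccentricity")
        if len(table) < 2:
            raise ValueError(
                f"need >= 2 eccentricities after exclusions, got {len(table)}"
            )
        x = table["eccentricity"].to_numpy()
        fits = {col: np.polyfit(x, table[col].to_numpy(), 1) for col in ("sd_tan", "sd_orth", "bias")}
        self.table_ = table
        self.model_ = SaccadeNoiseModel(
            sd_tan_slope=float(fits["sd_tan"][0]),
            sd_tan_intercept=float(fits["sd_tan"][1]),
            sd_orth_slope=float(fits["sd_orth"][0]),
            sd_orth_intercept=float(fits["sd_orth"][1]),
            bias_slope=float(fits["bias"][0]),
            bias_intercept=float(fits["bias"][1]),
        )
        return self


def fit_saccade_model(endpoints: pd.DataFrame) -> SaccadeNoiseModel:
    """Fit the saccadic noise/bias model from a calibration endpoint table."""
    return SaccadeCalibration().fit(endpoints).model_
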