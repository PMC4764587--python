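"""Bayesian ideal observer of pattern category.

The observer sees a sequence of revealings D = {z, x} (perceived pixel values at
revealed locations) and maintains a posterior over the two categories, patchy P
and stripy S, by comparing the GP marginal likelihoods of the three pattern
types.  The type prior is (1/2, 1/4, 1/4): categories are equiprobable and the
two stripy orientations split S equally, so

    P(c=P | D) = L_PA / (L_PA + 1/2 L_SH + 1/2 L_SV)

with L_t = N(z; 0, K_t + sigma_p^2 I).  Suboptimalities of a real observer are
parameterized by perception noise sigma_p, a prior bias on the assumed length
scales (multiplicative alpha or additive Delta), and decision noise: a softmax
with slope beta on the log posterior ratio plus a lapse rate kappa.

Log posterior ratios use the natural log (beta is a free scale, so the base
only rescales beta); entropies and information are reported in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .kernels import (
    DEFAULT_TYPE_SET,
    InvalidParameterError,
    LengthScales,
    ObservationSet,
    TypeSet,
    log_marginal,
)

LOG2 = np.log(2.0)


@dataclass(frozen=True)
class PriorBias:
    """Misrepresentation of the pattern length scales assumed by the observer.

    kind='none'   : veridical scales.
    kind='scale'  : all six length scales multiplied by alpha (value, dimensionless).
    kind='offset' : all six length scales shifted by Delta (value, degrees).
    """

    kind: str = "none"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "scale", "offset"):
            raise InvalidParameterError(f"unknown prior-bias kind {self.kind!r}")
        if not np.isfinite(self.value):
            raise InvalidParameterError("prior-bias value must be finite")


@dataclass(frozen=True)
class ObserverParams:
    """Observer model parameters: sigma_p, prior bias, softmax slope beta, lapse kappa."""

    sigma_p: float
    prior_bias: PriorBias = field(default_factory=PriorBias)
    beta: float = 1.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_p) or self.sigma_p < 0:
            raise InvalidParameterError(f"sigma_p must be >= 0, got {self.sigma_p}")
        if not (0.0 <= self.kappa <= 1.0):
            raise InvalidParameterError(f"kappa must be in [0, 1], got {self.kappa}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise InvalidParameterError(f"beta must be >= 0, got {self.beta}")


def biased_scales(type_set: TypeSet, bias: PriorBias) -> TypeSet:
    """Apply a prior bias to every length scale of every type.

    Raises :class:`InvalidParameterError` if a resulting scale is non-positive.
    """
    if bias.kind == "none":
        return type_set
    if bias.kind == "scale":
        fn = lambda s: LengthScales(s.lambda_h * bias.value, s.lambda_v * bias.value)
    else:  # offset
        fn = lambda s: LengthScales(s.lambda_h + bias.value, s.lambda_v + bias.value)
    try:
        return type_set.map_scales(fn)
    except InvalidParameterError as err:
        raise InvalidParameterError(
            f"prior bias {bias.kind}={bias.value} makes a length scale non-positive"
        ) from err


@dataclass(frozen=True)
class CategoryPosterior:
    """Posterior over categories and types given the revealings so far.

    ``type_weights`` follows the TypeSet order; ``p_patchy`` equals the weight of
    the patchy type; ``lpr`` = ln P(c=P|D) - ln P(c=S|D).
    """

    p_patchy: float
    type_weights: np.ndarray
    lpr: float


def type_log_marginals(D: ObservationSet, type_set: TypeSet, sigma_p: float) -> np.ndarray:
    """Log marginal likelihood of D under each type, in TypeSet order; 0s if D empty."""
    if len(D) == 0:
        return np.zeros(len(type_set.types))
    return np.array([log_marginal(D, t.scales, sigma_p) for t in type_set.types])


def category_posterior(
    D: ObservationSet, type_set: TypeSet = DEFAULT_TYPE_SET, sigma_p: float = 0.0
) -> CategoryPosterior:
    """Posterior over categories from the GP marginal likelihoods (log-space)."""
    logml = type_log_marginals(D, type_set, sigma_p)
    logw = np.log(type_set.type_prior()) + logml
    logz = logsumexp(logw)
    w = np.exp(logw - logz)
    is_p = np.array([t.category == "P" for t in type_set.types])
    log_pp = logsumexp(logw[is_p]) - logz
    log_ps = logsumexp(logw[~is_p]) - logz
    return CategoryPosterior(
        p_patchy=float(np.exp(log_pp)),
        type_weights=w,
        lpr=float(log_pp - log_ps),
    )


def binary_entropy_bits(p) -> float:
    """Binary entropy H2(p) in bits, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log2(p), 0.0) - np.where(q > 0, q * np.log2(q), 0.0)
    return float(h) if h.ndim == 0 else h


def information_gain(posterior) -> float:
    """Category information accumulated so far: 1 - H2(p_patchy), in bits."""
    p = posterior.p_patchy if isinstance(posterior, CategoryPosterior) else posterior
    return 1.0 - binary_entropy_bits(p)


def choice_probability(lpr, beta: float, kappa: float):
    """Probability of choosing 'patchy' given the log posterior ratio.

    (1 - kappa) * sigmoid(beta * LPR) + kappa / 2 — a softmax on the LPR with a
    stimulus-independent lapse.  Bounded in [kappa/2, 1 - kappa/2].
    """
    if not (0.0 <= kappa <= 1.0):
        raise InvalidParameterError(f"kappa must be in [0, 1], got {kappa}")
    if beta < 0:
        raise InvalidParameterError(f"beta must be >= 0, got {beta}")
    lpr = np.asarray(lpr, dtype=float)
    # numerically stable logistic
    out = (1.0 - kappa) * 0.5 * (1.0 + np.tanh(0.5 * beta * lpr)) + kappa / 2.0
    return float(out) if out.ndim == 0 else out


def perceive(z_true, sigma_p: float, rng: np.random.Generator):
    """Corrupt a displayed pixel value with Gaussian perception noise (SD sigma_p).

    Drawn once per revealing; the draw persists for the rest of the trial.
    """
    if sigma_p < 0:
        raise InvalidParameterError(f"sigma_p must be >= 0, got {sigma_p}")
    z_true = np.asarray(z_true, dtype=float)
    noise = rng.normal(0.0, sigma_p, size=z_true.shape) if sigma_p > 0 else 0.0
    out = z_true + noise
    return float(out) if out.ndim == 0 else out


class IdealObserver:
    """Convenience wrapper binding a TypeSet and ObserverParams.

    Applies the observer's prior bias to the veridical type set once, then
    exposes posterior / information queries on observation sets.
    """

    def __init__(self, params: ObserverParams, type_set: TypeSet = DEFAULT_TYPE_SET):
        self.params = params
        self.true_type_set = type_set
        self.type_set = biased_scales(type_set, params.prior_bias)

    def posterior(self, D: ObservationSet) -> CategoryPosterior:
        return category_posterior(D, self.type_set, self.params.sigma_p)

    def information(self, D: ObservationSet) -> float:
        return information_gain(self.posterior(D))

    def choice_prob_patchy(self, D: ObservationSet) -> float:
        return choice_probability(self.posterior(D).lpr, self.params.beta, self.params.kappa)
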