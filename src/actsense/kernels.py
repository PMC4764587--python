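"""Gaussian-process core: squared-exponential covariance and marginal/predictive math.

The stimuli are draws from a zero-mean, unit-variance 2D Gaussian process whose
stationary squared-exponential covariance has separate horizontal and vertical
correlation length scales (in degrees of visual angle).  Both the ideal observer
and the active sensor condition on a small number of revealed pixel values, so
all inference here is dense: Cholesky factorizations of matrices no larger than
the number of revealings in a trial (<= 25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Half-width of the stimulus in degrees; the image spans 27.8 deg per axis,
#: centered on the screen.
IMAGE_HALF_EXTENT = 13.9

#: Full span of the image in degrees.
IMAGE_SPAN = 2 * IMAGE_HALF_EXTENT


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its domain (e.g. length scale <= 0)."""


@dataclass(frozen=True)
class LengthScales:
    """Horizontal and vertical correlation length scales of a pattern, in degrees."""

    lambda_h: float
    lambda_v: float

    def __post_init__(self) -> None:
        for name, value in (("lambda_h", self.lambda_h), ("lambda_v", self.lambda_v)):
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"length scale {name} must be finite and > 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda_h, self.lambda_v], dtype=float)


@dataclass(frozen=True)
class PatternType:
    """A named pattern type: its length scales and its category label (P or S)."""

    name: str
    scales: LengthScales
    category: str

    def __post_init__(self) -> None:
        if self.category not in ("P", "S"):
            raise InvalidParameterError(f"category must be 'P' or 'S', got {self.category!r}")


@dataclass(frozen=True)
class TypeSet:
    """The three pattern types of the task and their category map.

    Exactly one type belongs to the patchy category P; the remaining two
    (horizontal and vertical stripes) share the stripy category S.  The
    category prior is P:S = 1:1 with the two stripy types equally likely,
    giving type prior (1/2, 1/4, 1/4).
    """

    types: tuple[PatternType, ...]

    def __post_init__(self) -> None:
        if len(self.types) != 3:
            raise InvalidParameterError(f"TypeSet needs exactly 3 types, got {len(self.types)}")
        cats = [t.category for t in self.types]
        if cats.count("P") != 1 or cats.count("S") != 2:
            raise InvalidParameterError("TypeSet needs one 'P' type and two 'S' types")
        names = [t.name for t in self.types]
        if len(set(names)) != 3:
            raise InvalidParameterError("type names must be distinct")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.types)

    @property
    def patchy(self) -> PatternType:
        return next(t for t in self.types if t.category == "P")

    @property
    def stripy(self) -> tuple[PatternType, ...]:
        return tuple(t for t in self.types if t.category == "S")

    def __getitem__(self, name: str) -> PatternType:
        for t in self.types:
            if t.name == name:
                return t
        raise KeyError(name)

    def type_prior(self) -> np.ndarray:
        """Prior over types in ``self.types`` order: 1/2 for P, 1/4 for each S."""
        return np.array([0.5 if t.category == "P" else 0.25 for t in self.types])

    def map_scales(self, fn) -> "TypeSet":
        """Return a new TypeSet with ``fn`` applied to each type's LengthScales."""
        return TypeSet(
            tuple(PatternType(t.name, fn(t.scales), t.category) for t in self.types)
        )


def default_type_set() -> TypeSet:
    """Pattern types of the categorization task: patchy and two stripy orientations."""
    return TypeSet(
        (
            PatternType("PA", LengthScales(1.39, 1.39), "P"),
            PatternType("SH", LengthScales(4.63, 0.91), "S"),
            PatternType("SV", LengthScales(0.91, 4.63), "S"),
        )
    )


DEFAULT_TYPE_SET = default_type_set()


class GaussianPredictive(NamedTuple):
    """One-dimensional Gaussian predictive for a pixel value (perceived scale)."""

    mean: float
    variance: float


class ObservationSet:
    """Ordered revealings: locations (degrees, image-centered) and perceived values.

    Order is preserved because order-dependent heuristics consume it; the GP
    likelihood itself is permutation invariant.
    """

    __slots__ = ("_locations", "_values")

    def __init__(self, locations=None, values=None):
        if locations is None:
            self._locations: list[tuple[float, float]] = []
            self._values: list[float] = []
        else:
            locations = np.atleast_2d(np.asarray(locations, dtype=float))
            values = np.atleast_1d(np.asarray(values, dtype=float))
            if locations.shape[0] != values.shape[0] or locations.shape[1] != 2:
                raise ValueError("locations must be (n, 2) and values (n,)")
            if not np.all(np.isfinite(values)):
                raise ValueError("observation values must be finite")
            self._locations = [tuple(map(float, row)) for row in locations]
            self._values = [float(v) for v in values]

    @classmethod
    def empty(cls) -> "ObservationSet":
        return cls()

    def append(self, location, value: float) -> None:
        x, y = float(location[0]), float(location[1])
        if not np.isfinite(value):
            raise ValueError("observation value must be finite")
        self._locations.append((x, y))
        self._values.append(float(value))

    def __len__(self) -> int:
        return len(self._values)

    @property
    def locations(self) -> np.ndarray:
        return np.array(self._locations, dtype=float).reshape(len(self._values), 2)

    @property
    def values(self) -> np.ndarray:
        return np.array(self._values, dtype=float)

    def subset(self, idx: Sequence[int]) -> "ObservationSet":
        locs = self.locations
        vals = self.values
        return ObservationSet(locs[list(idx)], vals[list(idx)])

    def copy(self) -> "ObservationSet":
        out = ObservationSet()
        out._locations = list(self._locations)
        out._values = list(self._values)
        return out


def kernel(x1, x2, scales: LengthScales) -> float:
    """Squared-exponential covariance between two 2D locations.

    k(x, x') = exp(-1/2 [ (dx/lambda_h)^2 + (dy/lambda_v)^2 ]), unit variance.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    d = x1 - x2
    q = (d[..., 0] / scales.lambda_h) ** 2 + (d[..., 1] / scales.lambda_v) ** 2
    return float(np.exp(-0.5 * q)) if np.ndim(q) == 0 else np.exp(-0.5 * q)


def kernel_matrix(X, scales: LengthScales, X2=None) -> np.ndarray:
    """Covariance matrix between location sets ``X`` (n,2) and ``X2`` (m,2).

    With ``X2=None`` returns the symmetric n x n Gram matrix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if X2 is None else np.atleast_2d(np.asarray(X2, dtype=float))
    dx = X[:, None, 0] - Y[None, :, 0]
    dy = X[:, None, 1] - Y[None, :, 1]
    K = np.exp(-0.5 * ((dx / scales.lambda_h) ** 2 + (dy / scales.lambda_v) ** 2))
    if X2 is None:
        K = 0.5 * (K + K.T)  # enforce exact symmetry
    return K


def chol_with_jitter(A: np.ndarray, jitter0: float = 1e-10, jitter_max: float = 1e-6):
    """Cholesky factor of ``A``, adding adaptive diagonal jitter if needed.

    Starts at ``jitter0`` and multiplies by 10 up to ``jitter_max``.  Jitter use
    is logged; it only triggers when the noise variance is ~0 and revealing
    locations (nearly) coincide.
    """
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        pass
    jitter = jitter0
    eye = np.eye(A.shape[0])
    while jitter <= jitter_max:
        try:
            L = np.linalg.cholesky(A + jitter * eye)
            logger.warning("covariance nearly singular; added jitter %.1e", jitter)
            return L
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"covariance not positive definite even with jitter {jitter_max:g}"
    )


def _noisy_chol(locations: np.ndarray, scales: LengthScales, sigma_p: float) -> np.ndarray:
    K = kernel_matrix(locations, scales)
    return chol_with_jitter(K + sigma_p**2 * np.eye(K.shape[0]))


def log_marginal(D: ObservationSet, scales: LengthScales, sigma_p: float) -> float:
    """Log marginal density of the perceived values under one pattern type.

    log N(z; 0, K_theta(x, x) + sigma_p^2 I).  Natural log.
    """
    if sigma_p < 0:
        raise InvalidParameterError(f"sigma_p must be >= 0, got {sigma_p}")
    n = len(D)
    if n == 0:
        raise ValueError("log_marginal requires a non-empty observation set")
    L = _noisy_chol(D.locations, scales, sigma_p)
    a = np.linalg.solve(L, D.values)
    return float(-0.5 * (a @ a) - np.log(np.diag(L)).sum() - 0.5 * n * np.log(2 * np.pi))


def predictive(x_star, scales: LengthScales, D: ObservationSet, sigma_p: float) -> GaussianPredictive:
    """GP predictive of the *perceived* pixel value at ``x_star`` given revealings.

    mean = k*^T (K + sigma_p^2 I)^-1 z
    var  = k** - k*^T (K + sigma_p^2 I)^-1 k* + sigma_p^2

    Empty D returns the prior N(0, 1 + sigma_p^2).
    """
    m, v = predictive_batch(np.asarray(x_star, dtype=float).reshape(1, 2), scales, D, sigma_p)
    return GaussianPredictive(float(m[0]), float(v[0]))


def predictive_batch(X_star, scales: LengthScales, D: ObservationSet, sigma_p: float):
    """Vectorized :func:`predictive` over a (m, 2) array of candidate locations."""
    if sigma_p < 0:
        raise InvalidParameterError(f"sigma_p must be >= 0, got {sigma_p}")
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    m = X_star.shape[0]
    if len(D) == 0:
        return np.zeros(m), np.full(m, 1.0 + sigma_p**2)
    L = _noisy_chol(D.locations, scales, sigma_p)
    Ks = kernel_matrix(D.locations, scales, X_star)  # (n, m)
    A = np.linalg.solve(L, Ks)  # L^-1 k*
    alpha = np.linalg.solve(L, D.values)
    mean = A.T @ alpha
    var = 1.0 - np.einsum("ij,ij->j", A, A) + sigma_p**2
    # guard tiny negative round-off at observed points when sigma_p ~ 0
    np.clip(var, max(sigma_p**2, 0.0), 1.0 + sigma_p**2, out=var)
    return mean, var
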