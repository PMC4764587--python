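"""Passive and heuristic revealing strategies.

The random strategy draws revealing locations from an image-centered isotropic
Gaussian (SD 9.27 deg), resampling draws that fall outside the image.  The
three heuristics resample fixation locations from a reference pool of trials
(in the synthetic pipeline, simulated active-sensor trials stand in for
participant trials), conditioning on revealing order, on the MAP pattern type,
or on both — but never on the actual geometry of previous revealings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import DEFAULT_TYPE_SET, IMAGE_HALF_EXTENT, ObservationSet, TypeSet
from .observer import type_log_marginals

#: SD of the isotropic Gaussian of the random revealing strategy, in degrees.
RANDOM_STRATEGY_SD = 9.27

HEURISTIC_MODES = ("order", "posterior", "both")


def random_location(rng: np.random.Generator, sd: float = RANDOM_STRATEGY_SD) -> np.ndarray:
    """One revealing location from the center-0 isotropic Gaussian, resampled into the image."""
    while True:
        loc = rng.normal(0.0, sd, size=2)
        if np.all(np.abs(loc) <= IMAGE_HALF_EXTENT):
            return loc


class PoolIndexError(KeyError):
    """Raised when a queried (order, type) pool cell is empty."""


@dataclass
class FixationPool:
    """Fixation locations from a reference trial set, indexed by order and type.

    ``table`` has one row per revealing with columns order (1-based), type,
    x, y.  Queries with ``order=None`` or ``type_name=None`` pool over that
    index.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"order", "type", "x", "y"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pool table needs columns {sorted(required)}")
        if len(self.table) == 0:
            raise ValueError("pool table is empty")

    def locations(self, order: int | None = None, type_name: str | None = None) -> np.ndarray:
        sel = self.table
        if order is not None:
            sel = sel[sel["order"] == order]
        if type_name is not None:
            sel = sel[sel["type"] == type_name]
        if len(sel) == 0:
            raise PoolIndexError(f"empty fixation pool for order={order}, type={type_name}")
        return sel[["x", "y"]].to_numpy()

    def sample(self, rng: np.random.Generator, order=None, type_name=None) -> np.ndarray:
        locs = self.locations(order, type_name)
        return locs[rng.integers(len(locs))].copy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FixationPool":
        return cls(pd.read_csv(path))


def build_pool(trials) -> FixationPool:
    """Pool executed revealing locations of a trial set, indexed by order and image type."""
    if not trials:
        raise ValueError("build_pool requires at least one trial")
    rows = []
    for trial in trials:
        for rev in trial.revealings:
            rows.append(
                {"order": rev.index, "type": trial.type_name, "x": rev.executed[0], "y": rev.executed[1]}
            )
    return FixationPool(pd.DataFrame(rows))


def map_type(
    D: ObservationSet, type_set: TypeSet = DEFAULT_TYPE_SET, sigma_p: float = 0.0
) -> str:
    """MAP pattern type under the (1/2, 1/4, 1/4) type prior.

    Ties are broken by TypeSet order (patchy first), so an empty D returns the
    patchy type, whose prior dominates.
    """
    logml = type_log_marginals(D, type_set, sigma_p)
    logw = np.log(type_set.type_prior()) + logml
    return type_set.types[int(np.argmax(logw))].name


def heuristic_sample(
    mode: str,
    pool: FixationPool,
    D: ObservationSet,
    i: int,
    type_set: TypeSet = DEFAULT_TYPE_SET,
    sigma_p: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample the i-th revealing location from the pool under one heuristic.

    mode='order'     : from the order-i pool, regardless of D.
    mode='posterior' : from the MAP type's pool, regardless of order.
    mode='both'      : from the (order-i, MAP type) pool.
    """
    if mode not in HEURISTIC_MODES:
        raise ValueError(f"unknown heuristic mode {mode!r}")
    rng = np.random.default_rng() if rng is None else rng
    if mode == "order":
        return pool.sample(rng, order=i)
    t = map_type(D, type_set, sigma_p)
    if mode == "posterior":
        return pool.sample(rng, type_name=t)
    return pool.sample(rng, order=i, type_name=t)
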