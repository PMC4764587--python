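"""Reading and writing of trial logs, images, score maps and configuration.

Trial logs are JSON lines, one trial per line:

    {"trial_id": ..., "type": ..., "category": ..., "strategy": ...,
     "n_revealings": ..., "revealings": [{"i": ..., "x_int": ..., "y_int": ...,
     "x_exec": ..., "y_exec": ..., "z_disp": ..., "z_perc": ...}, ...],
     "choice": ..., "correct": ..., "seed": ..., "image_seed": ...}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bas import ScoreMap
from .kernels import LengthScales, PatternType, TypeSet
from .observer import ObserverParams, PriorBias
from .simulate import Revealing, StimulusImage, TrialRecord


def trial_to_dict(trial: TrialRecord) -> dict:
    return {
        "trial_id": trial.trial_id,
        "type": trial.type_name,
        "category": trial.category,
        "strategy": trial.strategy,
        "n_revealings": trial.n_revealings,
        "revealings": [
            {
                "i": r.index,
                "x_int": r.intended[0],
                "y_int": r.intended[1],
                "x_exec": r.executed[0],
                "y_exec": r.executed[1],
                "z_disp": r.z_displayed,
                "z_perc": r.z_perceived,
            }
            for r in trial.revealings
        ],
        "choice": trial.choice,
        "correct": trial.correct,
        "seed": trial.seed,
        "image_seed": trial.image_seed,
    }


def trial_from_dict(d: dict) -> TrialRecord:
    revealings = tuple(
        Revealing(
            r["i"], (r["x_int"], r["y_int"]), (r["x_exec"], r["y_exec"]), r["z_disp"], r["z_perc"]
        )
        for r in d["revealings"]
    )
    return TrialRecord(
        type_name=d["type"],
        category=d["category"],
        strategy=d["strategy"],
        n_revealings=d["n_revealings"],
        revealings=revealings,
        choice=d["choice"],
        correct=d["correct"],
        trial_id=d.get("trial_id"),
        seed=d.get("seed"),
        image_seed=d.get("image_seed"),
    )


def write_trials(path, trials) -> None:
    """Append-free write of a trial list as JSON lines."""
    with open(path, "w") as fh:
        for t in trials:
            fh.write(json.dumps(trial_to_dict(t)) + "\n")


def read_trials(path) -> list[TrialRecord]:
    with open(path) as fh:
        return [trial_from_dict(json.loads(line)) for line in fh if line.strip()]


def trials_to_dataframe(trials) -> pd.DataFrame:
    """One row per revealing, with trial-level columns repeated."""
    rows = []
    for t in trials:
        for r in t.revealings:
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "type": t.type_name,
                    "category": t.category,
                    "strategy": t.strategy,
                    "n_revealings": t.n_revealings,
                    "order": r.index,
                    "x": r.executed[0],
                    "y": r.executed[1],
                    "z_disp": r.z_displayed,
                    "z_perc": r.z_perceived,
                    "choice": t.choice,
                    "correct": t.correct,
                }
            )
    return pd.DataFrame(rows)


def write_image_csv(path, image: StimulusImage) -> None:
    """Image grid as CSV with a metadata header (extent, spacing, type, seed)."""
    xs = image.grid
    header = (
        f"type={image.type_name},category={image.category},seed={image.seed},"
        f"extent={xs[0]}:{xs[-1]},n={len(xs)}"
    )
    np.savetxt(path, image.values, delimiter=",", header=header)


def read_image_csv(path) -> StimulusImage:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(item.split("=", 1) for item in header.split(","))
    values = np.loadtxt(path, delimiter=",", skiprows=1)
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return StimulusImage(values, meta["type"], meta["category"], seed=seed)


def write_score_map_csv(path, smap: ScoreMap) -> None:
    """Score grid as row-major CSV with the grid extent in the header."""
    header = (
        f"grid_x={smap.grid_x[0]}:{smap.grid_x[-1]},grid_y={smap.grid_y[0]}:{smap.grid_y[-1]},"
        f"n={len(smap.grid_x)}"
    )
    np.savetxt(path, smap.scores, delimiter=",", header=header)


def observer_params_to_dict(params: ObserverParams) -> dict:
    return {
        "sigma_p": params.sigma_p,
        "prior_bias": {"kind": params.prior_bias.kind, "value": params.prior_bias.value},
        "beta": params.beta,
        "kappa": params.kappa,
    }


def observer_params_from_dict(d: dict) -> ObserverParams:
    bias = d.get("prior_bias", {"kind": "none", "value": 0.0})
    return ObserverParams(
        sigma_p=float(d["sigma_p"]),
        prior_bias=PriorBias(bias.get("kind", "none"), float(bias.get("value", 0.0))),
        beta=float(d.get("beta", 1.0)),
        kappa=float(d.get("kappa", 0.0)),
    )


def type_set_from_config(entries) -> TypeSet:
    """Pattern-type definitions from config: name, lambda_h, lambda_v, category."""
    return TypeSet(
        tuple(
            PatternType(
                e["name"], LengthScales(float(e["lambda_h"]), float(e["lambda_v"])), e["category"]
            )
            for e in entries
        )
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def file_sha256(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
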