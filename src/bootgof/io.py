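"""Dataset file formats and fixture generation.

Datasets travel as long-format CSV with columns ``signal_id, coordinate,
value, sigma`` (header required); provenance goes into a JSON sidecar next to
the CSV (``<name>.json``).  Round-trips are lossless to full float precision.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import pandas as pd

from .data import Dataset, Design, DataValidationError, NoiseModel
from .defaults import (TRUE_PARAMS, case_of, default_design, default_sigma)
from .models import get_model, simulate

__all__ = ["read_dataset", "write_dataset", "make_fixture"]

REQUIRED_COLUMNS = ("signal_id", "coordinate", "value", "sigma")


def _sidecar(path: str) -> str:
    base, _ = os.path.splitext(str(path))
    return base + ".json"


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as long-format CSV plus a JSON provenance sidecar."""
    rows = []
    for sid, coords, vals, sigs in zip(dataset.design.signal_ids,
                                       dataset.design.coordinates,
                                       dataset.values, dataset.sigma):
        for c, v, s in zip(coords, vals, sigs):
            rows.append({"signal_id": sid, "coordinate": repr(float(c)),
                         "value": repr(float(v)), "sigma": repr(float(s))})
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump({"provenance": _jsonable(dataset.provenance)}, fh, indent=2)


def read_dataset(path) -> Dataset:
    """Read a long-format CSV dataset (and its provenance sidecar if present)."""
    df = pd.read_csv(path, dtype={"signal_id": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    for col in ("coordinate", "value", "sigma"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].isna()]
        if len(bad):
            raise DataValidationError(
                f"{path}: non-numeric {col} in row {int(bad[0]) + 1}")
    bad = df.index[df["sigma"] <= 0]
    if len(bad):
        raise DataValidationError(
            f"{path}: non-positive sigma in row {int(bad[0]) + 1}")
    ids, coords, vals, sigs = [], [], [], []
    for sid, grp in df.groupby("signal_id", sort=False):
        c = grp["coordinate"].to_numpy()
        if not np.all(np.diff(c) > 0):
            j = int(np.flatnonzero(np.diff(c) <= 0)[0])
            raise DataValidationError(
                f"{path}: signal {sid!r} coordinates not strictly increasing "
                f"at row {int(grp.index[j + 1]) + 1}")
        ids.append(sid)
        coords.append(c)
        vals.append(grp["value"].to_numpy())
        sigs.append(grp["sigma"].to_numpy())
    provenance: dict[str, Any] = {"kind": "observed", "path": str(path)}
    side = _sidecar(path)
    if os.path.exists(side):
        with open(side) as fh:
            provenance = json.load(fh).get("provenance", provenance)
    return Dataset(Design(tuple(ids), tuple(coords)), tuple(vals), tuple(sigs),
                   provenance)


def make_fixture(case: str, true_model: str | None = None,
                 seed: int | None = None, theta=None,
                 design: Design | None = None,
                 sigma: float | None = None) -> Dataset:
    """Generate a synthetic dataset under the benchmark study conditions.

    ``case`` is "static" (default truth MS1, sigma 0.5) or "dynamic" (default
    truth MD1, sigma 0.75), on the default 11-point design.  Provenance
    records the generator, true parameters and seed.
    """
    if case not in ("static", "dynamic"):
        raise ValueError("case must be 'static' or 'dynamic'")
    model_id = true_model or ("MS1" if case == "static" else "MD1")
    if case_of(model_id) != case:
        raise ValueError(f"model {model_id!r} is not a {case} model")
    model = get_model(model_id)
    theta = tuple(theta) if theta is not None else TRUE_PARAMS[model_id]
    design = design or default_design(case)
    sigma = sigma if sigma is not None else default_sigma(case)
    noise = NoiseModel.constant(sigma, design)
    clean = simulate(model, theta, design)
    rng = np.random.default_rng(seed)
    values = tuple(c + rng.normal(0.0, s) for c, s in zip(clean, noise.sigma))
    return Dataset(design, values, noise.sigma, {
        "kind": "synthetic", "case": case, "true_model": model_id,
        "theta": [float(t) for t in theta], "sigma": float(sigma),
        "seed": seed,
    })


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
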