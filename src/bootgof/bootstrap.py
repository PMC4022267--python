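"""Parametric bootstrap sampling and cloud construction.

Bootstrap samples are generated under the null hypothesis that a given model
(at its fitted parameters) is the true data-generating process: each sample
is the model's noise-free simulation plus a fresh realization of the additive
Gaussian measurement noise, on exactly the observed design.  Refitting one or
more models to every sample and evaluating test statistics on each fit yields
a *cloud* — a B x k matrix approximating the joint null distribution of the
statistic vector.

Reproducibility contract: every sample draws from its own RNG stream spawned
from the base seed and keyed by sample index, so the cloud is bit-identical
for a given seed regardless of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .data import Dataset, Design, NoiseModel
from .models import PredictorModel, simulate
from .statistics import DegenerateFitError, dw_statistic_rows

__all__ = [
    "BootstrapCloud",
    "CloudBuildError",
    "generate_bootstrap_samples",
    "build_cloud",
]

logger = logging.getLogger(__name__)


class CloudBuildError(RuntimeError):
    """Too many failed refits: the cloud would be unrepresentative."""


@dataclass
class BootstrapCloud:
    """B x k matrix of statistic vectors from refitting models to samples."""

    stat_matrix: np.ndarray
    statistic_names: tuple[str, ...]
    generator_model: dict[str, Any]
    fitted_models: tuple[str, ...]
    seed: int | None
    n_dropped: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.stat_matrix = np.asarray(self.stat_matrix, dtype=float)
        if self.stat_matrix.ndim != 2:
            raise ValueError("stat_matrix must be 2D (B x k)")
        if self.stat_matrix.shape[1] != len(self.statistic_names):
            raise ValueError("statistic_names length must match columns")
        if not np.all(np.isfinite(self.stat_matrix)):
            raise ValueError("cloud contains non-finite statistics")

    @property
    def B(self) -> int:
        return self.stat_matrix.shape[0]

    @property
    def k(self) -> int:
        return self.stat_matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.statistic_names.index(name)
        except ValueError:
            raise KeyError(
                f"no statistic {name!r} in cloud (have {self.statistic_names})"
            ) from None
        return self.stat_matrix[:, j]

    def to_csv(self, path) -> None:
        header = ",".join(self.statistic_names)
        np.savetxt(path, self.stat_matrix, delimiter=",", header=header,
                   comments="")

    def metadata(self) -> dict[str, Any]:
        return {
            "B": self.B,
            "statistic_names": list(self.statistic_names),
            "generator_model": self.generator_model,
            "fitted_models": list(self.fitted_models),
            "seed": self.seed,
            "n_dropped": self.n_dropped,
            **self.meta,
        }


def generate_bootstrap_samples(model: PredictorModel, theta_hat, design: Design,
                               noise: NoiseModel, B: int,
                               seed: int | None = None) -> list[Dataset]:
    """Simulate ``model`` at ``theta_hat`` and add B fresh Gaussian noise draws."""
    if B < 1:
        raise ValueError("B must be >= 1")
    noise.matching(design)
    clean = simulate(model, theta_hat, design)  # raises on non-finite output
    streams = np.random.SeedSequence(seed).spawn(B)
    theta_list = [float(t) for t in np.atleast_1d(theta_hat)]
    samples = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        vals = tuple(c + rng.normal(0.0, s) for c, s in zip(clean, noise.sigma))
        samples.append(Dataset(design, vals, noise.sigma, {
            "kind": "bootstrap",
            "generator_model": model.model_id,
            "theta": theta_list,
            "base_seed": seed,
            "index": i,
        }))
    return samples


def _resolve_statistics(statistics: Sequence[str],
                        fitted_models: Sequence[PredictorModel]
                        ) -> list[tuple[str, str, str | None]]:
    """Map statistic specs to (column_label, kind, model_id).

    Specs: ``chi2`` / ``dw`` (first model), ``chi2:<id>`` / ``dw:<id>``
    (named model), ``lhr`` / ``lhp`` (first minus/plus second model).
    """
    ids = [m.model_id for m in fitted_models]
    resolved = []
    for spec in statistics:
        kind, _, mid = spec.partition(":")
        if kind in ("chi2", "dw"):
            target = mid or ids[0]
            if target not in ids:
                raise ValueError(f"statistic {spec!r}: model {target!r} not fitted")
            label = f"{kind}_{target}" if (mid or len(ids) > 1) else kind
            resolved.append((label, kind, target))
        elif kind in ("lhr", "lhp"):
            if len(ids) < 2:
                raise ValueError(f"statistic {spec!r} needs two fitted models")
            resolved.append((kind, kind, None))
        else:
            raise ValueError(f"unknown statistic spec {spec!r}")
    return resolved


def build_cloud(samples: Sequence[Dataset], fitted_models: Sequence[PredictorModel],
                statistics: Sequence[str], fit_options: dict | None = None,
                failure_policy: str = "drop", max_drop_frac: float = 0.01,
                seed: int | None = None) -> BootstrapCloud:
    """Fit every model to every sample and evaluate the named statistics.

    All samples must share one design and noise level (as bootstrap samples
    do).  Rows where a fit fails are retried with extra restarts, then
    handled per ``failure_policy`` ("drop" with a hard error above
    ``max_drop_frac``, or "error").
    """
    if not samples:
        raise ValueError("no samples")
    design = samples[0].design
    sigma = samples[0].sigma
    for s in samples[1:]:
        if s.design.block_sizes != design.block_sizes:
            raise ValueError("samples do not share one design")
    specs = _resolve_statistics(statistics, fitted_models)
    fit_options = dict(fit_options or {})

    Y = np.vstack([s.values_flat() for s in samples])  # (B, N)
    w = 1.0 / np.concatenate(sigma)
    Bn = len(samples)

    per_model: dict[str, dict[str, np.ndarray]] = {}
    bad = np.zeros(Bn, dtype=bool)
    for model in fitted_models:
        theta, pred, conv = model.fit_many(design, sigma, Y, **fit_options)
        if not conv.all():
            for i in np.flatnonzero(~conv):  # retry individually, harder
                try:
                    res = model.fit(samples[i], **{**fit_options, "coarse_n": 1200})
                except TypeError:
                    res = model.fit(samples[i], **fit_options)
                if res.converged:
                    pred[i] = np.concatenate(
                        res.predicted if res.predicted is not None
                        else model.predict(res.theta_hat, design))
                    conv[i] = True
        bad |= ~conv
        R = Y - pred
        per_model[model.model_id] = {
            "chi2": ((R * w) ** 2).sum(axis=1),
            "resid": R,
        }

    columns = []
    for label, kind, mid in specs:
        if kind == "chi2":
            columns.append(per_model[mid]["chi2"])
        elif kind == "dw":
            dw = dw_statistic_rows(per_model[mid]["resid"], design.block_sizes)
            if np.isnan(dw).all():
                raise DegenerateFitError(
                    f"model {mid!r}: all residuals exactly zero in every "
                    "bootstrap fit; DW statistic undefined"
                )
            bad |= np.isnan(dw)
            columns.append(dw)
        elif kind == "lhr":
            columns.append(per_model[fitted_models[0].model_id]["chi2"]
                           - per_model[fitted_models[1].model_id]["chi2"])
        else:  # lhp
            columns.append(per_model[fitted_models[0].model_id]["chi2"]
                           + per_model[fitted_models[1].model_id]["chi2"])

    n_bad = int(bad.sum())
    if n_bad:
        if failure_policy == "error":
            raise CloudBuildError(f"{n_bad} of {Bn} refits failed")
        if n_bad > max_drop_frac * Bn:
            raise CloudBuildError(
                f"{n_bad} of {Bn} refits failed (> {max_drop_frac:.0%}); "
                "cloud would be unrepresentative"
            )
        logger.warning("dropping %d of %d failed refits", n_bad, Bn)

    keep = ~bad
    stat_matrix = np.column_stack(columns)[keep]
    gen = dict(samples[0].provenance)
    gen.pop("index", None)
    return BootstrapCloud(
        stat_matrix=stat_matrix,
        statistic_names=tuple(label for label, _, _ in specs),
        generator_model=gen,
        fitted_models=tuple(m.model_id for m in fitted_models),
        seed=seed if seed is not None else gen.get("base_seed"),
        n_dropped=n_bad,
    )
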