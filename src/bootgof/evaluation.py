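"""Benchmark harness: replicate datasets, ROC curves, and type-I calibration.

A :class:`Scenario` fixes the data-generating truth(s), the hypothesis models
tested as H0, the test battery, and all sizes and seeds.  Running it yields a
long-format p-value matrix — for each artificial dataset, every hypothesis is
tested with every configured test — from which ROC curves (power) and
observed-versus-nominal false-positive-rate curves (soundness) are computed.

When both models serve as truth and as H0, ``n_datasets`` replicates per
truth yield exactly ``2 * n_datasets`` true-H0 and ``2 * n_datasets``
false-H0 p-values per test.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .bootstrap import build_cloud, generate_bootstrap_samples
from .data import Dataset, Design, NoiseModel
from .defaults import (TRUE_PARAMS, case_of, default_design, default_sigma)
from .models import PredictorModel, builtin_models, get_model, simulate
from .rejection import (CollapsedCloudWarning, combine_simplistic,
                        empirical_p_1d, kde2d, p_value_2d)
from .statistics import dw_statistic

__all__ = [
    "Scenario",
    "EvaluationResult",
    "run_scenario",
    "roc_curve",
    "type1_calibration",
    "ALL_TESTS",
]

logger = logging.getLogger(__name__)

ALL_TESTS = ("chi2", "dw", "min", "max", "mean", "prod",
             "2d_chi2_dw", "2d_chi2_chi2", "lhr", "lhp")

_NEEDS_DW = {"dw", "min", "max", "mean", "prod", "2d_chi2_dw"}
_NEEDS_SECOND = {"2d_chi2_chi2", "lhr", "lhp"}


@dataclass
class Scenario:
    """One benchmark setting: truths, hypotheses, tests, sizes, seeds."""

    truths: list[tuple[str, tuple[float, ...]]]
    hypotheses: list[str]
    design: Design
    sigma: float
    tests: tuple[str, ...] = ALL_TESTS
    n_datasets: int = 500
    B: int = 1000
    base_seed: int = 0
    grid_n: int = 64
    alpha: float = 0.05
    fit_options: dict = field(default_factory=dict)
    name: str = "scenario"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_datasets < 10:
            raise ValueError("n_datasets must be >= 10")
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}")
        if set(self.tests) & _NEEDS_SECOND and len(self.hypotheses) < 2:
            raise ValueError("two-model tests need two hypothesis models")

    @classmethod
    def benchmark(cls, case: str, n_datasets: int = 500, B: int = 1000,
                  base_seed: int = 0, tests: Sequence[str] = ALL_TESTS,
                  grid_n: int = 64, **kw) -> "Scenario":
        """The standard two-model benchmark for the static or dynamic case."""
        models = [m for m in TRUE_PARAMS if case_of(m) == case]
        return cls(truths=[(m, TRUE_PARAMS[m]) for m in models],
                   hypotheses=list(models), design=default_design(case),
                   sigma=default_sigma(case), tests=tuple(tests),
                   n_datasets=n_datasets, B=B, base_seed=base_seed,
                   grid_n=grid_n, name=f"{case}-benchmark", **kw)


@dataclass
class EvaluationResult:
    """p-value matrix plus derived ROC and calibration summaries."""

    scenario: Scenario
    p_matrix: pd.DataFrame  # columns: truth, dataset, h0, test, p, h0_true
    n_failures: int = 0

    def p_split(self, test: str) -> tuple[np.ndarray, np.ndarray]:
        """(false-H0 p-values, true-H0 p-values) for one test."""
        sub = self.p_matrix[self.p_matrix["test"] == test]
        return (sub.loc[~sub["h0_true"], "p"].to_numpy(),
                sub.loc[sub["h0_true"], "p"].to_numpy())

    def roc(self, test: str, fpr_limit: float = 0.1) -> dict[str, Any]:
        p_false, p_true = self.p_split(test)
        return roc_curve(p_false, p_true, fpr_limit=fpr_limit)

    def pauc(self, test: str, fpr_limit: float = 0.1) -> float:
        return self.roc(test, fpr_limit)["pauc"]

    def calibration(self, test: str, alphas=None) -> dict[str, Any]:
        _, p_true = self.p_split(test)
        return type1_calibration(p_true, alphas)

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.scenario.tests:
            cal = self.calibration(t)
            rows.append({"test": t, "pauc_01": self.pauc(t),
                         "auc": self.roc(t)["auc"], "verdict": cal["verdict"]})
        return pd.DataFrame(rows)


def _seed_int(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_scenario(scenario: Scenario, checkpoint: str | None = None,
                 max_failure_frac: float = 0.05) -> EvaluationResult:
    """Run the full benchmark and assemble the p-value matrix.

    One bootstrap sample set is generated per (dataset, H0) pair and shared
    by every test: the joint statistic columns (chi2 and DW of the H0 model,
    chi2 of the competing model) are computed once per refit, and each test's
    p-value is derived from the same cloud.  With ``checkpoint`` set, rows
    are flushed to CSV after each dataset and completed datasets are skipped
    on rerun.
    """
    registry = builtin_models()
    models = {h: get_model(h, registry) for h in scenario.hypotheses}
    for m, _ in scenario.truths:
        models.setdefault(m, get_model(m, registry))

    done: set[tuple[str, int]] = set()
    rows: list[dict[str, Any]] = []
    if checkpoint and os.path.exists(checkpoint):
        prev = pd.read_csv(checkpoint)
        rows = prev.to_dict("records")
        done = {(r["truth"], int(r["dataset"])) for r in rows}
        logger.info("checkpoint: %d datasets already done", len(done))

    need_dw = bool(set(scenario.tests) & _NEEDS_DW)
    need_second = bool(set(scenario.tests) & _NEEDS_SECOND)
    n_failures = 0
    n_cells = 0

    for t_idx, (true_id, true_theta) in enumerate(scenario.truths):
        true_model = models[true_id]
        noise = NoiseModel.constant(scenario.sigma, scenario.design)
        clean = simulate(true_model, true_theta, scenario.design)
        for ds_idx in range(scenario.n_datasets):
            if (true_id, ds_idx) in done:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=scenario.base_seed,
                                       spawn_key=(t_idx, ds_idx)))
            values = tuple(c + rng.normal(0.0, s)
                           for c, s in zip(clean, noise.sigma))
            dataset = Dataset(scenario.design, values, noise.sigma,
                              {"kind": "synthetic", "true_model": true_id,
                               "theta": list(true_theta),
                               "seed": scenario.base_seed, "index": ds_idx})
            obs_fits = {h: models[h].fit(dataset, **scenario.fit_options)
                        for h in scenario.hypotheses}
            new_rows = []
            for h_idx, h0 in enumerate(scenario.hypotheses):
                n_cells += 1
                other = next((h for h in scenario.hypotheses if h != h0), None)
                try:
                    cell = _test_cell(scenario, models, dataset, obs_fits, h0,
                                      other, need_dw, need_second,
                                      seed=_seed_int(scenario.base_seed,
                                                     t_idx, ds_idx, h_idx))
                except Exception as exc:  # noqa: BLE001 - recorded per cell
                    n_failures += 1
                    logger.warning("cell (%s, %d, %s) failed: %s",
                                   true_id, ds_idx, h0, exc)
                    continue
                for test_name, p in cell.items():
                    new_rows.append({"truth": true_id, "dataset": ds_idx,
                                     "h0": h0, "test": test_name, "p": p,
                                     "h0_true": h0 == true_id})
            rows.extend(new_rows)
            if checkpoint:
                pd.DataFrame(new_rows).to_csv(
                    checkpoint, mode="a", index=False,
                    header=not os.path.exists(checkpoint))

    if n_cells and n_failures > max_failure_frac * n_cells:
        raise RuntimeError(
            f"{n_failures}/{n_cells} test cells failed (> {max_failure_frac:.0%})"
        )
    p_matrix = pd.DataFrame(rows,
                            columns=["truth", "dataset", "h0", "test", "p",
                                     "h0_true"])
    return EvaluationResult(scenario, p_matrix, n_failures=n_failures)


def _test_cell(scenario: Scenario, models: dict[str, PredictorModel],
               dataset: Dataset, obs_fits, h0: str, other: str | None,
               need_dw: bool, need_second: bool, seed: int) -> dict[str, float]:
    """All configured test p-values for one (dataset, H0) pair."""
    h0_model = models[h0]
    stats = [f"chi2:{h0}"]
    fitted = [h0_model]
    if need_dw:
        stats.append(f"dw:{h0}")
    if need_second and other is not None:
        stats.append(f"chi2:{other}")
        fitted.append(models[other])
    samples = generate_bootstrap_samples(h0_model, obs_fits[h0].theta_hat,
                                         dataset.design, dataset.noise_model(),
                                         scenario.B, seed)
    cloud = build_cloud(samples, fitted, stats,
                        fit_options=scenario.fit_options, seed=seed)
    chi2_col = cloud.column(f"chi2_{h0}")
    obs_chi2 = obs_fits[h0].chi2
    out: dict[str, float] = {}
    tests = set(scenario.tests)

    p_chi2 = p_dw = None
    if tests & ({"chi2"} | _NEEDS_DW):
        p_chi2 = empirical_p_1d(chi2_col, obs_chi2, "right")
    if need_dw:
        dw_col = cloud.column(f"dw_{h0}")
        obs_dw = dw_statistic(obs_fits[h0].residuals)
        p_dw = empirical_p_1d(dw_col, obs_dw, "left")
    if "chi2" in tests:
        out["chi2"] = p_chi2
    if "dw" in tests:
        out["dw"] = p_dw
    if tests & {"min", "max", "mean", "prod"}:
        combo = combine_simplistic(p_chi2, p_dw)
        for name in ("min", "max", "mean", "prod"):
            if name in tests:
                out[name] = combo[f"p_{name}"]
    if "2d_chi2_dw" in tests:
        out["2d_chi2_dw"] = _p2d(
            np.column_stack([chi2_col, cloud.column(f"dw_{h0}")]),
            (obs_chi2, dw_statistic(obs_fits[h0].residuals)), scenario.grid_n)
    if need_second and other is not None:
        chi2_other = cloud.column(f"chi2_{other}")
        obs_other = obs_fits[other].chi2
        if "2d_chi2_chi2" in tests:
            out["2d_chi2_chi2"] = _p2d(
                np.column_stack([chi2_col, chi2_other]),
                (obs_chi2, obs_other), scenario.grid_n)
        if "lhr" in tests:
            out["lhr"] = empirical_p_1d(chi2_col - chi2_other,
                                        obs_chi2 - obs_other, "two")
        if "lhp" in tests:
            out["lhp"] = empirical_p_1d(chi2_col + chi2_other,
                                        obs_chi2 + obs_other, "two")
    return out


def _p2d(points: np.ndarray, observed, grid_n: int) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CollapsedCloudWarning)
        grid, ev = kde2d(points, grid_n=grid_n)
    return p_value_2d(grid, ev, observed)


# ---------------------------------------------------------------------------
# ROC and calibration


def roc_curve(p_false_h0, p_true_h0, fpr_limit: float = 0.1,
              alpha_grid=None) -> dict[str, Any]:
    """Empirical ROC of a test from its two p-value populations.

    Thresholds are all distinct observed p-values plus a fixed alpha grid;
    at each threshold ``a``, FPR = fraction of true-H0 p-values below ``a``
    and TPR = fraction of false-H0 p-values below ``a``.  ``pauc`` is the
    trapezoid area on FPR in [0, fpr_limit], normalized by ``fpr_limit``;
    ``auc`` the full-range trapezoid area.
    """
    p_false = np.asarray(p_false_h0, dtype=float)
    p_true = np.asarray(p_true_h0, dtype=float)
    if p_false.size == 0 or p_true.size == 0:
        raise ValueError("both p-value arrays must be nonempty")
    if alpha_grid is None:
        alpha_grid = np.concatenate([np.logspace(-4, 0, 81), [0.0]])
    thresholds = np.unique(np.concatenate([p_false, p_true, alpha_grid,
                                           [0.0, 1.0, np.nextafter(1.0, 2.0)]]))
    fpr = np.searchsorted(np.sort(p_true), thresholds, side="left") / p_true.size
    tpr = np.searchsorted(np.sort(p_false), thresholds, side="left") / p_false.size
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], tpr[order]
    auc = float(np.trapezoid(tpr, fpr))
    tpr_at_limit = float(np.interp(fpr_limit, fpr, tpr))
    mask = fpr <= fpr_limit
    fx = np.concatenate([fpr[mask], [fpr_limit]])
    fy = np.concatenate([tpr[mask], [tpr_at_limit]])
    pauc = float(np.trapezoid(fy, fx)) / fpr_limit
    return {"fpr": fpr, "tpr": tpr, "auc": auc, "pauc": pauc,
            "fpr_limit": fpr_limit}


def type1_calibration(p_true_h0, alphas=None,
                      band: float = 0.99) -> dict[str, Any]:
    """Observed vs nominal false-positive rate, with a soundness verdict.

    For each nominal level ``alpha`` the observed FPR is the fraction of
    true-H0 p-values below ``alpha``; it is compared to the exact central
    binomial ``band`` interval around ``alpha``.  Verdict over the key levels
    {0.01, 0.05, 0.1}: ``sound`` if inside the band everywhere, ``liberal``
    if above it (and never below), ``conservative`` if below (and never
    above), else ``mixed``.
    """
    p = np.asarray(p_true_h0, dtype=float)
    if p.size == 0:
        raise ValueError("p-value array must be nonempty")
    if alphas is None:
        alphas = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5])
    alphas = np.asarray(alphas, dtype=float)
    n = p.size
    lo_q, hi_q = (1 - band) / 2, 1 - (1 - band) / 2
    records = []
    for a in alphas:
        observed = float(np.mean(p < a))
        lo = float(binom.ppf(lo_q, n, a)) / n
        hi = float(binom.ppf(hi_q, n, a)) / n
        status = "in" if lo <= observed <= hi else (
            "above" if observed > hi else "below")
        records.append({"alpha": float(a), "observed_fpr": observed,
                        "band_lo": lo, "band_hi": hi, "status": status})
    table = pd.DataFrame(records)
    key = table[table["alpha"].isin([0.01, 0.05, 0.1])]
    if key.empty:
        key = table
    above = (key["status"] == "above").any()
    below = (key["status"] == "below").any()
    verdict = ("sound" if not above and not below
               else "liberal" if above and not below
               else "conservative" if below and not above
               else "mixed")
    return {"table": table, "verdict": verdict, "n": n, "band": band}
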