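"""Predictor-based models and chi-square-minimizing parameter estimation.

A model is anything that maps a parameter vector plus a :class:`~bootgof.data.Design`
to predicted outputs.  The built-in registry covers the benchmark structures:

* ``MS1`` — straight line ``theta1*x + theta2`` (static, linear basis)
* ``MS2`` — exponential curve ``theta1*e^x + theta2`` (static, linear basis)
* ``MD1`` — mass-action decay ``dx/dt = -theta*x``, ``x(0) = 10``
* ``MD2`` — Michaelis-Menten decay ``dx/dt = -theta*x/(0.01 + x)``, ``x(0) = 10``
* ``CONST`` — per-signal constant (the "too simple" help model)
* ``FLEX`` — exact interpolant through every data point (the "hyper-flexible"
  help model; its cost is identically zero)

Static linear models are fitted exactly by weighted normal equations; the
one-parameter ODE models by deterministic multi-start bounded minimization of
the chi-square objective on a log parameter scale.  ``MD1`` and ``MD2`` are
evaluated through their exact solutions (closed form, and the implicit form
``x + 0.01 ln x = 10 + 0.01 ln 10 - theta*t`` solved by a safeguarded Newton
iteration in log space); a numerical initial-value integration is kept as
``predict_ode`` for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .data import Dataset, Design, DataValidationError

__all__ = [
    "SimulationError",
    "UnknownModelError",
    "FitResult",
    "PredictorModel",
    "LinearBasisModel",
    "ScalarODEModel",
    "ConstantModel",
    "InterpolantModel",
    "FrozenModel",
    "simulate",
    "fit",
    "builtin_models",
    "get_model",
]


class SimulationError(RuntimeError):
    """Model evaluation produced a non-finite state."""


class UnknownModelError(KeyError):
    """Requested model id is not in the registry."""


@dataclass
class FitResult:
    """Outcome of fitting a model to a dataset by chi-square minimization."""

    model_id: str
    theta_hat: np.ndarray
    chi2: float
    residuals: tuple[np.ndarray, ...]
    converged: bool
    n_restarts_used: int = 1

    @property
    def predicted(self) -> tuple[np.ndarray, ...] | None:
        return getattr(self, "_predicted", None)


def _chi2_of(values, sigma, predicted) -> float:
    return float(sum(
        np.sum(((v - p) / s) ** 2)
        for v, s, p in zip(values, sigma, predicted)
    ))


class PredictorModel:
    """Base contract: deterministic parameter->output map plus a fit strategy.

    Subclasses must set ``model_id``, ``n_params`` (``None`` if data-dimensioned,
    as for the interpolant), ``fit_strategy`` and ``param_bounds``, and implement
    :meth:`predict`.
    """

    model_id: str = "abstract"
    n_params: int | None = None
    fit_strategy: str = "abstract"
    param_bounds: tuple[tuple[float, float], ...] = ()

    def predict(self, theta: Sequence[float], design: Design) -> tuple[np.ndarray, ...]:
        raise NotImplementedError

    def fit(self, dataset: Dataset, **options) -> FitResult:
        raise NotImplementedError

    # Vectorized refitting over a (B, n_points) matrix of sample values that
    # share one design and sigma. Subclasses override where a closed form
    # exists; the fallback just loops.
    def fit_many(self, design: Design, sigma: tuple[np.ndarray, ...],
                 value_matrix: np.ndarray, **options) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(theta (B,p), pred (B,N), converged (B,))`` for stacked samples."""
        thetas, preds, conv = [], [], []
        for row in value_matrix:
            ds = Dataset(design, _split(row, design), sigma,
                         {"kind": "bootstrap"})
            res = self.fit(ds, **options)
            thetas.append(np.atleast_1d(res.theta_hat))
            preds.append(np.concatenate(res.predicted)
                         if res.predicted is not None else
                         np.concatenate(self.predict(res.theta_hat, design)))
            conv.append(res.converged)
        return np.asarray(thetas), np.asarray(preds), np.asarray(conv)

    def _check_theta(self, theta) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if self.n_params is not None and theta.size != self.n_params:
            raise ValueError(
                f"{self.model_id}: expected {self.n_params} parameters, got {theta.size}"
            )
        return theta

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} {self.model_id!r} ({self.fit_strategy})>"


def _split(flat: np.ndarray, design: Design) -> tuple[np.ndarray, ...]:
    out, start = [], 0
    for n in design.block_sizes:
        out.append(np.asarray(flat[start:start + n], dtype=float))
        start += n
    return tuple(out)


# ---------------------------------------------------------------------------
# static linear-basis models (MS1, MS2)


class LinearBasisModel(PredictorModel):
    """Model linear in its parameters: ``yhat = sum_k theta_k * basis_k(x)``.

    Fitted exactly by weighted least squares (normal equations), so the fit is
    deterministic, start-point free and idempotent.
    """

    fit_strategy = "linear_basis"

    def __init__(self, model_id: str, basis: Callable[[np.ndarray], np.ndarray],
                 n_params: int):
        self.model_id = model_id
        self._basis = basis
        self.n_params = n_params
        self.param_bounds = ((-1e8, 1e8),) * n_params

    def design_matrix(self, design: Design) -> np.ndarray:
        return np.vstack([self._basis(c) for c in design.coordinates])

    def predict(self, theta, design: Design) -> tuple[np.ndarray, ...]:
        theta = self._check_theta(theta)
        out = tuple(self._basis(c) @ theta for c in design.coordinates)
        _require_finite(out, self.model_id, theta)
        return out

    def fit(self, dataset: Dataset, **options) -> FitResult:
        X = self.design_matrix(dataset.design)          # (N, p)
        w = 1.0 / dataset.sigma_flat()
        y = dataset.values_flat()
        theta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        pred_flat = X @ theta
        pred = _split(pred_flat, dataset.design)
        res = FitResult(self.model_id, theta,
                        _chi2_of(dataset.values, dataset.sigma, pred),
                        tuple(v - p for v, p in zip(dataset.values, pred)),
                        converged=True)
        res._predicted = pred
        return res

    def fit_many(self, design, sigma, value_matrix, **options):
        X = self.design_matrix(design)
        w = 1.0 / np.concatenate(sigma)
        Xw = X * w[:, None]
        # theta = (Xw' Xw)^-1 Xw' (y*w) for every row at once
        A = np.linalg.solve(Xw.T @ Xw, Xw.T)            # (p, N)
        theta = (value_matrix * w) @ A.T                 # (B, p)
        pred = theta @ X.T                               # (B, N)
        conv = np.ones(len(value_matrix), dtype=bool)
        return theta, pred, conv


# ---------------------------------------------------------------------------
# one-parameter decay models (MD1, MD2)


class ScalarODEModel(PredictorModel):
    """One-parameter decay of a substrate from ``x(0) = 10``, observed directly.

    ``kinetics='mass_action'``:      dx/dt = -theta * x
    ``kinetics='michaelis_menten'``: dx/dt = -theta * x / (0.01 + x)

    Both are evaluated through exact solutions (see module docstring); the
    chi-square objective is minimized over ``log theta`` with multi-start
    bounded Brent search.
    """

    fit_strategy = "ode_search"
    X0 = 10.0
    KM = 0.01

    def __init__(self, model_id: str, kinetics: str,
                 bounds: tuple[float, float]):
        if kinetics not in ("mass_action", "michaelis_menten"):
            raise ValueError(f"unknown kinetics {kinetics!r}")
        self.model_id = model_id
        self.kinetics = kinetics
        self.n_params = 1
        self.param_bounds = (bounds,)

    # exact trajectory -----------------------------------------------------
    def _x_of_t(self, theta, t: np.ndarray) -> np.ndarray:
        """Exact solution; broadcasts over ``theta * t`` shapes."""
        t = np.asarray(t, dtype=float)
        if self.kinetics == "mass_action":
            with np.errstate(under="ignore"):
                return self.X0 * np.exp(-theta * t)
        # Michaelis-Menten: solve x + KM*ln x = X0 + KM*ln X0 - theta*t.
        # In u = ln x the residual F(u) = e^u + KM*u - c is increasing and
        # convex, so Newton started right of the root converges monotonically.
        c = self.X0 + self.KM * np.log(self.X0) - theta * t
        u = np.full_like(np.asarray(c, dtype=float), np.log(self.X0) + 1e-12)
        with np.errstate(under="ignore"):
            for _ in range(100):
                eu = np.exp(u)
                step = (eu + self.KM * u - c) / (eu + self.KM)
                u = u - step
                if np.max(np.abs(step)) < 1e-14:
                    break
            return np.exp(u)

    def predict(self, theta, design: Design) -> tuple[np.ndarray, ...]:
        theta = self._check_theta(theta)
        th = float(theta[0])
        if not np.isfinite(th) or th < 0:
            raise SimulationError(f"{self.model_id}: invalid rate theta={th}")
        out = tuple(self._x_of_t(th, c) for c in design.coordinates)
        _require_finite(out, self.model_id, theta)
        return out

    def predict_ode(self, theta, design: Design,
                    rtol: float = 1e-8, atol: float = 1e-10) -> tuple[np.ndarray, ...]:
        """Numeric initial-value solution (LSODA); cross-check for ``predict``."""
        theta = self._check_theta(theta)
        th = float(theta[0])
        if self.kinetics == "mass_action":
            rhs = lambda t, x: -th * x
        else:
            rhs = lambda t, x: -th * x / (self.KM + x)
        out = []
        for c in design.coordinates:
            t_span = (min(0.0, c[0]), c[-1])
            sol = solve_ivp(rhs, t_span, [self.X0], t_eval=c, method="LSODA",
                            rtol=rtol, atol=atol)
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise SimulationError(
                    f"{self.model_id}: integration failed for theta={th}: {sol.message}"
                )
            out.append(sol.y[0])
        return tuple(out)

    # fitting --------------------------------------------------------------
    # The chi-square objective of these decay models can carry shallow
    # secondary minima (the trajectory's fast-decay kink slides across data
    # points as theta varies), so local Brent from a handful of starts is not
    # reliable. Fitting therefore scans a dense log-spaced theta grid (every
    # grid point is a bounded start), brackets the best one, and refines with
    # golden-section plus a final Brent polish.
    def fit(self, dataset: Dataset, coarse_n: int = 300, xatol: float = 1e-12,
            theta_hint: float | None = None, **options) -> FitResult:
        sigma = dataset.sigma
        th_row, _, _ = self.fit_many(dataset.design, sigma,
                                     dataset.values_flat()[None, :],
                                     coarse_n=coarse_n)
        lo, hi = self.param_bounds[0]

        def objective(u: float) -> float:
            pred = self.predict([np.exp(u)], dataset.design)
            return _chi2_of(dataset.values, dataset.sigma, pred)

        best_u = np.log(th_row[0, 0])
        best_f = objective(best_u)
        span = (np.log(hi) - np.log(lo)) / (coarse_n - 1)
        r = minimize_scalar(objective,
                            bounds=(max(np.log(lo), best_u - span),
                                    min(np.log(hi), best_u + span)),
                            method="bounded", options={"xatol": xatol})
        ok = True
        if r.fun < best_f:
            best_u, best_f, ok = r.x, r.fun, bool(r.success)
        if theta_hint is not None and lo <= theta_hint <= hi:
            f = objective(np.log(theta_hint))
            if f < best_f:
                best_u, best_f = np.log(theta_hint), f
        theta = np.array([np.exp(best_u)])
        pred = self.predict(theta, dataset.design)
        res = FitResult(self.model_id, theta, best_f,
                        tuple(v - p for v, p in zip(dataset.values, pred)),
                        converged=ok and np.isfinite(best_f),
                        n_restarts_used=coarse_n)
        res._predicted = pred
        return res

    def fit_many(self, design, sigma, value_matrix, coarse_n: int = 300,
                 golden_iters: int = 60, **options):
        """Vectorized refitting: coarse log-grid bracketing followed by
        golden-section refinement, all rows advanced simultaneously.

        The chi-square objective of a one-parameter decay is unimodal on the
        bracket found by the coarse scan; 60 golden-section steps shrink the
        bracket by ~3e-13, well past statistical resolution.
        """
        Y = np.asarray(value_matrix, dtype=float)
        w = 1.0 / np.concatenate(sigma)
        t = np.concatenate(design.coordinates)
        lo, hi = self.param_bounds[0]
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), coarse_n))
        pred_grid = self._x_of_t(grid[:, None], t[None, :])   # (G, N)
        # chi2 of every sample at every grid theta
        cost = (((Y[:, None, :] - pred_grid[None, :, :]) * w) ** 2).sum(axis=2)
        j = np.argmin(cost, axis=1)
        ulo = np.log(grid[np.maximum(j - 1, 0)])
        uhi = np.log(grid[np.minimum(j + 1, coarse_n - 1)])

        def row_cost(u: np.ndarray) -> np.ndarray:
            pred = self._x_of_t(np.exp(u)[:, None], t[None, :])
            return (((Y - pred) * w) ** 2).sum(axis=1)

        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = ulo, uhi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = row_cost(c), row_cost(d)
        for _ in range(golden_iters):
            left = fc < fd               # minimum lies in [a, d]
            b = np.where(left, d, b)
            a = np.where(left, a, c)
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            # one interior point is inherited, the other needs evaluation
            fe = row_cost(np.where(left, c, d))
            fc, fd = np.where(left, fe, fd), np.where(left, fc, fe)
        u_best = 0.5 * (a + b)
        theta = np.exp(u_best)
        pred = self._x_of_t(theta[:, None], t[None, :])
        conv = np.ones(len(Y), dtype=bool)
        return theta[:, None], pred, conv


# ---------------------------------------------------------------------------
# help models


class ConstantModel(PredictorModel):
    """Approximates each data series by a single constant (its weighted mean)."""

    model_id = "CONST"
    fit_strategy = "constant"

    def __init__(self):
        self.n_params = None  # one constant per signal, set by the design
        self.param_bounds = ()

    def predict(self, theta, design: Design) -> tuple[np.ndarray, ...]:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.size != design.n_signals:
            raise ValueError(
                f"CONST: expected {design.n_signals} constants, got {theta.size}"
            )
        return tuple(np.full(c.size, th)
                     for th, c in zip(theta, design.coordinates))

    def fit(self, dataset: Dataset, **options) -> FitResult:
        w = tuple(1.0 / s ** 2 for s in dataset.sigma)
        theta = np.array([np.sum(wi * v) / np.sum(wi)
                          for wi, v in zip(w, dataset.values)])
        pred = self.predict(theta, dataset.design)
        res = FitResult(self.model_id, theta,
                        _chi2_of(dataset.values, dataset.sigma, pred),
                        tuple(v - p for v, p in zip(dataset.values, pred)),
                        converged=True)
        res._predicted = pred
        return res

    def fit_many(self, design, sigma, value_matrix, **options):
        preds = np.empty_like(value_matrix)
        thetas = np.empty((len(value_matrix), design.n_signals))
        start = 0
        for k, n in enumerate(design.block_sizes):
            w = 1.0 / np.concatenate(sigma)[start:start + n] ** 2
            block = value_matrix[:, start:start + n]
            m = (block * w).sum(axis=1) / w.sum()
            thetas[:, k] = m
            preds[:, start:start + n] = m[:, None]
            start += n
        return thetas, preds, np.ones(len(value_matrix), dtype=bool)


class InterpolantModel(PredictorModel):
    """Hyper-flexible model that passes exactly through every data point.

    Its parameter vector *is* the flattened data, so its chi-square cost is
    identically zero and its residuals vanish for any dataset.
    """

    model_id = "FLEX"
    fit_strategy = "interpolant"

    def __init__(self):
        self.n_params = None
        self.param_bounds = ()

    def predict(self, theta, design: Design) -> tuple[np.ndarray, ...]:
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != design.n_points:
            raise ValueError(
                f"FLEX: expected {design.n_points} values, got {theta.size}"
            )
        return _split(theta, design)

    def fit(self, dataset: Dataset, **options) -> FitResult:
        theta = dataset.values_flat().copy()
        pred = tuple(v.copy() for v in dataset.values)
        res = FitResult(self.model_id, theta, 0.0,
                        tuple(np.zeros_like(v) for v in dataset.values),
                        converged=True)
        res._predicted = pred
        return res

    def fit_many(self, design, sigma, value_matrix, **options):
        return (value_matrix.copy(), value_matrix.copy(),
                np.ones(len(value_matrix), dtype=bool))


class FrozenModel(PredictorModel):
    """A model with all parameters pinned: fitting is a no-op (0 free params).

    Useful as an analytic reference: refitting never happens, so for known
    sigma the chi-square of bootstrap samples follows a chi-square
    distribution with ``n_points`` degrees of freedom exactly.
    """

    fit_strategy = "fixed"

    def __init__(self, inner: PredictorModel, theta: Sequence[float],
                 model_id: str | None = None):
        self.inner = inner
        self.theta = np.atleast_1d(np.asarray(theta, dtype=float))
        self.model_id = model_id or f"{inner.model_id}@fixed"
        self.n_params = 0
        self.param_bounds = ()

    def predict(self, theta, design: Design) -> tuple[np.ndarray, ...]:
        return self.inner.predict(self.theta, design)

    def fit(self, dataset: Dataset, **options) -> FitResult:
        pred = self.predict((), dataset.design)
        res = FitResult(self.model_id, np.empty(0),
                        _chi2_of(dataset.values, dataset.sigma, pred),
                        tuple(v - p for v, p in zip(dataset.values, pred)),
                        converged=True)
        res._predicted = pred
        return res

    def fit_many(self, design, sigma, value_matrix, **options):
        pred_flat = np.concatenate(self.predict((), design))
        B = len(value_matrix)
        return (np.empty((B, 0)), np.broadcast_to(pred_flat, value_matrix.shape).copy(),
                np.ones(B, dtype=bool))


# ---------------------------------------------------------------------------
# module-level operations


def _require_finite(blocks, model_id: str, theta) -> None:
    for b in blocks:
        if not np.all(np.isfinite(b)):
            raise SimulationError(
                f"model {model_id}: non-finite output for theta={np.asarray(theta)}"
            )


def simulate(model: PredictorModel, theta, design: Design) -> tuple[np.ndarray, ...]:
    """Evaluate a model's predicted outputs on a design grid.

    Raises :class:`SimulationError` if the model produces non-finite values,
    and ``ValueError`` on a parameter-vector length mismatch.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    for th, (lo, hi) in zip(theta, model.param_bounds):
        if not (lo <= th <= hi):
            raise ValueError(
                f"model {model.model_id}: theta={th} outside bounds [{lo}, {hi}]"
            )
    return model.predict(theta, design)


def fit(model: PredictorModel, dataset: Dataset, **options) -> FitResult:
    """Fit ``model`` to ``dataset`` by minimizing the chi-square objective."""
    return model.fit(dataset, **options)


def builtin_models() -> dict[str, PredictorModel]:
    """Fresh registry of the built-in benchmark and help models."""
    return {
        "MS1": LinearBasisModel("MS1", lambda x: np.column_stack([x, np.ones_like(x)]), 2),
        "MS2": LinearBasisModel("MS2", lambda x: np.column_stack([np.exp(x), np.ones_like(x)]), 2),
        "MD1": ScalarODEModel("MD1", "mass_action", (1e-3, 20.0)),
        "MD2": ScalarODEModel("MD2", "michaelis_menten", (1e-2, 100.0)),
        "CONST": ConstantModel(),
        "FLEX": InterpolantModel(),
    }


def get_model(model_id: str,
              registry: dict[str, PredictorModel] | None = None) -> PredictorModel:
    reg = registry if registry is not None else builtin_models()
    try:
        return reg[model_id]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {model_id!r}; available: {sorted(reg)}"
        ) from None
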