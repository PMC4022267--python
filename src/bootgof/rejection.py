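"""Model-rejection tests: empirical p-values from bootstrap clouds.

One-dimensional tests interpolate the empirical CDF of a cloud column at the
observed statistic (right tail for chi-square, left tail for Durbin-Watson,
two-tailed for the LHR).  The joint two-dimensional test estimates the cloud's
density with a product-Gaussian kernel on a grid, draws the equidensity
contour through the observed statistic pair, and takes the probability mass at
*lower* density as the p-value — the highest-density-region analogue of a
two-tailed test.

The second axis of the 2D test can be the Durbin-Watson statistic of the same
model, or the chi-square of a second ("help" or competing) model fitted to the
same bootstrap samples.  If the help model is flexible enough to fit anything
exactly, its chi-square column is identically zero, the cloud collapses to a
line, and the test degrades — with a warning — to the one-dimensional density
variant, since no extra information is present in the second dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .bootstrap import BootstrapCloud, build_cloud, generate_bootstrap_samples
from .data import Dataset
from .models import PredictorModel, fit as fit_model
from .statistics import (StatisticVector, dw_statistic, lhr_statistic,
                         lhp_statistic)

__all__ = [
    "CollapsedCloudWarning",
    "SmallCloudWarning",
    "DensityGrid",
    "TestResult",
    "empirical_p_1d",
    "combine_simplistic",
    "kde2d",
    "p_value_2d",
    "test_chi2",
    "test_dw",
    "test_2d",
    "test_lhr",
    "cloud_geometry_diagnostic",
]

TAILS = ("right", "left", "two", "density")


class CollapsedCloudWarning(UserWarning):
    """One cloud dimension has no spread; degraded to a 1D density test."""


class SmallCloudWarning(UserWarning):
    """Cloud is small; empirical p-values will be coarse."""


# ---------------------------------------------------------------------------
# 1D empirical p-values


def empirical_p_1d(cloud_column, observed: float, tail: str = "right") -> float:
    """Empirical p-value of ``observed`` against a bootstrap cloud column.

    The empirical CDF is interpolated linearly between order statistics at
    plotting positions ``i/(B+1)``; values beyond the cloud range are clamped
    so p never reaches exactly 0 or 1 (floor ``1/(B+1)``).

    ``tail``: "right" (large values extreme), "left", "two"
    (``2*min(F, 1-F)`` capped at 1), or "density" (mass of cloud points whose
    1D kernel density is below that at ``observed``).
    """
    col = np.asarray(cloud_column, dtype=float)
    if col.size == 0 or not np.all(np.isfinite(col)):
        raise ValueError("cloud column must be nonempty and finite")
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    B = col.size
    if B < 50:
        warnings.warn(f"cloud size {B} < 50: p-values are coarse",
                      SmallCloudWarning, stacklevel=2)
    if tail == "density":
        if np.std(col) == 0.0:
            # degenerate column: observed either matches it or is extreme
            return 1.0 if observed == col[0] else 1.0 / (B + 1)
        kde = gaussian_kde(col, bw_method="silverman")
        rho_obs = kde(np.asarray([observed]))[0]
        return float(np.mean(kde(col) < rho_obs))
    xs = np.sort(col)
    pos = np.arange(1, B + 1) / (B + 1.0)
    F = float(np.interp(observed, xs, pos, left=0.0, right=1.0))
    lo = 1.0 / (B + 1.0)
    F = min(max(F, lo), 1.0 - lo)
    if tail == "right":
        return 1.0 - F
    if tail == "left":
        return F
    return min(1.0, 2.0 * min(F, 1.0 - F))


def combine_simplistic(p_chi2: float, p_dw: float) -> dict[str, float]:
    """The four naive p-value combinations (demonstration-only: unsound).

    ``min``/``max`` reject if either/both individual tests reject; ``mean``
    balances the two; ``prod`` treats them as a joint probability.  None of
    them preserves the nominal type-I error rate.
    """
    for p in (p_chi2, p_dw):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-values must lie in [0, 1], got {p}")
    return {
        "p_min": min(p_chi2, p_dw),
        "p_max": max(p_chi2, p_dw),
        "p_mean": 0.5 * (p_chi2 + p_dw),
        "p_prod": p_chi2 * p_dw,
    }


# ---------------------------------------------------------------------------
# 2D density estimation and the highest-density-region p-value


@dataclass
class DensityGrid:
    """Normalized kernel-density histogram of a 2D (or collapsed 1D) cloud.

    For the covariance-adaptive kernel the grid lives in *whitened*
    coordinates; ``unwhiten``/``mean`` map grid points back to the original
    statistic plane (``x = mean + unwhiten @ z``).  Density values are in
    whitened units throughout — only the ranking and the bin masses matter
    for p-values, and both are invariant under the linear map.
    """

    grid_x: np.ndarray          # bin centers, first (whitened) coordinate
    grid_y: np.ndarray | None   # bin centers, second coordinate (None if collapsed)
    mass: np.ndarray            # per-bin probability mass, sums to 1
    density: np.ndarray         # per-bin density values (same shape as mass)
    bandwidths: tuple[float, ...]
    extent: tuple[float, ...]
    collapsed_axis: int | None = None  # which input column had no spread
    mean: np.ndarray | None = None
    unwhiten: np.ndarray | None = None  # 2x2 map whitened -> original

    def __post_init__(self):
        if self.mass.min() < -1e-12:
            raise ValueError("negative bin mass")
        total = float(self.mass.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"bin masses sum to {total}, expected 1")


def _collapsed(col: np.ndarray) -> bool:
    return float(np.std(col)) <= 1e-9 * max(1.0, float(np.abs(col).max(initial=0.0)))


def kde2d(cloud, grid_n: int = 128, bandwidth: str | tuple[float, float] = "silverman",
          pad: float = 3.0) -> tuple[DensityGrid, Callable[[Sequence[float]], float]]:
    """Covariance-adaptive Gaussian kernel density of a 2-column cloud.

    With ``bandwidth="silverman"`` (default) the cloud is whitened by the
    eigendecomposition of its sample covariance and smoothed with an
    isotropic Gaussian kernel of bandwidth ``B**(-1/6)`` in whitened
    coordinates (the 2D Silverman rule with a full covariance matrix, as in
    ``scipy.stats.gaussian_kde``).  This makes the estimate
    affine-equivariant: linear re-parameterizations of the statistic plane —
    in particular the 45-degree tilt from (chi2_1, chi2_2) to (LHR, LHP) —
    leave highest-density-region p-values invariant up to grid error.
    Passing an explicit ``(hx, hy)`` tuple instead selects an axis-aligned
    product kernel with those bandwidths.

    Returns the normalized grid (a :class:`DensityGrid`) together with the
    *continuous* kernel evaluator (taking original-plane coordinates) used
    to compute the density at the observed point.  The grid covers the cloud
    extent padded by ``pad`` bandwidths.

    If exactly one column has zero spread — or the sample covariance is
    singular — the estimate degrades to a 1D density over the informative
    direction (with a :class:`CollapsedCloudWarning`); zero spread in both
    columns is an error.
    """
    if isinstance(cloud, BootstrapCloud):
        if cloud.k != 2:
            raise ValueError("kde2d needs a cloud with exactly 2 columns")
        pts = cloud.stat_matrix
    else:
        pts = np.asarray(cloud, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("expected a (B, 2) array of points")
    x, y = pts[:, 0], pts[:, 1]
    cx, cy = _collapsed(x), _collapsed(y)
    if cx and cy:
        raise ValueError("both cloud columns have zero spread; no density to estimate")
    if cx or cy:
        dead = 0 if cx else 1
        warnings.warn(
            f"cloud column {dead} has no spread; degrading to a 1D density "
            "(no information in that dimension)", CollapsedCloudWarning,
            stacklevel=2)
        live = y if cx else x
        return _build_1d(live, lambda z: z[1 - dead] if z.size == 2 else z[0],
                         pad, grid_n, collapsed_axis=dead)

    if bandwidth != "silverman":
        # axis-aligned product kernel with user-supplied bandwidths
        hx, hy = float(bandwidth[0]), float(bandwidth[1])
        if hx <= 0 or hy <= 0:
            raise ValueError("bandwidths must be positive")
        ex = (x.min() - pad * hx, x.max() + pad * hx)
        ey = (y.min() - pad * hy, y.max() + pad * hy)
        gx, gy = _centers(*ex, grid_n), _centers(*ey, grid_n)
        Kx = _gauss_matrix(gx, x, hx)
        Ky = _gauss_matrix(gy, y, hy)
        dens = Kx @ Ky.T / x.size
        grid = DensityGrid(grid_x=gx, grid_y=gy, mass=dens / dens.sum(),
                           density=dens, bandwidths=(hx, hy), extent=ex + ey,
                           mean=np.zeros(2), unwhiten=np.eye(2))

        def evaluator(point) -> float:
            z = np.asarray(point, dtype=float).ravel()
            kx = _gauss_matrix(z[:1], x, hx)[0]
            ky = _gauss_matrix(z[1:2], y, hy)[0]
            return float(np.mean(kx * ky))

        return grid, evaluator

    # covariance-adaptive kernel: whiten, smooth isotropically, stay whitened
    mean = pts.mean(axis=0)
    lam, V = np.linalg.eigh(np.cov(pts.T))
    if lam[0] <= 1e-12 * lam[1]:
        warnings.warn(
            "cloud covariance is singular (columns perfectly collinear); "
            "degrading to a 1D density along the principal axis",
            CollapsedCloudWarning, stacklevel=2)
        v = V[:, 1]
        return _build_1d((pts - mean) @ v,
                         lambda z: float((np.asarray(z, float).ravel() - mean) @ v),
                         pad, grid_n, collapsed_axis=-1)
    B = len(pts)
    Z = (pts - mean) @ V / np.sqrt(lam)       # unit covariance by construction
    h = B ** (-1.0 / 6.0)
    zx, zy = Z[:, 0], Z[:, 1]
    ex = (zx.min() - pad * h, zx.max() + pad * h)
    ey = (zy.min() - pad * h, zy.max() + pad * h)
    gx, gy = _centers(*ex, grid_n), _centers(*ey, grid_n)
    Kx = _gauss_matrix(gx, zx, h)             # (grid_n, B)
    Ky = _gauss_matrix(gy, zy, h)
    dens = Kx @ Ky.T / B                      # whitened-units density at centers
    grid = DensityGrid(grid_x=gx, grid_y=gy, mass=dens / dens.sum(),
                       density=dens, bandwidths=(h, h), extent=ex + ey,
                       mean=mean, unwhiten=V * np.sqrt(lam))

    def evaluator(point) -> float:
        z = (np.asarray(point, dtype=float).ravel() - mean) @ V / np.sqrt(lam)
        kx = _gauss_matrix(z[:1], zx, h)[0]
        ky = _gauss_matrix(z[1:2], zy, h)[0]
        return float(np.mean(kx * ky))

    return grid, evaluator


def _build_1d(live: np.ndarray, to_live, pad: float, grid_n: int,
              collapsed_axis: int):
    h = max(_silverman_1d(live), 1e-300)
    lo, hi = live.min() - pad * h, live.max() + pad * h
    centers = _centers(lo, hi, grid_n)
    dens = _gauss_matrix(centers, live, h).mean(axis=1)
    grid = DensityGrid(grid_x=centers, grid_y=None, mass=dens / dens.sum(),
                       density=dens, bandwidths=(h,), extent=(lo, hi),
                       collapsed_axis=collapsed_axis)

    def evaluator(point) -> float:
        v = to_live(np.asarray(point, dtype=float).ravel())
        return float(_gauss_matrix(np.atleast_1d(float(v)), live, h).mean())

    return grid, evaluator


def _silverman_1d(col: np.ndarray) -> float:
    n = col.size
    return float(np.std(col, ddof=1)) * (4.0 / (3.0 * n)) ** 0.2


def _centers(lo: float, hi: float, n: int) -> np.ndarray:
    step = (hi - lo) / n
    return np.linspace(lo + step / 2, hi - step / 2, n)


def _gauss_matrix(grid: np.ndarray, pts: np.ndarray, h: float) -> np.ndarray:
    z = (grid[:, None] - pts[None, :]) / h
    return np.exp(-0.5 * z * z) / (h * np.sqrt(2.0 * np.pi))


def p_value_2d(density: DensityGrid, kde_eval: Callable, observed) -> float:
    """Highest-density-region p-value of an observed statistic pair.

    The density at the observed point is computed with the continuous kernel
    evaluator (not grid interpolation); the p-value is the total mass of grid
    bins whose density lies *strictly below* that equidensity level.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed point must be finite")
    rho_obs = kde_eval(obs)
    return float(density.mass[density.density < rho_obs].sum())


# ---------------------------------------------------------------------------
# test pipelines


@dataclass
class TestResult:
    """A p-value with full provenance for one bootstrapped rejection test."""

    test_name: str
    p_value: float
    observed_stats: StatisticVector
    tail: str
    alpha: float
    cloud_ref: dict[str, Any]
    rejected: bool = field(init=False)
    warnings: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.rejected = bool(self.p_value < self.alpha)

    def to_dict(self) -> dict[str, Any]:
        return {
            "test_name": self.test_name,
            "p_value": self.p_value,
            "observed_stats": self.observed_stats.as_dict(),
            "tail": self.tail,
            "alpha": self.alpha,
            "rejected": self.rejected,
            "cloud_ref": self.cloud_ref,
            "warnings": self.warnings,
            "meta": self.meta,
        }


def _pipeline_cloud(model: PredictorModel, dataset: Dataset, statistics,
                    fitted_models, B: int, seed, fit_options):
    """Steps 1-3 of the bootstrap algorithm: fit, sample, refit."""
    fitres = fit_model(model, dataset, **(fit_options or {}))
    samples = generate_bootstrap_samples(model, fitres.theta_hat, dataset.design,
                                         dataset.noise_model(), B, seed)
    cloud = build_cloud(samples, fitted_models, statistics,
                        fit_options=fit_options, seed=seed)
    return fitres, cloud


def test_chi2(model: PredictorModel, dataset: Dataset, B: int = 1000,
              seed: int | None = None, tail: str = "right", alpha: float = 0.05,
              fit_options: dict | None = None) -> TestResult:
    """Bootstrapped chi-square test of ``model`` against ``dataset``."""
    fitres, cloud = _pipeline_cloud(model, dataset, ["chi2"], [model], B, seed,
                                    fit_options)
    p = empirical_p_1d(cloud.stat_matrix[:, 0], fitres.chi2, tail)
    return TestResult("chi2", p, StatisticVector(("chi2",), (fitres.chi2,)),
                      tail, alpha, cloud.metadata())


def test_dw(model: PredictorModel, dataset: Dataset, B: int = 1000,
            seed: int | None = None, tail: str = "left", alpha: float = 0.05,
            fit_options: dict | None = None) -> TestResult:
    """Bootstrapped Durbin-Watson test of ``model`` against ``dataset``.

    Left-tailed by default: only positive residual autocorrelation (DW below
    the cloud) counts as evidence against the model.
    """
    fitres = fit_model(model, dataset, **(fit_options or {}))
    observed = dw_statistic(fitres.residuals)  # raises on a degenerate fit
    samples = generate_bootstrap_samples(model, fitres.theta_hat, dataset.design,
                                         dataset.noise_model(), B, seed)
    cloud = build_cloud(samples, [model], ["dw"], fit_options=fit_options,
                        seed=seed)
    p = empirical_p_1d(cloud.stat_matrix[:, 0], observed, tail)
    return TestResult("dw", p, StatisticVector(("dw",), (observed,)),
                      tail, alpha, cloud.metadata())


def test_2d(model1: PredictorModel, dataset: Dataset,
            second_axis: str | PredictorModel = "dw", B: int = 1000,
            seed: int | None = None, grid_n: int = 128, alpha: float = 0.05,
            competing: bool = False, fit_options: dict | None = None,
            bandwidth="silverman"):
    """Joint 2D density test of ``model1`` (chi2 vs DW, or chi2 vs chi2).

    ``second_axis`` is ``"dw"`` for the chi-square-versus-Durbin-Watson test,
    or a second :class:`PredictorModel` whose chi-square on the same bootstrap
    samples forms the second axis.  With ``competing=True`` (second model
    only) the test is repeated with each model serving as H0 and a list of
    two :class:`TestResult` is returned, so the outcome can be to reject
    none, either, or both models.
    """
    if isinstance(second_axis, str):
        if second_axis != "dw":
            raise ValueError("second_axis must be 'dw' or a PredictorModel")
        fitres, cloud = _pipeline_cloud(model1, dataset, ["chi2", "dw"],
                                        [model1], B, seed, fit_options)
        observed = (fitres.chi2, dw_statistic(fitres.residuals))
        names = ("chi2", "dw")
        return _density_result("2d_chi2_dw", cloud, observed, names, alpha,
                               grid_n, bandwidth)

    model2 = second_axis
    if competing:
        return [
            test_2d(h0, dataset, second_axis=other, B=B, seed=seed,
                    grid_n=grid_n, alpha=alpha, competing=False,
                    fit_options=fit_options, bandwidth=bandwidth)
            for h0, other in ((model1, model2), (model2, model1))
        ]
    stats = [f"chi2:{model1.model_id}", f"chi2:{model2.model_id}"]
    fitres, cloud = _pipeline_cloud(model1, dataset, stats, [model1, model2],
                                    B, seed, fit_options)
    fit2 = fit_model(model2, dataset, **(fit_options or {}))
    observed = (fitres.chi2, fit2.chi2)
    names = (f"chi2_{model1.model_id}", f"chi2_{model2.model_id}")
    return _density_result("2d_chi2_chi2", cloud, observed, names, alpha,
                           grid_n, bandwidth, h0_model=model1.model_id)


def _density_result(test_name: str, cloud: BootstrapCloud, observed, names,
                    alpha: float, grid_n: int, bandwidth,
                    h0_model: str | None = None) -> TestResult:
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", CollapsedCloudWarning)
        grid, ev = kde2d(cloud.stat_matrix, grid_n=grid_n, bandwidth=bandwidth)
        p = p_value_2d(grid, ev, observed)
        caught = [str(w.message) for w in wlist
                  if issubclass(w.category, CollapsedCloudWarning)]
    res = TestResult(test_name, p, StatisticVector(tuple(names), tuple(observed)),
                     "density", alpha, cloud.metadata())
    res.warnings.extend(caught)
    if caught:
        res.meta["collapsed"] = True
    if h0_model:
        res.meta["h0_model"] = h0_model
    return res


def test_lhr(model1: PredictorModel, model2: PredictorModel, dataset: Dataset,
             h0_model: str = "model1", B: int = 1000, seed: int | None = None,
             alpha: float = 0.05, tail: str = "two",
             fit_options: dict | None = None) -> TestResult:
    """Bootstrapped log-likelihood-ratio test of model1 against model2.

    The LHR cloud (chi2 of model1 minus chi2 of model2, both refit to each
    sample) is generated under the chosen H0 model; the observed LHR is
    tested two-tailed against it.
    """
    if h0_model not in ("model1", "model2"):
        raise ValueError("h0_model must be 'model1' or 'model2'")
    fit1 = fit_model(model1, dataset, **(fit_options or {}))
    fit2 = fit_model(model2, dataset, **(fit_options or {}))
    observed = lhr_statistic(fit1.chi2, fit2.chi2)
    gen = model1 if h0_model == "model1" else model2
    gen_fit = fit1 if h0_model == "model1" else fit2
    samples = generate_bootstrap_samples(gen, gen_fit.theta_hat, dataset.design,
                                         dataset.noise_model(), B, seed)
    cloud = build_cloud(samples, [model1, model2],
                        ["lhr", f"chi2:{model2.model_id}"],
                        fit_options=fit_options, seed=seed)
    p = empirical_p_1d(cloud.column("lhr"), observed, tail)
    res = TestResult("lhr", p, StatisticVector(("lhr",), (observed,)),
                     tail, alpha, cloud.metadata())
    res.meta["h0_model"] = gen.model_id
    res.meta["lhp_observed"] = lhp_statistic(fit1.chi2, fit2.chi2)
    help_col = cloud.column(f"chi2_{model2.model_id}")
    if float(np.std(help_col)) <= 1e-9 * max(1.0, float(np.abs(help_col).max())):
        res.meta["collapsed"] = True
        res.warnings.append(
            f"help model {model2.model_id} fits every bootstrap sample with "
            "identical cost; the LHR degenerates to the (mirrored) "
            "chi-square distribution of the tested model")
    return res


def cloud_geometry_diagnostic(cloud) -> dict[str, Any]:
    """Geometry report for a 2-column cloud: does a 2D analysis add power?

    A cloud whose principal axis lies away from both coordinate axes carries
    joint information that neither 1D test sees; a collapsed or axis-parallel
    cloud does not.
    """
    pts = cloud.stat_matrix if isinstance(cloud, BootstrapCloud) else np.asarray(cloud, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("diagnostic needs a 2-column cloud")
    x, y = pts[:, 0], pts[:, 1]
    cx, cy = _collapsed(x), _collapsed(y)
    collapsed = cx or cy
    if collapsed:
        corr = 0.0
        angle = 0.0 if cy else 90.0
    else:
        corr = float(np.corrcoef(x, y)[0, 1])
        cov = np.cov(x, y)
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, int(np.argmax(evals))]
        angle = float(np.degrees(np.arctan2(v[1], v[0]))) % 180.0
        if angle > 90.0:
            angle -= 180.0
    return {
        "correlation": corr,
        "principal_angle_deg": angle,
        "collapsed": bool(collapsed),
        "collapsed_axis": (0 if cx else 1) if collapsed else None,
        "informative_2d": bool(not collapsed and abs(corr) > 0.05),
    }
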