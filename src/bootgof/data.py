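"""Core data containers: experiment design, noise model, and datasets.

A *design* fixes where a model is evaluated: one ordered coordinate grid per
measured signal (time points for dynamic models, a regressor for static
models).  A *dataset* couples a design with measured values and the assumed
per-point noise standard deviations, which are treated as known throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "Design",
    "NoiseModel",
    "Dataset",
    "DataValidationError",
]


class DataValidationError(ValueError):
    """Raised when a design/dataset violates its structural invariants."""


def _as_arrays(seq: Sequence[Any]) -> tuple[np.ndarray, ...]:
    return tuple(np.asarray(a, dtype=float) for a in seq)


@dataclass(frozen=True)
class Design:
    """Evaluation grid: per-signal coordinates plus optional exogenous input.

    Parameters
    ----------
    signal_ids : tuple of str
        Labels of the measured output signals.
    coordinates : tuple of ndarray
        One strictly increasing coordinate array per signal, each with at
        least 3 points (the Durbin-Watson statistic needs at least two
        adjacent residual pairs).
    inputs : dict, optional
        Constant exogenous input description (unused by the built-in models).
    """

    signal_ids: tuple[str, ...]
    coordinates: tuple[np.ndarray, ...]
    inputs: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal_ids", tuple(self.signal_ids))
        object.__setattr__(self, "coordinates", _as_arrays(self.coordinates))
        if len(self.signal_ids) != len(self.coordinates):
            raise DataValidationError(
                f"{len(self.signal_ids)} signal ids but "
                f"{len(self.coordinates)} coordinate arrays"
            )
        if not self.signal_ids:
            raise DataValidationError("design needs at least one signal")
        for sid, c in zip(self.signal_ids, self.coordinates):
            if c.ndim != 1 or c.size < 3:
                raise DataValidationError(
                    f"signal {sid!r}: need a 1D grid with >=3 points, got shape {c.shape}"
                )
            if not np.all(np.diff(c) > 0):
                raise DataValidationError(
                    f"signal {sid!r}: coordinates must be strictly increasing"
                )

    @property
    def n_signals(self) -> int:
        return len(self.signal_ids)

    @property
    def n_points(self) -> int:
        """Total number of observation points over all signals."""
        return int(sum(c.size for c in self.coordinates))

    @property
    def block_sizes(self) -> tuple[int, ...]:
        return tuple(c.size for c in self.coordinates)

    @classmethod
    def single(cls, coordinates: Sequence[float], signal_id: str = "y1",
               inputs: dict[str, Any] | None = None) -> "Design":
        """Convenience constructor for the common one-signal case."""
        return cls((signal_id,), (np.asarray(coordinates, dtype=float),), inputs)


@dataclass(frozen=True)
class NoiseModel:
    """Additive, zero-mean, i.i.d. Gaussian measurement noise.

    ``sigma`` holds one positive standard-deviation array per signal,
    aligned with a :class:`Design`.
    """

    sigma: tuple[np.ndarray, ...]
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", _as_arrays(self.sigma))
        if self.kind != "gaussian":
            raise DataValidationError(f"unsupported noise kind {self.kind!r}")
        for s in self.sigma:
            if not np.all(s > 0):
                raise DataValidationError("all noise sigma must be positive")

    @classmethod
    def constant(cls, sigma: float, design: Design) -> "NoiseModel":
        if sigma <= 0:
            raise DataValidationError("sigma must be positive")
        return cls(tuple(np.full(c.size, float(sigma)) for c in design.coordinates))

    def matching(self, design: Design) -> None:
        if tuple(s.size for s in self.sigma) != design.block_sizes:
            raise DataValidationError("noise sigma shapes do not match the design")


@dataclass(frozen=True)
class Dataset:
    """Measured (or simulated) values on a design with known noise levels.

    ``provenance`` records how the data came to be: ``observed`` for user
    data, ``synthetic`` for generator output (with true model, true
    parameters and seed), ``bootstrap`` for parametric-bootstrap samples.
    """

    design: Design
    values: tuple[np.ndarray, ...]
    sigma: tuple[np.ndarray, ...]
    provenance: dict[str, Any] = field(default_factory=lambda: {"kind": "observed"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_arrays(self.values))
        object.__setattr__(self, "sigma", _as_arrays(self.sigma))
        shapes = self.design.block_sizes
        if tuple(v.size for v in self.values) != shapes:
            raise DataValidationError("values shapes do not match the design")
        if tuple(s.size for s in self.sigma) != shapes:
            raise DataValidationError("sigma shapes do not match the design")
        for s in self.sigma:
            if not np.all(s > 0):
                raise DataValidationError("all sigma must be positive")

    @property
    def n_points(self) -> int:
        return self.design.n_points

    def values_flat(self) -> np.ndarray:
        return np.concatenate(self.values)

    def sigma_flat(self) -> np.ndarray:
        return np.concatenate(self.sigma)

    def noise_model(self) -> NoiseModel:
        return NoiseModel(self.sigma)

    def split_flat(self, flat: np.ndarray) -> tuple[np.ndarray, ...]:
        """Split a flat length-``n_points`` array back into per-signal blocks."""
        flat = np.asarray(flat, dtype=float)
        if flat.size != self.n_points:
            raise DataValidationError("flat array length does not match the design")
        out = []
        start = 0
        for n in self.design.block_sizes:
            out.append(flat[start:start + n])
            start += n
        return tuple(out)

    def replace_values(self, values: Sequence[np.ndarray],
                       provenance: dict[str, Any] | None = None) -> "Dataset":
        return Dataset(self.design, tuple(values), self.sigma,
                       provenance or dict(self.provenance))


def split_blocks(flat: np.ndarray, design: Design) -> tuple[np.ndarray, ...]:
    """Split a flat array into per-signal blocks following ``design``."""
    flat = np.asarray(flat, dtype=float)
    out = []
    start = 0
    for n in design.block_sizes:
        out.append(flat[start:start + n])
        start += n
    if start != flat.size:
        raise DataValidationError("flat array length does not match the design")
    return tuple(out)
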