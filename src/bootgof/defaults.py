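"""Benchmark study conditions: default designs, true parameters, noise levels.

The static case observes one signal at 11 equidistant regressor points on
[0, 2]; the dynamic case at 11 equidistant time points on [0, 3].  Noise is
additive i.i.d. Gaussian with sigma 0.5 (static) and 0.75 (dynamic) — on the
order of 5-10% of the average model output for the default true parameters.
"""

from __future__ import annotations

import numpy as np

from .data import Design

SIGMA_STATIC = 0.5
SIGMA_DYNAMIC = 0.75

#: default true parameters of the benchmark generators
TRUE_PARAMS: dict[str, tuple[float, ...]] = {
    "MS1": (4.0, 5.0),
    "MS2": (2.0, 3.0),
    "MD1": (0.7,),
    "MD2": (5.0,),
}

STATIC_MODELS = ("MS1", "MS2")
DYNAMIC_MODELS = ("MD1", "MD2")


def static_design() -> Design:
    return Design.single(np.linspace(0.0, 2.0, 11))


def dynamic_design() -> Design:
    return Design.single(np.linspace(0.0, 3.0, 11))


def case_of(model_id: str) -> str:
    if model_id in STATIC_MODELS:
        return "static"
    if model_id in DYNAMIC_MODELS:
        return "dynamic"
    raise ValueError(f"model {model_id!r} has no default case")


def default_design(case: str) -> Design:
    if case == "static":
        return static_design()
    if case == "dynamic":
        return dynamic_design()
    raise ValueError(f"case must be 'static' or 'dynamic', got {case!r}")


def default_sigma(case: str) -> float:
    return SIGMA_STATIC if case == "static" else SIGMA_DYNAMIC
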