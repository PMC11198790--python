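"""Analytic benchmark objectives with known global minima.

Standard test functions (sphere, Rastrigin, Ackley, Rosenbrock) on their
conventional boxes, used to validate and compare the optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from baoscnn.search_space import HyperparameterSpec, SearchSpace

__all__ = ["BenchmarkSpec", "benchmark", "benchmark_space", "BENCHMARKS"]


@dataclass(frozen=True)
class BenchmarkSpec:
    name: str
    bounds: tuple[float, float]  # per-dimension interval
    optimum_coordinate: float  # global minimum is at (c, ..., c)
    optimum_value: float


BENCHMARKS: dict[str, BenchmarkSpec] = {
    "sphere": BenchmarkSpec("sphere", (-5.12, 5.12), 0.0, 0.0),
    "rastrigin": BenchmarkSpec("rastrigin", (-5.12, 5.12), 0.0, 0.0),
    "ackley": BenchmarkSpec("ackley", (-32.768, 32.768), 0.0, 0.0),
    "rosenbrock": BenchmarkSpec("rosenbrock", (-5.0, 10.0), 1.0, 0.0),
}


def benchmark(name: str, x) -> float:
    """Evaluate the named benchmark at ``x``."""
    x = np.asarray(x, dtype=float)
    if name == "sphere":
        return float(np.sum(x**2))
    if name == "rastrigin":
        return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))
    if name == "ackley":
        d = x.size
        return float(
            -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / d))
            - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
            + 20.0
            + np.e
        )
    if name == "rosenbrock":
        return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))
    raise ValueError(f"unknown benchmark {name!r}")


def benchmark_space(name: str, d: int) -> SearchSpace:
    """Continuous d-dimensional box for the named benchmark."""
    spec = BENCHMARKS.get(name)
    if spec is None:
        raise ValueError(f"unknown benchmark {name!r}")
    lo, hi = spec.bounds
    return SearchSpace(
        specs=tuple(
            HyperparameterSpec(f"x{j}", "continuous", lower=lo, upper=hi) for j in range(d)
        )
    )
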