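"""Mixed continuous/discrete hyperparameter search spaces.

A :class:`SearchSpace` is an ordered list of dimensions.  Continuous
dimensions live in their native units ``[lower, upper]``; discrete
dimensions are represented internally on the unit interval and decoded
lazily to a member of their ordered category list.  Positions are plain
``numpy`` vectors of length ``d`` in this embedding, which is exactly the
relaxation the optimizers move in: discrete choices only materialise at
objective-evaluation time.

The decoding of a unit-interval coordinate ``R`` to one of ``n`` ordered
categories ``K1..Kn`` is

    alpha = 1 + n * R          # real, in [1, n + 1]
    beta  = min(floor(alpha), n)
    value = K_beta             # 1-based

which maps uniform ``R`` to uniform categories and clamps ``R = 1`` onto
the last category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "HyperparameterSpec",
    "SearchSpace",
    "default_seagrass_space",
    "desk_space",
    "discretize",
]


@dataclass(frozen=True)
class HyperparameterSpec:
    """One dimension of the search space.

    Parameters
    ----------
    name
        Unique identifier of the hyperparameter.
    kind
        ``"continuous"`` (needs ``lower < upper``) or ``"discrete"``
        (needs a non-empty, duplicate-free, ordered ``categories`` list).
    """

    name: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    categories: tuple[Any, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "continuous":
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(f"continuous dimension {self.name!r} needs lower < upper")
        else:
            if not self.categories:
                raise ValueError(f"discrete dimension {self.name!r} needs >= 1 category")
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"discrete dimension {self.name!r} has duplicate categories")
            object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def is_discrete(self) -> bool:
        return self.kind == "discrete"

    # Interval of the optimizer embedding for this dimension.
    @property
    def embedded_interval(self) -> tuple[float, float]:
        if self.is_discrete:
            return (0.0, 1.0)
        return (float(self.lower), float(self.upper))

    def to_config(self) -> dict:
        if self.is_discrete:
            return {"name": self.name, "kind": self.kind, "categories": list(self.categories)}
        return {"name": self.name, "kind": self.kind, "lower": self.lower, "upper": self.upper}

    @classmethod
    def from_config(cls, block: Mapping[str, Any]) -> "HyperparameterSpec":
        if block.get("kind") == "discrete":
            return cls(name=block["name"], kind="discrete", categories=tuple(block["categories"]))
        return cls(
            name=block["name"],
            kind="continuous",
            lower=float(block["lower"]),
            upper=float(block["upper"]),
        )


def discretize(R: float, categories: Sequence[Any]) -> Any:
    """Map a unit-interval coordinate onto an ordered category list.

    ``alpha = 1 + n*R`` maps ``R`` into ``[1, n + 1]``; ``beta =
    min(floor(alpha), n)`` clamps onto a valid 1-based index; the result is
    always a member of ``categories``.
    """
    n = len(categories)
    if n < 1:
        raise ValueError("categories must be non-empty")
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"R={R} outside [0, 1]")
    alpha = 1.0 + n * R
    beta = min(int(math.floor(alpha)), n)
    return categories[beta - 1]


@dataclass(frozen=True)
class SearchSpace:
    """Ordered, fixed-dimension mixed search space."""

    specs: tuple[HyperparameterSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        if len(self.specs) < 1:
            raise ValueError("search space needs at least one dimension")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")

    @property
    def d(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def embedded_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper bound vectors of the optimizer embedding."""
        lo = np.array([s.embedded_interval[0] for s in self.specs])
        hi = np.array([s.embedded_interval[1] for s in self.specs])
        return lo, hi

    @property
    def span(self) -> np.ndarray:
        lo, hi = self.embedded_bounds()
        return hi - lo

    def sample_uniform(self, count: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``count`` positions uniformly: ``lower + rand*(upper-lower)``
        per continuous dimension, ``rand`` in [0, 1] per discrete one.

        Returns an array of shape ``(count, d)``.
        """
        if count < 1:
            raise ValueError("count must be >= 1")
        lo, hi = self.embedded_bounds()
        u = rng.random((count, self.d))
        return lo + u * (hi - lo)

    def repair(self, position: np.ndarray) -> np.ndarray:
        """Clamp every coordinate into its admissible interval (idempotent)."""
        lo, hi = self.embedded_bounds()
        return np.clip(np.asarray(position, dtype=float), lo, hi)

    def decode(self, position: np.ndarray) -> dict[str, Any]:
        """Decode a position into a name -> native value assignment."""
        position = np.asarray(position, dtype=float)
        if position.shape != (self.d,):
            raise ValueError(f"position has shape {position.shape}, expected ({self.d},)")
        out: dict[str, Any] = {}
        for spec, x in zip(self.specs, position):
            if spec.is_discrete:
                out[spec.name] = discretize(float(x), spec.categories)
            else:
                out[spec.name] = float(x)
        return out

    def to_config(self) -> list[dict]:
        return [s.to_config() for s in self.specs]

    @classmethod
    def from_config(cls, blocks: Sequence[Mapping[str, Any]]) -> "SearchSpace":
        return cls(specs=tuple(HyperparameterSpec.from_config(b) for b in blocks))


def _grid(start: float, step: float, stop: float) -> tuple[float, ...]:
    vals = np.round(np.arange(start, stop + step / 2, step), 10)
    return tuple(float(v) for v in vals)


def default_seagrass_space() -> SearchSpace:
    """The nine-dimensional CNN hyperparameter space of the habitat
    classification study: layer count, kernel size, filter count, epochs,
    batch size, pool size, dropout, learning rate and momentum, all as
    ordered category grids.

    The learning-rate grid steps by 0.005 from 0.001 and appends the 0.1
    endpoint, which the raw step does not land on.
    """
    lr_grid = _grid(0.001, 0.005, 0.096) + (0.1,)
    return SearchSpace(
        specs=(
            HyperparameterSpec("n_conv", "discrete", categories=tuple(range(1, 21))),
            HyperparameterSpec("kernel_size", "discrete", categories=tuple(range(1, 31))),
            HyperparameterSpec("n_filters", "discrete", categories=tuple(range(1, 501))),
            HyperparameterSpec("n_epochs", "discrete", categories=tuple(range(1, 401))),
            HyperparameterSpec("batch_size", "discrete", categories=tuple(range(10, 201, 10))),
            HyperparameterSpec("pool_size", "discrete", categories=tuple(range(1, 21))),
            HyperparameterSpec("dropout", "discrete", categories=_grid(0.20, 0.05, 0.65)),
            HyperparameterSpec("learning_rate", "discrete", categories=lr_grid),
            HyperparameterSpec("momentum", "discrete", categories=_grid(0.05, 0.05, 0.95)),
        )
    )


def desk_space() -> SearchSpace:
    """A scaled-down nine-dimensional space for CPU desk runs.

    Same hyperparameters, ordering and character as
    :func:`default_seagrass_space` — wide grids in which most combinations
    are poor (undertrained, underparameterised, or unstable) and good
    configurations must be searched for — but with sizes that keep every
    candidate trainable in seconds on small synthetic patches.
    """
    return SearchSpace(
        specs=(
            HyperparameterSpec("n_conv", "discrete", categories=(1, 2, 3)),
            HyperparameterSpec("kernel_size", "discrete", categories=(1, 3, 5, 7)),
            HyperparameterSpec("n_filters", "discrete", categories=(2, 4, 8)),
            HyperparameterSpec("n_epochs", "discrete", categories=(2, 4, 6, 8)),
            HyperparameterSpec("batch_size", "discrete", categories=(16, 32, 64)),
            HyperparameterSpec("pool_size", "discrete", categories=(2, 3)),
            HyperparameterSpec("dropout", "discrete", categories=(0.2, 0.35, 0.5, 0.65)),
            HyperparameterSpec(
                "learning_rate", "discrete", categories=(0.005, 0.01, 0.02, 0.05, 0.1)
            ),
            HyperparameterSpec("momentum", "discrete", categories=(0.05, 0.3, 0.6, 0.9)),
        )
    )
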