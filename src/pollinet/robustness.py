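"""Secondary-extinction robustness of bipartite networks.

Species are removed stepwise from one trophic level (all their matrix
entries set to zero); species of the other level with no interactions left
go secondarily extinct.  Robustness R is the area under the survivor curve
on normalized axes, averaged over random removal orders: R -> 1 for
networks that keep the other level alive until the very end, R -> 0 for
networks that collapse immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .assembly import QuantNetwork
from .nulls import NullEnsemble, _walk_stream, patefield_sample, standardize_metric

Level = Literal["plant", "pollinator"]


@dataclass(frozen=True)
class ExtinctionResult:
    walk_id: str
    level_removed: Level
    curve: np.ndarray = field(repr=False)  # mean survivor curve, shape (n+1, 2)
    R: float
    R_se: float
    n_orders: int
    seed: int | None


def _oriented(net: QuantNetwork, level_removed: Level) -> np.ndarray:
    """Matrix with removed species as rows, surviving level as columns."""
    if level_removed == "plant":
        return net.a
    if level_removed == "pollinator":
        return net.a.T
    raise ValueError(f"unknown level {level_removed!r}")


def survivors_along_order(mat: np.ndarray, order: Sequence[int]) -> np.ndarray:
    """Count of surviving column-species after each removal step.

    ``order`` is a permutation of row indices.  Entry k is the number of
    columns with at least one nonzero interaction after removing the first
    k rows; entry 0 is the initial column count.
    """
    n_rows, n_cols = mat.shape
    if sorted(order) != list(range(n_rows)):
        raise ValueError("order must be a permutation of the removed level")
    remaining = mat.copy()
    counts = np.empty(n_rows + 1, dtype=np.int64)
    counts[0] = int((remaining.sum(axis=0) > 0).sum())
    for k, idx in enumerate(order, start=1):
        remaining[idx, :] = 0
        counts[k] = int((remaining.sum(axis=0) > 0).sum())
    return counts


def extinction_curve(net: QuantNetwork, level_removed: Level, order: Sequence[int]) -> np.ndarray:
    """Survivor curve for one removal order, on normalized axes.

    Returns an array of (fraction_removed, fraction_surviving) pairs
    starting at (0, 1) and ending at (1, 0).
    """
    mat = _oriented(net, level_removed)
    counts = survivors_along_order(mat, order)
    n_rows, n_cols = mat.shape
    x = np.arange(n_rows + 1) / n_rows
    y = counts / n_cols
    return np.column_stack([x, y])


def _area(curve: np.ndarray) -> float:
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def robustness(
    net: QuantNetwork,
    level_removed: Level,
    n_orders: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ExtinctionResult:
    """Mean trapezoidal area under the survivor curve over random orders."""
    if rng is None:
        rng = _walk_stream(seed, f"{net.walk_id}::robustness::{level_removed}")
    n_removed = _oriented(net, level_removed).shape[0]
    areas = np.empty(n_orders)
    mean_curve = np.zeros(n_removed + 1)
    for k in range(n_orders):
        order = rng.permutation(n_removed)
        curve = extinction_curve(net, level_removed, order)
        areas[k] = _area(curve)
        mean_curve += curve[:, 1]
    mean_curve /= n_orders
    x = np.arange(n_removed + 1) / n_removed
    se = float(areas.std(ddof=1) / np.sqrt(n_orders)) if n_orders > 1 else 0.0
    return ExtinctionResult(
        walk_id=net.walk_id,
        level_removed=level_removed,
        curve=np.column_stack([x, mean_curve]),
        R=float(areas.mean()),
        R_se=se,
        n_orders=n_orders,
        seed=seed,
    )


def standardized_robustness(
    net: QuantNetwork,
    level_removed: Level,
    n_orders: int = 100,
    n_null: int = 1000,
    seed: int | None = None,
) -> NullEnsemble:
    """z-score of R against fixed-marginal null networks.

    Each null network's R is computed with the same number of removal
    orders as the observed one; removal-order randomness is driven by a
    stream derived from the network's own id so that results do not depend
    on processing order.
    """
    order_rng = _walk_stream(seed, f"{net.walk_id}::orders::{level_removed}")

    def metric(n: QuantNetwork) -> float:
        return robustness(n, level_removed, n_orders=n_orders, rng=order_rng).R

    return standardize_metric(
        net,
        metric,
        n_null=n_null,
        seed=seed,
        sampler=patefield_sample,
        metric_name=f"robustness_{level_removed}",
    )
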