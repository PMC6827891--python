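"""Temporal gene selection and dense trajectory construction.

Short time-course expression experiments measure each gene at a handful of
timepoints (e.g. 0/6/12/24/48 h after treatment).  Network inference needs
(i) the subset of genes that actually change over time and (ii) a dense,
artifact-free reconstruction of each trajectory from which finite-difference
derivatives can be taken.  This module provides both:

* temporally-changing-gene (TCG) selection by an expression floor ``zeta``
  and a pairwise fold-change threshold ``delta``;
* shape-preserving piecewise-cubic Hermite interpolation (PCHIP), which
  keeps monotonicity, local extrema and nonnegativity of the measured
  knots — ordinary cubic splines can undershoot below zero, which is
  meaningless for expression data;
* forward-difference derivative matrices on the dense grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TimeCourseMatrix",
    "TCGCriteria",
    "DenseTrajectories",
    "select_tcgs",
    "hermite_interpolate",
    "finite_difference_derivatives",
]


@dataclass
class TimeCourseMatrix:
    """Genes x timepoints expression for one condition.

    ``times`` are hours since treatment; ``times[0]`` is the untreated
    baseline.  ``values`` holds nonnegative normalized expression
    (FPKM/TPM-like units), one row per gene.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) == 0:
            raise ValueError("TimeCourseMatrix must contain at least one gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least 2 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.times.size} timepoints"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.gene_ids[i]!r}, time {self.times[j]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, genes: list[str]) -> "TimeCourseMatrix":
        """Row-subset preserving the requested gene order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        rows = [index[g] for g in genes]
        return TimeCourseMatrix(list(genes), self.times.copy(), self.values[rows])


@dataclass
class TCGCriteria:
    """Thresholds of the temporally-changing-gene test.

    A gene is a TCG when its maximal expression reaches ``zeta`` (same
    units as the matrix) and some pair of timepoints differs by at least a
    ``delta``-fold change.  ``pseudocount`` is added to both sides of the
    fold-change ratio so dropout zeros do not trivially pass the test.
    """

    zeta: float = 10.0
    delta: float = 5.0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")
        if self.delta <= 1:
            raise ValueError("delta must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class DenseTrajectories:
    """Interpolated expression ``X`` and derivatives ``Y`` on a dense grid.

    ``X`` is genes x n; ``Y`` is the forward-difference derivative,
    genes x (n-1), with ``Y[i, k] = (X[i, k+1] - X[i, k]) / (t[k+1] - t[k])``.
    """

    gene_ids: list[str]
    grid_times: np.ndarray
    X: np.ndarray
    Y: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if np.any(np.diff(self.grid_times) <= 0):
            raise ValueError("grid times must be strictly increasing")
        if self.Y is None:
            self.Y = finite_difference_derivatives(self.X, self.grid_times)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (self.X.shape[0], self.X.shape[1] - 1):
            raise ValueError("Y must have exactly one fewer column than X")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, genes: list[str]) -> "DenseTrajectories":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return DenseTrajectories(
            list(genes), self.grid_times.copy(), self.X[rows], self.Y[rows]
        )


def select_tcgs(expr: TimeCourseMatrix, criteria: TCGCriteria | None = None) -> list[str]:
    """Return the genes passing the temporally-changing-gene criteria.

    A gene with measurements ``u_k`` passes when ``max_k u_k >= zeta`` and
    ``(u_j + c) / (u_k + c) >= delta`` for some pair ``(j, k)``, with
    ``c`` the pseudocount.  Input gene order is preserved.
    """
    if criteria is None:
        criteria = TCGCriteria()
    u = expr.values
    c = criteria.pseudocount
    floor_ok = u.max(axis=1) >= criteria.zeta
    # max over all (j, k) pairs of (u_j + c)/(u_k + c) = (max + c)/(min + c)
    fold = (u.max(axis=1) + c) / (u.min(axis=1) + c)
    fold_ok = fold >= criteria.delta
    keep = floor_ok & fold_ok
    return [g for g, k in zip(expr.gene_ids, keep) if k]


def hermite_interpolate(expr: TimeCourseMatrix, n: int = 100) -> DenseTrajectories:
    """Interpolate each gene onto ``n`` uniform points with PCHIP.

    The piecewise-cubic Hermite scheme (Fritsch–Carlson slopes: harmonic
    means in the interior, one-sided at the ends) passes through every
    knot, has a continuous first derivative, and preserves monotonicity
    and hence nonnegativity of the measured data.
    """
    if n < expr.times.size:
        raise ValueError(f"n={n} must be >= number of knots ({expr.times.size})")
    grid = np.linspace(expr.times[0], expr.times[-1], n)
    interp = PchipInterpolator(expr.times, expr.values, axis=1, extrapolate=False)
    X = interp(grid)
    # place knot times exactly (linspace hits the endpoints; interior knots
    # are evaluated, already exact up to float rounding)
    return DenseTrajectories(list(expr.gene_ids), grid, X)


def finite_difference_derivatives(X: np.ndarray, grid_times: np.ndarray) -> np.ndarray:
    """Forward differences of ``X`` columns over ``grid_times``.

    ``Y[i, k] = (X[i, k+1] - X[i, k]) / (t[k+1] - t[k])``; this is the
    response used as the regression target of the network model, valid
    because the dense grid step is small.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(grid_times, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 grid columns to differentiate")
    if t.size != X.shape[1]:
        raise ValueError("grid length must match number of columns")
    dt = np.diff(t)
    return np.diff(X, axis=1) / dt
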