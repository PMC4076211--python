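"""Recurrence matrices, recurrence networks, and the transitivity dimension.

A recurrence plot marks pairs of phase-space states within a threshold ε
of each other:

    R_ij = Θ(ε − ‖x̂_i − x̂_j‖)

Read as the adjacency matrix of an (unweighted, undirected) *recurrence
network*, its global transitivity

    T = (closed length-2 paths) / (all length-2 paths)

carries geometric information: for a set of dimension d sampled under
the maximum norm, T → (3/4)^d as ε → 0, which inverts to the
*transitivity dimension*

    D_T = log T / log(3/4)

— a dimension estimate that needs no scaling analysis across ε.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import Trajectory, delay_embed
from .errors import (
    DegenerateSeriesError,
    TransitivityDomainError,
    UndefinedTransitivityError,
)
from .series import Series, as_series

__all__ = [
    "RecurrenceConfig",
    "RecurrenceGraph",
    "recurrence_matrix",
    "transitivity",
    "transitivity_dimension",
    "window_transitivity_dimension",
    "write_recurrence_csv",
    "write_edge_list",
]

_NORMS = {"euclidean": "euclidean", "maximum": "chebyshev"}

#: log base of the transitivity-dimension closed form
_LOG_3_4 = math.log(3.0 / 4.0)


@dataclass(frozen=True)
class RecurrenceConfig:
    """How the recurrence threshold ε is fixed and distances measured.

    epsilon_mode
        ``"recurrence_rate"`` (default): ε is the distance quantile that
        makes the chosen fraction of admissible pairs recurrent — this
        keeps windows comparable regardless of their local amplitude.
        ``"absolute"``: ε is used as given, in signal units.
    epsilon
        Target recurrence rate in (0, 1) or the absolute threshold.
    norm
        ``"maximum"`` (default; the (3/4)^m identity is exact for
        max-norm hypercubes) or ``"euclidean"`` (small dimension bias).
    theiler
        Minimum temporal separation |i−j| for a pair to count; 1 removes
        exactly the main diagonal (trivial self-matches).
    """

    epsilon_mode: str = "recurrence_rate"
    epsilon: float = 0.10
    norm: str = "maximum"
    theiler: int = 1

    def __post_init__(self) -> None:
        if self.epsilon_mode not in ("absolute", "recurrence_rate"):
            raise ValueError("epsilon_mode must be 'absolute' or 'recurrence_rate'")
        if self.epsilon_mode == "recurrence_rate" and not (0.0 < self.epsilon < 1.0):
            raise ValueError("recurrence rate must lie strictly in (0, 1)")
        if self.epsilon_mode == "absolute" and self.epsilon <= 0:
            raise ValueError("absolute epsilon must be positive")
        if self.norm not in _NORMS:
            raise ValueError(f"norm must be one of {sorted(_NORMS)}")
        if self.theiler < 0:
            raise ValueError("theiler must be non-negative")


@dataclass(frozen=True)
class RecurrenceGraph:
    """Symmetric binary recurrence matrix; doubles as network adjacency."""

    matrix: np.ndarray
    epsilon_used: float
    theiler: int = 1

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("recurrence matrix must be square")
        object.__setattr__(self, "matrix", mat.astype(np.uint8))

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def recurrence_rate(self) -> float:
        """Fraction of off-diagonal cells that are recurrent."""
        n = self.n
        off = int(self.matrix.sum()) - int(np.trace(self.matrix))
        return off / float(n * n - n)


def recurrence_matrix(traj: Trajectory, cfg: RecurrenceConfig) -> RecurrenceGraph:
    """Build the thresholded recurrence matrix of a trajectory.

    In recurrence-rate mode, ε is set to the distance quantile over
    admissible pairs (|i−j| ≥ theiler) that achieves the target density
    to within one matrix cell.
    """
    pts = traj.points
    n = pts.shape[0]
    if n < 2:
        raise ValueError("trajectory must contain at least 2 points")
    dists = cdist(pts, pts, metric=_NORMS[cfg.norm])

    idx = np.arange(n)
    admissible = np.abs(idx[:, None] - idx[None, :]) >= max(cfg.theiler, 1)

    if cfg.epsilon_mode == "recurrence_rate":
        iu, ju = np.nonzero(np.triu(admissible))
        pair_d = np.sort(dists[iu, ju])
        if pair_d.size == 0:
            raise ValueError("theiler window excludes every pair")
        if pair_d[-1] == 0.0:
            raise DegenerateSeriesError(
                "all trajectory points identical: recurrence-rate quantile undefined"
            )
        k = int(round(cfg.epsilon * pair_d.size))
        k = min(max(k, 1), pair_d.size)
        eps = float(pair_d[k - 1])
    else:
        eps = float(cfg.epsilon)

    mat = ((dists <= eps) & admissible).astype(np.uint8)
    return RecurrenceGraph(matrix=mat, epsilon_used=eps, theiler=cfg.theiler)


def transitivity(graph: RecurrenceGraph) -> float:
    """Global transitivity: closed length-2 paths over all length-2 paths.

    Equals trace(A³) / (Σ A² − trace A²) for adjacency A.  Raises
    :class:`UndefinedTransitivityError` when the graph has no length-2
    path at all — a distinct outcome from a transitivity of zero.
    """
    a = graph.matrix.astype(np.float64)
    if a.shape[0] < 3:
        raise UndefinedTransitivityError("fewer than 3 nodes: no length-2 paths")
    a2 = a @ a
    paths2 = float(a2.sum() - np.trace(a2))
    if paths2 == 0.0:
        raise UndefinedTransitivityError("graph contains no length-2 paths")
    closed = float(np.trace(a2 @ a))
    return closed / paths2


def transitivity_dimension(t: float) -> float:
    """Closed-form dimension estimate D_T = log T / log(3/4), T ∈ (0, 1]."""
    if not (0.0 < t <= 1.0):
        raise TransitivityDomainError(f"transitivity must lie in (0, 1], got {t}")
    return math.log(t) / _LOG_3_4


def window_transitivity_dimension(
    series: Union[Series, Sequence[float]],
    m: int,
    tau: int,
    cfg: RecurrenceConfig,
) -> float:
    """Transitivity dimension of one window: embed → threshold → D_T."""
    traj = delay_embed(as_series(series), m=m, tau=tau)
    graph = recurrence_matrix(traj, cfg)
    return transitivity_dimension(transitivity(graph))


def write_recurrence_csv(graph: RecurrenceGraph, path: Union[str, Path]) -> None:
    """Dense 0/1 matrix, one row per line, comma-separated."""
    np.savetxt(Path(path), graph.matrix, fmt="%d", delimiter=",")


def write_edge_list(graph: RecurrenceGraph, path: Union[str, Path]) -> None:
    """Sparse upper-triangle edge list as two-column TSV (0-based i, j)."""
    iu, ju = np.nonzero(np.triu(graph.matrix))
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, j in zip(iu.tolist(), ju.tolist()):
            fh.write(f"{i}\t{j}\n")
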