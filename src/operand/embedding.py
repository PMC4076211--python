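"""Time-delay embedding and false-nearest-neighbour (FNN) dimension estimation.

A scalar signal x(t) generated by a deterministic system can be unfolded
into state vectors

    x̂_i = (x_i, x_{i+τ}, ..., x_{i+(m-1)τ})

for a delay τ and embedding dimension m.  When m is too small the
reconstructed trajectory self-intersects and points acquire *false*
nearest neighbours: pairs close in dimension m that separate sharply in
dimension m+1.  The optimal embedding dimension is the smallest m at
which the fraction of false neighbours (essentially) vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateSeriesError, SeriesTooShortError
from .series import Series, as_series

__all__ = [
    "EmbeddingConfig",
    "Trajectory",
    "delay_embed",
    "fnn_fraction",
    "optimal_embedding_dimension",
    "suggest_delay",
]

_NORMS = {"euclidean": "euclidean", "maximum": "chebyshev"}

#: relative distance below which two states are numerical duplicates.
#: Duplicate pairs are recurrences of the same state: their m -> m+1
#: distance ratio is 0/0 floating-point noise, so - like self-matches -
#: they are excluded from the nearest-neighbour search.
DUPLICATE_RTOL = 1e-10


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the FNN estimator.

    tau
        Time delay between successive delay-vector coordinates, in index
        units.  Default 1, appropriate for word-level polarity series.
    max_m
        Largest trial embedding dimension.
    r_tol
        Distance-ratio tolerance: a neighbour is false when the extra
        (m+1)-th coordinate distance exceeds ``r_tol`` times the
        m-dimensional neighbour distance.
    a_tol
        Attractor-size tolerance: a neighbour is also false when the
        (m+1)-dimensional distance exceeds ``a_tol`` standard deviations
        of the signal (catches "neighbours" that are merely the nearest
        points of a sparse cloud).
    vanish_fraction
        FNN fraction at or below which the count is deemed to have
        vanished (default 1%).
    norm
        ``"euclidean"`` or ``"maximum"``; ratio criteria are metric-stable.
    """

    tau: int = 1
    max_m: int = 20
    r_tol: float = 10.0
    a_tol: float = 2.0
    vanish_fraction: float = 0.01
    norm: str = "euclidean"

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be a positive integer")
        if self.max_m < 1:
            raise ValueError("max_m must be >= 1")
        if self.r_tol <= 0 or self.a_tol <= 0:
            raise ValueError("r_tol and a_tol must be positive")
        if not (0 <= self.vanish_fraction < 1):
            raise ValueError("vanish_fraction must lie in [0, 1)")
        if self.norm not in _NORMS:
            raise ValueError(f"norm must be one of {sorted(_NORMS)}")


@dataclass(frozen=True)
class Trajectory:
    """Delay-embedded state vectors with their (m, τ) parameters."""

    points: np.ndarray  # shape (n_points, m)
    m: int
    tau: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != self.m:
            raise ValueError("points must be an (n, m) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trajectory coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.shape[0])


def delay_embed(series: Union[Series, Sequence[float]], m: int, tau: int) -> Trajectory:
    """Embed a scalar series into m-dimensional delay vectors.

    Point i has coordinates (x_i, x_{i+τ}, ..., x_{i+(m-1)τ}); the number
    of points is N − (m−1)·τ.
    """
    series = as_series(series)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be positive integers")
    n = len(series) - (m - 1) * tau
    if n < 1:
        raise SeriesTooShortError(
            f"series of length {len(series)} too short to embed at m={m}, tau={tau}; "
            f"at least {(m - 1) * tau + 1} points required"
        )
    x = series.values
    pts = np.empty((n, m), dtype=float)
    for j in range(m):
        pts[:, j] = x[j * tau : j * tau + n]
    return Trajectory(points=pts, m=m, tau=tau)


def _fnn_fraction_values(x: np.ndarray, m: int, cfg: EmbeddingConfig) -> float:
    tau = cfg.tau
    n_test = x.size - m * tau  # points embeddable at dimension m+1
    if n_test < 2:
        raise SeriesTooShortError(
            f"series of length {x.size} too short for FNN at m={m}, tau={tau}; "
            f"at least {m * tau + 2} points required"
        )
    sigma = float(np.std(x))
    if sigma == 0.0:
        raise DegenerateSeriesError("constant series: attractor size is zero")

    # m-dimensional embedding restricted to points that extend to m+1
    pts = np.empty((n_test, m), dtype=float)
    for j in range(m):
        pts[:, j] = x[j * tau : j * tau + n_test]
    dists = cdist(pts, pts, metric=_NORMS[cfg.norm])
    np.fill_diagonal(dists, np.inf)
    dists[dists <= DUPLICATE_RTOL * sigma] = np.inf  # duplicate states excluded
    nn = np.argmin(dists, axis=1)  # argmin takes the smallest index on ties
    r_m = dists[np.arange(n_test), nn]
    testable = np.isfinite(r_m)  # points with at least one non-duplicate candidate
    if not np.any(testable):
        raise DegenerateSeriesError(
            "every candidate neighbour is a duplicate state; FNN undefined"
        )
    nn_t = nn[testable]
    r_m = r_m[testable]

    extra = np.abs(x[m * tau : m * tau + n_test][testable] - x[nn_t + m * tau])
    if cfg.norm == "euclidean":
        r_m1 = np.sqrt(r_m**2 + extra**2)
    else:
        r_m1 = np.maximum(r_m, extra)

    false = (extra / r_m > cfg.r_tol) | (r_m1 / sigma > cfg.a_tol)
    return float(np.count_nonzero(false)) / float(np.count_nonzero(testable))


def fnn_fraction(series: Union[Series, Sequence[float]], m: int, cfg: EmbeddingConfig) -> float:
    """Fraction of points whose nearest neighbour at dimension m is false.

    A neighbour is false when either the distance gained by the extra
    coordinate exceeds ``r_tol`` times the m-dimensional distance, or the
    (m+1)-dimensional distance exceeds ``a_tol`` signal standard
    deviations.  Nearest neighbours are taken over the points that extend
    to dimension m+1, with ties broken toward the smallest index and
    self-matches excluded.  Deterministic for fixed input.
    """
    series = as_series(series)
    if m < 1:
        raise ValueError("m must be a positive integer")
    return _fnn_fraction_values(series.values, m, cfg)


@dataclass(frozen=True)
class FnnResult:
    """Outcome of the optimal-embedding-dimension scan."""

    m_star: int
    fractions: list[float]
    converged: bool

    def __iter__(self):
        return iter((self.m_star, self.fractions, self.converged))


def optimal_embedding_dimension(
    series: Union[Series, Sequence[float]], cfg: EmbeddingConfig
) -> FnnResult:
    """Smallest embedding dimension at which false neighbours vanish.

    Scans m = 1..max_m (stopping at the largest m the series length
    allows) and returns the first m whose FNN fraction is at or below
    ``cfg.vanish_fraction``.  If no trial dimension qualifies, the argmin
    of the evaluated fractions is returned with ``converged=False`` —
    the signature of stochastic signals without a finite-dimensional
    attractor.
    """
    series = as_series(series)
    x = series.values
    fractions: list[float] = []
    for m in range(1, cfg.max_m + 1):
        if x.size - m * cfg.tau < 2:
            break  # largest feasible m reached
        fractions.append(_fnn_fraction_values(x, m, cfg))
        if fractions[-1] <= cfg.vanish_fraction:
            return FnnResult(m_star=m, fractions=fractions, converged=True)
    if not fractions:
        raise SeriesTooShortError(
            f"series of length {x.size} too short for any FNN evaluation at tau={cfg.tau}"
        )
    m_star = int(np.argmin(fractions)) + 1
    return FnnResult(m_star=m_star, fractions=fractions, converged=False)


def suggest_delay(series: Union[Series, Sequence[float]], max_lag: int | None = None) -> int:
    """Suggest a delay as the first local minimum of the autocorrelation.

    Falls back to the first zero crossing, and to 1 when neither exists
    within ``max_lag``.  The pipeline default remains τ = 1; this helper
    is advisory only.
    """
    series = as_series(series)
    x = series.values - series.values.mean()
    n = x.size
    if max_lag is None:
        max_lag = min(n - 2, 200)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise DegenerateSeriesError("constant series has no autocorrelation structure")
    acf = np.array([np.dot(x[: n - k], x[k:]) / denom for k in range(max_lag + 1)])
    for k in range(1, max_lag):
        if acf[k] < acf[k - 1] and acf[k] <= acf[k + 1]:
            return k
    crossings = np.nonzero(acf[1:] < 0)[0]
    if crossings.size:
        return int(crossings[0]) + 1
    return 1
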