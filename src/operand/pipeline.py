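"""The transition indicator itself: per-window dimension estimates over
pre-onset (A) and reference (B) windows, compared by rank-sum test.

For every window the pipeline estimates

* ``m_star`` — the optimal embedding dimension by false nearest
  neighbours, restricted to the window;
* ``d_t_fixed`` — the recurrence-network transitivity dimension under a
  fixed embedding dimension (the naive analysis, which *under*-embeds
  pre-transition dynamics and therefore reads low there);
* ``d_t_dynamic`` — the transitivity dimension under that window's own
  optimal embedding, which moves in the same direction as ``m_star``.

Medians of the two sets are compared with the two-sided Wilcoxon
rank-sum (Mann–Whitney) test; exact permutation enumeration is used for
small samples, the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .embedding import EmbeddingConfig, optimal_embedding_dimension
from .errors import (
    DegenerateSeriesError,
    OperandError,
    SeriesTooShortError,
    TransitivityDomainError,
    UndefinedTransitivityError,
)
from .recurrence import RecurrenceConfig, window_transitivity_dimension
from .series import Series, as_series
from .transitions import TransitionSet, WindowPartition, detect_transitions, partition_windows

__all__ = [
    "WindowDimensionRecord",
    "SetComparison",
    "OperandReport",
    "compare_sets",
    "analyze",
]

logger = logging.getLogger(__name__)

#: pooled-sample sizes up to which the rank-sum test is enumerated exactly
_EXACT_ENUMERATION_LIMIT = 200_000


@dataclass(frozen=True)
class WindowDimensionRecord:
    """Dimension estimates for one window."""

    window: tuple[int, int]
    set_label: str  # "A" or "B"
    m_star: Optional[int]
    converged: Optional[bool]
    d_t_fixed: Optional[float]
    d_t_dynamic: Optional[float]


@dataclass(frozen=True)
class SetComparison:
    """Median-vs-median rank-sum comparison of one measure."""

    median_A: Optional[float]
    median_B: Optional[float]
    p_value: Optional[float]
    computable: bool

    @property
    def a_greater(self) -> Optional[bool]:
        if not self.computable:
            return None
        return self.median_A > self.median_B

    @property
    def a_smaller(self) -> Optional[bool]:
        if not self.computable:
            return None
        return self.median_A < self.median_B


@dataclass(frozen=True)
class OperandReport:
    """Full outcome of one indicator run."""

    records: tuple[WindowDimensionRecord, ...]
    embedding_dimension: SetComparison
    dt_fixed: SetComparison
    dt_dynamic: SetComparison
    onsets: tuple[int, ...]
    theta: float
    w: int
    step: int
    fixed_m: int

    @property
    def direction_flags(self) -> dict[str, Optional[bool]]:
        """The indicator's expected pattern ahead of transitions:
        embedding dimension up, fixed-embedding D_T down, dynamic D_T up."""
        return {
            "m_star_higher_before_onset": self.embedding_dimension.a_greater,
            "dt_fixed_lower_before_onset": self.dt_fixed.a_smaller,
            "dt_dynamic_higher_before_onset": self.dt_dynamic.a_greater,
        }

    def to_dict(self) -> dict:
        def cmp_dict(c: SetComparison) -> dict:
            return {
                "median_A": c.median_A,
                "median_B": c.median_B,
                "p_value": c.p_value,
                "computable": c.computable,
            }

        return {
            "onsets": list(self.onsets),
            "theta": self.theta,
            "w": self.w,
            "step": self.step,
            "fixed_m": self.fixed_m,
            "embedding_dimension": cmp_dict(self.embedding_dimension),
            "dt_fixed": cmp_dict(self.dt_fixed),
            "dt_dynamic": cmp_dict(self.dt_dynamic),
            "direction_flags": self.direction_flags,
            "records": [asdict(r) for r in self.records],
        }


def _exact_ranksum_p(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided rank-sum p by exhaustive enumeration over group
    assignments, using midranks so ties are handled exactly."""
    pooled = np.concatenate([np.asarray(values_a, float), np.asarray(values_b, float)])
    ranks = stats.rankdata(pooled)  # midranks
    n_a = len(values_a)
    n = len(pooled)
    observed = float(ranks[:n_a].sum())
    mean_w = ranks.sum() * n_a / n
    obs_dev = abs(observed - mean_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        w = float(ranks[list(combo)].sum())
        if abs(w - mean_w) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return count / total


def compare_sets(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Medians of both groups and the two-sided Wilcoxon rank-sum p-value.

    Small samples (pooled enumeration up to ~2·10⁵ assignments) use exact
    permutation enumeration with midranks; larger samples fall back to
    the tie-corrected normal approximation of the Mann–Whitney test.
    Returns ``(median_A, median_B, None)`` markers when a group is empty.
    """
    a = [float(v) for v in values_a if v is not None and np.isfinite(v)]
    b = [float(v) for v in values_b if v is not None and np.isfinite(v)]
    med_a = float(np.median(a)) if a else None
    med_b = float(np.median(b)) if b else None
    if not a or not b:
        return med_a, med_b, None
    if math.comb(len(a) + len(b), len(a)) <= _EXACT_ENUMERATION_LIMIT:
        p = _exact_ranksum_p(a, b)
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return med_a, med_b, min(p, 1.0)


def _comparison(values_a: Sequence[Optional[float]], values_b: Sequence[Optional[float]]) -> SetComparison:
    med_a, med_b, p = compare_sets(
        [v for v in values_a if v is not None], [v for v in values_b if v is not None]
    )
    return SetComparison(median_A=med_a, median_B=med_b, p_value=p, computable=p is not None)


def analyze(
    series: Union[Series, Sequence[float]],
    theta: float,
    embedding_cfg: EmbeddingConfig | None = None,
    recurrence_cfg: RecurrenceConfig | None = None,
    w: int = 100,
    step: int = 20,
    fixed_m: int = 5,
    min_separation: int = 1,
    strict_convergence: bool = False,
    transitions: TransitionSet | None = None,
) -> OperandReport:
    """Run the full indicator on a scalar series.

    Detects onsets at threshold ``theta`` (or uses ``transitions`` when
    supplied), partitions windows into pre-onset set A and reference set
    B, estimates per-window dimensions, and compares the sets.

    ``strict_convergence=True`` drops windows whose FNN scan did not
    converge; the default keeps their argmin dimension (flagged), since
    dropping predominantly pre-onset windows would bias the comparison.
    Degenerate windows (constant, or with undefined transitivity) yield
    missing values and are excluded pairwise from each test.
    """
    series = as_series(series)
    embedding_cfg = embedding_cfg or EmbeddingConfig()
    recurrence_cfg = recurrence_cfg or RecurrenceConfig()
    if len(series) < 3 * w:
        raise SeriesTooShortError(
            f"series of length {len(series)} too short for windowed analysis: "
            f"at least 3*w = {3 * w} points required"
        )
    if fixed_m < 1:
        raise ValueError("fixed_m must be a positive integer")

    if transitions is None:
        transitions = detect_transitions(series, theta, min_separation=min_separation)
    partition = partition_windows(len(series), transitions, w=w, step=step)

    records: list[WindowDimensionRecord] = []
    for label, windows in (("A", partition.set_A), ("B", partition.set_B)):
        for start, end in windows:
            window = series.values[start:end]
            m_star: Optional[int] = None
            converged: Optional[bool] = None
            try:
                res = optimal_embedding_dimension(Series(window), embedding_cfg)
                if res.converged or not strict_convergence:
                    m_star, converged = res.m_star, res.converged
            except (DegenerateSeriesError, SeriesTooShortError) as exc:
                logger.warning("window [%d, %d): FNN not computable (%s)", start, end, exc)

            def _dt(m: int) -> Optional[float]:
                try:
                    return window_transitivity_dimension(
                        window, m=m, tau=embedding_cfg.tau, cfg=recurrence_cfg
                    )
                except (
                    DegenerateSeriesError,
                    SeriesTooShortError,
                    UndefinedTransitivityError,
                    TransitivityDomainError,
                ) as exc:
                    logger.warning("window [%d, %d): D_T at m=%d missing (%s)", start, end, m, exc)
                    return None

            records.append(
                WindowDimensionRecord(
                    window=(start, end),
                    set_label=label,
                    m_star=m_star,
                    converged=converged,
                    d_t_fixed=_dt(fixed_m),
                    d_t_dynamic=_dt(m_star) if m_star is not None else None,
                )
            )

    def values(label: str, attr: str) -> list[Optional[float]]:
        return [getattr(r, attr) for r in records if r.set_label == label]

    report = OperandReport(
        records=tuple(records),
        embedding_dimension=_comparison(values("A", "m_star"), values("B", "m_star")),
        dt_fixed=_comparison(values("A", "d_t_fixed"), values("B", "d_t_fixed")),
        dt_dynamic=_comparison(values("A", "d_t_dynamic"), values("B", "d_t_dynamic")),
        onsets=tuple(transitions.onsets),
        theta=transitions.threshold,
        w=w,
        step=step,
        fixed_m=fixed_m,
    )
    return report
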