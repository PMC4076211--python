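"""Transition-onset detection and pre-onset / reference window bookkeeping.

An onset is a time index where the first difference of the signal exceeds
a threshold θ.  For each onset t the window [t−w, t) immediately before
it joins set A; reference set B tiles the remainder of the series with
sliding windows of the same length, after excluding a zone of width 2w
centred on every onset so that no reference window touches transition
dynamics.  All intervals are half-open and 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .series import Series, as_series

__all__ = [
    "TransitionSet",
    "WindowPartition",
    "detect_transitions",
    "theta_from_quantile",
    "partition_windows",
    "write_onsets",
    "write_partition",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransitionSet:
    """Detected onsets (strictly increasing indices) and the threshold used."""

    onsets: tuple[int, ...]
    threshold: float

    def __post_init__(self) -> None:
        on = tuple(int(t) for t in self.onsets)
        if any(b <= a for a, b in zip(on, on[1:])):
            raise ValueError("onsets must be strictly increasing")
        if any(t < 1 for t in on):
            raise ValueError("onsets must be >= 1 (a first difference needs a predecessor)")
        object.__setattr__(self, "onsets", on)

    def __len__(self) -> int:
        return len(self.onsets)

    def __iter__(self):
        return iter(self.onsets)


@dataclass(frozen=True)
class WindowPartition:
    """Pre-onset windows (set A) and reference windows (set B)."""

    set_A: tuple[tuple[int, int], ...]
    set_B: tuple[tuple[int, int], ...]
    w: int
    step: int

    def __post_init__(self) -> None:
        for s, e in (*self.set_A, *self.set_B):
            if e - s != self.w:
                raise ValueError(f"window [{s}, {e}) does not have length w={self.w}")


def detect_transitions(
    series: Union[Series, Sequence[float]],
    theta: float,
    min_separation: int = 1,
    signed: bool = False,
) -> TransitionSet:
    """Indices t ≥ 1 where the first difference exceeds θ.

    By default the absolute difference |x_t − x_{t−1}| is compared against
    θ; ``signed=True`` keeps only positive jumps x_t − x_{t−1} > θ.
    ``min_separation`` > 1 thins bursts of consecutive crossings, keeping
    the earliest of each burst; the default keeps every crossing.
    """
    series = as_series(series)
    if theta <= 0:
        raise ValueError("theta must be positive")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    if len(series) < 2:
        raise ValueError("series must contain at least 2 points")
    diffs = np.diff(series.values)
    crossings = diffs > theta if signed else np.abs(diffs) > theta
    candidates = (np.nonzero(crossings)[0] + 1).tolist()
    onsets: list[int] = []
    for t in candidates:
        if not onsets or t - onsets[-1] >= min_separation:
            onsets.append(t)
    return TransitionSet(onsets=tuple(onsets), threshold=float(theta))


def theta_from_quantile(series: Union[Series, Sequence[float]], q: float = 0.99) -> float:
    """Data-driven threshold: the q-th quantile of |Δx|."""
    series = as_series(series)
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie strictly in (0, 1)")
    return float(np.quantile(np.abs(np.diff(series.values)), q))


def _tile(start: int, end: int, w: int, step: int) -> list[tuple[int, int]]:
    """Sliding windows of length w inside [start, end), stride ``step``,
    plus the flush-right window when the stride does not land on it."""
    if end - start < w:
        return []
    starts = list(range(start, end - w + 1, step))
    if starts[-1] != end - w:
        starts.append(end - w)
    return [(s, s + w) for s in starts]


def partition_windows(
    series_length: int,
    transitions: TransitionSet,
    w: int = 100,
    step: int = 20,
) -> WindowPartition:
    """Build pre-onset (A) and reference (B) window sets.

    A holds one window [t−w, t) per onset t with at least w preceding
    points (earlier onsets are skipped with a warning).  B tiles the
    complement of the exclusion zones [t−w, t+w) — width twice the window
    length, the onset in the middle — with stride ``step``, keeping only
    windows that fit entirely inside the complement.
    """
    if w < 2:
        raise ValueError("window length w must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if series_length < w:
        raise ValueError(
            f"series length {series_length} is shorter than the window length w={w}"
        )

    set_a: list[tuple[int, int]] = []
    exclusions: list[tuple[int, int]] = []
    for t in transitions:
        if t >= w:
            set_a.append((t - w, t))
        else:
            logger.warning(
                "onset at index %d has fewer than w=%d preceding points; "
                "skipped from set A (exclusion zone still applied)",
                t,
                w,
            )
        exclusions.append((max(0, t - w), min(series_length, t + w)))

    # maximal free intervals = complement of the union of exclusion zones
    set_b: list[tuple[int, int]] = []
    cursor = 0
    for ex_start, ex_end in sorted(exclusions):
        if ex_start > cursor:
            set_b.extend(_tile(cursor, ex_start, w, step))
        cursor = max(cursor, ex_end)
    if cursor < series_length:
        set_b.extend(_tile(cursor, series_length, w, step))

    part = WindowPartition(set_A=tuple(set_a), set_B=tuple(set_b), w=w, step=step)
    _assert_no_leakage(part, transitions)
    return part


def _assert_no_leakage(part: WindowPartition, transitions: TransitionSet) -> None:
    """Invariant: no reference window index lies within w of any onset."""
    for s, e in part.set_B:
        for t in transitions:
            if s < t + part.w and e > t - part.w:
                raise AssertionError(
                    f"reference window [{s}, {e}) leaks into the exclusion "
                    f"zone of the onset at {t}"
                )


def write_onsets(transitions: TransitionSet, path: Union[str, Path]) -> None:
    """One onset index per line."""
    Path(path).write_text("".join(f"{t}\n" for t in transitions), encoding="utf-8")


def write_partition(part: WindowPartition, path: Union[str, Path]) -> None:
    """TSV export: set label, start, end (half-open, 0-based)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("set\tstart\tend\n")
        for s, e in part.set_A:
            fh.write(f"A\t{s}\t{e}\n")
        for s, e in part.set_B:
            fh.write(f"B\t{s}\t{e}\n")
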