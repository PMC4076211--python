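"""Scalar time-series container and plain-text / CSV readers and writers.

The universal input of the pipeline is a uniformly sampled scalar signal
x(t).  Values are dimensionless; ``sampling_step`` carries the sampling
interval when the index is not the natural time unit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .errors import SeriesTooShortError

PathLike = Union[str, Path]


@dataclass(frozen=True)
class Series:
    """Uniformly indexed scalar observations.

    Parameters
    ----------
    values
        Ordered real observations.  All entries must be finite.
    sampling_step
        Positive sampling interval; defaults to one index unit.
    """

    values: np.ndarray
    sampling_step: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("Series values must be one-dimensional")
        if arr.size < 1:
            raise SeriesTooShortError("Series must contain at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Series values must all be finite")
        if self.sampling_step <= 0:
            raise ValueError("sampling_step must be positive")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, idx):
        return self.values[idx]

    @property
    def std(self) -> float:
        return float(np.std(self.values))


def as_series(data: Union[Series, Iterable[float], np.ndarray]) -> Series:
    """Coerce raw values into a :class:`Series` (no-op when already one)."""
    if isinstance(data, Series):
        return data
    return Series(np.asarray(list(data) if not isinstance(data, np.ndarray) else data, dtype=float))


def read_series(path: PathLike) -> Series:
    """Read a series from plain text (one number per line) or a
    single-column CSV with an optional header row."""
    path = Path(path)
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        rows = [line.strip() for line in fh if line.strip()]
    for i, row in enumerate(rows):
        cell = row.split(",")[0].strip()
        try:
            values.append(float(cell))
        except ValueError:
            if i == 0:  # header row of a CSV
                continue
            raise ValueError(f"{path}: cannot parse line {i + 1}: {row!r}") from None
    return Series(np.asarray(values, dtype=float))


def write_series(series: Series, path: PathLike, header: str | None = None) -> None:
    """Write one value per line; an optional header turns the file into a
    single-column CSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        if header is not None:
            writer.writerow([header])
        for v in series.values:
            writer.writerow([repr(float(v))])
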