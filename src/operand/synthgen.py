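"""Seeded synthetic generators for validating the transition indicator.

Three families of fixtures, each a pure function of its arguments and a
seed:

* step series — piecewise-constant levels with planted jumps, exercising
  the first-difference onset detector;
* dimension-shift series — a reference signal (white noise by default)
  into which segments whose effective embedding dimension is higher
  (strongly correlated AR(1) by default) are spliced immediately before
  each planted onset, emulating the hypothesis that the dimensionality
  of the context rises ahead of a transition;
* toy corpus — sentences in which planted words co-occur exclusively
  with positive or negative paradigm words, so their semantic
  orientation sign is knowable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SpecError
from .series import Series

__all__ = [
    "BenchmarkSpec",
    "lorenz_x",
    "henon_x",
    "noisy_sine",
    "ar1",
    "make_step_series",
    "make_dimension_shift_series",
    "make_toy_corpus",
]

_SOURCES = ("lorenz_x", "henon_x", "noisy_sine", "ar1")


def lorenz_x(
    n: int,
    seed: int = 0,
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    dt: float = 0.01,
    subsample: int = 5,
    transient: int = 5000,
) -> np.ndarray:
    """x-coordinate of the Lorenz system, standardized to zero mean and
    unit variance.

    Fixed-step RK4 at ``dt``, with ``transient`` integration steps
    discarded and the orbit subsampled every ``subsample`` steps.  The
    seed jitters the initial condition, so different seeds give
    different stretches of the attractor.
    """
    rng = np.random.default_rng(seed)
    state = np.array([1.0, 1.0, 20.0]) + rng.normal(scale=0.5, size=3)

    def deriv(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    total = transient + n * subsample
    out = np.empty(n)
    k_out = 0
    for step in range(total):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if step >= transient and (step - transient) % subsample == 0 and k_out < n:
            out[k_out] = state[0]
            k_out += 1
    out -= out.mean()
    sd = out.std()
    if sd > 0:
        out /= sd
    return out


def henon_x(n: int, seed: int = 0, a: float = 1.4, b: float = 0.3, transient: int = 1000) -> np.ndarray:
    """x-coordinate of the Hénon map, standardized; seed jitters x0."""
    rng = np.random.default_rng(seed)
    x, y = 0.1 + rng.uniform(-0.05, 0.05), 0.1
    out = np.empty(n)
    for i in range(transient + n):
        x, y = 1.0 - a * x * x + y, b * x
        if i >= transient:
            out[i - transient] = x
    out -= out.mean()
    sd = out.std()
    if sd > 0:
        out /= sd
    return out


def noisy_sine(n: int, seed: int = 0, period: float = 25.0, noise_sd: float = 0.0) -> np.ndarray:
    """Unit-variance sine (random phase) plus i.i.d. Gaussian noise."""
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    clean = np.sqrt(2.0) * np.sin(2.0 * np.pi * np.arange(n) / period + phase)
    return clean + rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else clean


def ar1(n: int, seed: int = 0, phi: float = 0.8, noise_sd: float = 1.0) -> np.ndarray:
    """Stationary AR(1) process, standardized innovations scale."""
    rng = np.random.default_rng(seed)
    eps = rng.normal(scale=noise_sd, size=n + 200)
    x = np.empty(n + 200)
    x[0] = eps[0] / np.sqrt(1 - phi**2)
    for i in range(1, n + 200):
        x[i] = phi * x[i - 1] + eps[i]
    out = x[200:]
    return (out - out.mean()) / out.std()


def _draw_source(
    name: str, n: int, seed: int, noise_sd: float, params: dict | None = None
) -> np.ndarray:
    params = dict(params or {})
    if name == "lorenz_x":
        return lorenz_x(n, seed=seed, **params)
    if name == "henon_x":
        return henon_x(n, seed=seed, **params)
    if name == "noisy_sine":
        params.setdefault("noise_sd", noise_sd)
        return noisy_sine(n, seed=seed, **params)
    if name == "ar1":
        return ar1(n, seed=seed, **params)
    raise SpecError(f"unknown source {name!r}; choose from {_SOURCES}")


@dataclass(frozen=True)
class BenchmarkSpec:
    """Layout of the dimension-shift benchmark.

    Default: a 16400-point white-noise backbone (AR(1) with φ = 0, an
    idealized stand-in for a word-polarity stream) carrying 40 planted
    onsets spaced 400 points apart.  The 100 points before each onset
    are replaced by a strongly correlated AR(1) segment (φ = 0.8): the
    context acquires memory the
    small fixed embedding cannot unfold, which is exactly the regime the
    indicator targets — the per-window optimal embedding dimension rises
    while the fixed-embedding transitivity dimension falls.  Each onset
    is marked by a level jump of 14 signal standard deviations, large
    enough that a threshold of half the jump recovers exactly the
    planted onsets.

    Chaotic sources (``lorenz_x``, ``henon_x``) and the noisy sine
    remain available via ``pre_onset_source`` / ``reference_source``
    with per-source ``*_params``.
    """

    length: int = 16400
    onset_times: tuple[int, ...] = tuple(range(400, 16001, 400))
    pre_onset_source: str = "ar1"
    reference_source: str = "ar1"
    pre_onset_params: tuple[tuple[str, float], ...] = (("phi", 0.8),)
    reference_params: tuple[tuple[str, float], ...] = (("phi", 0.0),)
    jump_size: float = 14.0
    noise_sd: float = 0.05
    seed: int = 0
    pre_window: int = 100

    def __post_init__(self) -> None:
        onsets = tuple(int(t) for t in self.onset_times)
        object.__setattr__(self, "onset_times", onsets)
        w = self.pre_window
        if self.jump_size <= 0:
            raise SpecError("jump_size must be positive")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise SpecError("onsets must be strictly increasing")
        if onsets and onsets[0] < w:
            raise SpecError(f"first onset must be at least pre_window={w} from the start")
        if any(b - a < 2 * w for a, b in zip(onsets, onsets[1:])):
            raise SpecError("onsets closer than twice the pre-onset window overlap segments")
        if onsets and onsets[-1] >= self.length:
            raise SpecError("onsets must lie inside the series")
        for name in (self.pre_onset_source, self.reference_source):
            if name not in _SOURCES:
                raise SpecError(f"unknown source {name!r}; choose from {_SOURCES}")


def make_step_series(
    length: int,
    onsets: Sequence[int],
    jump_size: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Series:
    """Piecewise-constant series with level jumps of |jump_size| at the
    given onsets (alternating sign, to stay bounded) plus Gaussian noise."""
    onsets = sorted(int(t) for t in onsets)
    if onsets and (onsets[0] < 1 or onsets[-1] >= length):
        raise SpecError("onsets must lie in [1, length)")
    rng = np.random.default_rng(seed)
    x = np.zeros(length)
    level, sign = 0.0, 1.0
    prev = 0
    for t in onsets:
        x[prev:t] = level
        level += sign * abs(jump_size)
        sign = -sign
        prev = t
    x[prev:] = level
    if noise_sd > 0:
        x += rng.normal(scale=noise_sd, size=length)
    return Series(x)


def make_dimension_shift_series(spec: BenchmarkSpec) -> tuple[Series, tuple[int, ...]]:
    """Series whose generating dynamics change dimensionality before each
    planted onset.

    The backbone is the (low-dimensional) reference source.  The
    ``pre_window`` points before each onset are replaced by a fresh
    segment of the (higher-dimensional) pre-onset source; both sources
    are standardized so the splice stays below the detection threshold.
    A level jump of ``jump_size`` (alternating sign) is added at each
    onset, so ``detect_transitions`` at θ = jump_size/2 recovers exactly
    the planted onsets.
    """
    w = spec.pre_window
    base = _draw_source(
        spec.reference_source, spec.length, spec.seed, spec.noise_sd, dict(spec.reference_params)
    )
    x = base.copy()
    for k, t in enumerate(spec.onset_times):
        seg = _draw_source(
            spec.pre_onset_source,
            w,
            (spec.seed * 100003 + 7 * k + 1) % 2_147_483_647,
            spec.noise_sd,
            dict(spec.pre_onset_params),
        )
        x[t - w : t] = seg
    # piecewise-constant offsets realize the jumps
    level, sign = 0.0, 1.0
    offsets = np.zeros(spec.length)
    prev = 0
    for t in spec.onset_times:
        offsets[prev:t] = level
        level += sign * spec.jump_size
        sign = -sign
        prev = t
    offsets[prev:] = level
    return Series(x + offsets), spec.onset_times


# --------------------------------------------------------------------------
# toy corpus for the semantic-orientation front end


def make_toy_corpus(
    n_pos_words: int,
    n_neg_words: int,
    docs: int,
    seed: int = 0,
):
    """Corpus whose planted words co-occur only with paradigm words of
    their own polarity class.

    Returns ``(corpus_text, model, paradigms, labels)`` where ``labels``
    maps each planted word to +1 or −1.  Every sentence contains one
    planted word flanked by two paradigm words of the same class, so with
    a context window of ±2 the planted word's context vector is supported
    exclusively on its own class — its semantic orientation has the
    correct sign by construction.
    """
    from .sentiment import ParadigmSets, build_cooccurrence_model

    if n_pos_words < 1 or n_neg_words < 1:
        raise SpecError("need at least one planted word per class")
    if docs < 1:
        raise SpecError("docs must be >= 1")
    rng = np.random.default_rng(seed)
    paradigms = ParadigmSets.default()
    # alphabetic suffixes: the tokenizer drops digits, so planted words
    # must survive tokenization and lemmatization unchanged
    alphabet = "abcdefghijklmnopqrtuvwxz"  # no "s": plural stripping would alter the lemma
    def _name(stem: str, i: int) -> str:
        suffix = ""
        i += 1
        while i:
            i, r = divmod(i - 1, len(alphabet))
            suffix = alphabet[r] + suffix
        return stem + suffix

    pos_words = [_name("brightlem", i) for i in range(n_pos_words)]
    neg_words = [_name("gloomlem", i) for i in range(n_neg_words)]
    labels = {w: 1 for w in pos_words}
    labels.update({w: -1 for w in neg_words})

    pos_par = sorted(paradigms.positives)
    neg_par = sorted(paradigms.negatives)
    sentences: list[str] = []
    for _ in range(docs):
        for w in pos_words:
            p1, p2 = rng.choice(pos_par, size=2, replace=False)
            sentences.append(f"{p1} {w} {p2}")
        for w in neg_words:
            p1, p2 = rng.choice(neg_par, size=2, replace=False)
            sentences.append(f"{p1} {w} {p2}")
    rng.shuffle(sentences)
    corpus = ". ".join(sentences) + "."
    # count within sentences so polarity classes never share contexts
    model = build_cooccurrence_model([s.split() for s in sentences], window=2)
    return corpus, model, paradigms, labels
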