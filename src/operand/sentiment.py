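"""Text → emotional-polarity time series via semantic orientation.

Content words (nouns, verbs, adjectives, adverbs) are extracted,
lemmatized, and scored against a word–context co-occurrence model: the
*semantic orientation* of a word w is

    SO(w) = cos(v_w, Σ_{p∈P} v_p) − cos(v_w, Σ_{n∈N} v_n)

where v_w is w's row of joint word–context probabilities and P / N are
small paradigm sets of unambiguously positive / negative words.  The
scores, taken in text order, form the scalar series the transition
indicator consumes.

Part-of-speech tagging and lemmatization are pluggable; the bundled
defaults are deliberately simple rule-based components (closed-class
stop list + suffix heuristics, inflection stripping with a small
irregular table) that need no external resources.  Any callable with the
same signature — e.g. a wrapper around a statistical tagger — can be
passed instead.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence, Union

import numpy as np

from .errors import OutOfVocabularyError
from .series import Series

__all__ = [
    "CooccurrenceModel",
    "ParadigmSets",
    "Token",
    "ScoredText",
    "RuleBasedTagger",
    "RuleBasedLemmatizer",
    "filter_and_lemmatize",
    "build_cooccurrence_model",
    "semantic_distance",
    "semantic_orientation",
    "text_to_series",
    "score_text",
]

logger = logging.getLogger(__name__)

CONTENT_TAGS = ("noun", "verb", "adj", "adv")


# --------------------------------------------------------------------------
# tokens, tagging, lemmatization


@dataclass(frozen=True)
class Token:
    surface: str
    pos_tag: str
    lemma: str
    so_score: float | None = None


@dataclass(frozen=True)
class ScoredText:
    """Retained content tokens, in text order, with their scores."""

    tokens: tuple[Token, ...]
    oov_count: int = 0

    def __len__(self) -> int:
        return len(self.tokens)


_WORD_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?")

# closed-class words: determiners, pronouns, prepositions, conjunctions,
# auxiliaries and modals — everything outside the four content categories
_STOPWORDS = frozenset(
    """
    a an the this that these those some any each every no
    i you he she it we they me him her us them my your his its our their
    mine yours hers ours theirs myself yourself himself herself itself
    ourselves themselves who whom whose which what
    in on at by for with about against between into through during before
    after above below to from up down out off over under again behind
    near beside among along across around of
    and or but nor so yet if because although though while when where
    whether than as until unless since
    be am is are was were been being
    have has had having do does did doing
    will would shall should may might must can could
    not there here then once
    """.split()
)

# suffix → part of speech, tried in order (longest patterns first)
_SUFFIX_TAGS = (
    ("ly", "adv"),
    ("ing", "verb"),
    ("ed", "verb"),
    ("ous", "adj"),
    ("ful", "adj"),
    ("ive", "adj"),
    ("ent", "adj"),
    ("ant", "adj"),
    ("able", "adj"),
    ("ible", "adj"),
    ("al", "adj"),
    ("y", "adj"),
)

# irregular inflections needed for everyday prose; extend via the
# lemmatizer's ``extra_irregulars`` argument
_IRREGULAR_LEMMAS = {
    "heard": "hear",
    "said": "say",
    "saw": "see",
    "made": "make",
    "felt": "feel",
    "knew": "know",
    "thought": "think",
    "took": "take",
    "came": "come",
    "went": "go",
    "got": "get",
    "gave": "give",
    "found": "find",
    "told": "tell",
    "left": "leave",
    "ran": "run",
    "held": "hold",
    "kept": "keep",
    "stood": "stand",
    "brought": "bring",
    "began": "begin",
    "children": "child",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
}

# words the -s stripping rule must not touch
_S_FINAL_GUARD = ("ss", "us", "is", "ous")

_VOWELS = set("aeiou")

# verbs tagged irregular (no telltale suffix); minimal everyday set
_IRREGULAR_VERBS = frozenset(
    "heard said saw made felt knew thought took came went got gave found "
    "told left ran held kept stood brought began hear say see make feel "
    "know think take come go get give find tell leave run hold keep stand "
    "bring begin".split()
)


class RuleBasedTagger:
    """Heuristic tagger: closed-class stop list plus suffix rules.

    Returns one of ``noun``/``verb``/``adj``/``adv`` for content words
    and ``None`` for closed-class words — the caller drops those.  Words
    with no matching suffix default to ``noun``.
    """

    def __init__(self, extra_stopwords: Iterable[str] = ()) -> None:
        self.stopwords = _STOPWORDS | {w.lower() for w in extra_stopwords}

    def __call__(self, word: str) -> str | None:
        w = word.lower()
        if w in self.stopwords:
            return None
        if w in _IRREGULAR_VERBS:
            return "verb"
        for suffix, tag in _SUFFIX_TAGS:
            if w.endswith(suffix) and len(w) > len(suffix) + 1:
                return tag
        return "noun"


class RuleBasedLemmatizer:
    """Inflection-stripping lemmatizer with a small irregular table.

    Handles -ing / -ed (with final-consonant undoubling, e.g.
    travelled → travel) and plural -s / -ies.  Already-base forms pass
    through unchanged.  A heuristic, not a dictionary: rare stems may be
    clipped imperfectly, which only perturbs their vocabulary key, never
    the token count or order.
    """

    def __init__(self, extra_irregulars: dict[str, str] | None = None) -> None:
        self.irregulars = dict(_IRREGULAR_LEMMAS)
        if extra_irregulars:
            self.irregulars.update({k.lower(): v.lower() for k, v in extra_irregulars.items()})

    @staticmethod
    def _undouble(stem: str) -> str:
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]
        return stem

    @staticmethod
    def _restore_e(stem: str) -> str:
        # noticed → notic → notice; danced → danc → dance
        if stem.endswith(("ic", "nc", "rg", "dg", "v", "u")):
            return stem + "e"
        return stem

    def __call__(self, word: str) -> str:
        w = word.lower()
        if w in self.irregulars:
            return self.irregulars[w]
        if w.endswith("ing") and len(w) > 5:
            return self._restore_e(self._undouble(w[:-3]))
        if w.endswith("ied") and len(w) > 4:
            return w[:-3] + "y"
        if w.endswith("ed") and len(w) > 4:
            return self._restore_e(self._undouble(w[:-2]))
        if w.endswith("ies") and len(w) > 4:
            return w[:-3] + "y"
        if w.endswith("es") and len(w) > 4 and w[-3] in "sxz":
            return w[:-2]
        if w.endswith("s") and len(w) > 3 and not w.endswith(_S_FINAL_GUARD):
            return w[:-1]
        return w


def filter_and_lemmatize(
    text: str,
    tagger: Callable[[str], str | None] | None = None,
    lemmatizer: Callable[[str], str] | None = None,
) -> list[Token]:
    """Keep content words (nouns, verbs, adjectives, adverbs), lemmatize
    them, and preserve text order.

    Punctuation and closed-class words are removed.  If the tagger or
    lemmatizer raises on a token, the token is passed through with a
    warning rather than silently dropped.
    """
    if not text or not text.strip():
        raise ValueError("text must be non-empty")
    tagger = tagger or RuleBasedTagger()
    lemmatizer = lemmatizer or RuleBasedLemmatizer()
    tokens: list[Token] = []
    for match in _WORD_RE.finditer(text):
        surface = match.group(0)
        try:
            tag = tagger(surface)
        except Exception:  # noqa: BLE001 - pluggable component may misbehave
            logger.warning("tagger failed on %r; token passed through as noun", surface)
            tag = "noun"
        if tag not in CONTENT_TAGS:
            continue
        try:
            lemma = lemmatizer(surface)
        except Exception:  # noqa: BLE001
            logger.warning("lemmatizer failed on %r; surface form kept", surface)
            lemma = surface.lower()
        tokens.append(Token(surface=surface, pos_tag=tag, lemma=lemma))
    return tokens


# --------------------------------------------------------------------------
# co-occurrence model and semantic orientation


@dataclass(frozen=True)
class CooccurrenceModel:
    """Word × context matrix of joint probabilities.

    Row w holds the probabilities that word w appears near (before or
    after, within the builder's window) each context word.
    """

    row_words: tuple[str, ...]
    context_words: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (len(self.row_words), len(self.context_words)):
            raise ValueError("probs shape must be (n_row_words, n_context_words)")
        if np.any(probs < 0):
            raise ValueError("joint probabilities must be non-negative")
        if probs.sum() > 1.0 + 1e-9:
            raise ValueError("joint probabilities must total at most 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.row_words)})

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        """Context-probability row of ``word``; raises on OOV or zero row."""
        idx = self._index.get(word)
        if idx is None:
            raise OutOfVocabularyError(f"word {word!r} not in the model vocabulary")
        row = self.probs[idx]
        if not row.any():
            raise OutOfVocabularyError(f"word {word!r} has an all-zero context row")
        return row

    # ---- plain-text round trips ------------------------------------------

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Sparse triples: row word, context word, probability."""
        with Path(path).open("w", encoding="utf-8") as fh:
            for i, w in enumerate(self.row_words):
                for j, c in enumerate(self.context_words):
                    p = self.probs[i, j]
                    if p > 0:
                        fh.write(f"{w}\t{c}\t{float(p)!r}\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CooccurrenceModel":
        triples: list[tuple[str, str, float]] = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                w, c, p = line.split("\t")
                triples.append((w, c, float(p)))
        rows = tuple(sorted({w for w, _, _ in triples}))
        cols = tuple(sorted({c for _, c, _ in triples}))
        ri = {w: i for i, w in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        probs = np.zeros((len(rows), len(cols)))
        for w, c, p in triples:
            probs[ri[w], ci[c]] = p
        return cls(row_words=rows, context_words=cols, probs=probs)

    def to_dense_csv(self, path: Union[str, Path]) -> None:
        """Dense matrix with row/column headers."""
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["word", *self.context_words])
            for i, w in enumerate(self.row_words):
                writer.writerow([w, *[repr(float(p)) for p in self.probs[i]]])

    @classmethod
    def from_dense_csv(cls, path: Union[str, Path]) -> "CooccurrenceModel":
        with Path(path).open("r", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            cols = tuple(header[1:])
            rows, data = [], []
            for record in reader:
                rows.append(record[0])
                data.append([float(v) for v in record[1:]])
        return cls(row_words=tuple(rows), context_words=cols, probs=np.asarray(data))


def build_cooccurrence_model(
    tokens: Union[Sequence[str], Sequence[Sequence[str]]],
    window: int = 2,
) -> CooccurrenceModel:
    """Count co-occurrences within a symmetric ±``window`` context and
    normalize the counts to joint probabilities.

    Accepts a flat token sequence or a sequence of sentences (token
    lists); in the latter case contexts never cross sentence boundaries.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not tokens:
        raise ValueError("tokens must be non-empty")
    sentences: list[list[str]]
    if isinstance(tokens[0], str):
        sentences = [[t.lower() for t in tokens]]  # type: ignore[list-item]
    else:
        sentences = [[t.lower() for t in sent] for sent in tokens]  # type: ignore[union-attr]

    vocab = tuple(sorted({t for sent in sentences for t in sent}))
    index = {w: i for i, w in enumerate(vocab)}
    counts = np.zeros((len(vocab), len(vocab)))
    total = 0
    for sent in sentences:
        for i, w in enumerate(sent):
            lo = max(0, i - window)
            hi = min(len(sent), i + window + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                counts[index[w], index[sent[j]]] += 1
                total += 1
    if total == 0:
        raise ValueError("no co-occurrence pairs found (all sentences length 1?)")
    return CooccurrenceModel(row_words=vocab, context_words=vocab, probs=counts / total)


# paradigm anchors of the semantic-orientation scale: small sets of
# unambiguously positive / negative everyday words
_DEFAULT_POSITIVES = ("good", "nice", "excellent", "positive", "fortunate", "correct", "superior")
_DEFAULT_NEGATIVES = ("bad", "nasty", "poor", "negative", "unfortunate", "wrong", "inferior")


@dataclass(frozen=True)
class ParadigmSets:
    """Disjoint, non-empty positive and negative anchor word sets."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        pos = frozenset(w.lower() for w in self.positives)
        neg = frozenset(w.lower() for w in self.negatives)
        if not pos or not neg:
            raise ValueError("both paradigm sets must be non-empty")
        if pos & neg:
            raise ValueError(f"paradigm sets must be disjoint; shared: {sorted(pos & neg)}")
        object.__setattr__(self, "positives", pos)
        object.__setattr__(self, "negatives", neg)

    @classmethod
    def default(cls) -> "ParadigmSets":
        return cls(positives=frozenset(_DEFAULT_POSITIVES), negatives=frozenset(_DEFAULT_NEGATIVES))

    @classmethod
    def from_files(cls, pos_path: Union[str, Path], neg_path: Union[str, Path]) -> "ParadigmSets":
        read = lambda p: frozenset(
            w.strip().lower() for w in Path(p).read_text(encoding="utf-8").split() if w.strip()
        )
        return cls(positives=read(pos_path), negatives=read(neg_path))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise OutOfVocabularyError("cosine undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def semantic_distance(w1: str, w2: str, model: CooccurrenceModel) -> float:
    """Cosine of the angle between the two words' context rows."""
    return _cosine(model.vector(w1.lower()), model.vector(w2.lower()))


def _paradigm_sum(words: Iterable[str], model: CooccurrenceModel, label: str) -> np.ndarray:
    total = np.zeros(len(model.context_words))
    used = 0
    for w in sorted(words):
        try:
            total += model.vector(w)
            used += 1
        except OutOfVocabularyError:
            logger.warning("%s paradigm word %r not in model; excluded", label, w)
    if used == 0:
        raise OutOfVocabularyError(f"no {label} paradigm word found in the model vocabulary")
    return total


def semantic_orientation(word: str, paradigms: ParadigmSets, model: CooccurrenceModel) -> float:
    """SO(w): cosine to the summed positive-paradigm vector minus cosine
    to the summed negative-paradigm vector.  Antisymmetric under swapping
    the paradigm sets; invariant to positive rescaling of any row."""
    v = model.vector(word.lower())
    pos = _paradigm_sum(paradigms.positives, model, "positive")
    neg = _paradigm_sum(paradigms.negatives, model, "negative")
    return _cosine(v, pos) - _cosine(v, neg)


def score_text(
    text: str,
    paradigms: ParadigmSets,
    model: CooccurrenceModel,
    tagger: Callable[[str], str | None] | None = None,
    lemmatizer: Callable[[str], str] | None = None,
    oov_policy: str = "zero",
) -> ScoredText:
    """Filter, lemmatize and score every retained token via its lemma.

    ``oov_policy="zero"`` (default) scores out-of-vocabulary lemmas 0 and
    reports their count, preserving alignment with text order;
    ``"drop"`` removes them from the series.
    """
    if oov_policy not in ("zero", "drop"):
        raise ValueError("oov_policy must be 'zero' or 'drop'")
    tokens = filter_and_lemmatize(text, tagger=tagger, lemmatizer=lemmatizer)
    if not tokens:
        raise ValueError("no content tokens retained from the text")
    pos = _paradigm_sum(paradigms.positives, model, "positive")
    neg = _paradigm_sum(paradigms.negatives, model, "negative")
    cache: dict[str, float | None] = {}
    scored: list[Token] = []
    oov = 0
    for tok in tokens:
        if tok.lemma not in cache:
            try:
                v = model.vector(tok.lemma)
                cache[tok.lemma] = _cosine(v, pos) - _cosine(v, neg)
            except OutOfVocabularyError:
                cache[tok.lemma] = None
        score = cache[tok.lemma]
        if score is None:
            oov += 1
            if oov_policy == "drop":
                continue
            score = 0.0
        scored.append(Token(tok.surface, tok.pos_tag, tok.lemma, score))
    return ScoredText(tokens=tuple(scored), oov_count=oov)


def text_to_series(
    text: str,
    paradigms: ParadigmSets,
    model: CooccurrenceModel,
    tagger: Callable[[str], str | None] | None = None,
    lemmatizer: Callable[[str], str] | None = None,
    oov_policy: str = "zero",
) -> Series:
    """One semantic-orientation score per retained token, in text order."""
    scored = score_text(text, paradigms, model, tagger=tagger, lemmatizer=lemmatizer, oov_policy=oov_policy)
    if not scored.tokens:
        raise ValueError("no scoreable tokens: series would be empty")
    if scored.oov_count:
        logger.info("%d of %d tokens out of vocabulary", scored.oov_count, len(scored))
    return Series(np.array([t.so_score for t in scored.tokens], dtype=float))
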