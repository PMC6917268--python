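"""Overall study outcome: PROMISING / negative / mixed / other.

Two binary linear SVMs (positive vs not-positive, negative vs not-negative)
are trained over a shared sparse feature space extracted from the
classification context (title plus the final two sentences) and combined by
a fixed decision table:

    positive + not-negative -> PROMISING
    positive + negative     -> mixed
    not-positive + negative -> negative
    neither                 -> other

Feature families: Porter-stemmed unigrams/bigrams; change-word scope tags
(``word_MORE`` / ``word_LESS`` up to the next punctuation); change/polarity
co-occurrence within a 4-word window (MORE/LESS x GOOD/BAD, with
Disorders-group mentions counting as BAD); negation scope (``word_NEG``
after *no*); and one indicator per UMLS semantic type present.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .annotation import DISORDER_SEMANTIC_TYPES, Mention
from .corpus_io import Abstract, classification_context
from .stemming import porter_stem
from .tokenize import tokenize

log = logging.getLogger(__name__)

LABELS = ("PROMISING", "negative", "mixed", "other")

#: gold-label to binary-task mapping implied by the combination table
POSITIVE_LABELS = frozenset({"PROMISING", "mixed"})
NEGATIVE_LABELS = frozenset({"negative", "mixed"})

DEFAULT_COOC_WINDOW = 4
NEGATION_TRIGGERS = frozenset({"no"})


def _read_wordlist(filename: str) -> frozenset[str]:
    text = (resources.files("menagerie.data") / filename).read_text()
    return frozenset(
        line.strip().casefold()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class WordLists:
    """MORE/LESS change words and GOOD/BAD polarity words (stem-matched)."""

    more: frozenset[str]
    less: frozenset[str]
    good: frozenset[str]
    bad: frozenset[str]

    @classmethod
    def packaged(cls) -> "WordLists":
        return cls(
            more=_read_wordlist("wordlist_more.txt"),
            less=_read_wordlist("wordlist_less.txt"),
            good=_read_wordlist("wordlist_good.txt"),
            bad=_read_wordlist("wordlist_bad.txt"),
        )

    def stems(self, which: str) -> frozenset[str]:
        return frozenset(porter_stem(w) for w in getattr(self, which))


def _stem_set(words: Iterable[str]) -> frozenset[str]:
    return frozenset(porter_stem(w.casefold()) for w in words)


def _matches(token: str, stems: frozenset[str]) -> bool:
    return porter_stem(token.casefold()) in stems


# --- SCOPE features ------------------------------------------------------

def tag_change_scope(
    tokens: Sequence[str],
    more_list: Iterable[str],
    less_list: Iterable[str],
) -> list[str]:
    """``word_MORE`` / ``word_LESS`` tags for words inside a change scope.

    Every word token strictly after a trigger, up to (exclusive) the next
    punctuation token, is tagged.  A later trigger opens its own scope, so a
    word can carry both tags; all scopes close at punctuation.  Trigger
    matching is Porter-stem based; *tokens* must include punctuation tokens.
    """
    more_stems, less_stems = _stem_set(more_list), _stem_set(less_list)
    is_punct = [not _is_word(t) for t in tokens]
    out: list[str] = []
    active: set[str] = set()
    for tok, punct in zip(tokens, is_punct):
        if punct:
            active.clear()
            continue
        for tag in sorted(active):
            out.append(f"{tok.casefold()}_{tag}")
        if _matches(tok, more_stems):
            active.add("MORE")
        if _matches(tok, less_stems):
            active.add("LESS")
    return out


def _is_word(token: str) -> bool:
    return any(ch.isalnum() for ch in token)


# --- COOC features -------------------------------------------------------

def cooccurrence_features(
    tokens: Sequence[str],
    more_list: Iterable[str],
    less_list: Iterable[str],
    good_list: Iterable[str],
    bad_list: Iterable[str],
    disorder_spans: Iterable[int] = (),
    window: int = DEFAULT_COOC_WINDOW,
) -> set[str]:
    """Binary MORE/LESS x GOOD/BAD co-occurrence features.

    A feature fires when a change token and a polarity token lie within
    *window* word tokens of each other (punctuation excluded from the
    count; direction-agnostic).  *disorder_spans* are indices into *tokens*
    belonging to Disorders-group mentions; those tokens count as BAD.
    """
    more_stems, less_stems = _stem_set(more_list), _stem_set(less_list)
    good_stems, bad_stems = _stem_set(good_list), _stem_set(bad_list)
    disorder_idx = set(disorder_spans)
    words = [(i, t) for i, t in enumerate(tokens) if _is_word(t)]
    feats: set[str] = set()
    for wi, (i, ti) in enumerate(words):
        changes = []
        if _matches(ti, more_stems):
            changes.append("MORE")
        if _matches(ti, less_stems):
            changes.append("LESS")
        if not changes:
            continue
        for wj, (j, tj) in enumerate(words):
            if i == j or abs(wi - wj) > window:
                continue
            pols = []
            if _matches(tj, good_stems):
                pols.append("GOOD")
            if _matches(tj, bad_stems) or j in disorder_idx:
                pols.append("BAD")
            for c in changes:
                for p in pols:
                    feats.add(f"{c}_{p}")
    return feats


# --- NEG features --------------------------------------------------------

def negation_features(tokens: Sequence[str]) -> set[str]:
    """``word_NEG`` for words after a negation trigger, up to punctuation."""
    out: set[str] = set()
    active = False
    for tok in tokens:
        if not _is_word(tok):
            active = False
            continue
        if active:
            out.add(f"{tok.casefold()}_NEG")
        if tok.casefold() in NEGATION_TRIGGERS:
            active = True
    return out


# --- full feature extraction --------------------------------------------

@dataclass(frozen=True)
class ContextMention:
    """A concept mention mapped into classification-context coordinates."""

    start: int
    end: int
    sem_types: frozenset


def extract_outcome_features(
    context: str,
    mentions: Sequence[ContextMention] = (),
    word_lists: WordLists | None = None,
    window: int = DEFAULT_COOC_WINDOW,
    ngram_binary: bool = True,
) -> dict[str, float]:
    """Sparse feature map over the five families for one context string."""
    if word_lists is None:
        word_lists = WordLists.packaged()
    if not context.strip():
        log.warning("empty classification context")
        return {}
    toks = tokenize(context)
    texts = [t.text for t in toks]
    feats: dict[str, float] = {}
    # NGRAM: stemmed, lowercased unigrams and bigrams, binary presence
    stems = [porter_stem(t.folded()) for t in toks if t.is_word]
    for s in stems:
        feats[f"NG:{s}"] = feats.get(f"NG:{s}", 0.0) + 1.0
    for a, b in zip(stems, stems[1:]):
        feats[f"NG:{a}_{b}"] = feats.get(f"NG:{a}_{b}", 0.0) + 1.0
    if ngram_binary:
        for k in list(feats):
            feats[k] = 1.0
    # SCOPE
    for tag in tag_change_scope(texts, word_lists.more, word_lists.less):
        feats[f"SCOPE:{tag}"] = 1.0
    # COOC: disorder token indices from mention character spans
    disorder_idx = [
        i for i, t in enumerate(toks)
        if t.is_word and any(
            m.start <= t.start and t.end <= m.end
            for m in mentions
            if m.sem_types & DISORDER_SEMANTIC_TYPES
        )
    ]
    for f in cooccurrence_features(
        texts, word_lists.more, word_lists.less, word_lists.good,
        word_lists.bad, disorder_idx, window,
    ):
        feats[f"COOC:{f}"] = 1.0
    # NEG
    for f in negation_features(texts):
        feats[f"NEG:{f}"] = 1.0
    # SEMTYPE
    for m in mentions:
        for st in m.sem_types:
            feats[f"ST:{st}"] = 1.0
    return feats


def context_mentions(
    abstract: Abstract, mentions: Sequence[Mention]
) -> list[ContextMention]:
    """Map document-space mentions into classification-context coordinates.

    The context is the title plus the final two sentences joined by single
    spaces; mentions outside those regions are dropped.
    """
    regions: list[tuple[int, int]] = [(0, len(abstract.title))]
    off = len(abstract.title) + 1
    for s in abstract.sentences[-2:]:
        regions.append((off + s.start, off + s.end))
    out = []
    ctx_off = 0
    for rs, re_ in regions:
        for m in mentions:
            if m.start >= rs and m.end <= re_:
                out.append(ContextMention(
                    start=m.start - rs + ctx_off,
                    end=m.end - rs + ctx_off,
                    sem_types=m.sem_types,
                ))
        ctx_off += (re_ - rs) + 1  # joining space
    return out


# --- the model pair ------------------------------------------------------

@dataclass
class LinearModel:
    """A fitted linear decision function over named features."""

    weights: dict[str, float]
    bias: float

    def decide(self, feats: dict[str, float]) -> bool:
        score = self.bias + sum(
            self.weights.get(k, 0.0) * v for k, v in feats.items()
        )
        return score > 0.0


@dataclass
class OutcomeModelPair:
    pos_model: LinearModel
    neg_model: LinearModel
    seed: int = 0
    C: float = 1.0

    def to_json(self) -> str:
        return json.dumps({
            "version": 1, "seed": self.seed, "C": self.C,
            "pos": {"weights": self.pos_model.weights, "bias": self.pos_model.bias},
            "neg": {"weights": self.neg_model.weights, "bias": self.neg_model.bias},
        })

    @classmethod
    def from_json(cls, text: str) -> "OutcomeModelPair":
        d = json.loads(text)
        return cls(
            pos_model=LinearModel(d["pos"]["weights"], d["pos"]["bias"]),
            neg_model=LinearModel(d["neg"]["weights"], d["neg"]["bias"]),
            seed=d.get("seed", 0), C=d.get("C", 1.0),
        )


@dataclass
class OutcomeConfig:
    word_lists: WordLists = field(default_factory=WordLists.packaged)
    annotator: Callable[[Abstract], Sequence[Mention]] | None = None
    C: float = 1.0
    seed: int = 0
    cooc_window: int = DEFAULT_COOC_WINDOW
    ngram_binary: bool = True


def abstract_features(abstract: Abstract, config: OutcomeConfig) -> dict[str, float]:
    """Classification-context features for one abstract."""
    mentions = config.annotator(abstract) if config.annotator else []
    return extract_outcome_features(
        classification_context(abstract),
        context_mentions(abstract, mentions),
        config.word_lists,
        window=config.cooc_window,
        ngram_binary=config.ngram_binary,
    )


def _fit_binary(
    X, y: np.ndarray, C: float, seed: int, task: str
) -> tuple[np.ndarray, float]:
    if len(set(y.tolist())) < 2:
        raise ValueError(f"{task} model: training data contains a single class")
    clf = LinearSVC(
        C=C, loss="hinge", class_weight="balanced",
        random_state=seed, max_iter=20000,
    )
    clf.fit(X, y)
    return clf.coef_[0], float(clf.intercept_[0])


def train_outcome_models(
    labeled: Sequence[tuple[Abstract, str]],
    config: OutcomeConfig | None = None,
) -> OutcomeModelPair:
    """Fit the positive and negative L2 linear SVMs on a labeled corpus.

    Gold labels must come from :data:`LABELS`; ``mixed`` counts as both
    positive and negative.  Training is deterministic given the seed and
    data order.
    """
    config = config or OutcomeConfig()
    feats = [abstract_features(ab, config) for ab, _ in labeled]
    return train_from_features(feats, [lab for _, lab in labeled], config)


def train_from_features(
    feats: Sequence[dict[str, float]],
    labels: Sequence[str],
    config: OutcomeConfig | None = None,
) -> OutcomeModelPair:
    """Fit the model pair on precomputed feature maps (one per abstract)."""
    config = config or OutcomeConfig()
    for label in labels:
        if label not in LABELS:
            raise ValueError(f"unknown outcome label {label!r}")
    labeled = list(zip(feats, labels))
    vec = DictVectorizer(sparse=True, sort=True)
    X = vec.fit_transform(feats).tocsr()
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    names = vec.get_feature_names_out()
    y_pos = np.array([1 if lab in POSITIVE_LABELS else 0 for _, lab in labeled])
    y_neg = np.array([1 if lab in NEGATIVE_LABELS else 0 for _, lab in labeled])
    wp, bp = _fit_binary(X, y_pos, config.C, config.seed, "positive")
    wn, bn = _fit_binary(X, y_neg, config.C, config.seed, "negative")
    def as_map(w):
        return {names[i]: float(w[i]) for i in np.nonzero(w)[0]}
    return OutcomeModelPair(
        pos_model=LinearModel(as_map(wp), bp),
        neg_model=LinearModel(as_map(wn), bn),
        seed=config.seed, C=config.C,
    )


def combine(pos: bool, neg: bool) -> str:
    """Fixed decision table from the two binary predictions."""
    if pos and not neg:
        return "PROMISING"
    if pos and neg:
        return "mixed"
    if neg:
        return "negative"
    return "other"


def predict_overall_outcome(
    abstract: Abstract,
    models: OutcomeModelPair,
    config: OutcomeConfig | None = None,
) -> str:
    """Four-way outcome label for one abstract from the fitted model pair."""
    if models.pos_model is None or models.neg_model is None:
        raise ValueError("outcome models are not fitted")
    config = config or OutcomeConfig()
    feats = abstract_features(abstract, config)
    return predict_from_features(feats, models)


def predict_from_features(
    feats: dict[str, float], models: OutcomeModelPair
) -> str:
    return combine(models.pos_model.decide(feats), models.neg_model.decide(feats))
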