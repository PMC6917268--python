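"""Scoring against gold annotations and classifier cross-validation.

Extraction output is scored with precision / recall / F1 under exact or
approximate span matching (mention level) or unique-term comparison
(abstract level).  The outcome classifier is evaluated with repeated
stratified k-fold cross-validation; the majority-vote baseline predicts the
modal label everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .corpus_io import Abstract
from . import outcome as outcome_mod

MATCH_MODES = ("exact", "approximate")
LEVELS = ("mention", "abstract", "title")


@dataclass(frozen=True)
class GoldItem:
    term: str
    span: tuple[int, int] | None = None
    identifier: str | None = None

    def key(self) -> str:
        """Abstract-level identity: identifier when present, else folded term."""
        return self.identifier if self.identifier else self.term.casefold()


@dataclass
class GoldAnnotation:
    pmid: str
    level: str
    module: str
    items: list[GoldItem] = field(default_factory=list)

    def __post_init__(self):
        if self.level not in ("mention", "abstract"):
            raise ValueError(f"unknown gold level {self.level!r}")
        if self.level == "mention" and any(i.span is None for i in self.items):
            raise ValueError("mention-level gold items need spans")


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    mode: str = "exact"
    level: str = "abstract"

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def prf(tp: int, fp: int, fn: int, mode: str = "exact",
        level: str = "abstract") -> EvalReport:
    """Precision/recall/F1 report with the 0/0 -> 0 convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    return EvalReport(tp, fp, fn, mode, level)


def _spans_match(pred: tuple[int, int], gold: tuple[int, int], mode: str) -> bool:
    if mode == "exact":
        return pred == gold
    return pred[0] < gold[1] and gold[0] < pred[1]  # any character overlap


def match_terms(
    pred: Sequence[GoldItem],
    gold: Sequence[GoldItem],
    mode: str = "exact",
    level: str = "mention",
) -> tuple[int, int, int]:
    """(tp, fp, fn) under the stated matching mode and level.

    Mention level matches spans one-to-one, greedily left-to-right: exact
    mode requires identical boundaries, approximate mode accepts any
    character overlap.  Abstract level compares unique normalized term keys.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown matching mode {mode!r}")
    if level == "abstract":
        pset = {i.key() for i in pred}
        gset = {i.key() for i in gold}
        tp = len(pset & gset)
        return tp, len(pset) - tp, len(gset) - tp
    preds = sorted(pred, key=lambda i: i.span)
    golds = sorted(gold, key=lambda i: i.span)
    used = [False] * len(golds)
    tp = 0
    for p in preds:
        for gi, g in enumerate(golds):
            if used[gi]:
                continue
            if _spans_match(p.span, g.span, mode):
                used[gi] = True
                tp += 1
                break
    return tp, len(preds) - tp, len(golds) - tp


def evaluate(
    pred: Sequence[GoldItem],
    gold: Sequence[GoldItem],
    mode: str = "exact",
    level: str = "mention",
) -> EvalReport:
    tp, fp, fn = match_terms(pred, gold, mode, level)
    return EvalReport(tp, fp, fn, mode, level)


# --- classifier evaluation ----------------------------------------------

def iter_folds(n: int, k: int, seed: int, y: np.ndarray, stratify: bool = True):
    """Yield (train_idx, test_idx) pairs for one shuffled k-fold split.

    Folds partition the items (each appears in exactly one test fold) and
    sizes differ by at most one.
    """
    if stratify:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        yield from splitter.split(np.zeros(n), y)
    else:
        rng = np.random.RandomState(seed)
        order = rng.permutation(n)
        for i in range(k):
            test = order[i::k]
            yield np.setdiff1d(order, test), test

@dataclass
class CVReport:
    """Mean per-label precision/recall/F1 and accuracy over repeats."""

    per_label: dict[str, dict[str, float]]
    accuracy: float
    k: int
    repeats: int


def _label_scores(y_true: list[str], y_pred: list[str]) -> dict[str, dict[str, float]]:
    out = {}
    for label in outcome_mod.LABELS:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == p == label)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != label and p == label)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == label and p != label)
        rep = EvalReport(tp, fp, fn)
        out[label] = {"precision": rep.precision, "recall": rep.recall,
                      "f1": rep.f1}
    return out


def cross_validate_outcome(
    labeled: Sequence[tuple[Abstract, str]],
    k: int = 10,
    repeats: int = 50,
    seed: int = 0,
    config: "outcome_mod.OutcomeConfig | None" = None,
    stratify: bool = True,
) -> CVReport:
    """Repeated stratified k-fold CV of the outcome model pair.

    Each repeat shuffles with a derived seed (``seed + repeat``), splits
    into k folds, trains on k-1 and predicts the held-out fold; per-label
    metrics and accuracy are computed on the pooled predictions of the
    repeat and averaged over repeats.  Deterministic given *seed*.
    """
    n = len(labeled)
    if k > n:
        raise ValueError(f"k={k} exceeds corpus size {n}")
    labels = [lab for _, lab in labeled]
    if len(set(labels)) < 2:
        raise ValueError("cross-validation needs at least two classes")
    config = config or outcome_mod.OutcomeConfig()
    # Features are deterministic per abstract; compute once, reuse per fold.
    feats = [outcome_mod.abstract_features(ab, config) for ab, _ in labeled]
    y = np.array(labels)
    per_label_acc: list[dict] = []
    accuracies = []
    for r in range(repeats):
        folds = iter_folds(n, k, seed + r, y, stratify)
        y_true: list[str] = []
        y_pred: list[str] = []
        for train_idx, test_idx in folds:
            pair = outcome_mod.train_from_features(
                [feats[i] for i in train_idx],
                [labels[i] for i in train_idx],
                config,
            )
            for i in test_idx:
                y_true.append(labels[i])
                y_pred.append(outcome_mod.predict_from_features(feats[i], pair))
        per_label_acc.append(_label_scores(y_true, y_pred))
        accuracies.append(
            sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
        )
    mean_per_label = {
        label: {
            metric: float(np.mean([rep[label][metric] for rep in per_label_acc]))
            for metric in ("precision", "recall", "f1")
        }
        for label in outcome_mod.LABELS
    }
    return CVReport(mean_per_label, float(np.mean(accuracies)), k, repeats)


def majority_vote_baseline(
    labeled: Sequence[tuple[Abstract, str]]
) -> tuple[dict[str, EvalReport], float]:
    """Score the classifier that predicts the modal label for every item."""
    labels = [lab for _, lab in labeled]
    modal = max(sorted(set(labels)), key=labels.count)
    preds = [modal] * len(labels)
    reports = {}
    for label in outcome_mod.LABELS:
        tp = sum(1 for t, p in zip(labels, preds) if t == p == label)
        fp = sum(1 for t, p in zip(labels, preds) if t != label and p == label)
        fn = sum(1 for t, p in zip(labels, preds) if t == label and p != label)
        reports[label] = EvalReport(tp, fp, fn)
    accuracy = labels.count(modal) / len(labels)
    return reports, accuracy
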