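"""Outcome feature families (with brute-force oracles), stemming, the
combination table, and model training/prediction."""

import random

import pytest

from menagerie.corpus_io import Abstract
from menagerie.outcome import (
    ContextMention,
    OutcomeConfig,
    OutcomeModelPair,
    WordLists,
    combine,
    cooccurrence_features,
    extract_outcome_features,
    negation_features,
    predict_overall_outcome,
    tag_change_scope,
    train_outcome_models,
)
from menagerie.stemming import porter_stem
from menagerie.tokenize import tokenize

from conftest import make_abstract

MORE = ["increase", "boost"]
LESS = ["alleviate", "reduce"]
GOOD = ["ameliorate", "improvement"]
BAD = ["exacerbate", "deficit"]


def toks(text):
    return [t.text for t in tokenize(text)]


class TestPorterStemmer:
    # frozen pairs from the algorithm's published reference vocabulary
    @pytest.mark.parametrize("word,stem", [
        ("caresses", "caress"), ("ponies", "poni"), ("ties", "ti"),
        ("agreed", "agre"), ("plastered", "plaster"), ("motoring", "motor"),
        ("hopping", "hop"), ("falling", "fall"), ("filing", "file"),
        ("happy", "happi"), ("relational", "relat"), ("rational", "ration"),
        ("digitizer", "digit"), ("operator", "oper"),
        ("decisiveness", "decis"), ("hopefulness", "hope"),
        ("triplicate", "triplic"), ("formative", "form"),
        ("electriciti", "electr"), ("adjustable", "adjust"),
        ("replacement", "replac"), ("adoption", "adopt"),
        ("activate", "activ"), ("effective", "effect"),
        ("rate", "rate"), ("cease", "ceas"), ("controll", "control"),
        ("alleviated", "allevi"), ("improvement", "improv"),
        ("treatment", "treatment"), ("increased", "increas"),
    ])
    def test_reference_pairs(self, word, stem):
        assert porter_stem(word) == stem


class TestChangeScope:
    def test_less_scope_tags_until_punctuation(self):
        got = tag_change_scope(toks("alleviate motor deficits ."), MORE, LESS)
        assert set(got) == {"motor_LESS", "deficits_LESS"}

    def test_no_trigger_no_tags(self):
        assert tag_change_scope(toks("plain words here ."), MORE, LESS) == []

    def test_trigger_before_punctuation_empty_scope(self):
        assert tag_change_scope(toks("values alleviate ."), MORE, LESS) == []

    def test_inflected_trigger_matches_by_stem(self):
        got = tag_change_scope(toks("increased motor scores ."), MORE, LESS)
        assert set(got) == {"motor_MORE", "scores_MORE"}

    def test_matches_sweep_oracle_on_random_sequences(self):
        rng = random.Random(41)
        vocab = ["motor", "scores", "cells", "values"] + MORE + LESS
        punct = [".", ",", ";"]
        for trial in range(350):
            seq = [
                rng.choice(punct) if rng.random() < 0.2 else rng.choice(vocab)
                for _ in range(rng.randint(1, 25))
            ]
            got = set(tag_change_scope(seq, MORE, LESS))
            # oracle: for each trigger, sweep forward to the next punctuation
            want = []
            more_stems = {porter_stem(w) for w in MORE}
            less_stems = {porter_stem(w) for w in LESS}
            for i, tok in enumerate(seq):
                if tok in ".,;":
                    continue
                tags = []
                if porter_stem(tok.lower()) in more_stems:
                    tags.append("MORE")
                if porter_stem(tok.lower()) in less_stems:
                    tags.append("LESS")
                for tag in tags:
                    for j in range(i + 1, len(seq)):
                        if seq[j] in ".,;":
                            break
                        want.append(f"{seq[j].lower()}_{tag}")
            assert got == set(want), f"trial {trial}: {seq}"


class TestCooccurrence:
    def test_alleviate_disorder_sets_less_bad(self):
        tk = toks("alleviate Parkinson's disease")
        got = cooccurrence_features(tk, MORE, LESS, GOOD, BAD,
                                    disorder_spans=[1, 2])
        assert got == {"LESS_BAD"}

    def test_more_good_within_window(self):
        tk = toks("increase then later ameliorate signs")
        assert cooccurrence_features(tk, MORE, LESS, GOOD, BAD) == {"MORE_GOOD"}

    def test_beyond_window_no_feature(self):
        tk = toks("increase one two three four five ameliorate")
        assert cooccurrence_features(tk, MORE, LESS, GOOD, BAD) == set()

    def test_punctuation_excluded_from_word_count(self):
        # 3 intervening words plus punctuation: still within the 4-word window
        tk = toks("increase , one , two , three ameliorate")
        assert cooccurrence_features(tk, MORE, LESS, GOOD, BAD) == {"MORE_GOOD"}

    def test_matches_window_oracle_on_random_sequences(self):
        rng = random.Random(43)
        vocab = ["motor", "cells", "disease"] + MORE + LESS + GOOD + BAD
        for trial in range(350):
            seq = [
                "," if rng.random() < 0.15 else rng.choice(vocab)
                for _ in range(rng.randint(1, 20))
            ]
            disorder = [
                i for i, t in enumerate(seq)
                if t == "disease" and rng.random() < 0.5
            ]
            got = cooccurrence_features(seq, MORE, LESS, GOOD, BAD, disorder)
            # oracle: enumerate all ordered word pairs and their distances
            words = [(i, t) for i, t in enumerate(seq) if t != ","]
            stems = {
                "MORE": {porter_stem(w) for w in MORE},
                "LESS": {porter_stem(w) for w in LESS},
                "GOOD": {porter_stem(w) for w in GOOD},
                "BAD": {porter_stem(w) for w in BAD},
            }
            want = set()
            for wi, (i, ti) in enumerate(words):
                for wj, (j, tj) in enumerate(words):
                    if i == j or abs(wi - wj) > 4:
                        continue
                    for c in ("MORE", "LESS"):
                        if porter_stem(ti) not in stems[c]:
                            continue
                        if porter_stem(tj) in stems["GOOD"]:
                            want.add(f"{c}_GOOD")
                        if porter_stem(tj) in stems["BAD"] or j in disorder:
                            want.add(f"{c}_BAD")
            assert got == want, f"trial {trial}: {seq}"


class TestNegation:
    def test_no_significant_change(self):
        got = negation_features(toks("no significant change"))
        assert got == {"significant_NEG", "change_NEG"}

    def test_no_before_punctuation_empty(self):
        assert negation_features(toks("no .")) == set()

    def test_scope_closes_at_comma(self):
        got = negation_features(toks("there was no loss , however"))
        assert got == {"loss_NEG"}

    def test_matches_scope_oracle_on_random_sequences(self):
        rng = random.Random(47)
        vocab = ["no", "loss", "change", "gain", "effect"]
        for trial in range(300):
            seq = [
                "," if rng.random() < 0.2 else rng.choice(vocab)
                for _ in range(rng.randint(1, 15))
            ]
            got = negation_features(seq)
            want = set()
            for i, tok in enumerate(seq):
                if tok != "no":
                    continue
                for j in range(i + 1, len(seq)):
                    if seq[j] == ",":
                        break
                    want.add(f"{seq[j]}_NEG")
            assert got == want, f"trial {trial}: {seq}"


class TestFeatureExtraction:
    def test_stemmed_bigram_present(self):
        feats = extract_outcome_features("Treatment alleviated tremor.")
        assert "NG:treatment_allevi" in feats
        assert "NG:allevi_tremor" in feats

    def test_semtype_feature_from_context_mention(self):
        ctx = "alleviate Parkinson's disease"
        m = ContextMention(10, 29, frozenset(["Disease or Syndrome"]))
        feats = extract_outcome_features(ctx, [m])
        assert feats.get("ST:Disease or Syndrome") == 1.0
        assert feats.get("COOC:LESS_BAD") == 1.0

    def test_empty_context_empty_features(self):
        assert extract_outcome_features("") == {}

    def test_deterministic_and_mention_order_independent(self):
        ctx = "Treatment alleviated Parkinson's disease but raised toxicity."
        m1 = ContextMention(20, 39, frozenset(["Disease or Syndrome"]))
        m2 = ContextMention(0, 9, frozenset(["Therapeutic or Preventive Procedure"]))
        assert (extract_outcome_features(ctx, [m1, m2])
                == extract_outcome_features(ctx, [m2, m1]))


class TestCombine:
    @pytest.mark.parametrize("pos,neg,label", [
        (True, False, "PROMISING"),
        (True, True, "mixed"),
        (False, True, "negative"),
        (False, False, "other"),
    ])
    def test_decision_table(self, pos, neg, label):
        assert combine(pos, neg) == label

    def test_total_and_injective(self):
        images = {combine(p, n) for p in (False, True) for n in (False, True)}
        assert images == {"PROMISING", "negative", "mixed", "other"}


def tiny_labeled():
    texts = {
        "PROMISING": "Treatment alleviated deficits and produced improvement.",
        "negative": "Treatment exacerbated deficits and increased toxicity.",
        "mixed": "Treatment produced improvement but increased toxicity.",
        "other": "The findings were inconclusive and need further study.",
    }
    out = []
    for i, (label, text) in enumerate(sorted(texts.items())):
        for k in range(3):
            ab = make_abstract(f"{label}{k}", f"Study {i}{k}.", text)
            out.append((ab, label))
    return out


class TestTraining:
    def test_minimal_set_trains_and_memorizes(self):
        labeled = tiny_labeled()
        pair = train_outcome_models(labeled)
        for ab, label in labeled:
            assert predict_overall_outcome(ab, pair) == label

    def test_single_class_binary_raises(self):
        labeled = [lab for lab in tiny_labeled() if lab[1] == "PROMISING"]
        with pytest.raises(ValueError, match="single class"):
            train_outcome_models(labeled)

    def test_unknown_label_rejected(self):
        ab = make_abstract("1", "T.", "Body text.")
        with pytest.raises(ValueError, match="unknown outcome label"):
            train_outcome_models([(ab, "great")])

    def test_unknown_feature_context_is_deterministic(self):
        pair = train_outcome_models(tiny_labeled())
        ab = make_abstract("z", "Unseen words entirely.",
                          "Zq zq zq verbal novelty.")
        assert (predict_overall_outcome(ab, pair)
                == predict_overall_outcome(ab, pair))

    def test_json_round_trip_preserves_predictions(self):
        labeled = tiny_labeled()
        pair = train_outcome_models(labeled)
        again = OutcomeModelPair.from_json(pair.to_json())
        for ab, _ in labeled:
            assert (predict_overall_outcome(ab, pair)
                    == predict_overall_outcome(ab, again))

    def test_training_deterministic_given_seed(self):
        labeled = tiny_labeled()
        cfg = OutcomeConfig(seed=5)
        assert (train_outcome_models(labeled, cfg).to_json()
                == train_outcome_models(labeled, cfg).to_json())
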