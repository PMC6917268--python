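"""Species exclusion rules, hierarchy reduction, phrase-window pairing."""

import random

import pytest

from menagerie.annotation import annotate_dictionary
from menagerie.species_model import (
    SpeciesHierarchy,
    extract_models,
    extract_species,
    extract_species_model_facts,
    pair_species_models,
    phrase_ordinals,
)

from conftest import make_abstract


def species_of(ab, resources, hierarchy):
    ments = annotate_dictionary(ab, [resources.species])
    return extract_species(ab, ments, hierarchy)


class TestSpeciesRules:
    """Constructed abstracts exercising the exclusion rules one by one."""

    def test_unstructured_first_sentence_only_excluded(self, resources, hierarchy):
        ab = make_abstract("1", "A title.",
                          "Earlier work used mice. We studied cell lines here.")
        assert species_of(ab, resources, hierarchy) == set()

    def test_first_sentence_plus_later_mention_kept(self, resources, hierarchy):
        ab = make_abstract("1", "A title.",
                          "Earlier work used mice. Here mice were treated again.")
        assert species_of(ab, resources, hierarchy) == {"Mouse"}

    def test_structured_background_only_excluded(self, resources, hierarchy):
        body = ("BACKGROUND: Prior studies used rats. "
                "RESULTS: Cultured cells responded well.")
        ab = make_abstract("1", "A title.", body, structured=True)
        assert species_of(ab, resources, hierarchy) == set()

    def test_structured_background_and_methods_kept(self, resources, hierarchy):
        body = ("BACKGROUND: Prior studies used rats. "
                "METHODS: Adult rats were dosed daily.")
        ab = make_abstract("1", "A title.", body, structured=True)
        assert species_of(ab, resources, hierarchy) == {"Rat"}

    def test_objective_counts_as_background(self, resources, hierarchy):
        body = ("OBJECTIVE: We revisit findings in dogs. "
                "RESULTS: Assay values were stable.")
        ab = make_abstract("1", "A title.", body, structured=True)
        assert species_of(ab, resources, hierarchy) == set()

    def test_human_only_in_final_15pct_excluded(self, resources, hierarchy):
        sents = [f"Sentence number {i} reports data." for i in range(9)]
        sents.append("These findings may help patients.")
        ab = make_abstract("1", "A title.", " ".join(sents))
        assert len(ab.sentences) == 10
        assert species_of(ab, resources, hierarchy) == set()

    def test_human_in_final_15pct_and_earlier_kept(self, resources, hierarchy):
        sents = ["Patients were enrolled in the study."]
        sents += [f"Sentence number {i} reports data." for i in range(8)]
        sents.append("These findings may help patients.")
        ab = make_abstract("1", "A title.", " ".join(sents))
        # first-sentence rule does not fire: Human also appears at the end,
        # and the tail rule does not fire: Human also appears at the start
        assert species_of(ab, resources, hierarchy) == {"Human"}

    def test_human_tail_rule_uses_ceil(self, resources, hierarchy):
        # 7 sentences -> ceil(1.05) = 2 excluded tail sentences
        sents = [f"Sentence number {i} reports data." for i in range(5)]
        sents.append("Patients may benefit from this.")
        sents.append("Final remark closes the abstract.")
        ab = make_abstract("1", "A title.", " ".join(sents))
        assert species_of(ab, resources, hierarchy) == set()

    def test_human_rule_structured_conclusions_only(self, resources, hierarchy):
        body = ("METHODS: Samples were processed. "
                "CONCLUSIONS: This may translate to patients.")
        ab = make_abstract("1", "A title.", body, structured=True)
        assert species_of(ab, resources, hierarchy) == set()

    def test_animal_species_not_subject_to_tail_rule(self, resources, hierarchy):
        ab = make_abstract("1", "A title.",
                          "Assays were run. Values rose. Mice recovered fully.")
        assert species_of(ab, resources, hierarchy) == {"Mouse"}

    def test_specific_term_beats_general(self, resources, hierarchy):
        ab = make_abstract("1", "A title.",
                          "Filler sentence first. Macaques were dosed. "
                          "Non-human primates tolerated it.")
        assert species_of(ab, resources, hierarchy) == {"Macaque"}

    def test_general_term_survives_alone(self, resources, hierarchy):
        ab = make_abstract("1", "A title.",
                          "Filler sentence first. Non-human primates were dosed.")
        assert species_of(ab, resources, hierarchy) == {"Non-human primate"}

    def test_hierarchy_skips_levels(self, resources, hierarchy):
        ab = make_abstract("1", "A title.",
                          "Filler sentence first. Mice and rodents and animal "
                          "models were compared.")
        assert species_of(ab, resources, hierarchy) == {"Mouse"}

    def test_title_mention_is_allowed_region(self, resources, hierarchy):
        ab = make_abstract("1", "Mice in a titled study.",
                          "Unrelated opening sentence. Cells were assayed.")
        assert species_of(ab, resources, hierarchy) == {"Mouse"}

    def test_empty_mentions_empty_set(self, hierarchy):
        ab = make_abstract("1", "A title.", "Nothing relevant here.")
        assert extract_species(ab, [], hierarchy) == set()


class TestHierarchy:
    def test_reduce_idempotent_and_order_independent(self, hierarchy):
        terms = {"Mouse", "Rodent", "Animal model", "Macaque",
                 "Non-human primate", "Human"}
        once = hierarchy.reduce(terms)
        assert hierarchy.reduce(once) == once
        assert once == {"Mouse", "Macaque", "Human"}

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            SpeciesHierarchy({"a": "b", "b": "a"})


class TestModels:
    def test_long_and_short_mptp_surfaces_consolidate(self, resources):
        ab = make_abstract(
            "1", "A title.",
            "1-methyl-4-phenyl-1,2,3,6-tetrahydropyridine (MPTP) was given.",
        )
        ments = annotate_dictionary(ab, [resources.models])
        assert len(ments) == 2
        assert extract_models(ab, ments) == {"MPTP"}

    def test_transgenic_maps_to_genetic_model(self, resources):
        ab = make_abstract("1", "A title.",
                          "Alpha-synuclein transgenic mice were compared.")
        ments = annotate_dictionary(ab, [resources.models])
        assert extract_models(ab, ments) == {"Genetically altered model"}

    def test_no_signals_empty(self, resources):
        ab = make_abstract("1", "A title.", "Nothing about toxins here.")
        assert extract_models(ab, annotate_dictionary(ab, [resources.models])) == set()


def oracle_pairs(ab, sp_ments, mo_ments, window):
    """Independent pairing oracle: count phrase ordinals by scanning
    delimiters in the document prefix before each mention start."""
    import re

    doc = f"{ab.title} {ab.body}"
    delims = [m.end() for m in re.finditer(r"[,;:.!?]", doc)]
    off = len(ab.title) + 1
    sent_cuts = set()
    for s in ab.sentences:
        sent_cuts.add(off + s.start)
        sent_cuts.add(off + s.end)
    cuts = sorted(set(delims) | sent_cuts | {0, len(doc)})
    segments = []
    for a, b in zip(cuts, cuts[1:]):
        if doc[a:b].strip():
            segments.append((a, b))

    def ordinal(pos):
        for k, (a, b) in enumerate(segments):
            if a <= pos < b:
                return k
        return len(segments) - 1

    out = set()
    for sm in sp_ments:
        for mm in mo_ments:
            if abs(ordinal(sm.start) - ordinal(mm.start)) <= window:
                out.add((sm.canonical, mm.canonical))
    return out


class TestPairing:
    def test_same_phrase_distance_zero(self, resources):
        ab = make_abstract("1", "A title.", "MPTP-treated mice showed deficits.")
        ments = annotate_dictionary(ab, [resources.species, resources.models])
        sp = [m for m in ments if m.category == "species_signal"]
        mo = [m for m in ments if m.category == "model_signal"]
        assert pair_species_models(ab, sp, mo) == {("Mouse", "MPTP")}

    def test_excluded_species_never_pairs(self, resources, hierarchy):
        # "mice" only in the first sentence is excluded, so no pair survives
        # even though the model is within the window.
        ab = make_abstract("1", "A title.",
                          "Mice were described before. MPTP was applied to cells.")
        facts = extract_species_model_facts(
            ab, annotate_dictionary(ab, [resources.species, resources.models]),
            hierarchy,
        )
        assert facts.species == set()
        assert facts.models == {"MPTP"}
        assert facts.pairs == set()

    def test_surviving_species_pairs_through_pipeline(self, resources, hierarchy):
        ab = make_abstract("1", "A title.",
                          "Opening filler sentence. MPTP-treated mice improved.")
        facts = extract_species_model_facts(
            ab, annotate_dictionary(ab, [resources.species, resources.models]),
            hierarchy,
        )
        assert facts.pairs == {("Mouse", "MPTP")}

    def test_far_apart_phrases_do_not_pair(self, resources, hierarchy):
        body = ("Mice were housed. Filler phrase one, filler phrase two, "
                "filler phrase three, filler phrase four; rotenone was applied.")
        ab = make_abstract("1", "A title.", body)
        ments = annotate_dictionary(ab, [resources.species, resources.models])
        sp = [m for m in ments if m.category == "species_signal"]
        mo = [m for m in ments if m.category == "model_signal"]
        assert pair_species_models(ab, sp, mo, window=3) == set()
        assert pair_species_models(ab, sp, mo, window=3) == oracle_pairs(ab, sp, mo, 3)

    def test_adjacent_phrases_cross_pair(self, resources, hierarchy):
        ab = make_abstract("1", "A title.",
                          "Rats received 6-OHDA; mice received MPTP.")
        ments = annotate_dictionary(ab, [resources.species, resources.models])
        sp = [m for m in ments if m.category == "species_signal"]
        mo = [m for m in ments if m.category == "model_signal"]
        got = pair_species_models(ab, sp, mo, window=3)
        assert got == oracle_pairs(ab, sp, mo, 3)
        assert {("Rat", "6-OHDA"), ("Mouse", "MPTP"),
                ("Rat", "MPTP"), ("Mouse", "6-OHDA")} == got

    def test_random_documents_match_oracle_and_windows_monotone(
        self, resources, hierarchy
    ):
        rng = random.Random(29)
        fillers = ["filler", "assay", "tissue", "values", "groups"]
        species_words = ["mice", "rats", "macaques"]
        model_words = ["MPTP", "rotenone", "paraquat"]
        for trial in range(60):
            words = []
            for _ in range(rng.randint(10, 40)):
                r = rng.random()
                if r < 0.12:
                    words.append(rng.choice(species_words))
                elif r < 0.24:
                    words.append(rng.choice(model_words))
                else:
                    words.append(rng.choice(fillers))
                if rng.random() < 0.2:
                    words.append(rng.choice([",", ";", "."]))
            body = ""
            for w in words:
                body += w if w in ",;." and body else (" " + w if body else w)
            body = body.strip() + "."
            ab = make_abstract("1", "A title.", body)
            ments = annotate_dictionary(
                ab, [resources.species, resources.models]
            )
            sp = [m for m in ments if m.category == "species_signal"]
            mo = [m for m in ments if m.category == "model_signal"]
            prev = set()
            for w in (0, 1, 2, 3, 5):
                got = pair_species_models(ab, sp, mo, window=w)
                assert got == oracle_pairs(ab, sp, mo, w), f"trial {trial} w={w}"
                assert prev <= got  # monotone in window size
                prev = got


class TestPhraseOrdinals:
    def test_title_is_leading_phrase(self, resources):
        ab = make_abstract("1", "A title.", "One phrase, two phrases.")
        phrases = phrase_ordinals(ab)
        doc = f"{ab.title} {ab.body}"
        assert doc[phrases[0][0] : phrases[0][1]].strip() == "A title."
        assert [p[2] for p in phrases] == list(range(len(phrases)))
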