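"""Abstract-level species and disease-model extraction.

Species mentions are consolidated with two relevance rules — background /
first-sentence exclusion, and Human-only-in-conclusions exclusion — plus a
specificity hierarchy that keeps the most specific co-mentioned term.
Species and model mentions occurring within a phrase window of each other
are paired to make the species/model link explicit.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .annotation import Mention, body_offset, document_text
from .corpus_io import Abstract

DEFAULT_PAIR_WINDOW = 3

#: Fraction of trailing sentences treated as the "conclusion" region of an
#: unstructured abstract when applying the Human exclusion rule.
HUMAN_TAIL_FRACTION = 0.15


@dataclass
class SpeciesHierarchy:
    """Specific-term → general-term edges (e.g. Macaque → Non-human primate)."""

    edges: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term in self.edges:
            seen = {term}
            cur = term
            while cur in self.edges:
                cur = self.edges[cur]
                if cur in seen:
                    raise ValueError(f"hierarchy cycle through {term!r}")
                seen.add(cur)

    def ancestors(self, term: str) -> set[str]:
        out = set()
        cur = term
        while cur in self.edges:
            cur = self.edges[cur]
            out.add(cur)
        return out

    def reduce(self, terms: set[str]) -> set[str]:
        """Drop any term that has a strict descendant in the set."""
        dominated = set()
        for t in terms:
            dominated |= self.ancestors(t) & terms
        return set(terms) - dominated


def load_hierarchy(path_or_fh=None) -> SpeciesHierarchy:
    if path_or_fh is None:
        text = (resources.files("menagerie.data") / "species_hierarchy.tsv").read_text()
    elif hasattr(path_or_fh, "read"):
        text = path_or_fh.read()
    else:
        with open(path_or_fh, encoding="utf-8") as f:
            text = f.read()
    edges = {}
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    for row in reader:
        edges[row["specific"].strip()] = row["general"].strip()
    return SpeciesHierarchy(edges)


@dataclass
class SpeciesModelFacts:
    pmid: str
    species: set[str] = field(default_factory=set)
    models: set[str] = field(default_factory=set)
    pairs: set[tuple[str, str]] = field(default_factory=set)


# --- species exclusion rules --------------------------------------------

def _background_indices(abstract: Abstract) -> set[int]:
    if abstract.structured:
        return {s.index for s in abstract.sentences if s.section == "BACKGROUND"}
    return {0} if abstract.sentences else set()


def _conclusion_indices(abstract: Abstract) -> set[int]:
    if abstract.structured:
        return {s.index for s in abstract.sentences if s.section == "CONCLUSIONS"}
    n = len(abstract.sentences)
    if n == 0:
        return set()
    k = math.ceil(HUMAN_TAIL_FRACTION * n)
    return {s.index for s in abstract.sentences[n - k :]}


def extract_species(
    abstract: Abstract,
    mentions: Iterable[Mention],
    hierarchy: SpeciesHierarchy,
) -> set[str]:
    """Consolidated species set after the exclusion rules and hierarchy.

    Rule 1 drops a species found only in the background section (structured)
    or only in the first sentence (unstructured).  Rule 2 drops Human found
    only in the conclusion section (structured) or only within the final
    ``ceil(0.15 * n)`` sentences (unstructured).  Title mentions count as
    occurrences outside both excluded regions.  Finally the hierarchy keeps
    the most specific co-mentioned terms.
    """
    background = _background_indices(abstract)
    conclusion = _conclusion_indices(abstract)
    sentences_by_term: dict[str, set[int]] = {}
    for m in mentions:
        if m.category != "species_signal":
            continue
        sentences_by_term.setdefault(m.canonical, set()).add(m.sentence_index)
    kept = set()
    for term, idxs in sentences_by_term.items():
        body_idxs = {i for i in idxs if i >= 0}  # -1 = title, always allowed
        if -1 not in idxs and body_idxs and body_idxs <= background:
            continue
        if term == "Human" and -1 not in idxs and body_idxs and body_idxs <= conclusion:
            continue
        kept.add(term)
    return hierarchy.reduce(kept)


def extract_models(abstract: Abstract, mentions: Iterable[Mention]) -> set[str]:
    """Unique canonical model terms consolidated at the abstract level."""
    return {m.canonical for m in mentions if m.category == "model_signal"}


# --- phrase-window pairing ----------------------------------------------

_PHRASE_DELIM_RE = re.compile(r"[,;:.!?]")


def phrase_ordinals(abstract: Abstract) -> list[tuple[int, int, int]]:
    """Phrase segments over the title+body document space.

    A phrase is a maximal segment delimited by comma/semicolon/colon or a
    sentence boundary; the title is its own leading phrase run.  Returns
    ``(start, end, ordinal)`` triples covering the document.
    """
    doc = document_text(abstract)
    cuts = {0, len(doc)}
    for m in _PHRASE_DELIM_RE.finditer(doc):
        cuts.add(m.end())
    off = body_offset(abstract)
    for s in abstract.sentences:  # sentence boundaries always cut
        cuts.add(off + s.start)
        cuts.add(off + s.end)
    cuts.add(min(off, len(doc)))
    ordered = sorted(cuts)
    phrases = []
    ordinal = 0
    for a, b in zip(ordered, ordered[1:]):
        if doc[a:b].strip():
            phrases.append((a, b, ordinal))
            ordinal += 1
    return phrases


def _phrase_of(phrases: Sequence[tuple[int, int, int]], offset: int) -> int:
    for a, b, k in phrases:
        if a <= offset < b:
            return k
    return phrases[-1][2] if phrases else 0


def pair_species_models(
    abstract: Abstract,
    species_mentions: Sequence[Mention],
    model_mentions: Sequence[Mention],
    window: int = DEFAULT_PAIR_WINDOW,
) -> set[tuple[str, str]]:
    """Pairs (species, model) whose mentions lie within *window* phrases.

    Distance is the absolute difference of phrase ordinals over the whole
    document, counting across sentence boundaries; pairs are deduplicated at
    the abstract level.
    """
    phrases = phrase_ordinals(abstract)
    pairs = set()
    for sm in species_mentions:
        ks = _phrase_of(phrases, sm.start)
        for mm in model_mentions:
            km = _phrase_of(phrases, mm.start)
            if abs(ks - km) <= window:
                pairs.add((sm.canonical, mm.canonical))
    return pairs


def extract_species_model_facts(
    abstract: Abstract,
    mentions: Sequence[Mention],
    hierarchy: SpeciesHierarchy,
    window: int = DEFAULT_PAIR_WINDOW,
) -> SpeciesModelFacts:
    """Species, models and pairs for one abstract.

    Pairing only considers mentions of species that survived the exclusion
    rules and the hierarchy reduction, so an excluded background species
    never forms a pair.
    """
    species = extract_species(abstract, mentions, hierarchy)
    models = extract_models(abstract, mentions)
    sp_mentions = [
        m for m in mentions
        if m.category == "species_signal" and m.canonical in species
    ]
    mo_mentions = [m for m in mentions if m.category == "model_signal"]
    pairs = pair_species_models(abstract, sp_mentions, mo_mentions, window)
    return SpeciesModelFacts(abstract.pmid, species, models, pairs)
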