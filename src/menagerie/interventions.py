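"""Interventions / disease modifiers and functional-outcome reporting.

Interventions are gathered from chemical mentions, semantically filtered
concept mentions, gene mentions in the title, and an essential-interventions
lexicon; generic surfaces on the exclusion list are dropped, and database
identifiers collapse synonyms onto one entry.  By default every source is
restricted to the title, where entities are most likely to be the study's
actual intervention; ``scope="abstract"`` widens all sources to the whole
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .annotation import (
    INTERVENTION_SEMANTIC_TYPES,
    Lexicon,
    LexiconEntry,
    Mention,
    annotate_dictionary,
    packaged_lexicon,
)
from .corpus_io import Abstract


def default_exclusions() -> frozenset[str]:
    text = (resources.files("menagerie.data") / "intervention_exclusions.txt").read_text()
    return frozenset(
        line.strip().casefold()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def default_functional_terms() -> list[str]:
    text = (resources.files("menagerie.data") / "functional_outcomes.txt").read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


@dataclass
class InterventionFacts:
    pmid: str
    interventions: set[tuple[str, str, str]] = field(default_factory=set)
    functional_outcome: str = "NO"


def _identifier(m: Mention) -> str:
    """MeSH > NCBI Gene > UMLS CUI; chemical-first precedence."""
    for ns in ("MeSH", "NCBIGene", "UMLS"):
        if ns in m.ids:
            return f"{ns}:{m.ids[ns]}"
    return f"TERM:{m.canonical.casefold()}"


def extract_interventions(
    abstract: Abstract,
    mentions: Sequence[Mention],
    essential: Lexicon | None = None,
    exclusions: frozenset[str] | None = None,
    scope: str = "title",
) -> set[tuple[str, str, str]]:
    """Abstract-level (canonical, identifier, source) intervention set.

    Sources: ``chemical`` mentions, ``semantic`` concept mentions passing the
    ten-type semantic filter, ``title_gene`` gene mentions inside the title
    span, and ``essential`` lexicon matches.  Gene mentions outside the title
    never qualify regardless of *scope*.
    """
    if scope not in ("title", "abstract"):
        raise ValueError(f"unknown interventions scope {scope!r}")
    if essential is None:
        essential = packaged_lexicon("interventions_essential.tsv")
    if exclusions is None:
        exclusions = default_exclusions()
    title_end = len(abstract.title)

    def in_scope(m: Mention) -> bool:
        return scope == "abstract" or m.start < title_end

    candidates: list[tuple[Mention, str]] = []
    for m in mentions:
        if not in_scope(m):
            continue
        if m.category == "chemical":
            candidates.append((m, "chemical"))
        elif m.category not in ("species_signal", "model_signal", "gene") and (
            m.sem_types & INTERVENTION_SEMANTIC_TYPES
        ):
            candidates.append((m, "semantic"))
    # genes from the title only, regardless of scope
    for m in mentions:
        if m.category == "gene" and m.start < title_end:
            candidates.append((m, "title_gene"))
    for m in annotate_dictionary(abstract, [essential]):
        if in_scope(m):
            candidates.append((m, "essential"))

    out: dict[str, tuple[str, str, str]] = {}
    for m, source in candidates:
        if m.surface.strip().casefold() in exclusions:
            continue
        ident = _identifier(m)
        out.setdefault(ident, (m.canonical, ident, source))
    return set(out.values())


def detect_functional_outcome(
    abstract: Abstract, functional_terms: Iterable[str] | None = None
) -> str:
    """YES iff a functional-outcome term occurs in title+body (token bounded)."""
    terms = list(functional_terms) if functional_terms is not None else default_functional_terms()
    if not terms:
        raise ValueError("functional-outcome term list is empty")
    lex = Lexicon(
        "functional",
        entries=[
            LexiconEntry(
                surface=t, canonical=t, ids={},
                sem_types=frozenset(["Finding"]), category="other",
            )
            for t in terms
        ],
    )
    return "YES" if annotate_dictionary(abstract, [lex]) else "NO"


def extract_intervention_facts(
    abstract: Abstract,
    mentions: Sequence[Mention],
    essential: Lexicon | None = None,
    exclusions: frozenset[str] | None = None,
    functional_terms: Iterable[str] | None = None,
    scope: str = "title",
) -> InterventionFacts:
    return InterventionFacts(
        pmid=abstract.pmid,
        interventions=extract_interventions(
            abstract, mentions, essential, exclusions, scope
        ),
        functional_outcome=detect_functional_outcome(abstract, functional_terms),
    )
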