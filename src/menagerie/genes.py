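"""Gene/protein mention extraction, false-positive filtering, consolidation.

Annotator-derived gene mentions (dictionary matcher or an external adapter
such as a PubTator file) are augmented with a curated Parkinson's-disease
gene lexicon, cleaned of known false-positive classes, and consolidated to
one stable identifier per gene (NCBI Gene ID preferred over UMLS CUI).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .annotation import (
    GENE_SEMANTIC_TYPES,
    Lexicon,
    Mention,
    annotate_dictionary,
    packaged_lexicon,
)
from .corpus_io import Abstract

log = logging.getLogger(__name__)

#: surface matches an ordinal number (2nd, 3rd, 21st ...)
ORDINAL_RE = re.compile(r"^\d+(st|nd|rd|th)$", re.IGNORECASE)
#: surface looks like a confidence-interval fragment (CI 0.95, CI: 1.2)
CI_RE = re.compile(r"^ci[\s:=]*\d", re.IGNORECASE)

STOPLIST_FILES = (
    "gene_stoplist_common.txt",
    "gene_stoplist_nonspecific.txt",
    "gene_stoplist_crossmodule.txt",
    "gene_stoplist_training.txt",
)


def _read_list(filename: str) -> frozenset[str]:
    text = (resources.files("menagerie.data") / filename).read_text()
    return frozenset(
        line.strip().casefold()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def default_stoplist() -> frozenset[str]:
    out: set[str] = set()
    for fn in STOPLIST_FILES:
        out |= _read_list(fn)
    return frozenset(out)


@dataclass
class GeneFacts:
    pmid: str
    mentions: list[Mention] = field(default_factory=list)
    consolidated: set[tuple[str, str]] = field(default_factory=set)


def extract_gene_mentions(
    abstract: Abstract,
    mentions: Iterable[Mention],
    pd_lexicon: Lexicon | None = None,
) -> list[Mention]:
    """Union of annotator gene mentions and PD-dictionary matches.

    *mentions* should already carry the gene semantic-type filter where they
    come from a concept annotator.  Duplicate spans are merged, keeping the
    entry with the richer identifier map.
    """
    if pd_lexicon is None:
        pd_lexicon = packaged_lexicon("genes_pd.tsv")
    pool = [
        m for m in mentions
        if m.category == "gene" and (not m.sem_types or m.sem_types & GENE_SEMANTIC_TYPES)
    ]
    pool.extend(annotate_dictionary(abstract, [pd_lexicon]))
    by_span: dict[tuple[int, int], Mention] = {}
    for m in sorted(pool, key=lambda m: (m.start, m.end, -len(m.ids))):
        by_span.setdefault((m.start, m.end), m)
    return [by_span[k] for k in sorted(by_span)]


def filter_gene_false_positives(
    mentions: Iterable[Mention],
    stoplist: frozenset[str] | None = None,
) -> list[Mention]:
    """Drop ordinals, confidence intervals, and stoplisted surfaces.

    The stoplist unions the packaged lists: common-English collisions,
    non-specific genetic terms, cross-module terms, and curated training-set
    exclusions.  Filtering is a pure subset operation and idempotent.
    """
    if stoplist is None:
        stoplist = default_stoplist()
    out = []
    for m in mentions:
        surf = m.surface.strip().casefold()
        if ORDINAL_RE.match(surf) or CI_RE.match(surf):
            continue
        if surf in stoplist:
            continue
        out.append(m)
    return out


def consolidate_genes(mentions: Iterable[Mention]) -> set[tuple[str, str]]:
    """Abstract-level (canonical, identifier) set, NCBI Gene ID > UMLS CUI.

    Mentions carrying both identifiers are keyed by the NCBI id, so CUI-only
    and NCBI-bearing mentions of the same gene collapse onto one entry.
    Mentions without any identifier are excluded with a warning.
    """
    best: dict[str, tuple[int, str]] = {}  # canonical -> (rank, identifier)
    for m in mentions:
        if "NCBIGene" in m.ids:
            rank, ident = 0, f"NCBIGene:{m.ids['NCBIGene']}"
        elif "UMLS" in m.ids:
            rank, ident = 1, f"UMLS:{m.ids['UMLS']}"
        else:
            log.warning("%s: gene mention %r has no identifier; excluded",
                        m.pmid, m.surface)
            continue
        cur = best.get(m.canonical)
        if cur is None or rank < cur[0]:
            best[m.canonical] = (rank, ident)
    return {(canon, ident) for canon, (_, ident) in best.items()}


def extract_gene_facts(
    abstract: Abstract,
    mentions: Iterable[Mention],
    pd_lexicon: Lexicon | None = None,
    stoplist: frozenset[str] | None = None,
) -> GeneFacts:
    surviving = filter_gene_false_positives(
        extract_gene_mentions(abstract, mentions, pd_lexicon), stoplist
    )
    return GeneFacts(abstract.pmid, surviving, consolidate_genes(surviving))
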