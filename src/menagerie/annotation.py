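"""Concept mentions over abstracts.

The default annotator is a longest-match dictionary matcher over packaged
lexicons; pre-computed annotation files in PubTator format can substitute
for it through :func:`read_pubtator`.  Title and body share one coordinate
space: the title occupies ``[0, len(title))`` and body offsets are shifted
by ``len(title) + 1`` (one synthetic joining space).
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Sequence

from .corpus_io import Abstract
from .tokenize import fold_tokens, tokenize

log = logging.getLogger(__name__)

CATEGORIES = (
    "species_signal", "model_signal", "gene", "chemical", "disorder", "other",
)

#: UMLS semantic-type filter for gene/protein concept mentions.
GENE_SEMANTIC_TYPES = frozenset(
    {"Gene or Genome", "Amino Acid, Peptide, or Protein", "Enzyme"}
)

#: Semantic-type filter for intervention concept mentions.
INTERVENTION_SEMANTIC_TYPES = frozenset({
    "Amino Acid, Peptide, or Protein", "Biologically Active Substance",
    "Chemical", "Food", "Hazardous or Poisonous Substance", "Hormone",
    "Inorganic Chemical", "Organic Chemical", "Substance", "Vitamin",
})

#: UMLS semantic types belonging to the Disorders semantic group.
DISORDER_SEMANTIC_TYPES = frozenset({
    "Disease or Syndrome", "Mental or Behavioral Dysfunction",
    "Neoplastic Process", "Sign or Symptom", "Pathologic Function",
    "Congenital Abnormality", "Injury or Poisoning", "Finding",
})


@dataclass(frozen=True)
class Mention:
    pmid: str
    start: int
    end: int
    surface: str
    canonical: str
    ids: dict = field(default_factory=dict, hash=False, compare=False)
    sem_types: frozenset = field(default_factory=frozenset)
    category: str = "other"
    sentence_index: int = -1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("mention span must be non-empty")
        if not self.ids and not self.sem_types:
            raise ValueError("mention needs at least one identifier or semantic type")


@dataclass
class LexiconEntry:
    surface: str
    canonical: str
    ids: dict
    sem_types: frozenset
    category: str


@dataclass
class Lexicon:
    name: str
    entries: list[LexiconEntry]
    case_sensitive: bool = False

    def __post_init__(self):
        seen: dict[str, str] = {}
        for e in self.entries:
            key = e.surface if self.case_sensitive else e.surface.casefold()
            if key in seen and seen[key] != e.canonical:
                raise ValueError(
                    f"lexicon {self.name}: surface {e.surface!r} maps to both "
                    f"{seen[key]!r} and {e.canonical!r}"
                )
            if not e.canonical:
                raise ValueError(f"lexicon {self.name}: entry without canonical term")
            seen[key] = e.canonical


def _parse_ids(cell: str) -> dict:
    ids = {}
    for chunk in cell.split("|"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" not in chunk:
            raise ValueError(f"identifier {chunk!r} lacks a namespace prefix")
        ns, ident = chunk.split(":", 1)
        ids[ns] = ident
    return ids


REQUIRED_COLUMNS = ("surface", "canonical", "ids", "semtypes", "category")


def load_lexicon(path_or_fh, name: str | None = None,
                 case_sensitive: bool = False) -> Lexicon:
    """Load a TSV lexicon with columns surface/canonical/ids/semtypes/category.

    ``ids`` holds ``namespace:identifier`` pairs separated by ``|``;
    ``semtypes`` is ``|``-separated.  Duplicate surfaces with conflicting
    canonicals, missing columns, and empty files all raise ``ValueError``.
    """
    if hasattr(path_or_fh, "read"):
        text = path_or_fh.read()
        lex_name = name or "lexicon"
    else:
        with open(path_or_fh, encoding="utf-8") as f:
            text = f.read()
        lex_name = name or str(path_or_fh)
    with io.StringIO(text) as f:
        reader = csv.DictReader(f, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"lexicon {lex_name}: empty file")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"lexicon {lex_name}: missing columns {missing}")
        entries = []
        for row in reader:
            entries.append(LexiconEntry(
                surface=row["surface"].strip(),
                canonical=row["canonical"].strip(),
                ids=_parse_ids(row["ids"] or ""),
                sem_types=frozenset(
                    t.strip() for t in (row["semtypes"] or "").split("|") if t.strip()
                ),
                category=row["category"].strip() or "other",
            ))
    if not entries:
        raise ValueError(f"lexicon {lex_name}: no entries")
    return Lexicon(lex_name, entries, case_sensitive)


def packaged_lexicon(filename: str) -> Lexicon:
    """Load one of the lexicons shipped under ``menagerie/data``."""
    text = (resources.files("menagerie.data") / filename).read_text()
    return load_lexicon(io.StringIO(text), name=filename)


# --- document coordinate space ------------------------------------------

def document_text(abstract: Abstract) -> str:
    return f"{abstract.title} {abstract.body}"


def body_offset(abstract: Abstract) -> int:
    return len(abstract.title) + 1


def sentence_index_at(abstract: Abstract, doc_start: int) -> int:
    """Sentence ordinal for a document-space offset; -1 inside the title."""
    off = doc_start - body_offset(abstract)
    if off < 0:
        return -1
    idx = 0
    for s in abstract.sentences:
        if off < s.end:
            return s.index if off >= s.start else max(0, s.index - 1)
        idx = s.index
    return idx


# --- dictionary annotation ----------------------------------------------

def annotate_dictionary(
    abstract: Abstract, lexicons: Sequence[Lexicon]
) -> list[Mention]:
    """Token-boundary, longest-match-first dictionary annotation.

    Matching is case-insensitive unless the lexicon says otherwise and is
    greedy left-to-right: at each token the longest matching entry wins and
    consumes its tokens, so matches from one lexicon never overlap.  Mentions
    from different lexicons may overlap.
    """
    doc = document_text(abstract)
    tokens = [t for t in tokenize(doc) if t.is_word]
    mentions: list[Mention] = []
    for lex in lexicons:
        by_key: dict[tuple[str, ...], LexiconEntry] = {}
        max_len = 1
        for e in lex.entries:
            if lex.case_sensitive:
                key = tuple(t.text for t in tokenize(e.surface) if t.is_word)
            else:
                key = fold_tokens(e.surface)
            if key:
                by_key.setdefault(key, e)
                max_len = max(max_len, len(key))
        i = 0
        while i < len(tokens):
            hit = None
            for n in range(min(max_len, len(tokens) - i), 0, -1):
                window = tokens[i : i + n]
                key = tuple(
                    (t.text if lex.case_sensitive else t.folded()) for t in window
                )
                if key in by_key:
                    hit = (n, by_key[key])
                    break
            if hit is None:
                i += 1
                continue
            n, entry = hit
            start, end = tokens[i].start, tokens[i + n - 1].end
            mentions.append(Mention(
                pmid=abstract.pmid, start=start, end=end,
                surface=doc[start:end], canonical=entry.canonical,
                ids=dict(entry.ids), sem_types=entry.sem_types,
                category=entry.category,
                sentence_index=sentence_index_at(abstract, start),
            ))
            i += n
    mentions.sort(key=lambda m: (m.start, m.end, m.category))
    return mentions


# --- PubTator reader -----------------------------------------------------

_PUBTATOR_CATEGORY = {
    "Gene": "gene", "Chemical": "chemical", "Species": "species_signal",
    "Disease": "disorder",
}


def read_pubtator(fh: IO | str) -> list[Mention]:
    """Read PubTator plain-text annotations.

    Document blocks are ``pmid|t|title`` and ``pmid|a|abstract`` lines
    followed by tab-separated annotation lines
    ``pmid<TAB>start<TAB>end<TAB>surface<TAB>type<TAB>identifier``.
    Annotations whose span text disagrees with the surface column are
    rejected with a logged record-level error.
    """
    lines = (fh if isinstance(fh, str) else fh.read()).splitlines()
    docs: dict[str, dict[str, str]] = {}
    mentions: list[Mention] = []
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if "|t|" in line or "|a|" in line:
            pmid, kind, text = line.split("|", 2)
            docs.setdefault(pmid, {})[kind] = text
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            log.error("pubtator line %d: malformed annotation", ln)
            continue
        pmid, start, end, surface, ann_type = parts[:5]
        ident = parts[5] if len(parts) > 5 else ""
        start, end = int(start), int(end)
        doc = docs.get(pmid, {})
        full = f"{doc.get('t', '')} {doc.get('a', '')}"
        if full[start:end] != surface:
            log.error(
                "pubtator %s line %d: span text %r != surface %r",
                pmid, ln, full[start:end], surface,
            )
            continue
        category = _PUBTATOR_CATEGORY.get(ann_type, "other")
        ids = {}
        if ident:
            if ann_type == "Gene":
                ids["NCBIGene"] = ident
            elif ident.startswith(("MESH:", "MeSH:")):
                ids["MeSH"] = ident.split(":", 1)[1]
            elif ann_type == "Species":
                ids["NCBITaxon"] = ident
            else:
                ids["UMLS"] = ident
        mentions.append(Mention(
            pmid=pmid, start=start, end=end, surface=surface,
            canonical=surface, ids=ids,
            sem_types=frozenset([ann_type]), category=category,
        ))
    return mentions


def filter_by_semantic_type(
    mentions: Iterable[Mention], allowed: frozenset[str] | set[str]
) -> list[Mention]:
    """Keep mentions whose semantic types intersect *allowed* (stable order)."""
    allowed = frozenset(allowed)
    if not allowed:
        raise ValueError("empty allowed semantic-type set is ambiguous")
    return [m for m in mentions if m.sem_types & allowed]
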