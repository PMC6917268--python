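"""Abstract records: parsing, sentence segmentation, sections, metadata.

An :class:`Abstract` holds the title, body, and the body's sentences with
0-based half-open character ranges.  Structured abstracts carry NLM-style
section labels (BACKGROUND/METHODS/RESULTS/CONCLUSIONS) on their sentences.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import IO, Iterable

from lxml import etree

log = logging.getLogger(__name__)

SECTIONS = ("BACKGROUND", "METHODS", "RESULTS", "CONCLUSIONS")

#: MEDLINE label variance: map dialect labels onto the four canonical sections.
SECTION_DIALECT = {
    "BACKGROUND": "BACKGROUND",
    "OBJECTIVE": "BACKGROUND",
    "OBJECTIVES": "BACKGROUND",
    "AIM": "BACKGROUND",
    "AIMS": "BACKGROUND",
    "INTRODUCTION": "BACKGROUND",
    "PURPOSE": "BACKGROUND",
    "METHODS": "METHODS",
    "METHOD": "METHODS",
    "MATERIALS AND METHODS": "METHODS",
    "DESIGN": "METHODS",
    "RESULTS": "RESULTS",
    "RESULT": "RESULTS",
    "FINDINGS": "RESULTS",
    "CONCLUSIONS": "CONCLUSIONS",
    "CONCLUSION": "CONCLUSIONS",
    "INTERPRETATION": "CONCLUSIONS",
}

#: Publication types treated as secondary data; everything else (journal
#: articles, clinical trials, meta-analyses) is primary.
SECONDARY_PUB_TYPES = frozenset(
    {"Review", "Case Reports", "Editorial", "Letter", "Comment"}
)


@dataclass(frozen=True)
class Sentence:
    index: int
    start: int
    end: int
    text: str
    section: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("sentence range must be non-empty")


@dataclass
class Abstract:
    pmid: str
    title: str
    body: str
    sentences: list[Sentence] = field(default_factory=list)
    year: int = 0
    journal: str = ""
    pub_types: list[str] = field(default_factory=list)

    @property
    def structured(self) -> bool:
        return any(s.section is not None for s in self.sentences)

    def validate(self) -> None:
        prev_end = -1
        for i, s in enumerate(self.sentences):
            if s.index != i:
                raise ValueError(f"{self.pmid}: sentence index {s.index} != {i}")
            if s.start < 0 or s.end > len(self.body):
                raise ValueError(f"{self.pmid}: bad sentence range {s.start}:{s.end}")
            if s.start < prev_end:
                raise ValueError(f"{self.pmid}: overlapping sentences")
            if self.body[s.start : s.end] != s.text:
                raise ValueError(f"{self.pmid}: sentence text mismatch at {i}")
            prev_end = s.end

    # --- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "title": self.title,
            "body": self.body,
            "sentences": [
                {"index": s.index, "start": s.start, "end": s.end,
                 "text": s.text, "section": s.section}
                for s in self.sentences
            ],
            "year": self.year,
            "journal": self.journal,
            "pub_types": list(self.pub_types),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Abstract":
        return cls(
            pmid=d["pmid"], title=d["title"], body=d["body"],
            sentences=[Sentence(**s) for s in d["sentences"]],
            year=d.get("year", 0), journal=d.get("journal", ""),
            pub_types=list(d.get("pub_types", [])),
        )


# --- sentence segmentation ----------------------------------------------

def _load_abbreviations() -> frozenset[str]:
    text = (resources.files("menagerie.data") / "abbreviations.txt").read_text()
    return frozenset(
        line.strip().casefold()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )

_DEFAULT_ABBREV = _load_abbreviations()

_BOUNDARY_RE = re.compile(r"[.!?]+")
_TRAILING_TOKEN_RE = re.compile(r"[A-Za-z0-9.]+$")


def segment_sentences(
    text: str, abbreviations: Iterable[str] | None = None
) -> list[Sentence]:
    """Deterministic split on sentence-final punctuation.

    A candidate boundary is a run of ``.!?`` followed by whitespace-then-
    uppercase/digit or end of text.  Periods directly after a guard-listed
    abbreviation (``e.g.``, ``i.p.``, ``Fig.``) never split.  Offsets are
    0-based half-open into *text*; leading/trailing whitespace is excluded
    from each sentence's range.
    """
    abbrev = frozenset(a.casefold() for a in abbreviations) if abbreviations is not None else _DEFAULT_ABBREV
    boundaries = []
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        if end < len(text):
            # require whitespace then an uppercase letter, digit or quote
            rest = text[end:]
            stripped = rest.lstrip()
            if rest == stripped:  # no whitespace after punctuation
                continue
            if stripped and not (stripped[0].isupper() or stripped[0].isdigit()
                                 or stripped[0] in "\"'(“"):
                continue
        if "." in m.group(0):
            prefix = text[: m.start()]
            tok = _TRAILING_TOKEN_RE.search(prefix + ".")
            if tok:
                word = tok.group(0).rstrip(".").casefold()
                if word in abbrev or (len(word) == 1 and word.isalpha()):
                    continue
        boundaries.append(end)
    if not boundaries or boundaries[-1] < len(text.rstrip()):
        if text.strip():
            boundaries.append(len(text))
    sentences = []
    start = 0
    for b in boundaries:
        chunk = text[start:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        s0, e0 = start + lead, b - trail
        if e0 > s0:
            sentences.append(Sentence(len(sentences), s0, e0, text[s0:e0]))
        start = b
    return sentences


# --- structured-abstract sections ---------------------------------------

_INLINE_LABEL_RE = re.compile(
    r"^(?P<label>[A-Z][A-Z /&]{2,40}?):\s*"
)


def detect_sections(abstract: Abstract) -> Abstract:
    """Label sentences by the most recent preceding section heading.

    Recognizes inline ``HEADING:`` tokens at sentence starts (dialects mapped
    through :data:`SECTION_DIALECT`).  Sentences whose section was already
    assigned (e.g. from XML ``Label`` attributes) are kept.  With no labels at
    all, every section stays ``None`` and the abstract is unstructured.
    """
    seen: dict[str, int] = {}
    current = None
    new_sents = []
    any_explicit = any(s.section for s in abstract.sentences)
    for s in abstract.sentences:
        if s.section:  # explicit label from the record
            current = s.section
            new_sents.append(s)
            continue
        m = _INLINE_LABEL_RE.match(s.text)
        if m:
            label = SECTION_DIALECT.get(m.group("label").strip())
            if label:
                if label in seen:
                    log.warning(
                        "%s: duplicate section label %s; first occurrence wins",
                        abstract.pmid, label,
                    )
                else:
                    seen[label] = s.index
                current = label
        new_sents.append(replace(s, section=current) if current else s)
    # Unstructured unless at least one explicit or inline label was found
    if not any_explicit and not seen:
        return abstract
    abstract.sentences = new_sents
    return abstract


def classify_publication_type(pub_types: list[str]) -> str:
    """``secondary`` iff any type is a review/case report/editorial/letter."""
    if not pub_types:
        log.warning("empty publication type list; defaulting to primary")
        return "primary"
    if any(pt in SECONDARY_PUB_TYPES for pt in pub_types):
        return "secondary"
    return "primary"


def classification_context(abstract: Abstract) -> str:
    """Title plus the final two sentences — the span the outcome models see."""
    tail = abstract.sentences[-2:]
    parts = [abstract.title] + [s.text for s in tail]
    return " ".join(p for p in parts if p)


# --- parsing ------------------------------------------------------------

def parse_pubmed_xml(source: IO | str) -> tuple[list[Abstract], int]:
    """Parse a MEDLINE/PubMed ``PubmedArticleSet`` stream.

    Returns ``(abstracts, skipped)`` where *skipped* counts articles without
    an abstract.  Structured ``AbstractText Label=...`` blocks become section
    labels on the sentences of that block.  Records without a PMID are
    skipped with a log entry.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc
    abstracts: list[Abstract] = []
    skipped = 0
    for art in tree.iter("PubmedArticle"):
        pmid_el = art.find(".//PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            log.error("article without PMID skipped")
            continue
        pmid = pmid_el.text.strip()
        title = "".join(art.find(".//ArticleTitle").itertext()) if art.find(".//ArticleTitle") is not None else ""
        abst_el = art.find(".//Abstract")
        if abst_el is None:
            skipped += 1
            continue
        blocks = []  # (text, section label or None)
        for at in abst_el.findall("AbstractText"):
            text = "".join(at.itertext()).strip()
            if not text:
                continue
            label = SECTION_DIALECT.get((at.get("Label") or "").strip().upper())
            blocks.append((text, label))
        if not blocks:
            skipped += 1
            continue
        body_parts, sent_objs, offset = [], [], 0
        for text, label in blocks:
            if body_parts:
                offset += 1  # single joining space
            for s in segment_sentences(text):
                sent_objs.append(
                    Sentence(len(sent_objs), s.start + offset, s.end + offset,
                             s.text, label)
                )
            body_parts.append(text)
            offset += len(text)
        body = " ".join(body_parts)
        year = 0
        year_el = art.find(".//PubDate/Year")
        if year_el is not None and (year_el.text or "").strip().isdigit():
            year = int(year_el.text.strip())
        journal_el = art.find(".//Journal/Title")
        journal = journal_el.text.strip() if journal_el is not None and journal_el.text else ""
        pub_types = [
            "".join(pt.itertext()).strip()
            for pt in art.findall(".//PublicationTypeList/PublicationType")
        ]
        ab = Abstract(pmid, title.strip(), body, sent_objs, year, journal, pub_types)
        ab.validate()
        abstracts.append(detect_sections(ab))
    return abstracts, skipped


def parse_tsv(source: IO | str) -> tuple[list[Abstract], int]:
    """Parse the ``pmid<TAB>year<TAB>pubtypes(;-sep)<TAB>title<TAB>abstract`` dialect."""
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()
    abstracts, skipped = [], 0
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"line {ln}: expected 5 tab-separated fields")
        pmid, year, pub_types, title, body = parts
        if not body.strip():
            skipped += 1
            continue
        ab = Abstract(
            pmid=pmid.strip(), title=title.strip(), body=body,
            sentences=segment_sentences(body),
            year=int(year) if year.strip().isdigit() else 0,
            pub_types=[p.strip() for p in pub_types.split(";") if p.strip()],
        )
        ab.validate()
        abstracts.append(detect_sections(ab))
    return abstracts, skipped


def write_jsonl(abstracts: Iterable[Abstract], fh: IO) -> None:
    for ab in abstracts:
        fh.write(json.dumps(ab.to_dict()) + "\n")


def read_jsonl(fh: IO) -> list[Abstract]:
    out = []
    for line in fh:
        if line.strip():
            ab = Abstract.from_dict(json.loads(line))
            ab.validate()
            out.append(ab)
    return out
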