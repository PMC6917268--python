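"""Synthetic abstract corpora with exact, by-construction ground truth.

The generator assembles abstracts from packaged sentence templates with
planted species/model/gene/intervention mentions, label-consistent outcome
phrasing in the conclusion, optional functional-outcome sentences, and
distractor mentions in the regions the extraction rules exclude
(background/first-sentence species; Human in the trailing conclusion
region).  Gold offsets are recorded during assembly — never recovered by
re-searching the text — so extraction, classification, storage and
evaluation can all be tested offline against known truth.

The corpus emulates the contract structure of interventional
neurodegeneration abstracts, not real PubMed token statistics.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from .corpus_io import Abstract, Sentence
from .evaluation import GoldAnnotation, GoldItem, EvalReport, match_terms
from .pipeline import Resources, extract_facts
from .store_query import FactRecord
from .species_model import SpeciesHierarchy, load_hierarchy

YEARS = (2008, 2012, 2017)

#: (surface, canonical) pools drawn from the packaged lexicons
SPECIES_POOL = [
    ("mice", "Mouse"), ("rats", "Rat"), ("macaques", "Macaque"),
    ("marmosets", "Marmoset"), ("zebrafish", "Zebrafish"),
    ("drosophila", "Drosophila"), ("worms", "Worm"), ("cats", "Cat"),
    ("dogs", "Dog"), ("rabbits", "Rabbit"),
]
MODEL_POOL = [
    ("MPTP", "MPTP"), ("6-OHDA", "6-OHDA"),
    ("6-hydroxydopamine", "6-OHDA"), ("rotenone", "Rotenone"),
    ("paraquat", "Paraquat"), ("reserpine", "Reserpine"),
    ("haloperidol", "Haloperidol"),
    ("lipopolysaccharide", "Lipopolysaccharide induced model"),
    ("lactacystin", "Lactacystin"),
]
GENE_POOL = [
    ("alpha-synuclein", "SNCA", "NCBIGene:6622"),
    ("parkin", "PRKN", "NCBIGene:5071"),
    ("LRRK2", "LRRK2", "NCBIGene:120892"),
    ("PINK1", "PINK1", "NCBIGene:65018"),
    ("tyrosine hydroxylase", "TH", "NCBIGene:7054"),
    ("DJ-1", "PARK7", "NCBIGene:11315"),
    ("GBA", "GBA", "NCBIGene:2629"),
]
INTERVENTION_POOL = [
    ("levodopa", "levodopa", "MeSH:D007980"),
    ("selegiline", "selegiline", "MeSH:D012642"),
    ("rasagiline", "rasagiline", "MeSH:D000068556"),
    ("exenatide", "exenatide", "MeSH:D000077446"),
    ("caffeine", "caffeine", "MeSH:D002110"),
    ("melatonin", "melatonin", "MeSH:D008550"),
    ("curcumin", "curcumin", "MeSH:D003474"),
    ("minocycline", "minocycline", "MeSH:D008911"),
]
FUNCTIONAL_POOL = [
    "rotarod performance", "turning behavior", "gait analysis",
    "locomotor activity", "cylinder test",
]


@dataclass
class FixtureConfig:
    n_abstracts: int = 100
    seed: int = 0
    structured_fraction: float = 0.5
    #: corpus-level mix: the promising-heavy skew reported for the field
    label_distribution: dict[str, float] = field(default_factory=lambda: {
        "PROMISING": 0.76, "negative": 0.08, "mixed": 0.08, "other": 0.08,
    })
    #: probability that the conclusion carries label-consistent phrasing
    signal_strength: float = 1.0
    species_rate: float = 0.9
    model_rate: float = 0.8
    gene_rate: float = 0.7
    intervention_rate: float = 0.7
    functional_rate: float = 0.6
    #: probability of planting signals in rule-excluded regions
    distractor_rate: float = 0.2
    secondary_rate: float = 0.28

    def __post_init__(self):
        total = sum(self.label_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("label distribution must sum to 1")
        for name in ("structured_fraction", "signal_strength", "species_rate",
                     "model_rate", "gene_rate", "intervention_rate",
                     "functional_rate", "distractor_rate", "secondary_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_abstracts < 1:
            raise ValueError("n_abstracts must be positive")


@dataclass
class FixtureBundle:
    abstracts: list[Abstract]
    gold: list[GoldAnnotation]
    labels: dict[str, dict]

    def gold_for(self, pmid: str, module: str, level: str) -> list[GoldItem]:
        for g in self.gold:
            if g.pmid == pmid and g.module == module and g.level == level:
                return g.items
        return []

    def records(self) -> list[FactRecord]:
        """Gold-derived fact records (ground truth for store/query tests)."""
        out = []
        for ab in self.abstracts:
            meta = self.labels[ab.pmid]
            pairs = {
                tuple(i.term.split("|", 1))
                for i in self.gold_for(ab.pmid, "pair", "abstract")
            }
            out.append(FactRecord(
                pmid=ab.pmid, year=ab.year, data_class=meta["data_class"],
                species={i.term for i in self.gold_for(ab.pmid, "species", "abstract")},
                models={i.term for i in self.gold_for(ab.pmid, "model", "abstract")},
                pairs=pairs,
                genes={(i.term, i.identifier)
                       for i in self.gold_for(ab.pmid, "gene", "abstract")},
                interventions={(i.term, i.identifier, "essential")
                               for i in self.gold_for(ab.pmid, "intervention", "abstract")},
                outcome=meta["outcome"], functional=meta["functional"],
            ))
        return out


def _templates(name: str) -> list[str]:
    text = (resources.files("menagerie.data") / "templates" / f"{name}.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def _fill(template: str, values: dict[str, str]) -> tuple[str, dict[str, tuple[int, int]]]:
    """Fill ``{slot}`` placeholders, returning the text and slot spans."""
    out: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    i = 0
    while i < len(template):
        j = template.find("{", i)
        if j < 0:
            out.append(template[i:])
            break
        out.append(template[i:j])
        pos += j - i
        k = template.find("}", j)
        name = template[j + 1 : k]
        val = values[name]
        spans[name] = (pos, pos + len(val))
        out.append(val)
        pos += len(val)
        i = k + 1
    return "".join(out), spans


_CONCLUSION_TEMPLATES = {
    "PROMISING": "conclusion_promising",
    "negative": "conclusion_negative",
    "mixed": "conclusion_mixed",
    "other": "conclusion_other",
}

_SECTIONS = ("BACKGROUND", "METHODS", "RESULTS", "RESULTS",
             "CONCLUSIONS", "CONCLUSIONS")


def generate_corpus(config: FixtureConfig) -> FixtureBundle:
    """Deterministic synthetic corpus with gold computed during assembly."""
    rng = random.Random(config.seed)
    labels_sorted = sorted(config.label_distribution)
    weights = [config.label_distribution[l] for l in labels_sorted]
    hierarchy = load_hierarchy()
    abstracts: list[Abstract] = []
    gold: list[GoldAnnotation] = []
    labels: dict[str, dict] = {}
    for idx in range(config.n_abstracts):
        pmid = f"SYN{idx:06d}"
        label = rng.choices(labels_sorted, weights)[0]
        structured = rng.random() < config.structured_fraction
        year = rng.choice(YEARS)
        secondary = rng.random() < config.secondary_rate
        pub_types = ["Review"] if secondary else ["Journal Article"]

        species = rng.choice(SPECIES_POOL) if rng.random() < config.species_rate else None
        model = rng.choice(MODEL_POOL) if rng.random() < config.model_rate else None
        gene = rng.choice(GENE_POOL) if rng.random() < config.gene_rate else None
        intervention = (rng.choice(INTERVENTION_POOL)
                        if rng.random() < config.intervention_rate else None)
        functional = (rng.choice(FUNCTIONAL_POOL)
                      if rng.random() < config.functional_rate else None)
        distract_species = None
        distract_human = False
        if rng.random() < config.distractor_rate:
            choices = [s for s in SPECIES_POOL if s != species]
            distract_species = rng.choice(choices)
        if rng.random() < config.distractor_rate:
            distract_human = True

        # --- title ------------------------------------------------------
        slot_mentions: list[tuple[str, int, int, tuple]] = []  # kind, doc span, payload
        if intervention is not None:
            t_tpl = rng.choice(_templates("titles_intervention"))
            title, t_spans = _fill(t_tpl, {"intervention": intervention[0]})
            s, e = t_spans["intervention"]
            slot_mentions.append(("intervention", s, e, intervention))
        else:
            title = rng.choice(_templates("titles_plain"))

        # --- sentences ----------------------------------------------------
        sent_texts: list[str] = []
        sent_slots: list[dict[str, tuple[int, int]]] = []

        def add(tpl: str, values: dict[str, str] | None = None):
            text, spans = _fill(tpl, values or {})
            sent_texts.append(text)
            sent_slots.append(spans)

        if distract_species is not None:
            add(rng.choice(_templates("background_species")),
                {"species": distract_species[0]})
        else:
            add(rng.choice(_templates("background_plain")))
        if species is not None and model is not None:
            add(rng.choice(_templates("methods_species_model")),
                {"species": species[0], "model": model[0]})
        elif species is not None:
            add(rng.choice(_templates("methods_species")), {"species": species[0]})
        elif model is not None:
            add(rng.choice(_templates("methods_model")), {"model": model[0]})
        else:
            add(rng.choice(_templates("methods_plain")))
        if gene is not None:
            add(rng.choice(_templates("results_gene")), {"gene": gene[0]})
        else:
            add(rng.choice(_templates("results_plain")))
        if functional is not None:
            add(rng.choice(_templates("results_functional")),
                {"functional": functional})
        else:
            add(rng.choice(_templates("results_plain")))
        signal = rng.random() < config.signal_strength
        add(rng.choice(_templates(
            _CONCLUSION_TEMPLATES[label] if signal else "conclusion_other"
        )))
        if distract_human:
            add(rng.choice(_templates("final_human")))
        else:
            add(rng.choice(_templates("final_plain")))

        # --- assemble body with offsets ----------------------------------
        sentences: list[Sentence] = []
        body_parts: list[str] = []
        offset = 0
        doc_off = len(title) + 1
        for si, (text, spans) in enumerate(zip(sent_texts, sent_slots)):
            if si:
                offset += 1
            sentences.append(Sentence(
                si, offset, offset + len(text), text,
                _SECTIONS[si] if structured else None,
            ))
            for slot, (s, e) in spans.items():
                payload = {
                    "species": species, "model": model, "gene": gene,
                    "functional": functional,
                }.get(slot)
                if slot == "species" and si == 0:
                    payload = distract_species
                slot_mentions.append(
                    (slot, doc_off + offset + s, doc_off + offset + e, payload)
                )
            body_parts.append(text)
            offset += len(text)
        body = " ".join(body_parts)
        ab = Abstract(pmid, title, body, sentences, year=year,
                      pub_types=pub_types, journal="Synthetic J Neurodegener")
        ab.validate()
        abstracts.append(ab)

        # --- gold, by construction ---------------------------------------
        allowed_species = {species[1]} if species is not None else set()
        gold_species = hierarchy.reduce(allowed_species)
        gold_models = {model[1]} if model is not None else set()
        gold_pairs = (
            {(species[1], model[1])}
            if species is not None and model is not None else set()
        )
        gold.append(GoldAnnotation(pmid, "abstract", "species",
                                   [GoldItem(t) for t in sorted(gold_species)]))
        gold.append(GoldAnnotation(pmid, "abstract", "model",
                                   [GoldItem(t) for t in sorted(gold_models)]))
        gold.append(GoldAnnotation(pmid, "abstract", "pair",
                                   [GoldItem(f"{s}|{m}") for s, m in sorted(gold_pairs)]))
        gene_mentions = [
            GoldItem(payload[1], (s, e), payload[2])
            for kind, s, e, payload in slot_mentions if kind == "gene"
        ]
        gold.append(GoldAnnotation(pmid, "mention", "gene", gene_mentions))
        gold.append(GoldAnnotation(
            pmid, "abstract", "gene",
            [GoldItem(gene[1], None, gene[2])] if gene is not None else [],
        ))
        gold.append(GoldAnnotation(
            pmid, "abstract", "intervention",
            [GoldItem(intervention[1], None, intervention[2])]
            if intervention is not None else [],
        ))
        # The sampled label stays the gold outcome even when no signal phrase
        # was planted: the text then under-reports the study's conclusion,
        # which is exactly the noise signal_strength models.
        labels[pmid] = {
            "outcome": label,
            "functional": "YES" if functional is not None else "NO",
            "data_class": "secondary" if secondary else "primary",
            "year": year,
            "signal": signal,
        }
    return FixtureBundle(abstracts, gold, labels)


def bundle_checksum(bundle: FixtureBundle) -> str:
    """Stable serialization digest used by determinism tests."""
    payload = json.dumps(
        {
            "abstracts": [a.to_dict() for a in bundle.abstracts],
            "gold": [
                {
                    "pmid": g.pmid, "level": g.level, "module": g.module,
                    "items": [(i.term, i.span, i.identifier) for i in g.items],
                }
                for g in bundle.gold
            ],
            "labels": bundle.labels,
        },
        sort_keys=True,
    )
    import hashlib

    return hashlib.sha256(payload.encode()).hexdigest()


def end_to_end_check(
    bundle: FixtureBundle, res: Resources | None = None
) -> dict[str, EvalReport]:
    """Run annotate→extract→evaluate over the bundle; one report per module.

    With no distractors and full signal strength the extraction modules
    should reach F1 = 1.0 by construction.
    """
    res = res or Resources.packaged()
    totals = {m: [0, 0, 0] for m in ("species", "model", "pair", "gene",
                                     "intervention", "functional")}
    for ab in bundle.abstracts:
        facts = extract_facts(ab, res)
        checks = {
            "species": ([GoldItem(t) for t in facts.species_model.species],
                        bundle.gold_for(ab.pmid, "species", "abstract")),
            "model": ([GoldItem(t) for t in facts.species_model.models],
                      bundle.gold_for(ab.pmid, "model", "abstract")),
            "pair": ([GoldItem(f"{s}|{m}") for s, m in facts.species_model.pairs],
                     bundle.gold_for(ab.pmid, "pair", "abstract")),
            "gene": ([GoldItem(c, None, i) for c, i in facts.genes.consolidated],
                     bundle.gold_for(ab.pmid, "gene", "abstract")),
            "intervention": (
                [GoldItem(c, None, i) for c, i, _ in facts.interventions.interventions],
                bundle.gold_for(ab.pmid, "intervention", "abstract"),
            ),
        }
        for module, (pred, gold_items) in checks.items():
            tp, fp, fn = match_terms(pred, gold_items, "exact", "abstract")
            totals[module][0] += tp
            totals[module][1] += fp
            totals[module][2] += fn
        want = bundle.labels[ab.pmid]["functional"]
        got = facts.interventions.functional_outcome
        if got == want == "YES":
            totals["functional"][0] += 1
        elif got == "YES":
            totals["functional"][1] += 1
        elif want == "YES":
            totals["functional"][2] += 1
    return {
        m: EvalReport(tp, fp, fn, "exact", "abstract")
        for m, (tp, fp, fn) in totals.items()
    }


def labeled_corpus(bundle: FixtureBundle) -> list[tuple[Abstract, str]]:
    """(abstract, outcome gold) pairs for classifier training/evaluation."""
    return [(ab, bundle.labels[ab.pmid]["outcome"]) for ab in bundle.abstracts]
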