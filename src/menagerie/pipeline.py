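"""End-to-end extraction: annotate an abstract and run every fact module.

Bundles the packaged lexicons into a reusable :class:`Resources` object and
produces one :class:`~menagerie.store_query.FactRecord` per abstract, ready
for the relational store.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotation import Lexicon, Mention, annotate_dictionary, packaged_lexicon
from .corpus_io import Abstract, classify_publication_type
from .genes import extract_gene_facts, GeneFacts
from .interventions import extract_intervention_facts, InterventionFacts
from .species_model import (
    SpeciesHierarchy,
    SpeciesModelFacts,
    extract_species_model_facts,
    load_hierarchy,
)
from .store_query import FactRecord
from . import outcome as outcome_mod


@dataclass
class Resources:
    """Lexicons and rule tables shared by the extraction modules."""

    species: Lexicon
    models: Lexicon
    genes: Lexicon
    disorders: Lexicon
    essential: Lexicon
    hierarchy: SpeciesHierarchy
    pair_window: int = 3
    interventions_scope: str = "title"

    @classmethod
    def packaged(cls) -> "Resources":
        return cls(
            species=packaged_lexicon("species.tsv"),
            models=packaged_lexicon("models.tsv"),
            genes=packaged_lexicon("genes_pd.tsv"),
            disorders=packaged_lexicon("disorders.tsv"),
            essential=packaged_lexicon("interventions_essential.tsv"),
            hierarchy=load_hierarchy(),
        )

    def annotate(self, abstract: Abstract) -> list[Mention]:
        return annotate_dictionary(
            abstract,
            [self.species, self.models, self.genes, self.disorders,
             self.essential],
        )


@dataclass
class AbstractFacts:
    pmid: str
    species_model: SpeciesModelFacts
    genes: GeneFacts
    interventions: InterventionFacts
    outcome: str | None = None


def extract_facts(
    abstract: Abstract,
    resources: Resources | None = None,
    mentions: Sequence[Mention] | None = None,
    models: "outcome_mod.OutcomeModelPair | None" = None,
    outcome_config: "outcome_mod.OutcomeConfig | None" = None,
) -> AbstractFacts:
    """Run every extraction module over one abstract.

    *mentions* may carry externally computed annotations; by default the
    packaged dictionary annotator supplies them.  The outcome label is only
    filled when a fitted model pair is passed.
    """
    res = resources or Resources.packaged()
    ments = list(mentions) if mentions is not None else res.annotate(abstract)
    sm = extract_species_model_facts(abstract, ments, res.hierarchy,
                                     res.pair_window)
    gf = extract_gene_facts(abstract, ments, res.genes)
    iv = extract_intervention_facts(abstract, ments, res.essential,
                                    scope=res.interventions_scope)
    label = None
    if models is not None:
        label = outcome_mod.predict_overall_outcome(
            abstract, models, outcome_config
        )
    return AbstractFacts(abstract.pmid, sm, gf, iv, label)


def to_record(abstract: Abstract, facts: AbstractFacts) -> FactRecord:
    return FactRecord(
        pmid=abstract.pmid,
        year=abstract.year,
        data_class=classify_publication_type(abstract.pub_types),
        species=set(facts.species_model.species),
        models=set(facts.species_model.models),
        pairs=set(facts.species_model.pairs),
        genes=set(facts.genes.consolidated),
        interventions=set(facts.interventions.interventions),
        outcome=facts.outcome,
        functional=facts.interventions.functional_outcome,
    )
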