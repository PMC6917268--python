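# Methods

This note documents the models, rules, parameters and design choices in
`menagerie`, and what the synthetic-corpus tests do and do not show.

## Document model and coordinates

An abstract is a title plus a body segmented into sentences with 0-based,
half-open character ranges; slicing the body at a sentence's range
reproduces its text exactly. Mentions live in a single document coordinate
space: the title occupies `[0, len(title))` and body offsets are shifted
by `len(title) + 1` (one synthetic joining space), so one dictionary pass
covers "title and abstract".

Sentence segmentation splits on runs of `.!?` followed by whitespace and
an uppercase letter or digit, guarded by a packaged, user-extensible
abbreviation list (`e.g.`, `i.p.`, `Fig.`, single initials). No published
convention exists for sentence units in this setting; the splitter is
deterministic, total, and exposed so a different segmenter can be
substituted — the trailing-15% species rule below inherits whatever
segmentation is in force.

Structured-abstract sections come from MEDLINE `Label` attributes or
inline `HEADING:` tokens; a dialect table maps OBJECTIVE/AIM/PURPOSE to
BACKGROUND, CONCLUSION to CONCLUSIONS, and so on. Duplicate headings keep
the first occurrence and log a warning. Records lacking a year carry the
sentinel `year=0` and are excluded from trend queries rather than dropped
silently.

## Dictionary annotation

The default annotator is a case-insensitive, token-boundary-respecting,
longest-match-first dictionary matcher (greedy left-to-right; at equal
length the left-most match wins; matches within one lexicon never
overlap). Hyphen and slash are token boundaries, so `MPTP/probenecid`
and `6-hydroxydopamine` decompose into comparable tokens; an apostrophe
between alphanumerics stays inside its token (`Parkinson's`). The matcher
is verified against a brute-force oracle that tests every token span and
resolves overlaps greedily.

UMLS is license-restricted, so no UMLS data ships with the package. The
packaged lexicons carry curated exemplar mappings (species signals and
synonyms, PD model signals, a PD gene dictionary with NCBI Gene IDs,
essential interventions with MeSH descriptors, disorder terms) and are
TSV files a user can extend. External concept annotators are supported
through a PubTator-format reader rather than re-implemented; annotation
lines whose span text disagrees with the surface column are rejected with
a logged record-level error.

## Species and model rules

Two exclusion rules remove species terms judged irrelevant to the study:

1. a species found **only** in the background section (structured) or only
   in the first sentence (unstructured) is dropped — background text
   routinely summarizes prior findings across species;
2. **Human** found only in the conclusion section (structured) or only in
   the final `ceil(0.15 · n)` sentences (unstructured) is dropped —
   animal studies often close with speculation about patients. `ceil`
   makes the exclusion region conservative: at n ≤ 6 it is the last
   sentence only.

Title mentions count as occurrences outside both excluded regions. A
specificity hierarchy (packaged edge-list TSV: Macaque → Non-human
primate → Animal model, Mouse → Rodent → Animal model, ...) then removes
any term with a more specific co-mentioned descendant; generic terms
(Rodent, Animal model) are legitimate outputs when no descendant occurs.
The reduction is idempotent and order-independent.

Model signals are consolidated to canonical terms at the abstract level
(both `1-methyl-4-phenyl-1,2,3,6-tetrahydropyridine` and `MPTP` yield
MPTP). Generic genetic-alteration signals (transgenic, knockout, mutant,
overexpressing) map to a single "Genetically altered model" category; no
strain- or allele-level resolution is attempted.

**Species/model pairing.** "Phrase" has no standard definition here; this
package defines it as a maximal segment delimited by comma, semicolon,
colon or a sentence boundary, with phrase ordinals counted over the whole
document (title first, counting across sentence boundaries). A pair is
emitted when a species mention and a model mention lie within the window
(default 3 phrases, `--pair-window`). Only species that survived the
exclusion rules participate, so a background distractor never forms a
pair. Pairing is monotone in the window size and is checked against an
independent ordinal-counting oracle.

## Genes

Gene mentions are the union of annotator-derived mentions (filtered to
the UMLS types *Gene or Genome*; *Amino Acid, Peptide, or Protein*;
*Enzyme*) and PD gene-dictionary matches; duplicate spans merge, keeping
the richer identifier map. False-positive classes are removed by
token-anchored, case-insensitive regexes (ordinals `2nd`, confidence
intervals `CI 0.95`) and four packaged stoplists: common-English
collisions (*all*, *impact*), non-specific genetic terms (*transcription
factor*, *protein*, *candidate gene*), cross-module terms (*dopa*,
*mptp(+)*, *liraglutide*), and curated exclusions (*neurotrophin*,
*glutamate*, *acetylcysteine*). Filtering is a pure, idempotent subset
operation.

Consolidation produces one `(canonical, identifier)` entry per gene with
precedence NCBI Gene ID > UMLS CUI, so CUI-only and NCBI-bearing mentions
of the same gene collapse (e.g. *dopaminergic D1 receptor* and *D1
receptor* both land on NCBI Gene 24316). The packaged PD dictionary is a
curated seed, not a byte-exact reproduction of any external database
snapshot; taxon disambiguation of species-ambiguous identifiers is out of
scope — the lexicon stores whichever taxon's identifier the curator
assigned (24316 is the rat Drd1 record).

## Interventions and functional outcomes

Intervention candidates come from four sources: chemical mentions,
concept mentions passing a ten-type semantic filter (*Amino Acid, Peptide,
or Protein*; *Biologically Active Substance*; *Chemical*; *Food*;
*Hazardous or Poisonous Substance*; *Hormone*; *Inorganic Chemical*;
*Organic Chemical*; *Substance*; *Vitamin*), gene mentions **in the title
only**, and an essential-interventions lexicon. Title scoping reflects
the observation that title entities are the study's actual intervention,
whereas abstract bodies mention many incidental substances; all sources
are title-restricted by default (`--interventions-scope abstract` widens
everything except the gene source, which stays title-only by policy).
Generic surfaces on the exclusion list (*treatments*, *therapy*, ...) are
dropped. Identifier precedence is MeSH > NCBI Gene > UMLS CUI —
chemical-first, mirroring a MeSH-normalizing chemical annotator — and
deduplication is exact on the identifier, so *deprenyl* and *selegiline*
collapse onto MeSH D012642.

Functional-outcome detection is a token-bounded lexicon check over
title+body: YES iff any term matches. The packaged list covers clinical
scales (UPDRS), neurologic signs (bradykinesia), and animal assays
(rotarod performance, turning behavior); it is versioned and
user-extensible, and detection is monotone in the list.

## Outcome classifier

Features are extracted from the classification context (title + final two
sentences). N-grams are Porter-stemmed, lowercased unigrams and bigrams,
binary by default (a flag switches to counts; binary was chosen because
the contexts are short and repeated stems carry little extra signal).
Scope tags accompany, not replace, the plain unigrams. The Porter stemmer
is implemented from the classic 1980 algorithm and verified against the
published reference vocabulary pairs.

Change/polarity word lists ship as packaged files with 15 MORE, 34 LESS,
49 GOOD and 12 BAD entries, seeded from the printed exemplars (*increase*,
*alleviate*, *ameliorate*, *exacerbate*) and curated to those sizes; list
matching is stem-based so inflections match. The co-occurrence window is
4 word tokens, punctuation excluded, direction-agnostic
(`--cooc-window`, `--cooc-directional` analogues in the config). The
negation trigger list is exactly {*no*}, extensible via config.

Both SVMs are L2-regularized linear SVMs (LIBLINEAR family, hinge loss,
C = 1.0, balanced class weights — chosen as standard defaults since no
hyperparameters are prescribed for this design). Binary gold derivation
treats *mixed* as both positive and negative, as the combination table
implies. Training is deterministic given seed and data order; fitted
pairs persist as versioned JSON weight maps, and prediction is a plain
dot product over named features, independent of the training backend.

## Store and queries

Facts persist to a single-file SQLite store (desk-scale reproducibility;
no server), one table per module output, upserted idempotently by PMID
within one transaction. Conjunction queries return matching PMIDs with
per-year counts and proportions whose denominator is all records passing
the year/data-class filters alone — rows over a multi-valued field
(an abstract can mention several species) need not sum to 1. Publication
types {Review, Case Reports, Editorial, Letter, Comment} mark a record as
secondary data; everything else, including meta-analyses and clinical
trials, is primary. Trends report per-year counts and last/first fold
change, flagged undefined when the first-year count is zero. A pure
in-memory aggregator with the same contract backs differential tests.

## Evaluation harness

Precision = tp/(tp+fp), recall = tp/(tp+fn), F1 their harmonic mean, all
0 when the denominator is 0. Mention-level matching is one-to-one via
greedy left-to-right assignment (standard NER evaluation practice; the
choice matters only for many-to-many overlaps and is documented and
testable). Exact mode requires identical span boundaries; approximate
mode accepts any character overlap, so approximate scores dominate exact
scores. Abstract-level identity is the identifier when present, else the
case-folded term.

Cross-validation is stratified k-fold (default k = 10), repeated with a
seed ladder `seed + repeat`; per-label metrics and accuracy are computed
on each repeat's pooled predictions and averaged over repeats.
Stratification is the default with a `--no-stratify` escape hatch.
Features are deterministic per abstract and are computed once and reused
across folds. The majority-vote baseline predicts the modal label
everywhere; its accuracy equals the modal-label fraction by construction.

## Synthetic fixture corpus

The generator assembles abstracts from packaged sentence templates —
background, methods (species/model slots), results (gene and
functional-outcome slots), conclusion (outcome phrasing), final sentence —
with gold offsets recorded during assembly, never recovered by re-search,
and never by running the extractor (which would make the tests circular).
Defaults emulate the field's reported conditions: outcome mix 76%
PROMISING / 8% negative / 8% mixed / 8% other (the promising-heavy skew
of the published literature), years drawn from {2008, 2012, 2017},
28% secondary publications, half structured abstracts, and per-abstract
planting rates of 0.9/0.8/0.7/0.7/0.6 for
species/model/gene/intervention/functional mentions.

`signal_strength` is the probability that the conclusion carries
label-consistent phrasing; when it does not, the sampled label remains
the gold outcome while the text stays neutral, modelling under-reporting
noise. `distractor_rate` plants species in excluded regions
(first-sentence/background species; *patients* in the final conclusion
region), recorded as gold-negative because the exclusion rules define
them as irrelevant.

What passing these tests shows: the rules, pairing, normalization,
classifier plumbing, store and evaluation algebra are internally
consistent and lossless on text whose vocabulary the lexicons cover, with
linearly separable outcome phrasing. What it does not show: performance
on real PubMed abstracts, whose vocabulary, syntax, ambiguity (gene
homonyms, taxon ambiguity) and label noise the templates deliberately do
not model. Real-corpus scores require manually annotated gold data that
is not distributed with this package.

## Numerical and degenerate-input conventions

Offsets are 0-based half-open throughout. Empty text segments to an empty
sentence list; an empty classification context yields an empty feature
map with a warning; an empty publication-type list defaults to primary
with a warning; empty allowed-semantic-type sets, empty functional
lexicons, empty query predicate sets, and single-class training data are
errors rather than silent no-ops. Fold-change with a zero first-year
count is flagged undefined rather than infinite. All randomness flows
from explicit integer seeds; fixture generation, training and
cross-validation are reproducible run-to-run.

## Known limitations

- Dictionary matching cannot find surfaces absent from the lexicons; the
  PubTator adapter is the intended path for CRF/ML mention detection.
- No relation extraction; species/model links rest on phrase proximity.
- No taxon disambiguation for species-ambiguous gene identifiers.
- The trailing-15% rule depends on the sentence splitter in force.
- The packaged word lists and functional-outcome terms are curated seeds;
  domain transfer (e.g. to Alzheimer's disease) requires extending the
  model and intervention lexicons, which the TSV format supports.
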