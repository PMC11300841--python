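# Methods

## Problem setting

The workflow extracts sentence-level miRNA–disease associations from
abstracts and normalizes both entities: miRNA mentions to miRBase mature
(`MIMAT`) or precursor (`MI`) accessions, disease mentions to MeSH
descriptors. An association is a scored record
`(mirna_id, disease_id, doc_id, sentence, p)` where `p ∈ [0, 1]` is the
classifier's positive-class probability. Because associations are judged one
sentence at a time, relations expressed across sentence boundaries are out
of reach by construction; this is the dominant known source of missed
recall.

## miRNA grammar and linking

miRNA nomenclature is productive but regular. The recognizer is a grammar,
not a dictionary: optional three-letter species prefix, a family token from
{miR, mir, miRNA, microRNA, let, lin} (case-tolerant over a fixed
inventory), a family number, optional letter suffix (`miR-29a`), optional
paralog index (`miR-121-2`), optional arm (`-5p`/`-3p`). A family keyword is
mandatory, so gene symbols (GFAP, Stat3, BRCA1, LIN28) can never match;
`let`/`lin` additionally require a hyphen before the number to keep LIN28-
style symbols out. Generic mentions without a number ("miRNAs") are not
linkable and therefore not mentions. Enumerations sharing a stem
(`miR-200b/c`) expand to one mention per alternative.

Linking is deterministic lookup against a lexicon of canonical names:

* a missing species prefix defaults to the run's species context, `hsa`
  (human) by default — the target associations are human-disease centric;
* lowercase `mir-` is tried against precursor entries first and falls
  through to mature entries otherwise;
* an arm-less mention tries the bare name first (some matures, e.g.
  hsa-miR-133b, have no arm suffix), then `-5p`, then `-3p`. The 5p-first
  default reflects how arm-less names are conventionally resolved in curated
  examples (let-7b → hsa-let-7b-5p); `both_arms=True` returns every arm
  instead.

Unknown names yield an empty result, never a guess. The shipped fixture
lexicon contains the well-known human miRNAs used throughout the tests plus
50 synthetic `hsa-miR-7xxx-5p` entries; any miRBase-derived TSV with columns
`canonical_name, accession, type` drops in.

## Disease linking

Disease normalization is a dictionary linker: exact match after folding
(lowercase, punctuation → space, collapsed whitespace) against a
`term → MeSH id` table, plus in-document abbreviation expansion. Short forms
are harvested from `long form (SF)` patterns; the long form is the shortest
preceding word window that starts with the short form's initial and contains
its letters in order. A neural normalizer can replace this component behind
the same mention-in/mention-out interface; the dictionary keeps the pipeline
complete, fast and fully offline.

## Tagging model

The trainable NER path encodes sentences as IOB label sequences. Alignment
to subwords follows the first-subtoken convention: the first piece of every
word carries the word label, continuations are marked IGNORE and excluded
from the loss and from decoding. Decoding is total — `I-x` after `O`, after
a different class, or at sequence start is repaired to `B-x` — so any
predicted sequence yields valid mentions. Sentences longer than `max_length`
subtokens are truncated with a counted warning; abstract sentences fit
comfortably, so no sliding windows. There is no CRF layer and nested
entities are unsupported.

## Relation model

Each candidate pair is classified from the masked sentence: the pair's two
mentions are replaced by the atomic placeholders `@MIRNA$` and `@DISEASE$`
(registered with the tokenizer, never split); other mentions stay verbatim,
so a sentence with m miRNAs and d diseases yields exactly m·d distinct
instances. Masking prevents the classifier from memorizing entity names and
disambiguates multi-candidate sentences. Provenance (spans and surfaces) is
retained, so the original sentence is exactly reconstructible.

The classifier is a single linear layer over the pooled encoder state —
experiments with deeper heads are deliberately out of scope since the linear
head is the established best performer for this architecture family. Two
score heads exist: 2-logit softmax (default) and single-logit sigmoid; both
return the positive-class probability. Training modes:

* **STM** — one task, one head.
* **MTM** — one head per task over a shared encoder. Batch scheduling is
  proportional sampling: each epoch interleaves all tasks' batches in a
  seed-controlled shuffle, so large auxiliary corpora cannot drown the
  primary task. The returned classifier scores with the primary head only.

High-confidence filtering keeps `p ≥ 0.9`, boundary inclusive.

## The encoder

Tagger and classifier are encoder-agnostic; the shipped encoder is a
compact, fully deterministic numpy implementation:

* greedy longest-match wordpiece tokenizer; vocabulary = specials + atomic
  placeholders + all characters (with `##` continuations) + the most
  frequent training words, default size 512;
* token embeddings (width 32) followed by two layers
  `H ← tanh(H·W_s + 1·(mean(H)·W_c) + b)`; the mean term makes every state
  (including the CLS position used for pooling) contextual;
* linear heads are zero-initialized, so an untrained classifier is exactly
  uninformative (all scores tied at 0.5) and the first optimizer step breaks
  symmetry through the loss;
* plain backpropagation with Adam (lr 0.01–0.02, batch 8, 8 epochs by
  default); a full training run on the fixture corpora takes under a second
  on one CPU and is bit-reproducible per seed.

Pooling is CLS-position by default, mean-pooling by configuration.

## Distant supervision

Auto-labeling is doc-scoped closed-world: a single-pair sentence is positive
iff its normalized pair is asserted by the KB *for that PMID*, else a
negative candidate. PMID-scoping is stricter and less noisy than KB-global
matching, which remains available as a fallback (`pmid_scoped=False`).
Sentences with multiple miRNA or disease mentions, or with an
un-normalizable mention, are never auto-labeled: they go to the curation
queue with a reason (`multi_mirna`, `multi_disease`, `both`,
`unnormalized`). Counts reconcile by construction — every filtered sentence
becomes either auto-labeled instances or exactly one queue item. Corpus
merging collapses exact duplicates, lets a designated curated corpus
override auto labels, and raises on any other label conflict.

## Evaluation

* NER: entity-level precision/recall/F1 with exact (start, end, class)
  matching; micro scores pool tp/fp/fn over classes. The degenerate 0/0
  precision/recall is reported as 0 with supports alongside. A relaxed
  overlap mode exists but is non-default.
* RE: AUROC (Mann–Whitney pairwise concordance, ties ½ — verified against a
  brute-force O(n²) oracle in the tests) and AUPR as step-wise average
  precision, which avoids the optimism of trapezoidal interpolation. Both
  delegate to scikit-learn.
* Model selection: stratified k-fold cross-validation (stratified on the
  binary relation label; for NER fixtures, on sentence entity presence),
  reporting per-fold values with mean ± sd, deterministic per seed.

The hyperparameter-search hook is a contract (suggest / report / prune):
the built-in backend is budgeted random search with a median pruner that
halts a trial when an intermediate value falls below the median of earlier
trials at the same step; a pruned trial is never selected as best. Any
Bayesian backend honoring the same contract can replace it.

## Inference and comparison

Collection inference chains detection, normalization, masking and scoring.
Every candidate pair lands in exactly one of four buckets — emitted,
below-threshold, classified-negative, unnormalized — and the counters sum to
the candidate total, so losses are visible, not silent. Unique associations
deduplicate on `(MIMAT accession, MeSH id)` with per-pair evidence counts;
the per-pair score is the maximum over evidence sentences ("high confidence
exists somewhere"). Disease-centric comparison expands the disease of
interest to its MONDO subclass closure from an offline mapping table (never
a live ontology API; cycle-safe via a visited set), bridges UMLS references
to MeSH through the same table, and partitions unique pairs into novel /
overlap / reference-only; un-bridgeable reference pairs are reported in an
`unmapped` bucket rather than dropped.

## Synthetic fixtures and what they show

The generator emits abstract-like documents from the template
`<miRNA> <cue> in patients with <disease>.` with planted mentions, a KB
consistent with the planted positive sentences, configurable fractions of
multi-mention sentences (default 0.15) and filler sentences (default 0.2),
and balanced positive/negative cues (default p_positive 0.5). Separability
is deliberately lexical — positive and negative sentences draw from disjoint
cue phrase sets — so that a tiny encoder can reach high AUROC and
learning-sanity checks stay cheap and stable. Default problem sizes: 400
training / 120 held-out relation instances, 200 training / 60 held-out
tagged sentences, 40–50 document collections.

Consequently, passing tests demonstrate that the machinery is correct
(formats round-trip, labels conserve, learning works, thresholds are honored)
— not that the desk-scale models match the accuracy of large pretrained
encoders on real abstracts, whose lexical variety, anaphora and cross-
sentence relations the generator does not emulate. Scores on the synthetic
corpora (AUROC/F1 near 1.0) should be read as sanity ceilings, not
benchmarks.

## Known limitations

* Sentence-level only; cross-sentence associations are missed.
* Dictionary disease linking requires the term (or its in-document long
  form) to be in the lexicon; no fuzzy or embedding-based matching.
* No cross-species orthology in miRNA linking; no miRBase version
  migration.
* PubMed XML support covers the abstract subset (`PubmedArticle/
  MedlineCitation`); full-text JATS is out of scope.
* The published relation corpus can be verified only after a one-time
  manual download (see README); its sentence boundaries are taken as given,
  never re-split.
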