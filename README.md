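# mirtext

Extraction of normalized miRNA–disease associations from biomedical text.

MicroRNAs (miRNAs) regulate gene expression post-transcriptionally, and their
deregulation is implicated in cancers, epilepsies and neurodegenerative
diseases. Most newly reported miRNA–disease associations exist only as
sentences in abstracts, so curated resources (HMDD, miR2Disease, DisGeNET)
lag the literature. `mirtext` implements the full literature-mining workflow
that closes this gap, for bioinformaticians and curators who need machine-
readable `(miRBase accession, MeSH descriptor)` pairs with provenance:

1. **NER** — rule-based miRNA recognition (a grammar over miRBase
   nomenclature: species prefix, family token, number, letter/paralog
   suffixes, `-5p`/`-3p` arm) plus a trainable IOB token tagger for miRNA
   and disease mentions.
2. **Entity linking** — rule-based normalization of miRNA names to miRBase
   mature (`MIMAT…`) or precursor (`MI…`) accessions, and a dictionary MeSH
   linker with case/punctuation folding and in-document abbreviation
   expansion ("temporal lobe epilepsy (TLE)" → later "TLE" mentions inherit
   the long form's descriptor).
3. **Relation extraction** — each sentence with a candidate pair is masked
   (`@MIRNA$`, `@DISEASE$`) and scored by a sentence classifier: a single
   linear layer over a pooled encoder state, trained single-task (STM) or
   multi-task over a shared encoder with one head per auxiliary corpus (MTM).
   The positive-class probability `p = softmax(W h(s) + b)₁` is the
   association confidence; high-confidence output keeps `p ≥ 0.9`.

Training data is built by **distant supervision**: documents are annotated,
sentences with at least one miRNA and one disease mention are kept, and a
single-pair sentence is labeled positive iff its normalized pair is asserted
by a knowledge base for that PMID (closed-world negative otherwise).
Sentences with multiple miRNA or disease mentions are never auto-labeled;
they are routed to a curation queue for human review. Predicted association
sets can be compared against a reference database, with the disease of
interest expanded to its MONDO subclass closure and UMLS↔MeSH identifiers
bridged through an offline mapping table.

The package is encoder-agnostic: any model satisfying the two contracts
(text → per-subtoken vectors; text → pooled vector) can back the tagger and
the classifier. It ships with a compact trainable numpy encoder (embeddings
plus two context-mixing tanh layers, zero-initialized linear heads, Adam)
that trains in seconds on a CPU and is exactly reproducible per seed, plus a
synthetic-corpus generator with planted ground truth for every stage.

## Worked example

```python
from mirtext import synthetic, mirna_rules, tagging, relation_model
from mirtext.corpus_io import Sentence

mirbase, mesh = synthetic.generate_lexicons()
text = ("Overexpression of let-7b inhibited hippocampal glial cell "
        "activation, inflammatory response and epileptic seizures by "
        "targeting Stat3.")
mirnas = mirna_rules.normalize_mentions(text, mirbase)
diseases = tagging.detect_disease_mentions(text, mesh)
for m in mirnas + diseases:
    print(m.entity_class.value, repr(m.surface),
          [str(c) for c in m.normalized_ids])
[inst] = relation_model.make_instances(
    Sentence(text=text, mentions=mirnas + diseases), doc_id="32648622")
print(inst.masked_text)
```

prints

```
mirna 'let-7b' ['MIRBASE:MIMAT0000063']
disease 'epileptic seizures' ['MESH:D004827']
Overexpression of @MIRNA$ inhibited hippocampal glial cell activation, inflammatory response and @DISEASE$ by targeting Stat3.
```

The mention `let-7b` carries no arm suffix; the linker resolves it to the
5p mature product `MIMAT0000063` (hsa-let-7b-5p) by the documented arm
default. The masked sentence is what the relation classifier scores; a score
of, say, 0.97 would survive the 0.9 high-confidence filter and be emitted as
the association `(MIRBASE:MIMAT0000063, MESH:D004827)` with PMID 32648622
and the sentence as provenance.

The same pipeline runs from the shell:

```bash
mirtext generate --out demo --n-documents 30 --seed 7
mirtext build-corpus --documents demo/documents --kb demo/kb.tsv \
    --mirbase demo/mirbase_lexicon.tsv --mesh demo/mesh_lexicon.tsv \
    --out demo/relations.tsv --curation-out demo/curation.tsv
# {"auto_labeled": 56, "curation": 8, "positive": 24, "negative": 32}
mirtext train --corpus demo/relations.tsv --model-out demo/model --seed 7
# {"n_train": 45, "n_test": 11, "auroc": 1.0, "aupr": 1.0}
mirtext infer --documents demo/documents --model demo/model \
    --mirbase demo/mirbase_lexicon.tsv --mesh demo/mesh_lexicon.tsv \
    --out demo/associations.tsv --threshold 0.9
# {"associations": 30, "unique_pairs": 29, "candidates": 72,
#  "below_threshold": 0, "negative": 42, "unnormalized": 0}
```

The four counters always sum to the number of candidate pairs: nothing is
silently dropped.

## Layout

| module | contents |
| --- | --- |
| `mirtext.corpus_io` | document model, IOB/relation-TSV/BRAT/PubMed-XML IO, sentence segmentation, stratified splits |
| `mirtext.mirna_rules` | miRNA grammar, name parsing, miRBase linker |
| `mirtext.tagging` | IOB codec, subword alignment, trainable tagger, MeSH dictionary linker |
| `mirtext.distant_supervision` | KB loading, sentence filtering, auto-labeling, curation queue, corpus merging |
| `mirtext.relation_model` | entity masking, STM/MTM fine-tuning, scoring, hyperparameter-search hook |
| `mirtext.evaluation` | entity-level PRF, confusion counts, AUROC/AUPR, stratified k-fold CV |
| `mirtext.inference_compare` | collection inference, unique-pair aggregation, confidence filter, MONDO expansion, reference comparison |
| `mirtext.synthetic` | deterministic fixture generators and tiny model presets |
| `mirtext.encoder` | wordpiece tokenizer and the compact trainable encoder |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
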