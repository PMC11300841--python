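"""Synthetic corpora, lexicons and desk-scale model presets with known truth.

Everything the pipeline consumes can be generated here deterministically:
templated abstract-like documents with planted miRNA/disease mentions, a toy
knowledge base consistent with the planted positive sentences, lexically
separable relation corpora (positive and negative sentences use disjoint cue
phrases, so even a tiny encoder can learn the signal), and miRBase/MeSH
fixture lexicons.

The generators emulate the *structure* of distant-supervision inputs — one
assertion per sentence, KB triples keyed by PMID, single- and multi-mention
sentences — not the lexical statistics of real abstracts. Separability is
lexical by design: it makes learning-sanity checks cheap and stable.

All outputs are bit-for-bit reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus_io import (ConceptID, Document, DocumentSource, EntityClass,
                        EntityMention, Namespace, RelationLabel, Sentence)
from .distant_supervision import KBAssociation, KnowledgeBase
from .mirna_rules import MirbaseLexicon
from .relation_model import MaskedInstance, RelationModelConfig, make_instances
from .tagging import MeshLexicon, TaggerConfig

# Name -> accession rows for mentions that recur throughout the test suite
# (well-known human miRNAs), followed by synthetic entries.
FIXTURE_MATURE_ENTRIES: dict[str, str] = {
    "hsa-miR-501-3p": "MIMAT0004774",
    "hsa-miR-501-5p": "MIMAT0002872",
    "hsa-miR-502-3p": "MIMAT0004775",
    "hsa-miR-877-5p": "MIMAT0004949",
    "hsa-miR-133b": "MIMAT0000770",
    "hsa-miR-221-3p": "MIMAT0000278",
    "hsa-let-7b-5p": "MIMAT0000063",
    "hsa-let-7b-3p": "MIMAT0004482",
    "hsa-miR-21-5p": "MIMAT0000076",
    "hsa-miR-29a-3p": "MIMAT0000086",
    "hsa-miR-200b-3p": "MIMAT0000318",
    "hsa-miR-200c-3p": "MIMAT0000617",
}

FIXTURE_PRECURSOR_ENTRIES: dict[str, str] = {
    "hsa-mir-21": "MI0000077",
    "hsa-mir-501": "MI0003185",
    "hsa-let-7b": "MI0000063",
}

FIXTURE_MESH_TERMS: dict[str, str] = {
    "epilepsy": "D004827",
    "epileptic seizures": "D004827",
    "seizures": "D012640",
    "temporal lobe epilepsy": "D004833",
    "Alzheimer disease": "D000544",
    "Alzheimer's disease": "D000544",
    "AD": "D000544",
    "Parkinson disease": "D010300",
    "Parkinson's disease": "D010300",
    "PD": "D010300",
    "glioma": "D005910",
    "hepatocellular carcinoma": "D006528",
}

_ADJECTIVES = ["cortical", "spinal", "hepatic", "renal", "gastric", "pulmonary",
               "cardiac", "ocular", "dermal", "thymic"]
_NOUNS = ["neuropathy", "carcinoma", "dystrophy", "fibrosis", "atrophy"]

POSITIVE_CUES = [
    "was significantly upregulated",
    "promoted tumor progression",
    "was markedly elevated",
    "drove inflammatory activation",
    "aggravated neuronal loss",
]
NEGATIVE_CUES = [
    "showed no association",
    "remained unchanged",
    "was not differentially expressed",
    "had no detectable effect",
    "was comparable to controls",
]

FILLER_SENTENCES = [
    "All experiments were performed in triplicate.",
    "Samples were processed according to the manufacturer's protocol.",
    "Statistical analysis was carried out with standard software.",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus generator."""

    n_documents: int = 50
    sentences_per_document: int = 3
    mirna_vocabulary: int = 30
    disease_vocabulary: int = 20
    positive_cues: list[str] = field(default_factory=lambda: list(POSITIVE_CUES))
    negative_cues: list[str] = field(default_factory=lambda: list(NEGATIVE_CUES))
    p_positive: float = 0.5
    p_multi_mention: float = 0.15
    p_filler: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.positive_cues or not self.negative_cues:
            raise ValueError("cue vocabularies must be non-empty")
        if not 0.0 < self.p_positive <= 1.0:
            raise ValueError("p_positive must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------

def generate_lexicons(config: GeneratorConfig | None = None
                      ) -> tuple[MirbaseLexicon, MeshLexicon]:
    """Fixture miRBase and MeSH lexicons: curated rows plus synthetic entries."""
    config = config or GeneratorConfig()
    mirbase = MirbaseLexicon()
    for name, acc in FIXTURE_MATURE_ENTRIES.items():
        mirbase.add(name, acc, "mature")
    for name, acc in FIXTURE_PRECURSOR_ENTRIES.items():
        mirbase.add(name, acc, "precursor")
    for i in range(max(config.mirna_vocabulary, 50)):
        number = 7001 + i
        mirbase.add(f"hsa-miR-{number}-5p", f"MIMAT09{number:05d}", "mature")

    mesh = MeshLexicon()
    for term, mesh_id in FIXTURE_MESH_TERMS.items():
        mesh.add(term, mesh_id)
    names = _disease_names()
    for i, name in enumerate(names):
        mesh.add(name, f"D09{i:04d}")
    return mirbase, mesh


def _disease_names() -> list[str]:
    return [f"{adj} {noun}" for adj in _ADJECTIVES for noun in _NOUNS]


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCorpus:
    """Documents with planted gold mentions plus the matching toy KB."""

    documents: list[Document]
    kb: KnowledgeBase
    #: (doc_id, sentence index) -> gold label; multi-mention sentences map to
    #: None (they must be curated, never auto-labeled).
    gold_labels: dict[tuple[str, int], RelationLabel | None]
    mirbase_lexicon: MirbaseLexicon
    mesh_lexicon: MeshLexicon
    config: GeneratorConfig

    def strip_annotations(self) -> list[Document]:
        """Deep-ish copy of the documents with mention lists cleared."""
        stripped = []
        for doc in self.documents:
            sentences = [Sentence(text=s.text, start=s.start, mentions=[])
                         for s in doc.sentences]
            stripped.append(Document(doc_id=doc.doc_id, source=doc.source,
                                     text=doc.text, sentences=sentences))
        return stripped


def generate_corpus(config: GeneratorConfig | None = None) -> SyntheticCorpus:
    """Generate documents, gold mentions, a consistent KB, and gold labels.

    Each content sentence follows the template ``<miRNA> <cue> in patients
    with <disease>.``; positive sentences draw a positive cue and their
    normalized pair is inserted into the KB under the document's id. A
    configurable fraction of sentences carries two miRNA mentions
    (``<m1> and <m2> <cue> ...``) and is gold-labeled as curation material.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    mirbase, mesh = generate_lexicons(config)

    mirna_names = [f"miR-{7001 + i}" for i in range(config.mirna_vocabulary)]
    disease_names = _disease_names()[: config.disease_vocabulary]

    documents: list[Document] = []
    kb = KnowledgeBase()
    gold_labels: dict[tuple[str, int], RelationLabel | None] = {}

    for d_i in range(config.n_documents):
        doc_id = str(90000001 + d_i)
        sentences: list[Sentence] = []
        pieces: list[str] = []
        offset = 0
        for s_i in range(config.sentences_per_document):
            if rng.random() < config.p_filler:
                text = FILLER_SENTENCES[rng.integers(len(FILLER_SENTENCES))]
                sentence = Sentence(text=text, start=offset, mentions=[])
            else:
                sentence, label = _content_sentence(
                    rng, config, mirna_names, disease_names, mirbase, mesh,
                    offset)
                if label is RelationLabel.POSITIVE:
                    mirna_id = sentence.mentions_of(EntityClass.MIRNA)[0] \
                        .normalized_ids[0]
                    disease_id = sentence.mentions_of(EntityClass.DISEASE)[0] \
                        .normalized_ids[0]
                    kb.add(KBAssociation(mirna_id=mirna_id,
                                         disease_id=disease_id,
                                         pmid=doc_id, source="toy_kb"))
                gold_labels[(doc_id, s_i)] = label
            sentences.append(sentence)
            pieces.append(sentence.text)
            offset += len(sentence.text) + 1
        text = " ".join(pieces)
        doc = Document(doc_id=doc_id, source=DocumentSource.PUBMED_ABSTRACT,
                       text=text, sentences=sentences)
        doc.validate()
        documents.append(doc)

    return SyntheticCorpus(documents=documents, kb=kb,
                           gold_labels=gold_labels, mirbase_lexicon=mirbase,
                           mesh_lexicon=mesh, config=config)


def _content_sentence(rng, config, mirna_names, disease_names, mirbase, mesh,
                      offset) -> tuple[Sentence, RelationLabel | None]:
    disease = disease_names[rng.integers(len(disease_names))]
    multi = rng.random() < config.p_multi_mention
    positive = rng.random() < config.p_positive
    cues = config.positive_cues if positive else config.negative_cues
    cue = cues[rng.integers(len(cues))]

    if multi:
        i, j = rng.choice(len(mirna_names), size=2, replace=False)
        m1, m2 = mirna_names[i], mirna_names[j]
        text = f"Both {m1} and {m2} {cue} in patients with {disease}."
        mention_specs = [(m1, text.index(m1)), (m2, text.index(m2, text.index(m1) + len(m1)))]
        label: RelationLabel | None = None
    else:
        name = mirna_names[rng.integers(len(mirna_names))]
        text = f"The level of {name} {cue} in patients with {disease}."
        mention_specs = [(name, text.index(name))]
        label = RelationLabel.POSITIVE if positive else RelationLabel.NEGATIVE

    mentions: list[EntityMention] = []
    for name, start in mention_specs:
        acc = mirbase.mature_accession(f"hsa-{name}-5p")
        mentions.append(EntityMention(
            start, start + len(name), name, EntityClass.MIRNA,
            [ConceptID(Namespace.MIRBASE, acc)] if acc else []))
    d_start = text.rindex(disease)
    mentions.append(EntityMention(
        d_start, d_start + len(disease), disease, EntityClass.DISEASE,
        [ConceptID(Namespace.MESH, mesh.lookup(disease))]))
    sentence = Sentence(text=text, start=offset, mentions=mentions)
    sentence.validate()
    return sentence, label


# ---------------------------------------------------------------------------
# Relation corpora (masked instances)
# ---------------------------------------------------------------------------

def relation_instances_from_corpus(corpus: SyntheticCorpus
                                   ) -> list[MaskedInstance]:
    """Gold-labeled masked instances from the single-pair sentences."""
    instances: list[MaskedInstance] = []
    for doc in corpus.documents:
        for s_i, sentence in enumerate(doc.sentences):
            label = corpus.gold_labels.get((doc.doc_id, s_i))
            if label is None:
                continue
            instances.extend(make_instances(sentence, doc_id=doc.doc_id,
                                            label=label))
    return instances


def generate_relation_corpus(n_instances: int, seed: int,
                             cue_offset: int = 0,
                             entity_prefix: str = "miR-"
                             ) -> list[MaskedInstance]:
    """A lexically separable masked-instance corpus, balanced in expectation.

    ``cue_offset`` rotates the cue lists so auxiliary tasks share structure
    but not the exact vocabulary; ``entity_prefix`` swaps the entity family
    (e.g. ``GENE`` for a gene-disease auxiliary task).
    """
    rng = np.random.default_rng(seed)
    pos = POSITIVE_CUES[cue_offset:] + POSITIVE_CUES[:cue_offset]
    neg = NEGATIVE_CUES[cue_offset:] + NEGATIVE_CUES[:cue_offset]
    diseases = _disease_names()
    instances: list[MaskedInstance] = []
    for i in range(n_instances):
        positive = bool(rng.random() < 0.5)
        cue = (pos if positive else neg)[rng.integers(len(pos))]
        name = f"{entity_prefix}{7001 + int(rng.integers(40))}"
        disease = diseases[rng.integers(len(diseases))]
        text = f"The level of {name} {cue} in patients with {disease}."
        m_start = text.index(name)
        d_start = text.rindex(disease)
        sentence = Sentence(text=text, mentions=[
            EntityMention(m_start, m_start + len(name), name,
                          EntityClass.MIRNA),
            EntityMention(d_start, d_start + len(disease), disease,
                          EntityClass.DISEASE),
        ])
        label = RelationLabel.POSITIVE if positive else RelationLabel.NEGATIVE
        masked = make_instances(sentence, doc_id=f"syn{seed}-{i}", label=label)
        instances.extend(masked)
    return instances


# ---------------------------------------------------------------------------
# NER fixture sentences
# ---------------------------------------------------------------------------

def generate_tagged_sentences(n_sentences: int, seed: int):
    """IOB-tagged sentences for NER training, derived from generate_corpus."""
    from .tagging import iob_encode

    per_doc = 2
    config = GeneratorConfig(
        n_documents=(n_sentences + per_doc - 1) // per_doc,
        sentences_per_document=per_doc, p_filler=0.15, seed=seed)
    corpus = generate_corpus(config)
    tagged = [iob_encode(s) for doc in corpus.documents for s in doc.sentences]
    return tagged[:n_sentences]


# ---------------------------------------------------------------------------
# Tiny model presets
# ---------------------------------------------------------------------------

def tiny_tagger_config(seed: int = 0, **overrides) -> TaggerConfig:
    """Desk-scale tagger preset: trains on one CPU in well under a minute."""
    defaults = dict(encoder_id="tiny", max_length=48, learning_rate=0.01,
                    epochs=8, batch_size=8, seed=seed, width=32, n_layers=2,
                    vocab_size=512)
    defaults.update(overrides)
    return TaggerConfig(**defaults)


def tiny_relation_config(seed: int = 0, **overrides) -> RelationModelConfig:
    """Desk-scale relation-classifier preset (2-layer, width 32)."""
    defaults = dict(max_length=48, learning_rate=0.02, epochs=8, batch_size=8,
                    seed=seed, width=32, n_layers=2, vocab_size=512,
                    head="softmax", pooling="cls")
    defaults.update(overrides)
    return RelationModelConfig(**defaults)
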