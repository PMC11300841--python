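"""Distant-supervision corpus construction from KB association triples.

Given documents annotated with miRNA and disease mentions and a knowledge
base of (miRNA, disease, PMID) association triples (HMDD/miR2Disease-style
exports), the builder:

1. keeps only sentences with at least one miRNA AND one disease mention,
2. auto-labels sentences with exactly one mention of each class — positive
   when the normalized pair is asserted by the KB for that document's PMID
   (optionally KB-wide), otherwise a negative candidate under the closed-world
   assumption,
3. routes every sentence with multiple miRNA or multiple disease mentions,
   and every sentence whose mention cannot be normalized, to a curation
   queue for human review — such sentences are never auto-labeled.

Counts reconcile by construction: every filtered sentence yields either
auto-labeled instances or one curation item, never both.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from .corpus_io import (ConceptID, Document, EntityClass, EntityMention,
                        Namespace, RelationInstance, RelationLabel, Sentence)


@dataclass(frozen=True)
class KBAssociation:
    """One KB triple: miRNA, disease and the PMID asserting the association."""

    mirna_id: ConceptID
    disease_id: ConceptID
    pmid: str
    source: str

    def __post_init__(self) -> None:
        if not self.pmid or not self.source:
            raise ValueError("pmid and source must be non-empty")


class KnowledgeBase:
    """Pair lookup over KB triples, PMID-scoped or global."""

    def __init__(self, associations: Sequence[KBAssociation] = ()):
        self.associations = list(associations)
        self._by_pmid: set[tuple[str, ConceptID, ConceptID]] = set()
        self._pairs: set[tuple[ConceptID, ConceptID]] = set()
        for assoc in self.associations:
            self.add(assoc, _append=False)

    def add(self, assoc: KBAssociation, _append: bool = True) -> None:
        if _append:
            self.associations.append(assoc)
        self._by_pmid.add((assoc.pmid, assoc.mirna_id, assoc.disease_id))
        self._pairs.add((assoc.mirna_id, assoc.disease_id))

    def contains(self, mirna_id: ConceptID, disease_id: ConceptID,
                 pmid: str | None = None,
                 pmid_scoped: bool = True) -> bool:
        if pmid_scoped:
            return pmid is not None and \
                (pmid, mirna_id, disease_id) in self._by_pmid
        return (mirna_id, disease_id) in self._pairs

    def __len__(self) -> int:
        return len(self.associations)


def load_kb(path: str | Path, source: str | None = None) -> KnowledgeBase:
    """Read a KB TSV with columns mirna, disease_mesh, pmid, source."""
    kb = KnowledgeBase()
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            kb.add(KBAssociation(
                mirna_id=ConceptID(Namespace.MIRBASE, row["mirna"]),
                disease_id=ConceptID(Namespace.MESH, row["disease_mesh"]),
                pmid=row["pmid"],
                source=source or row.get("source", "kb"),
            ))
    return kb


def write_kb(kb: KnowledgeBase, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["mirna", "disease_mesh", "pmid", "source"])
        for a in kb.associations:
            writer.writerow([a.mirna_id.accession, a.disease_id.accession,
                             a.pmid, a.source])
    return path


# ---------------------------------------------------------------------------
# Annotation and filtering
# ---------------------------------------------------------------------------

def annotate_documents(documents: Sequence[Document], mirna_detector,
                       disease_detector) -> list[Document]:
    """Attach miRNA and disease mentions to every sentence, in place.

    ``mirna_detector(sentence_text) -> mentions`` and
    ``disease_detector(sentence_text, context_text) -> mentions`` are any
    callables honoring the mention contract (the rule grammar, a trained
    tagger, or a dictionary lexicon).
    """
    for doc in documents:
        for sentence in doc.sentences:
            sentence.mentions = list(mirna_detector(sentence.text)) + \
                list(disease_detector(sentence.text, doc.text))
            sentence.validate()
    return list(documents)


def filter_sentences(documents: Sequence[Document]
                     ) -> list[tuple[str, Sentence]]:
    """Keep (doc_id, sentence) pairs with >=1 miRNA and >=1 disease mention."""
    kept: list[tuple[str, Sentence]] = []
    for doc in documents:
        for sentence in doc.sentences:
            if sentence.mentions_of(EntityClass.MIRNA) \
                    and sentence.mentions_of(EntityClass.DISEASE):
                kept.append((doc.doc_id, sentence))
    return kept


# ---------------------------------------------------------------------------
# Auto-labeling and curation queue
# ---------------------------------------------------------------------------

class CurationReason(str, Enum):
    MULTI_MIRNA = "multi_mirna"
    MULTI_DISEASE = "multi_disease"
    BOTH = "both"
    UNNORMALIZED = "unnormalized"


@dataclass
class CurationItem:
    doc_id: str
    sentence: Sentence
    reason: CurationReason


@dataclass
class LabelingResult:
    instances: list[RelationInstance]
    curation_queue: list[CurationItem]

    def counts(self) -> dict[str, int]:
        return {
            "auto_labeled": len(self.instances),
            "curation": len(self.curation_queue),
            "positive": sum(1 for i in self.instances
                            if i.label == RelationLabel.POSITIVE),
            "negative": sum(1 for i in self.instances
                            if i.label == RelationLabel.NEGATIVE),
        }


def _single_id(mention: EntityMention, namespace: Namespace) -> ConceptID | None:
    ids = [c for c in mention.normalized_ids if c.namespace == namespace]
    return ids[0] if len(ids) >= 1 else None


def label_instances(candidates: Sequence[tuple[str, Sentence]],
                    kb: KnowledgeBase,
                    pmid_scoped: bool = True) -> LabelingResult:
    """Auto-label single-pair sentences against the KB; queue the rest.

    Mentions must already carry normalized ids (miRBase for miRNA, MeSH for
    disease); an unnormalizable mention routes the sentence to the curation
    queue rather than producing a guessed label.
    """
    instances: list[RelationInstance] = []
    queue: list[CurationItem] = []
    for doc_id, sentence in candidates:
        mirnas = sentence.mentions_of(EntityClass.MIRNA)
        diseases = sentence.mentions_of(EntityClass.DISEASE)
        multi_m, multi_d = len(mirnas) > 1, len(diseases) > 1
        if multi_m or multi_d:
            reason = (CurationReason.BOTH if multi_m and multi_d
                      else CurationReason.MULTI_MIRNA if multi_m
                      else CurationReason.MULTI_DISEASE)
            queue.append(CurationItem(doc_id, sentence, reason))
            continue
        mirna, disease = mirnas[0], diseases[0]
        mirna_id = _single_id(mirna, Namespace.MIRBASE)
        disease_id = _single_id(disease, Namespace.MESH)
        if mirna_id is None or disease_id is None:
            queue.append(CurationItem(doc_id, sentence,
                                      CurationReason.UNNORMALIZED))
            continue
        in_kb = kb.contains(mirna_id, disease_id, pmid=doc_id,
                            pmid_scoped=pmid_scoped)
        label = RelationLabel.POSITIVE if in_kb else RelationLabel.NEGATIVE
        instances.append(RelationInstance(
            sentence=sentence, mirna=mirna, disease=disease, label=label,
            doc_id=doc_id, provenance="distant_supervision"))
    return LabelingResult(instances=instances, curation_queue=queue)


def write_curation_queue(queue: Sequence[CurationItem],
                         path: str | Path) -> Path:
    """Emit the curation queue as TSV for external annotation tools."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "sentence_text", "reason", "mentions"])
        for item in queue:
            mentions = ";".join(
                f"{m.entity_class.value}:{m.start}-{m.end}:{m.surface}"
                for m in item.sentence.mentions)
            writer.writerow([item.doc_id, item.sentence.text,
                             item.reason.value, mentions])
    return path


# ---------------------------------------------------------------------------
# Corpus merging
# ---------------------------------------------------------------------------

class MergeConflict(ValueError):
    def __init__(self, conflicts: list[tuple]):
        self.conflicts = conflicts
        super().__init__(
            f"{len(conflicts)} conflicting label(s) across sources: "
            + "; ".join(map(str, conflicts))
        )


def merge_corpora(*corpora: Sequence[RelationInstance],
                  curated_index: int | None = None
                  ) -> list[RelationInstance]:
    """Merge relation corpora, collapsing exact duplicates.

    Duplicate (sentence, pair) instances with the same label collapse to one.
    When ``curated_index`` names one corpus as curated, its label silently
    overrides a disagreeing auto label for the same instance (that is what
    curation is for). Any other label conflict raises :class:`MergeConflict`
    listing every conflicting instance.
    """
    merged: dict[tuple, tuple[RelationInstance, int]] = {}
    conflicts: list[tuple] = []
    for src, corpus in enumerate(corpora):
        for inst in corpus:
            key = inst.instance_id
            if key not in merged:
                merged[key] = (inst, src)
                continue
            kept, kept_src = merged[key]
            if kept.label == inst.label:
                continue
            if curated_index is not None and src == curated_index:
                merged[key] = (inst, src)
            elif curated_index is not None and kept_src == curated_index:
                pass  # curated label already wins
            else:
                conflicts.append((key, kept.label.value, inst.label.value))
    if conflicts:
        raise MergeConflict(conflicts)
    return [inst for inst, _src in merged.values()]
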