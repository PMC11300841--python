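"""Large-collection inference and comparison against a reference database.

``run_inference`` chains the trained/configured components over a document
collection: mention detection, normalization, pair enumeration with entity
masking, classification, and confidence filtering. Every candidate pair ends
in exactly one of four buckets — emitted, below-threshold, classified
negative, or dropped for failed normalization — and the four counters sum to
the number of candidates, so nothing is silently lost.

The comparison side mirrors how curated resources are matched: the disease
of interest is expanded to its MONDO subclass closure, the closure's MeSH and
UMLS cross-references select the relevant predicted and reference pairs, and
the report partitions unique (miRBase, MeSH) pairs into novel / overlap /
reference-only sets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus_io import (ConceptID, Document, EntityClass, Namespace, Sentence)
from .relation_model import (MaskedInstance, RelationClassifier,
                             make_instances, predict_proba)

logger = logging.getLogger(__name__)


@dataclass
class AssociationRecord:
    """One normalized, scored miRNA-disease assertion with its provenance."""

    mirna_id: ConceptID
    disease_id: ConceptID
    doc_id: str
    sentence_text: str
    score: float

    def pair(self) -> tuple[ConceptID, ConceptID]:
        return (self.mirna_id, self.disease_id)


@dataclass
class InferenceCounters:
    emitted: int = 0
    below_threshold: int = 0
    negative: int = 0
    unnormalized: int = 0

    @property
    def total_candidates(self) -> int:
        return (self.emitted + self.below_threshold + self.negative
                + self.unnormalized)


@dataclass
class InferenceResult:
    records: list[AssociationRecord]
    counters: InferenceCounters


def run_inference(documents: Sequence[Document], mirna_detector,
                  disease_detector, classifier: RelationClassifier,
                  threshold: float = 0.9,
                  positive_cutoff: float = 0.5) -> InferenceResult:
    """Extract scored associations from a document collection.

    Detectors follow the same contract as in corpus construction and must
    attach normalized ids to the mentions they return. A candidate pair is
    emitted only when the classifier scores it as positive
    (score >= ``positive_cutoff``), the score clears ``threshold``
    (inclusive), and both entities carry a normalized id. Per-document
    failures are logged and skipped; the run continues.
    """
    counters = InferenceCounters()
    records: list[AssociationRecord] = []
    for doc in documents:
        try:
            doc_records = _infer_document(doc, mirna_detector, disease_detector,
                                          classifier, threshold,
                                          positive_cutoff, counters)
        except Exception:  # noqa: BLE001 - contract: keep going
            logger.exception("inference failed for document %s", doc.doc_id)
            continue
        records.extend(doc_records)
    return InferenceResult(records=records, counters=counters)


def _infer_document(doc: Document, mirna_detector, disease_detector,
                    classifier: RelationClassifier, threshold: float,
                    positive_cutoff: float,
                    counters: InferenceCounters) -> list[AssociationRecord]:
    records: list[AssociationRecord] = []
    for sentence in doc.sentences:
        mirnas = list(mirna_detector(sentence.text))
        diseases = list(disease_detector(sentence.text, doc.text))
        if not mirnas or not diseases:
            continue
        annotated = Sentence(text=sentence.text, start=sentence.start,
                             mentions=mirnas + diseases)
        instances = make_instances(annotated, doc_id=doc.doc_id)
        pairs = [(m, d) for m in mirnas for d in diseases]
        scores = predict_proba(classifier, instances)
        for (mirna, disease), score in zip(pairs, scores):
            mirna_ids = [c for c in mirna.normalized_ids
                         if c.namespace == Namespace.MIRBASE]
            disease_ids = [c for c in disease.normalized_ids
                           if c.namespace == Namespace.MESH]
            if not mirna_ids or not disease_ids:
                counters.unnormalized += 1
                continue
            if score < positive_cutoff:
                counters.negative += 1
                continue
            if score < threshold:
                counters.below_threshold += 1
                continue
            counters.emitted += 1
            records.append(AssociationRecord(
                mirna_id=mirna_ids[0], disease_id=disease_ids[0],
                doc_id=doc.doc_id, sentence_text=sentence.text,
                score=float(score)))
    return records


# ---------------------------------------------------------------------------
# Aggregation and confidence filtering
# ---------------------------------------------------------------------------

@dataclass
class UniquePair:
    mirna_id: ConceptID
    disease_id: ConceptID
    evidence_count: int
    max_score: float


def aggregate_unique(records: Sequence[AssociationRecord]) -> list[UniquePair]:
    """Deduplicate on (miRBase id, MeSH id); per-pair evidence count and the
    maximum score across evidence sentences."""
    table: dict[tuple[ConceptID, ConceptID], UniquePair] = {}
    for record in records:
        key = record.pair()
        if key not in table:
            table[key] = UniquePair(record.mirna_id, record.disease_id, 0, 0.0)
        entry = table[key]
        entry.evidence_count += 1
        entry.max_score = max(entry.max_score, record.score)
    return sorted(table.values(),
                  key=lambda u: (u.mirna_id, u.disease_id))


def filter_high_confidence(records: Sequence[AssociationRecord],
                           cutoff: float = 0.9) -> list[AssociationRecord]:
    """Keep records with score >= cutoff (boundary inclusive)."""
    return [r for r in records if r.score >= cutoff]


def write_associations(records: Sequence[AssociationRecord],
                       path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["mirna_id", "disease_mesh_id", "doc_id", "sentence",
                         "score"])
        for r in records:
            writer.writerow([r.mirna_id.accession, r.disease_id.accession,
                             r.doc_id, r.sentence_text, f"{r.score:.6f}"])
    return path


# ---------------------------------------------------------------------------
# MONDO-based disease expansion
# ---------------------------------------------------------------------------

@dataclass
class MondoMapping:
    """Offline MONDO subclass + cross-reference table.

    Rows: (mondo_id, parent_mondo_id or "", mesh_id or "", umls_id or "").
    """

    children: dict[str, list[str]] = field(default_factory=dict)
    mesh_xref: dict[str, str] = field(default_factory=dict)
    umls_xref: dict[str, str] = field(default_factory=dict)
    known: set[str] = field(default_factory=set)

    def add_row(self, mondo_id: str, parent: str = "", mesh_id: str = "",
                umls_id: str = "") -> None:
        self.known.add(mondo_id)
        if parent:
            self.known.add(parent)
            self.children.setdefault(parent, []).append(mondo_id)
        if mesh_id:
            self.mesh_xref[mondo_id] = mesh_id
        if umls_id:
            self.umls_xref[mondo_id] = umls_id


def load_mondo_mapping(path: str | Path) -> MondoMapping:
    mapping = MondoMapping()
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            mapping.add_row(row["mondo_id"], row.get("parent_mondo_id", ""),
                            row.get("mesh_id", ""), row.get("umls_id", ""))
    return mapping


def expand_disease_concepts(root_concept: str,
                            mapping: MondoMapping) -> set[ConceptID]:
    """MeSH/UMLS ids of the transitive MONDO subclass closure (root included).

    Cycle-safe via a visited set; an unknown root is an error.
    """
    if root_concept not in mapping.known:
        raise KeyError(f"root concept {root_concept!r} absent from mapping")
    closure: set[str] = set()
    stack = [root_concept]
    while stack:
        node = stack.pop()
        if node in closure:
            continue
        closure.add(node)
        stack.extend(mapping.children.get(node, []))
    ids: set[ConceptID] = set()
    for node in closure:
        if node in mapping.mesh_xref:
            ids.add(ConceptID(Namespace.MESH, mapping.mesh_xref[node]))
        if node in mapping.umls_xref:
            ids.add(ConceptID(Namespace.UMLS, mapping.umls_xref[node]))
    return ids


# ---------------------------------------------------------------------------
# Comparison against a reference association database
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Partition of unique pairs: novel / overlap / reference-only.

    The three sets are pairwise disjoint; novel and overlap together are
    exactly the predicted pairs surviving the disease filter. Reference pairs
    whose disease id cannot be bridged into MeSH are reported separately,
    never silently dropped.
    """

    novel: set[tuple[ConceptID, ConceptID]]
    overlap: set[tuple[ConceptID, ConceptID]]
    reference_only: set[tuple[ConceptID, ConceptID]]
    unmapped: set[tuple[ConceptID, ConceptID]] = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return {"novel": len(self.novel), "overlap": len(self.overlap),
                "reference_only": len(self.reference_only),
                "unmapped": len(self.unmapped)}


def compare_with_reference(predicted: Sequence[UniquePair],
                           reference: Sequence[tuple[ConceptID, ConceptID]],
                           disease_filter: set[ConceptID] | None = None,
                           mapping: MondoMapping | None = None
                           ) -> ComparisonReport:
    """Compare predicted unique pairs with a reference database.

    ``disease_filter`` (e.g. from :func:`expand_disease_concepts`) restricts
    both sides to the diseases of interest. Reference diseases given as UMLS
    ids are bridged to MeSH through ``mapping``; un-bridgeable pairs land in
    the report's ``unmapped`` bucket.
    """
    umls_to_mesh: dict[str, str] = {}
    if mapping is not None:
        for mondo_id, umls in mapping.umls_xref.items():
            mesh = mapping.mesh_xref.get(mondo_id)
            if mesh:
                umls_to_mesh[umls] = mesh

    def in_filter(disease_id: ConceptID) -> bool:
        return disease_filter is None or disease_id in disease_filter

    pred_pairs = {
        (u.mirna_id, u.disease_id) for u in predicted
        if in_filter(u.disease_id)
    }
    ref_pairs: set[tuple[ConceptID, ConceptID]] = set()
    unmapped: set[tuple[ConceptID, ConceptID]] = set()
    for mirna_id, disease_id in reference:
        if disease_id.namespace == Namespace.MESH:
            if in_filter(disease_id):
                ref_pairs.add((mirna_id, disease_id))
        elif disease_id.namespace == Namespace.UMLS:
            mesh = umls_to_mesh.get(disease_id.accession)
            if mesh is None:
                unmapped.add((mirna_id, disease_id))
            else:
                bridged = ConceptID(Namespace.MESH, mesh)
                if in_filter(bridged) or in_filter(disease_id):
                    ref_pairs.add((mirna_id, bridged))
        else:
            unmapped.add((mirna_id, disease_id))
    return ComparisonReport(
        novel=pred_pairs - ref_pairs,
        overlap=pred_pairs & ref_pairs,
        reference_only=ref_pairs - pred_pairs,
        unmapped=unmapped,
    )
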