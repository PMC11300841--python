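"""End-to-end inference, aggregation, MONDO expansion, reference comparison."""

import numpy as np
import pytest

from mirtext import synthetic
from mirtext.corpus_io import ConceptID, Namespace, RelationLabel
from mirtext.inference_compare import (AssociationRecord, MondoMapping,
                                       aggregate_unique,
                                       compare_with_reference,
                                       expand_disease_concepts,
                                       filter_high_confidence, run_inference)
from mirtext.mirna_rules import normalize_mentions
from mirtext.relation_model import fine_tune_stm
from mirtext.tagging import detect_disease_mentions


@pytest.fixture(scope="module")
def pipeline():
    """Synthetic collection + classifier trained on its cue vocabulary."""
    corpus = synthetic.generate_corpus(
        synthetic.GeneratorConfig(n_documents=40, seed=31,
                                  p_multi_mention=0.0))
    train = synthetic.generate_relation_corpus(400, seed=7)
    clf = fine_tune_stm(train, [], synthetic.tiny_relation_config(seed=7))
    mirna_detector = lambda text: normalize_mentions(
        text, corpus.mirbase_lexicon)
    disease_detector = lambda text, ctx: detect_disease_mentions(
        text, corpus.mesh_lexicon, context_text=ctx)
    return corpus, clf, mirna_detector, disease_detector


def _record(m, d, doc="1", score=0.95):
    return AssociationRecord(
        mirna_id=ConceptID(Namespace.MIRBASE, m),
        disease_id=ConceptID(Namespace.MESH, d),
        doc_id=doc, sentence_text="s", score=score)


class TestRunInference:
    def test_planted_positives_recovered_negatives_suppressed(self, pipeline):
        corpus, clf, mirna_detector, disease_detector = pipeline
        result = run_inference(corpus.strip_annotations(), mirna_detector,
                               disease_detector, clf, threshold=0.5)
        predicted = {(r.mirna_id, r.disease_id, r.doc_id)
                     for r in result.records}
        planted_pos = {(a.mirna_id, a.disease_id, a.pmid)
                       for a in corpus.kb.associations}
        assert planted_pos <= predicted
        # negatives: single-pair sentences gold-labeled negative never emitted
        sentence_gold = {}
        for doc in corpus.documents:
            for i, s in enumerate(doc.sentences):
                label = corpus.gold_labels.get((doc.doc_id, i))
                if label is not None:
                    sentence_gold[s.text] = label
        for record in result.records:
            assert sentence_gold[record.sentence_text] == RelationLabel.POSITIVE

    def test_impossible_threshold_empty(self, pipeline):
        corpus, clf, mirna_detector, disease_detector = pipeline
        result = run_inference(corpus.strip_annotations(), mirna_detector,
                               disease_detector, clf, threshold=1.01)
        assert result.records == []
        assert result.counters.emitted == 0

    def test_document_without_diseases_yields_nothing(self, pipeline):
        _corpus, clf, mirna_detector, _dd = pipeline
        from mirtext.corpus_io import segment_document
        doc = segment_document("x", "The level of miR-7001 rose sharply.")
        result = run_inference([doc], mirna_detector,
                               lambda text, ctx: [], clf, threshold=0.5)
        assert result.records == []
        assert result.counters.total_candidates == 0

    def test_conservation_of_candidates(self, pipeline):
        corpus, clf, mirna_detector, disease_detector = pipeline
        result = run_inference(corpus.strip_annotations(), mirna_detector,
                               disease_detector, clf, threshold=0.9)
        counters = result.counters
        n_candidates = 0
        for doc in corpus.documents:
            for s in doc.sentences:
                from mirtext.corpus_io import EntityClass
                n_candidates += (len(s.mentions_of(EntityClass.MIRNA))
                                 * len(s.mentions_of(EntityClass.DISEASE)))
        assert counters.total_candidates == n_candidates
        assert counters.emitted == len(result.records)

    def test_unnormalized_pairs_counted_not_emitted(self, pipeline):
        corpus, clf, _md, disease_detector = pipeline
        # a detector that strips ids: every candidate must land in the
        # unnormalized bucket
        bare = lambda text: [
            m.__class__(m.start, m.end, m.surface, m.entity_class, [])
            for m in normalize_mentions(text, corpus.mirbase_lexicon)]
        result = run_inference(corpus.strip_annotations(), bare,
                               disease_detector, clf, threshold=0.5)
        assert result.records == []
        assert result.counters.unnormalized == \
            result.counters.total_candidates > 0

    def test_deterministic(self, pipeline):
        corpus, clf, mirna_detector, disease_detector = pipeline
        r1 = run_inference(corpus.strip_annotations(), mirna_detector,
                           disease_detector, clf, threshold=0.9)
        r2 = run_inference(corpus.strip_annotations(), mirna_detector,
                           disease_detector, clf, threshold=0.9)
        assert [(x.mirna_id, x.disease_id, x.score) for x in r1.records] == \
            [(x.mirna_id, x.disease_id, x.score) for x in r2.records]


class TestAggregation:
    def test_three_records_one_pair(self):
        records = [_record("MIMAT0000076", "D005910", doc=str(i),
                           score=0.5 + 0.1 * i) for i in range(3)]
        [unique] = aggregate_unique(records)
        assert unique.evidence_count == 3
        assert unique.max_score == pytest.approx(0.7)

    def test_empty_input(self):
        assert aggregate_unique([]) == []

    def test_counts_match_hand_tally(self):
        rng = np.random.default_rng(2)
        mirnas = [f"MIMAT000000{i}" for i in range(5)]
        diseases = [f"D00000{i}" for i in range(2)]
        records = [
            _record(mirnas[rng.integers(5)], diseases[rng.integers(2)],
                    doc=str(i))
            for i in range(40)
        ]
        unique = aggregate_unique(records)
        assert sum(u.evidence_count for u in unique) == 40
        assert len(unique) == len({(r.mirna_id, r.disease_id)
                                   for r in records})


class TestConfidenceFilter:
    def test_boundary_inclusive(self):
        records = [_record("MIMAT0000076", "D005910", score=s)
                   for s in (0.95, 0.9, 0.89999, 0.5)]
        kept = filter_high_confidence(records)
        assert [r.score for r in kept] == [0.95, 0.9]

    def test_conservation(self):
        rng = np.random.default_rng(1)
        records = [_record("MIMAT0000076", "D005910", score=float(s))
                   for s in rng.random(50)]
        kept = filter_high_confidence(records, cutoff=0.7)
        dropped = [r for r in records if r.score < 0.7]
        assert len(kept) + len(dropped) == 50


class TestMondoExpansion:
    @staticmethod
    def _tree():
        mapping = MondoMapping()
        # root epilepsy-like concept with a 3-level subclass tree
        mapping.add_row("MONDO:0005027", mesh_id="D004827",
                        umls_id="C0014544")
        mapping.add_row("MONDO:0005579", parent="MONDO:0005027",
                        mesh_id="D004833", umls_id="C0014556")
        mapping.add_row("MONDO:0015653", parent="MONDO:0005027")
        mapping.add_row("MONDO:0020310", parent="MONDO:0015653",
                        mesh_id="D065768")
        return mapping

    def test_leaf_with_single_xref(self):
        ids = expand_disease_concepts("MONDO:0020310", self._tree())
        assert ids == {ConceptID(Namespace.MESH, "D065768")}

    def test_three_level_closure(self):
        ids = expand_disease_concepts("MONDO:0005027", self._tree())
        assert ids == {
            ConceptID(Namespace.MESH, "D004827"),
            ConceptID(Namespace.UMLS, "C0014544"),
            ConceptID(Namespace.MESH, "D004833"),
            ConceptID(Namespace.UMLS, "C0014556"),
            ConceptID(Namespace.MESH, "D065768"),
        }

    def test_cycle_safe(self):
        mapping = self._tree()
        mapping.add_row("MONDO:0005027", parent="MONDO:0020310")  # cycle
        ids = expand_disease_concepts("MONDO:0005027", mapping)
        assert ConceptID(Namespace.MESH, "D004827") in ids

    def test_unknown_root_rejected(self):
        with pytest.raises(KeyError):
            expand_disease_concepts("MONDO:9999999", self._tree())


class TestComparison:
    @staticmethod
    def _pair(m, d, namespace=Namespace.MESH):
        return (ConceptID(Namespace.MIRBASE, m), ConceptID(namespace, d))

    def test_partition_on_small_example(self):
        predicted = aggregate_unique([
            _record("MIMAT0000001", "D000001"),
            _record("MIMAT0000002", "D000002"),
        ])
        reference = [self._pair("MIMAT0000002", "D000002"),
                     self._pair("MIMAT0000003", "D000003")]
        report = compare_with_reference(predicted, reference)
        assert report.counts() == {"novel": 1, "overlap": 1,
                                   "reference_only": 1, "unmapped": 0}

    def test_empty_reference_all_novel(self):
        predicted = aggregate_unique([_record("MIMAT0000001", "D000001")])
        report = compare_with_reference(predicted, [])
        assert report.counts()["novel"] == 1
        assert report.counts()["overlap"] == 0

    def test_umls_bridged_through_mapping(self):
        mapping = TestMondoExpansion._tree()
        predicted = aggregate_unique([_record("MIMAT0000001", "D004833")])
        reference = [self._pair("MIMAT0000001", "C0014556", Namespace.UMLS)]
        report = compare_with_reference(predicted, reference, mapping=mapping)
        assert report.counts()["overlap"] == 1

    def test_unbridgeable_reference_reported_not_dropped(self):
        predicted = aggregate_unique([_record("MIMAT0000001", "D000001")])
        reference = [self._pair("MIMAT0000009", "C9999999", Namespace.UMLS)]
        report = compare_with_reference(predicted, reference)
        assert report.counts()["unmapped"] == 1
        assert report.counts()["reference_only"] == 0

    def test_partition_property_fuzz(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            pred_pairs = {(f"MIMAT{i:07d}", f"D{i % 7:06d}")
                          for i in rng.integers(0, 15, size=10)}
            ref_pairs = {(f"MIMAT{i:07d}", f"D{i % 7:06d}")
                         for i in rng.integers(0, 15, size=10)}
            predicted = aggregate_unique(
                [_record(m, d) for m, d in pred_pairs])
            reference = [self._pair(m, d) for m, d in ref_pairs]
            report = compare_with_reference(predicted, reference)
            assert report.novel.isdisjoint(report.overlap)
            assert report.novel.isdisjoint(report.reference_only)
            assert report.overlap.isdisjoint(report.reference_only)
            assert len(report.novel) + len(report.overlap) == len(pred_pairs)
            assert report.novel | report.overlap == \
                {(u.mirna_id, u.disease_id) for u in predicted}

    def test_disease_filter_restricts_both_sides(self):
        mapping = TestMondoExpansion._tree()
        disease_filter = expand_disease_concepts("MONDO:0005027", mapping)
        predicted = aggregate_unique([
            _record("MIMAT0000001", "D004833"),  # in filter
            _record("MIMAT0000001", "D005910"),  # out of filter
        ])
        reference = [self._pair("MIMAT0000002", "D004827"),
                     self._pair("MIMAT0000002", "D999999")]
        report = compare_with_reference(predicted, reference,
                                        disease_filter=disease_filter)
        assert report.counts() == {"novel": 1, "overlap": 0,
                                   "reference_only": 1, "unmapped": 0}
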