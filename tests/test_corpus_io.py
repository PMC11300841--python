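"""Corpus formats: IOB files, the relation TSV dialect, documents, splits."""

import numpy as np
import pytest

from mirtext import corpus_io, synthetic
from mirtext.corpus_io import (ConceptID, EntityClass, EntityMention,
                               Namespace, ParseError, RelationInstance,
                               RelationLabel, Sentence, read_documents,
                               read_iob, read_pubmed_xml,
                               read_relation_corpus, read_standoff,
                               split_corpus, split_sentences, word_tokenize,
                               write_iob, write_relation_corpus,
                               write_standoff)
from mirtext.tagging import iob_encode


# ---------------------------------------------------------------------------
# IOB files
# ---------------------------------------------------------------------------

class TestIOBFiles:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "a.iob"
        path.write_text("The\tO\nmiR-21\tB-mirna\n\n")
        sentences = read_iob(path)
        assert len(sentences) == 1
        assert sentences[0].tokens == ["The", "miR-21"]
        assert sentences[0].labels == ["O", "B-mirna"]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.iob"
        path.write_text("")
        assert read_iob(path) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.iob"
        path.write_text("The\tO\nmiR-21\tB-mirna\textra\n")
        with pytest.raises(ParseError, match=":2"):
            read_iob(path)

    def test_unknown_label_prefix_rejected(self, tmp_path):
        path = tmp_path / "bad.iob"
        path.write_text("The\tQ-mirna\n")
        with pytest.raises(ParseError, match="label"):
            read_iob(path)

    def test_orphan_inside_tag_parses(self, tmp_path):
        """An I- tag after O is a legal file; repair is the decoder's job."""
        path = tmp_path / "orphan.iob"
        path.write_text("The\tO\nseizures\tI-disease\n\n")
        [sentence] = read_iob(path)
        assert sentence.labels == ["O", "I-disease"]

    def test_round_trip_small(self, tmp_path):
        sentences = synthetic.generate_tagged_sentences(3, seed=5)
        path = write_iob(sentences, tmp_path / "rt.iob")
        reread = read_iob(path)
        assert [s.tokens for s in reread] == [s.tokens for s in sentences]
        assert [s.labels for s in reread] == [s.labels for s in sentences]

    def test_all_o_block(self, tmp_path):
        sent = corpus_io.TaggedSentence(["no", "entities", "here"],
                                        ["O", "O", "O"])
        path = write_iob([sent], tmp_path / "o.iob")
        assert read_iob(path)[0].labels == ["O", "O", "O"]

    def test_double_write_byte_identical(self, tmp_path):
        sentences = synthetic.generate_tagged_sentences(100, seed=11)
        p1 = write_iob(sentences, tmp_path / "w1.iob")
        p2 = write_iob(sentences, tmp_path / "w2.iob")
        assert p1.read_bytes() == p2.read_bytes()

    def test_bad_label_refused_on_write(self, tmp_path):
        sent = corpus_io.TaggedSentence(["x"], ["B-mirna"])
        sent.labels = ["Bmirna"]
        with pytest.raises(ValueError):
            write_iob([sent], tmp_path / "x.iob")


# ---------------------------------------------------------------------------
# Relation TSV
# ---------------------------------------------------------------------------

def _instance(doc_id="12345", text="miR-21 causes glioma.", label=RelationLabel.POSITIVE,
              score=None):
    mirna = EntityMention(0, 6, "miR-21", EntityClass.MIRNA)
    disease = EntityMention(14, 20, "glioma", EntityClass.DISEASE)
    return RelationInstance(
        sentence=Sentence(text=text, mentions=[mirna, disease]),
        mirna=mirna, disease=disease, label=label, doc_id=doc_id, score=score)


class TestRelationCorpus:
    def test_round_trip(self, tmp_path):
        instances = [_instance(doc_id=str(i), score=0.25 * i / 4)
                     for i in range(5)]
        path = tmp_path / "rel.tsv"
        write_relation_corpus(instances, path)
        reread = read_relation_corpus(path)
        assert len(reread) == 5
        assert [i.instance_id for i in reread] == \
            [i.instance_id for i in instances]
        assert [i.label for i in reread] == [i.label for i in instances]

    def test_surface_mismatch_is_record_error(self, tmp_path):
        path = tmp_path / "rel.tsv"
        write_relation_corpus([_instance()], path)
        text = path.read_text().replace("miR-21\t", "miR-99\t", 1)
        path.write_text(text)
        with pytest.raises(ParseError, match="row 2"):
            read_relation_corpus(path)

    def test_duplicate_instance_rejected(self, tmp_path):
        path = tmp_path / "rel.tsv"
        inst = _instance()
        write_relation_corpus([inst, inst], path)
        with pytest.raises(ParseError, match="duplicate"):
            read_relation_corpus(path)

    def test_empty_corpus_is_header_only(self, tmp_path):
        path = write_relation_corpus([], tmp_path / "empty.tsv")
        lines = path.read_text().splitlines()
        assert lines == ["\t".join(corpus_io.RELATION_COLUMNS)]

    def test_scores_stable_across_writes(self, tmp_path):
        instances = [_instance(doc_id=str(i), score=1 / 3 if i % 2 else None)
                     for i in range(10)]
        p1 = write_relation_corpus(instances, tmp_path / "a.tsv")
        p2 = write_relation_corpus(instances, tmp_path / "b.tsv")
        assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# Documents
# ---------------------------------------------------------------------------

PUBMED_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>36454178</PMID>
      <Article>
        <Abstract>
          <AbstractText>The miR-501-3p was identified in AD brains.</AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>11111111</PMID>
      <Article>
        <Abstract>
          <AbstractText></AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>22222222</PMID>
      <Article/>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


class TestDocuments:
    def test_plain_two_sentences(self, tmp_path):
        (tmp_path / "doc1.txt").write_text(
            "miR-21 was elevated in glioma. Controls were unaffected.")
        [doc] = read_documents(tmp_path, "plain")
        assert doc.doc_id == "doc1"
        assert len(doc.sentences) == 2
        doc.validate()

    def test_pubmed_xml_pmid_and_skips(self, tmp_path):
        path = tmp_path / "batch.xml"
        path.write_text(PUBMED_XML)
        docs, skipped = read_pubmed_xml(path)
        assert [d.doc_id for d in docs] == ["36454178", "11111111"]
        assert docs[0].sentences[0].text.startswith("The miR-501-3p")
        # abstract element present but empty: a document with zero sentences
        assert docs[1].sentences == []
        # no abstract element at all: skipped with a warning count
        assert skipped == 1

    def test_sentence_offsets_consistent(self):
        text = ("Expression was measured (see Fig. 2 for details). "
                "Values rose vs. controls in C. elegans assays. Final point.")
        spans = split_sentences(text)
        assert [text[s:e] for s, e in spans] == [
            "Expression was measured (see Fig. 2 for details).",
            "Values rose vs. controls in C. elegans assays.",
            "Final point.",
        ]

    def test_word_tokenize_offsets(self):
        text = "Elevated miR-133b (p<0.05), then."
        tokens, spans = word_tokenize(text)
        assert all(text[s:e] == tok for tok, (s, e) in zip(tokens, spans))
        assert "miR-133b" in tokens


class TestStandoff:
    def test_round_trip(self, tmp_path):
        sent = Sentence(text="miR-21 causes glioma.", mentions=[
            EntityMention(0, 6, "miR-21", EntityClass.MIRNA),
            EntityMention(14, 20, "glioma", EntityClass.DISEASE)])
        write_standoff(sent, tmp_path / "d.txt", tmp_path / "d.ann")
        reread = read_standoff(tmp_path / "d.txt", tmp_path / "d.ann")
        assert reread.text == sent.text
        assert [(m.start, m.end, m.entity_class) for m in reread.mentions] == \
            [(m.start, m.end, m.entity_class) for m in sent.mentions]
        ann = (tmp_path / "d.ann").read_text()
        assert "T1\tmirna 0 6\tmiR-21" in ann


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

class TestSplitCorpus:
    @staticmethod
    def _corpus(n_pos, n_neg):
        return (
            [_instance(doc_id=f"p{i}") for i in range(n_pos)]
            + [_instance(doc_id=f"n{i}", label=RelationLabel.NEGATIVE)
               for i in range(n_neg)]
        )

    def test_exact_divisibility(self):
        instances = self._corpus(50, 50)
        manifest = split_corpus(instances, [0.8, 0.2], seed=3)
        by_split = {}
        for inst in instances:
            split = manifest.assignment[inst.instance_id]
            by_split.setdefault(split, []).append(inst.label)
        assert len(by_split["train"]) == 80
        assert len(by_split["test"]) == 20
        assert by_split["train"].count(RelationLabel.POSITIVE) == 40
        assert by_split["test"].count(RelationLabel.POSITIVE) == 10

    def test_same_seed_identical(self):
        instances = self._corpus(30, 20)
        m1 = split_corpus(instances, [0.6, 0.2, 0.2], seed=9)
        m2 = split_corpus(instances, [0.6, 0.2, 0.2], seed=9)
        assert m1.assignment == m2.assignment

    def test_partition_property(self):
        instances = self._corpus(33, 14)
        manifest = split_corpus(instances, [0.7, 0.3], seed=1)
        assert len(manifest.assignment) == len(instances)
        assert set(manifest.assignment) == {i.instance_id for i in instances}

    def test_label_proportions_preserved(self):
        """A 460/290 positive/negative corpus keeps its 61.3%/38.7% ratio."""
        instances = self._corpus(460, 290)
        manifest = split_corpus(instances, [1.0], seed=0,
                                split_names=["test"])
        labels = [i.label for i in instances
                  if manifest.assignment[i.instance_id] == "test"]
        assert len(labels) == 750
        prop = labels.count(RelationLabel.POSITIVE) / len(labels)
        assert prop == pytest.approx(0.6133, abs=1e-3)
        # and under a real split, within one instance per split
        manifest = split_corpus(instances, [0.8, 0.2], seed=0)
        for split, expected_n in (("train", 600), ("test", 150)):
            labels = [i.label for i in instances
                      if manifest.assignment[i.instance_id] == split]
            assert len(labels) == expected_n
            n_pos = labels.count(RelationLabel.POSITIVE)
            assert abs(n_pos - 460 * expected_n / 750) <= 1

    def test_rare_label_rejected(self):
        instances = self._corpus(10, 1)
        with pytest.raises(ValueError, match="fewer than"):
            split_corpus(instances, [0.5, 0.5], seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_corpus(self._corpus(5, 5), [0.5, 0.4], seed=0)


# ---------------------------------------------------------------------------
# Offset invariant after any read
# ---------------------------------------------------------------------------

def test_surface_equals_slice_everywhere():
    corpus = synthetic.generate_corpus(
        synthetic.GeneratorConfig(n_documents=20, seed=42))
    for doc in corpus.documents:
        doc.validate()
        for sentence in doc.sentences:
            for mention in sentence.mentions:
                assert sentence.text[mention.start:mention.end] == mention.surface
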