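"""Corpus formats and splits for the miRNA-disease extraction workflow.

This module owns the in-memory document model (documents, sentences, typed
entity mentions, relation instances) and every on-disk format the pipeline
touches:

* IOB/CoNLL two-column token files (token TAB label, blank-line sentences),
* a tab-separated relation-corpus dialect (one sentence + one miRNA mention +
  one disease mention + label per row),
* BRAT-style standoff (``.txt`` + ``.ann`` with ``T`` lines),
* a PubMed XML subset (``PubmedArticle/MedlineCitation`` abstracts),
* plain-text documents (one document per file).

All character offsets are 0-based and half-open. Mention offsets are relative
to their sentence; sentence offsets are relative to the document text.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

IOB_LABEL_RE = re.compile(r"^(O|[BI]-[A-Za-z_][A-Za-z0-9_]*)$")


class ParseError(ValueError):
    """Raised when an on-disk corpus file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class Namespace(str, Enum):
    MIRBASE = "MIRBASE"
    MESH = "MESH"
    UMLS = "UMLS"
    MONDO = "MONDO"


_NAMESPACE_SYNTAX = {
    Namespace.MIRBASE: re.compile(r"^(MIMAT\d+|MI\d+)$"),
    Namespace.MESH: re.compile(r"^[DC]\d+$"),
}


@dataclass(frozen=True, order=True)
class ConceptID:
    """A namespaced database identifier, e.g. ``MIRBASE:MIMAT0004774``."""

    namespace: Namespace
    accession: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        syntax = _NAMESPACE_SYNTAX.get(self.namespace)
        if syntax is not None and not syntax.match(self.accession):
            raise ValueError(
                f"accession {self.accession!r} is not valid for namespace "
                f"{self.namespace.value}"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.namespace.value}:{self.accession}"


class EntityClass(str, Enum):
    MIRNA = "mirna"
    DISEASE = "disease"


@dataclass
class EntityMention:
    """A typed span inside one sentence; ``surface`` equals the text slice."""

    start: int
    end: int
    surface: str
    entity_class: EntityClass
    normalized_ids: list[ConceptID] = field(default_factory=list)

    def validate_against(self, sentence_text: str) -> None:
        if not (0 <= self.start < self.end <= len(sentence_text)):
            raise ValueError(
                f"mention span [{self.start},{self.end}) outside sentence of "
                f"length {len(sentence_text)}"
            )
        if sentence_text[self.start:self.end] != self.surface:
            raise ValueError(
                f"surface {self.surface!r} != slice "
                f"{sentence_text[self.start:self.end]!r}"
            )


@dataclass
class Sentence:
    text: str
    start: int = 0
    mentions: list[EntityMention] = field(default_factory=list)

    def mentions_of(self, entity_class: EntityClass) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_class == entity_class]

    def validate(self) -> None:
        for m in self.mentions:
            m.validate_against(self.text)
        for cls in EntityClass:
            spans = sorted((m.start, m.end) for m in self.mentions_of(cls))
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping {cls.value} mentions at {s1} and {s2}"
                    )


class DocumentSource(str, Enum):
    PUBMED_ABSTRACT = "pubmed_abstract"
    PMC_FULLTEXT = "pmc_fulltext"
    OTHER = "other"


@dataclass
class Document:
    doc_id: str
    source: DocumentSource
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    def validate(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        prev_end = 0
        for sent in self.sentences:
            if sent.start < prev_end:
                raise ValueError("sentence spans overlap or are unordered")
            end = sent.start + len(sent.text)
            if end > len(self.text):
                raise ValueError("sentence extends past document text")
            if self.text[sent.start:end] != sent.text:
                raise ValueError("sentence text disagrees with document slice")
            prev_end = end
            sent.validate()


class RelationLabel(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


@dataclass
class RelationInstance:
    """One sentence with exactly one miRNA and one disease mention picked out."""

    sentence: Sentence
    mirna: EntityMention
    disease: EntityMention
    label: RelationLabel
    doc_id: str
    score: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.mirna.entity_class != EntityClass.MIRNA:
            raise ValueError("mirna mention must have class 'mirna'")
        if self.disease.entity_class != EntityClass.DISEASE:
            raise ValueError("disease mention must have class 'disease'")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")

    @property
    def instance_id(self) -> tuple:
        return (
            self.doc_id,
            self.sentence.text,
            self.mirna.start,
            self.mirna.end,
            self.disease.start,
            self.disease.end,
        )


@dataclass
class TaggedSentence:
    """Parallel token/IOB-label sequences with per-token character spans."""

    tokens: list[str]
    labels: list[str]
    char_spans: list[tuple[int, int]] = field(default_factory=list)
    text: str = ""

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError("tokens and labels must be parallel")
        if not self.text:
            self._rebuild_text()
        elif not self.char_spans:
            raise ValueError("text given without char_spans")

    def _rebuild_text(self) -> None:
        if not self.char_spans:
            spans, pos = [], 0
            for tok in self.tokens:
                spans.append((pos, pos + len(tok)))
                pos += len(tok) + 1
            self.char_spans = spans
        self.text = " ".join(self.tokens)


# ---------------------------------------------------------------------------
# Tokenization and sentence segmentation
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"[^\s]+")

# Sentence-final punctuation is split off words; internal hyphens/slashes kept
# so that miRNA names ("miR-501-3p", "miR-200b/c") stay single tokens.
_TRAILING_PUNCT = ".,;:!?)]}\"'"
_LEADING_PUNCT = "([{\"'"


def word_tokenize(text: str) -> tuple[list[str], list[tuple[int, int]]]:
    """Whitespace tokenization with leading/trailing punctuation split off.

    Returns parallel lists of tokens and 0-based half-open character spans.
    """
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for match in _WORD_RE.finditer(text):
        start, end = match.start(), match.end()
        while start < end and text[start] in _LEADING_PUNCT:
            tokens.append(text[start])
            spans.append((start, start + 1))
            start += 1
        trailing: list[tuple[str, int]] = []
        while end > start and text[end - 1] in _TRAILING_PUNCT:
            end -= 1
            trailing.append((text[end], end))
        if end > start:
            tokens.append(text[start:end])
            spans.append((start, end))
        for ch, pos in reversed(trailing):
            tokens.append(ch)
            spans.append((pos, pos + 1))
    return tokens, spans


#: Tokens after which a period does not end a sentence.
ABBREVIATIONS = frozenset({
    "fig", "figs", "al", "e.g", "i.e", "vs", "cf", "ca", "approx", "resp",
    "dr", "prof", "no", "sp", "spp", "subsp", "str", "var",
    # species abbreviations common in biomedical text
    "h", "m", "r", "c", "d", "s", "e", "p",
})

_BOUNDARY_RE = re.compile(r"[.?!]+[\"')\]]*\s+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence segmentation returning character spans.

    A run of ``.?!`` followed by whitespace ends a sentence unless the word
    before the period is a known abbreviation (``Fig.``, ``et al.``, species
    initials such as ``C. elegans``) or the next character is lowercase.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        end = match.start() + len(match.group().rstrip())
        nxt = match.end()
        if nxt < len(text) and text[nxt].islower():
            continue
        preceding = text[start:match.start()]
        last_word = preceding.rsplit(None, 1)[-1].lstrip("([{\"'") if preceding.split() else ""
        if last_word.rstrip(".").lower() in ABBREVIATIONS:
            continue
        if len(last_word.rstrip(".")) == 1 and last_word[:1].isupper():
            continue  # single-letter initial, e.g. "C. elegans"
        spans.append((start, end))
        start = nxt
    if start < len(text) and text[start:].strip():
        stripped = text.rstrip()
        spans.append((start, len(stripped)))
    return spans


def segment_document(doc_id: str, text: str,
                     source: DocumentSource = DocumentSource.OTHER) -> Document:
    sentences = [
        Sentence(text=text[s:e], start=s) for s, e in split_sentences(text)
    ]
    doc = Document(doc_id=doc_id, source=source, text=text, sentences=sentences)
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# IOB files
# ---------------------------------------------------------------------------

def read_iob(path: str | Path) -> list[TaggedSentence]:
    """Read a two-column (token TAB/space label) IOB file.

    Sentences are separated by blank lines. Labels must match
    ``O``/``B-<class>``/``I-<class>``; an ``I-`` tag without a matching
    ``B-`` is accepted here and repaired downstream by the IOB decoder.
    """
    sentences: list[TaggedSentence] = []
    tokens: list[str] = []
    labels: list[str] = []
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if tokens:
                    sentences.append(TaggedSentence(tokens, labels))
                    tokens, labels = [], []
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            token, label = parts
            if not IOB_LABEL_RE.match(label):
                raise ParseError(f"{path}:{lineno}: malformed IOB label {label!r}")
            tokens.append(token)
            labels.append(label)
    if tokens:
        sentences.append(TaggedSentence(tokens, labels))
    return sentences


def write_iob(sentences: Sequence[TaggedSentence], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for sent in sentences:
            for token, label in zip(sent.tokens, sent.labels):
                if not IOB_LABEL_RE.match(label):
                    raise ValueError(f"cannot serialize label {label!r}")
                handle.write(f"{token}\t{label}\n")
            handle.write("\n")
    return path


# ---------------------------------------------------------------------------
# Relation corpus TSV dialect
# ---------------------------------------------------------------------------

RELATION_COLUMNS = [
    "doc_id", "sentence_text", "mirna_start", "mirna_end", "mirna_surface",
    "disease_start", "disease_end", "disease_surface", "label", "score",
]


def read_relation_corpus(path: str | Path) -> list[RelationInstance]:
    """Read the tab-separated relation-corpus dialect (one relation per row)."""
    path = Path(path)
    instances: list[RelationInstance] = []
    seen: set[tuple] = set()
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames != RELATION_COLUMNS:
            raise ParseError(
                f"{path}: header {reader.fieldnames} does not match the "
                f"relation dialect {RELATION_COLUMNS}"
            )
        for rownum, row in enumerate(reader, start=2):
            text = row["sentence_text"]
            try:
                mirna = EntityMention(
                    int(row["mirna_start"]), int(row["mirna_end"]),
                    row["mirna_surface"], EntityClass.MIRNA)
                disease = EntityMention(
                    int(row["disease_start"]), int(row["disease_end"]),
                    row["disease_surface"], EntityClass.DISEASE)
                mirna.validate_against(text)
                disease.validate_against(text)
                label = RelationLabel(row["label"])
                score = float(row["score"]) if row["score"] else None
                instance = RelationInstance(
                    sentence=Sentence(text=text, mentions=[mirna, disease]),
                    mirna=mirna, disease=disease, label=label,
                    doc_id=row["doc_id"], score=score)
            except ValueError as exc:
                raise ParseError(f"{path}: row {rownum}: {exc}") from exc
            if instance.instance_id in seen:
                raise ParseError(
                    f"{path}: row {rownum}: duplicate instance {instance.instance_id}"
                )
            seen.add(instance.instance_id)
            instances.append(instance)
    return instances


def write_relation_corpus(instances: Iterable[RelationInstance],
                          path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(RELATION_COLUMNS)
        for inst in instances:
            score = "" if inst.score is None else f"{inst.score:.6f}"
            writer.writerow([
                inst.doc_id, inst.sentence.text,
                inst.mirna.start, inst.mirna.end, inst.mirna.surface,
                inst.disease.start, inst.disease.end, inst.disease.surface,
                inst.label.value, score,
            ])
    return path


def verify_corpus_counts(instances: Sequence[RelationInstance]) -> dict[str, int]:
    """Label tally of a relation corpus (used for corpus integrity checks)."""
    counts = {"positive": 0, "negative": 0, "unknown": 0}
    for inst in instances:
        counts[inst.label.value] += 1
    counts["total"] = len(instances)
    return counts


# ---------------------------------------------------------------------------
# BRAT-style standoff
# ---------------------------------------------------------------------------

_BRAT_T_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_standoff(txt_path: str | Path, ann_path: str | Path) -> Sentence:
    """Read a BRAT ``.txt`` + ``.ann`` pair into a single annotated sentence."""
    text = Path(txt_path).read_text(encoding="utf-8").rstrip("\n")
    mentions: list[EntityMention] = []
    for lineno, line in enumerate(
            Path(ann_path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line or not line.startswith("T"):
            continue
        match = _BRAT_T_RE.match(line)
        if not match:
            raise ParseError(f"{ann_path}:{lineno}: malformed T line")
        _tid, cls, start, end, surface = match.groups()
        mention = EntityMention(int(start), int(end), surface, EntityClass(cls))
        mention.validate_against(text)
        mentions.append(mention)
    sent = Sentence(text=text, mentions=mentions)
    sent.validate()
    return sent


def write_standoff(sentence: Sentence, txt_path: str | Path,
                   ann_path: str | Path) -> None:
    Path(txt_path).write_text(sentence.text + "\n", encoding="utf-8")
    lines = []
    for i, m in enumerate(sentence.mentions, start=1):
        lines.append(f"T{i}\t{m.entity_class.value} {m.start} {m.end}\t{m.surface}")
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""),
                              encoding="utf-8")


# ---------------------------------------------------------------------------
# Documents (plain text / PubMed XML subset)
# ---------------------------------------------------------------------------

def read_documents(path: str | Path, format: str) -> list[Document]:
    """Load documents and apply sentence segmentation.

    ``format`` is ``"plain"`` (one document per ``.txt`` file; the file stem
    is the document id) or ``"pubmed-xml"`` (``PubmedArticle`` records; the
    ``MedlineCitation/PMID`` is the id and ``Abstract/AbstractText`` the text).
    Records without abstract text are skipped; the skip count is available on
    the returned list via :func:`read_pubmed_xml`.
    """
    path = Path(path)
    if format == "plain":
        files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
        return [
            segment_document(f.stem, f.read_text(encoding="utf-8").strip())
            for f in files
        ]
    if format == "pubmed-xml":
        docs, _skipped = read_pubmed_xml(path)
        return docs
    raise ValueError(f"unknown document format {format!r}")


def read_pubmed_xml(path: str | Path) -> tuple[list[Document], int]:
    """Parse the PubMed XML abstract subset; returns (documents, n_skipped)."""
    tree = etree.parse(str(path))
    docs: list[Document] = []
    skipped = 0
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//MedlineCitation/PMID")
        if not pmid:
            skipped += 1
            continue
        fragments = [
            " ".join(node.itertext()).strip()
            for node in article.findall(".//Abstract/AbstractText")
        ]
        text = " ".join(f for f in fragments if f).strip()
        if not article.findall(".//Abstract/AbstractText"):
            skipped += 1
            continue
        docs.append(segment_document(pmid.strip(), text,
                                     DocumentSource.PUBMED_ABSTRACT))
    return docs, skipped


# ---------------------------------------------------------------------------
# Stratified splits
# ---------------------------------------------------------------------------

@dataclass
class SplitManifest:
    """Deterministic assignment of instance ids to named splits."""

    assignment: dict[tuple, str]
    seed: int
    fractions: dict[str, float]

    def ids_for(self, split: str) -> list[tuple]:
        return [k for k, v in self.assignment.items() if v == split]


DEFAULT_SPLIT_NAMES = ("train", "validation", "test")


def split_corpus(instances: Sequence[RelationInstance],
                 fractions: Sequence[float], seed: int,
                 split_names: Sequence[str] | None = None) -> SplitManifest:
    """Stratified partition of a relation corpus into named splits.

    Label proportions are preserved within one instance per split (largest
    remainder allocation inside each label stratum). Deterministic for a
    fixed seed.
    """
    fractions = list(fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    if split_names is None:
        split_names = list(DEFAULT_SPLIT_NAMES[:len(fractions)])
        if len(split_names) == 2:
            split_names = ["train", "test"]
    if len(split_names) != len(fractions):
        raise ValueError("one name per fraction required")

    by_label: dict[RelationLabel, list[RelationInstance]] = {}
    for inst in instances:
        by_label.setdefault(inst.label, []).append(inst)
    n_nonzero = sum(1 for f in fractions if f > 0)
    for label, group in by_label.items():
        if len(group) < n_nonzero:
            raise ValueError(
                f"label {label.value!r} has {len(group)} instances, fewer than "
                f"{n_nonzero} splits"
            )

    rng = np.random.default_rng(seed)
    assignment: dict[tuple, str] = {}
    for label in sorted(by_label, key=lambda l: l.value):
        group = sorted(by_label[label], key=lambda i: i.instance_id)
        order = rng.permutation(len(group))
        # largest-remainder apportionment of the stratum across splits
        exact = [f * len(group) for f in fractions]
        counts = [int(np.floor(x)) for x in exact]
        remainders = np.array(exact) - np.array(counts)
        short = len(group) - sum(counts)
        for idx in np.argsort(-remainders, kind="stable")[:short]:
            counts[idx] += 1
        pos = 0
        for name, count in zip(split_names, counts):
            for j in order[pos:pos + count]:
                assignment[group[j].instance_id] = name
            pos += count
    return SplitManifest(assignment=assignment, seed=seed,
                         fractions=dict(zip(split_names, fractions)))
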