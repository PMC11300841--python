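"""Model-based NER and dictionary-based disease linking.

IOB conventions: ``O`` for outside, ``B-<class>`` for the first token of an
entity, ``I-<class>`` for continuation tokens. Decoding is total: an ``I-x``
following ``O``, the sentence start, or a different class is repaired to
``B-x``, so any label sequence yields a valid set of mentions.

Subword alignment follows the usual first-subtoken convention: the first
subtoken of every word carries the word's label, continuation subtokens are
marked :data:`IGNORE` and excluded from the loss and from decoding.

Disease normalization is a dictionary linker over a MeSH term lexicon with
case/punctuation folding plus in-document abbreviation expansion ("temporal
lobe epilepsy (TLE)" makes later "TLE" mentions resolve to the long form's
descriptor). The linker interface accepts any drop-in normalizer.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .corpus_io import (ConceptID, EntityClass, EntityMention, Namespace,
                        Sentence, TaggedSentence, word_tokenize)
from .encoder import (AdamOptimizer, EncoderConfig, LinearHead, TinyEncoder,
                      WordpieceTokenizer, softmax, softmax_xent_grad)

logger = logging.getLogger(__name__)

IGNORE = "[IGNORE]"

_LABEL_RE = re.compile(r"^([BI])-(.+)$")


# ---------------------------------------------------------------------------
# IOB encoding / decoding
# ---------------------------------------------------------------------------

def iob_encode(sentence: Sentence,
               tokenizer: Callable = word_tokenize) -> TaggedSentence:
    """Token/IOB-label view of an annotated sentence.

    The first token overlapping a mention is labeled ``B-<class>``, further
    overlapping tokens ``I-<class>``. A mention whose boundary falls inside a
    token is aligned to the covering tokens (and logged), never dropped.
    """
    tokens, spans = tokenizer(sentence.text)
    labels = ["O"] * len(tokens)
    for mention in sorted(sentence.mentions, key=lambda m: (m.start, m.end)):
        covering = [
            i for i, (s, e) in enumerate(spans)
            if s < mention.end and e > mention.start
        ]
        if not covering:
            logger.warning("mention %r aligned to no token; kept via covering "
                           "tokens failed", mention.surface)
            continue
        first = covering[0]
        if spans[first][0] != mention.start or spans[covering[-1]][1] != mention.end:
            logger.warning("mention %r not aligned to token boundaries; "
                           "aligned to covering tokens", mention.surface)
        labels[first] = f"B-{mention.entity_class.value}"
        for i in covering[1:]:
            labels[i] = f"I-{mention.entity_class.value}"
    return TaggedSentence(tokens=tokens, labels=labels, char_spans=spans,
                          text=sentence.text)


def repair_iob(labels: Sequence[str]) -> list[str]:
    """Promote illegal ``I-x`` tags (no matching ``B-x``/``I-x`` before) to ``B-x``."""
    repaired: list[str] = []
    prev_class: str | None = None
    for label in labels:
        match = _LABEL_RE.match(label)
        if match is None:
            repaired.append("O")
            prev_class = None
            continue
        prefix, cls = match.groups()
        if prefix == "I" and prev_class != cls:
            label = f"B-{cls}"
        repaired.append(label)
        prev_class = cls
    return repaired


def iob_decode(tagged: TaggedSentence) -> list[EntityMention]:
    """Mentions from an IOB sequence; total via :func:`repair_iob`."""
    labels = repair_iob(tagged.labels)
    mentions: list[EntityMention] = []
    current: tuple[str, int, int] | None = None  # (class, start, end)
    for label, (start, end) in zip(labels, tagged.char_spans):
        match = _LABEL_RE.match(label)
        if match is None:
            cls = None
        else:
            prefix, cls = match.groups()
        if current is not None and (cls is None or prefix == "B"
                                    or cls != current[0]):
            mentions.append(_mention_from(current, tagged.text))
            current = None
        if cls is not None:
            if prefix == "B" or current is None:
                current = (cls, start, end)
            else:
                current = (current[0], current[1], end)
    if current is not None:
        mentions.append(_mention_from(current, tagged.text))
    return mentions


def _mention_from(span: tuple[str, int, int], text: str) -> EntityMention:
    cls, start, end = span
    return EntityMention(start, end, text[start:end], EntityClass(cls))


# ---------------------------------------------------------------------------
# Subtoken alignment
# ---------------------------------------------------------------------------

def align_to_subtokens(labels: Sequence[str],
                       word_index: Sequence[int]) -> list[str]:
    """Project per-token labels onto a subtoken sequence.

    ``word_index`` gives the source token index per subtoken (-1 for special
    positions such as CLS). The first subtoken of each token carries the
    label; continuations and specials carry :data:`IGNORE`.
    """
    present = {w for w in word_index if w >= 0}
    missing = [i for i in range(len(labels)) if i not in present]
    if missing:
        raise ValueError(f"tokens {missing} have zero subtokens")
    aligned: list[str] = []
    seen: set[int] = set()
    for w in word_index:
        if w < 0 or w in seen:
            aligned.append(IGNORE)
        else:
            seen.add(w)
            aligned.append(labels[w])
    return aligned


def project_from_subtokens(sub_labels: Sequence[str],
                           word_index: Sequence[int],
                           n_tokens: int) -> list[str]:
    """Inverse of :func:`align_to_subtokens`: per-token labels of original length.

    Tokens without a (kept) first subtoken — e.g. truncated away — become ``O``.
    """
    labels = ["O"] * n_tokens
    seen: set[int] = set()
    for label, w in zip(sub_labels, word_index):
        if w >= 0 and w not in seen:
            seen.add(w)
            labels[w] = label if label != IGNORE else "O"
    return labels


# ---------------------------------------------------------------------------
# Tagger
# ---------------------------------------------------------------------------

@dataclass
class TaggerConfig:
    """Training configuration for the token-classification tagger."""

    encoder_id: str = "tiny"
    max_length: int = 64
    learning_rate: float = 0.01
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    label_set: list[str] | None = None
    width: int = 32
    n_layers: int = 2
    vocab_size: int = 512


class Tagger:
    """Token classifier: tiny encoder + single linear layer per subtoken."""

    def __init__(self, tokenizer: WordpieceTokenizer, encoder: TinyEncoder,
                 head: LinearHead, label_set: list[str],
                 config: TaggerConfig):
        self.tokenizer = tokenizer
        self.encoder = encoder
        self.head = head
        self.label_set = label_set
        self.label_to_id = {l: i for i, l in enumerate(label_set)}
        self.config = config
        self.truncation_warnings = 0

    def _encode(self, tokens: list[str]) -> tuple[list[int], list[int]]:
        ids, word_index = self.tokenizer.encode_words(tokens)
        if len(ids) > self.config.max_length:
            self.truncation_warnings += 1
            logger.warning("sentence truncated from %d to %d subtokens",
                           len(ids), self.config.max_length)
            ids = ids[: self.config.max_length]
            word_index = word_index[: self.config.max_length]
        return ids, word_index

    def predict(self, sentences: Sequence[TaggedSentence]) -> list[TaggedSentence]:
        out: list[TaggedSentence] = []
        for sent in sentences:
            ids, word_index = self._encode(sent.tokens)
            states, _ = self.encoder.forward(ids)
            pred = np.argmax(self.head.logits(states), axis=1)
            sub_labels = [self.label_set[i] for i in pred]
            labels = repair_iob(project_from_subtokens(
                sub_labels, word_index, len(sent.tokens)))
            out.append(TaggedSentence(tokens=list(sent.tokens), labels=labels,
                                      char_spans=list(sent.char_spans),
                                      text=sent.text))
        return out


def train_tagger(train_sentences: Sequence[TaggedSentence],
                 val_sentences: Sequence[TaggedSentence],
                 config: TaggerConfig) -> Tagger:
    """Fine-tune the tagger on IOB-labeled sentences; deterministic per seed."""
    if not train_sentences:
        raise ValueError("empty training set")
    train_labels = {l for s in train_sentences for l in s.labels}
    val_labels = {l for s in val_sentences for l in s.labels}
    if not val_labels <= train_labels:
        raise ValueError(
            f"labels {sorted(val_labels - train_labels)} present in "
            "validation but not in training data"
        )
    label_set = config.label_set or sorted(train_labels | {"O"})

    tokenizer = WordpieceTokenizer.train(
        [" ".join(s.tokens) for s in train_sentences],
        vocab_size=config.vocab_size)
    encoder = TinyEncoder(EncoderConfig(
        vocab_size=len(tokenizer), width=config.width,
        n_layers=config.n_layers, max_length=config.max_length,
        seed=config.seed))
    rng = np.random.default_rng(config.seed + 1)
    head = LinearHead.create(config.width, len(label_set), rng, name="tagger")
    tagger = Tagger(tokenizer, encoder, head, label_set, config)

    params = encoder.parameters() | head.parameters()
    optimizer = AdamOptimizer(params, lr=config.learning_rate)
    for _epoch in range(config.epochs):
        order = rng.permutation(len(train_sentences))
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            grads = optimizer.zero_grads()
            for idx in batch:
                sent = train_sentences[idx]
                ids, word_index = tagger._encode(sent.tokens)
                aligned = align_to_subtokens(sent.labels, word_index) \
                    if max(word_index) == len(sent.tokens) - 1 \
                    else _aligned_truncated(sent.labels, word_index)
                states, cache = encoder.forward(ids)
                logits = head.logits(states)
                d_logits = np.zeros_like(logits)
                for pos, label in enumerate(aligned):
                    if label == IGNORE:
                        continue
                    _loss, d = softmax_xent_grad(
                        logits[pos], tagger.label_to_id[label])
                    d_logits[pos] = d
                d_states = head.backward(states, d_logits, grads)
                encoder.backward(cache, d_states, grads)
            optimizer.step(grads)
    return tagger


def _aligned_truncated(labels: Sequence[str],
                       word_index: Sequence[int]) -> list[str]:
    kept = max(word_index) + 1
    return align_to_subtokens(list(labels)[:kept], word_index)


def predict_tags(tagger: Tagger,
                 sentences: Sequence[TaggedSentence]) -> list[TaggedSentence]:
    """Predict IOB labels; sequences are legal after repair."""
    return tagger.predict(sentences)


# ---------------------------------------------------------------------------
# MeSH dictionary linker (stand-in interface for any disease normalizer)
# ---------------------------------------------------------------------------

_FOLD_RE = re.compile(r"[^\w\s]")
_MESH_ID_RE = re.compile(r"^[DC]\d+$")


def fold_term(term: str) -> str:
    """Case/punctuation folding: lowercase, punctuation → space, collapse."""
    return " ".join(_FOLD_RE.sub(" ", term.lower()).split())


@dataclass
class MeshLexicon:
    """Folded disease term → MeSH descriptor id."""

    terms: dict[str, str] = field(default_factory=dict)

    def add(self, term: str, mesh_id: str) -> None:
        if not _MESH_ID_RE.match(mesh_id):
            raise ValueError(f"invalid MeSH id {mesh_id!r}")
        self.terms[fold_term(term)] = mesh_id

    def lookup(self, term: str) -> str | None:
        return self.terms.get(fold_term(term))

    def __len__(self) -> int:
        return len(self.terms)


def load_mesh_lexicon(path: str | Path) -> MeshLexicon:
    lexicon = MeshLexicon()
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            lexicon.add(row["term"], row["mesh_id"])
    return lexicon


def write_mesh_lexicon(lexicon: MeshLexicon, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["term", "mesh_id"])
        for term in sorted(lexicon.terms):
            writer.writerow([term, lexicon.terms[term]])
    return path


_ABBR_RE = re.compile(r"\(\s*([A-Z][A-Za-z]{1,7})s?\s*\)")


def find_abbreviations(text: str) -> dict[str, str]:
    """Short form → long form pairs from ``long form (SF)`` patterns.

    The long form is the shortest word window before the parenthesis whose
    first word starts with the short form's first letter and that contains
    the short form's letters in order.
    """
    pairs: dict[str, str] = {}
    for match in _ABBR_RE.finditer(text):
        short = match.group(1)
        before = text[: match.start()].rstrip()
        words = re.findall(r"[\w-]+", before)
        for k in range(1, min(len(short) + 3, len(words) + 1)):
            candidate = " ".join(words[-k:])
            if _letters_in_order(short, candidate):
                pairs[short] = candidate
                break
    return pairs


def _letters_in_order(short: str, candidate: str) -> bool:
    cand = candidate.lower()
    if not cand.startswith(short[0].lower()):
        return False
    pos = 0
    for ch in short.lower():
        pos = cand.find(ch, pos)
        if pos < 0:
            return False
        pos += 1
    return True


def link_disease_mentions(mentions: Sequence[EntityMention],
                          lexicon: MeshLexicon,
                          context_text: str = "") -> list[EntityMention]:
    """Attach MeSH ids to disease mentions (exact folded match, then local
    abbreviation expansion over ``context_text``); unmatched → empty ids."""
    abbreviations = find_abbreviations(context_text) if context_text else {}
    linked: list[EntityMention] = []
    for mention in mentions:
        if mention.entity_class != EntityClass.DISEASE:
            linked.append(mention)
            continue
        mesh_id = lexicon.lookup(mention.surface)
        if mesh_id is None and mention.surface in abbreviations:
            mesh_id = lexicon.lookup(abbreviations[mention.surface])
        ids = [ConceptID(Namespace.MESH, mesh_id)] if mesh_id else []
        linked.append(replace(mention, normalized_ids=ids))
    return linked


def detect_disease_mentions(sentence_text: str, lexicon: MeshLexicon,
                            max_ngram: int = 5,
                            context_text: str = "") -> list[EntityMention]:
    """Longest-match dictionary tagging of disease terms in one sentence."""
    tokens, spans = word_tokenize(sentence_text)
    abbreviations = find_abbreviations(context_text) if context_text else {}
    mentions: list[EntityMention] = []
    def is_word(tok: str) -> bool:
        return any(ch.isalnum() for ch in tok)

    i = 0
    while i < len(tokens):
        found = None
        for n in range(min(max_ngram, len(tokens) - i), 0, -1):
            if not is_word(tokens[i]) or not is_word(tokens[i + n - 1]):
                continue  # folded lookup must not swallow punctuation tokens
            start, end = spans[i][0], spans[i + n - 1][1]
            surface = sentence_text[start:end]
            mesh_id = lexicon.lookup(surface)
            if mesh_id is None and n == 1 and surface in abbreviations:
                mesh_id = lexicon.lookup(abbreviations[surface])
            if mesh_id is not None:
                found = (n, EntityMention(
                    start, end, surface, EntityClass.DISEASE,
                    [ConceptID(Namespace.MESH, mesh_id)]))
                break
        if found is not None:
            mentions.append(found[1])
            i += found[0]
        else:
            i += 1
    return mentions
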