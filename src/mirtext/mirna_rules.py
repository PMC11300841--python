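"""Rule-based miRNA mention detection and miRBase normalization.

miRNA nomenclature is regular enough that a grammar covers the forms found in
abstracts: an optional three-letter species prefix (``hsa-``), a family token
(``miR``/``mir``/``miRNA``/``microRNA``/``let``/``lin``), a family number,
optional letter suffix (``miR-29a``), optional paralog index (``miR-121-2``)
and optional arm (``-5p``/``-3p``). A lowercase ``mir`` family token denotes
the precursor hairpin (MI accessions); all other forms denote mature
sequences (MIMAT accessions).

Generic mentions without a number ("miRNAs", "microRNA") are not linkable and
are therefore not mentions. Enumerations sharing a stem ("miR-200b/c") are
split into one mention per alternative.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .corpus_io import ConceptID, EntityClass, EntityMention, Namespace

# Family tokens; matching is case-tolerant on the fixed inventory below but a
# family keyword is always required, so bare gene symbols never match.
_FAMILY_TOKENS = [
    "microRNA", "MicroRNA", "microrna", "MICRORNA",
    "miRNA", "MiRNA", "MIRNA",
    "miR", "MiR", "MIR", "mir",
    "let", "Let", "LET",
    "lin", "Lin", "LIN",
]
_FAMILY_ALT = "|".join(sorted(_FAMILY_TOKENS, key=len, reverse=True))

#: One miRNA name. ``let``/``lin`` require a hyphen before the number so that
#: gene symbols like ``LIN28`` are not picked up; the miR family allows
#: ``miR21`` style fusion.
_NAME_CORE = (
    r"(?P<species>[a-z]{3}-)?"
    r"(?P<family>" + _FAMILY_ALT + r")"
    r"(?P<hyphen>-?)"
    r"(?P<number>\d+)"
    r"(?P<letter>[a-z]{1,2})?"
    r"(?:-(?P<paralog>\d+)(?!\d*p))?"
    r"(?:-(?P<arm>[53]p))?"
)
_NAME_RE = re.compile(_NAME_CORE)
_MENTION_RE = re.compile(
    r"(?<![A-Za-z0-9-])" + _NAME_CORE + r"(?P<alts>(?:/[a-z0-9]{1,4})*)"
    r"(?![A-Za-z0-9])"
)

_MATURE_ACC_RE = re.compile(r"^MIMAT\d+$")
_PRECURSOR_ACC_RE = re.compile(r"^MI\d+$")


@dataclass(frozen=True)
class MirnaNameParts:
    """Structured decomposition of one miRNA name."""

    family: str  # canonical: "miR", "let" or "lin"
    number: int
    species_prefix: str | None = None
    letter_suffix: str | None = None
    paralog_index: int | None = None
    arm: str | None = None  # "5p", "3p" or None (unspecified)
    precursor_flag: bool = False

    def serialize(self) -> str:
        """Canonical name, e.g. ``hsa-miR-501-3p`` or ``mir-21``."""
        family = "mir" if self.precursor_flag and self.family == "miR" else self.family
        parts = [f"{family}-{self.number}{self.letter_suffix or ''}"]
        if self.species_prefix:
            parts.insert(0, self.species_prefix)
        name = "-".join(parts)
        if self.paralog_index is not None:
            name += f"-{self.paralog_index}"
        if self.arm:
            name += f"-{self.arm}"
        return name

    def with_(self, **kwargs) -> "MirnaNameParts":
        data = self.__dict__ | kwargs
        return MirnaNameParts(**data)


_CANONICAL_FAMILY = {"mir": "miR", "mirna": "miR", "microrna": "miR",
                     "let": "let", "lin": "lin"}


def parse_mirna_name(surface: str) -> MirnaNameParts | None:
    """Parse one miRNA name; ``None`` when the grammar does not match.

    Lossless on canonical names: ``parse(x).serialize() == x``.
    """
    match = _NAME_RE.fullmatch(surface.strip())
    if match is None:
        return None
    raw_family = match.group("family")
    family = _CANONICAL_FAMILY[raw_family.lower()]
    if family in ("let", "lin") and not match.group("hyphen"):
        return None
    paralog = match.group("paralog")
    return MirnaNameParts(
        family=family,
        number=int(match.group("number")),
        species_prefix=(match.group("species") or "").rstrip("-") or None,
        letter_suffix=match.group("letter"),
        paralog_index=int(paralog) if paralog else None,
        arm=match.group("arm"),
        precursor_flag=(raw_family == "mir"),
    )


def detect_mirna_mentions(sentence_text: str) -> list[EntityMention]:
    """Find all miRNA mentions in one sentence (non-overlapping spans).

    Enumerations like ``miR-200b/c`` yield one mention for the full head name
    and one short mention per alternative suffix; the parts of every mention
    (including alternatives, which share the numeric stem) are available via
    :func:`detect_and_parse`.
    """
    return [m for m, _parts in detect_and_parse(sentence_text)]


def detect_and_parse(
    sentence_text: str,
) -> list[tuple[EntityMention, MirnaNameParts]]:
    results: list[tuple[EntityMention, MirnaNameParts]] = []
    for match in _MENTION_RE.finditer(sentence_text):
        raw_family = match.group("family")
        if raw_family.lower() in ("let", "lin") and not match.group("hyphen"):
            continue
        head_end = match.end() - len(match.group("alts") or "")
        head_surface = sentence_text[match.start():head_end]
        parts = parse_mirna_name(head_surface)
        if parts is None:  # pragma: no cover - grammar and parser agree
            continue
        mention = EntityMention(match.start(), head_end, head_surface,
                                EntityClass.MIRNA)
        results.append((mention, parts))
        # alternatives in "miR-200b/c" or "miR-200b/429" share the stem
        pos = head_end
        for alt in (match.group("alts") or "").split("/")[1:]:
            start = pos + 1  # skip the slash
            end = start + len(alt)
            alt_parts = _alternative_parts(parts, alt)
            if alt_parts is not None:
                results.append((
                    EntityMention(start, end, alt, EntityClass.MIRNA),
                    alt_parts,
                ))
            pos = end
    return results


def _alternative_parts(stem: MirnaNameParts, alt: str) -> MirnaNameParts | None:
    if re.fullmatch(r"[a-z]{1,2}", alt):
        return stem.with_(letter_suffix=alt, arm=None, paralog_index=None)
    if re.fullmatch(r"[53]p", alt):
        return stem.with_(arm=alt)
    if re.fullmatch(r"\d{1,4}", alt):
        return stem.with_(number=int(alt), letter_suffix=None, arm=None,
                          paralog_index=None)
    return None


# ---------------------------------------------------------------------------
# miRBase lexicon and normalization
# ---------------------------------------------------------------------------

class LexiconError(ValueError):
    """Raised for malformed or conflicting lexicon rows."""


@dataclass
class MirbaseLexicon:
    """Canonical-name → accession tables for mature and precursor miRNAs."""

    mature: dict[str, str] = field(default_factory=dict)
    precursor: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, accession: str, kind: str) -> None:
        table = {"mature": self.mature, "precursor": self.precursor}.get(kind)
        if table is None:
            raise LexiconError(f"unknown entry type {kind!r}")
        pattern = _MATURE_ACC_RE if kind == "mature" else _PRECURSOR_ACC_RE
        if not pattern.match(accession):
            raise LexiconError(f"accession {accession!r} invalid for {kind}")
        key = _fold_name(name)
        if key in table and table[key] != accession:
            raise LexiconError(
                f"conflicting accessions for {name!r}: {table[key]} vs {accession}"
            )
        table[key] = accession

    def mature_accession(self, name: str) -> str | None:
        return self.mature.get(_fold_name(name))

    def precursor_accession(self, name: str) -> str | None:
        return self.precursor.get(_fold_name(name))

    def __len__(self) -> int:
        return len(self.mature) + len(self.precursor)

    def canonical_mature_names(self) -> list[str]:
        return sorted(self.mature)


def _fold_name(name: str) -> str:
    # case-insensitive on the family token, i.e. on everything but the
    # species prefix, which is lowercase by convention anyway
    return name.strip().lower()


def load_mirbase_lexicon(path: str | Path) -> MirbaseLexicon:
    """Load a lexicon TSV with columns canonical_name, accession, type."""
    lexicon = MirbaseLexicon()
    with Path(path).open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"canonical_name", "accession", "type"}
        if reader.fieldnames is None:
            return lexicon
        if not required.issubset(reader.fieldnames):
            raise LexiconError(
                f"{path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            lexicon.add(row["canonical_name"], row["accession"], row["type"])
    return lexicon


def write_mirbase_lexicon(lexicon: MirbaseLexicon, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["canonical_name", "accession", "type"])
        for name in sorted(lexicon.mature):
            writer.writerow([name, lexicon.mature[name], "mature"])
        for name in sorted(lexicon.precursor):
            writer.writerow([name, lexicon.precursor[name], "precursor"])
    return path


def normalize_to_mirbase(parts: MirnaNameParts, lexicon: MirbaseLexicon,
                         species_context: str = "hsa",
                         both_arms: bool = False) -> list[ConceptID]:
    """Map a parsed miRNA name to miRBase accessions.

    A missing species prefix defaults to ``species_context`` (human unless a
    run says otherwise). A lowercase ``mir`` token is tried against precursor
    entries first. When the mention does not specify an arm, the bare name is
    tried first (some matures, e.g. hsa-miR-133b, carry no arm suffix), then
    the ``-5p`` arm, then ``-3p``; with ``both_arms=True`` every arm present
    in the lexicon is returned. Unknown names yield an empty list.
    """
    if parts.species_prefix is None:
        parts = parts.with_(species_prefix=species_context)

    if parts.precursor_flag:
        acc = lexicon.precursor_accession(parts.serialize())
        if acc is not None:
            return [ConceptID(Namespace.MIRBASE, acc)]
        parts = parts.with_(precursor_flag=False)  # fall through to mature

    if parts.arm is not None:
        acc = lexicon.mature_accession(parts.serialize())
        return [ConceptID(Namespace.MIRBASE, acc)] if acc else []

    candidates = [parts.serialize(),
                  parts.with_(arm="5p").serialize(),
                  parts.with_(arm="3p").serialize()]
    found = [(name, lexicon.mature_accession(name)) for name in candidates]
    found = [(name, acc) for name, acc in found if acc]
    if not found:
        return []
    if both_arms:
        seen: list[ConceptID] = []
        for _name, acc in found:
            cid = ConceptID(Namespace.MIRBASE, acc)
            if cid not in seen:
                seen.append(cid)
        return seen
    return [ConceptID(Namespace.MIRBASE, found[0][1])]


def normalize_mentions(sentence_text: str, lexicon: MirbaseLexicon,
                       species_context: str = "hsa") -> list[EntityMention]:
    """Detect miRNA mentions and attach miRBase ids in one pass."""
    mentions = []
    for mention, parts in detect_and_parse(sentence_text):
        mention.normalized_ids = normalize_to_mirbase(
            parts, lexicon, species_context=species_context)
        mentions.append(mention)
    return mentions
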