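"""Parsing and arithmetic for the coding/protein HGVS subset used in
targeted gene screening reports.

Covers c.-coordinates with signed intron offsets (``c.7595-3C>G``,
``c.5573-843A>G``), unknown intronic breakpoints (``c.8559-?_8681+?del``),
substitutions, deletions, duplications, insertions and deletion-insertions,
plus protein-level deletion spans (``p.(Tyr2854_Arg2894del)``) with the
``,=`` mosaic suffix produced by leaky splice defects.

Not a full HGVS grammar: inversions, repeat notation and alleles-in-cis
syntax are out of scope, as is projection onto real reference transcripts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering

from .residues import as_one_letter, as_three_letter

# the extracted literature text uses U+2212 for intronic minus offsets
_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}


def _normalize(text: str) -> str:
    for bad, good in _MINUS_VARIANTS.items():
        text = text.replace(bad, good)
    return text.strip()


@total_ordering
@dataclass(frozen=True)
class CodingPosition:
    """A c.-coordinate: coding base plus signed intron offset (0 = exonic).

    ``offset_unknown`` marks the ``-?`` / ``+?`` notation for breakpoints
    that lie an undetermined distance into the intron; ``offset`` then
    only records the direction as +/-1.
    """

    base: int
    offset: int = 0
    offset_unknown: bool = False

    def __post_init__(self) -> None:
        if self.base < 1:
            raise ValueError(f"coding base must be >= 1, got {self.base}")

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0 or self.offset_unknown

    def _key(self) -> tuple[int, int]:
        # transcript order: upstream-intronic < exonic < downstream-intronic
        return (self.base, self.offset)

    def __lt__(self, other: "CodingPosition") -> bool:
        return self._key() < other._key()

    def __str__(self) -> str:
        if self.offset_unknown:
            return f"{self.base}{'+' if self.offset >= 0 else '-'}?"
        if self.offset:
            return f"{self.base}{self.offset:+d}"
        return str(self.base)


_POS_RE = r"(?P<{p}base>\d+)(?:(?P<{p}sign>[+-])(?P<{p}off>\d+|\?))?"
_C_RE = re.compile(
    "^c\\."
    + _POS_RE.format(p="s")
    + "(?:_" + _POS_RE.format(p="e") + ")?"
    + r"(?P<edit>(?:[ACGT]>[ACGT])|delins(?:[ACGT]+|\d+)|del[ACGT]*|dup[ACGT]*|ins(?:[ACGT]+|\d+))$"
)


@dataclass(frozen=True)
class CodingVariant:
    """One parsed c.-variant (SNV, small indel or large deletion span)."""

    start: CodingPosition
    end: CodingPosition
    edit: str  # substitution | del | dup | ins | delins
    ref: str = ""
    alt: str = ""
    inserted_length: int = 0  # for delinsN / insN numeric forms
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"span end precedes start in {self.raw!r}")
        if self.edit == "substitution" and self.start != self.end:
            raise ValueError("substitution must have a single-position span")

    @property
    def has_unknown_breakpoint(self) -> bool:
        return self.start.offset_unknown or self.end.offset_unknown

    @property
    def exonic_span_nt(self) -> int:
        """Number of coding bases between start.base and end.base inclusive.

        For deletions with unknown intronic breakpoints this is the exon
        span, matching the convention of reporting such events by the
        exonic sequence they remove.
        """
        return self.end.base - self.start.base + 1

    def format(self) -> str:
        """Canonical ASCII form (round-trips through :func:`parse_c`)."""
        span = str(self.start)
        if self.end != self.start:
            span += f"_{self.end}"
        if self.edit == "substitution":
            return f"c.{span}{self.ref}>{self.alt}"
        if self.edit == "delins":
            payload = self.alt if self.alt else str(self.inserted_length)
            return f"c.{span}delins{payload}"
        if self.edit == "ins":
            payload = self.alt if self.alt else str(self.inserted_length)
            return f"c.{span}ins{payload}"
        return f"c.{span}{self.edit}{self.ref}"

    def __str__(self) -> str:
        return self.format()


def _build_pos(m: re.Match, prefix: str) -> CodingPosition | None:
    base = m.group(f"{prefix}base")
    if base is None:
        return None
    sign = m.group(f"{prefix}sign")
    off = m.group(f"{prefix}off")
    if sign is None:
        return CodingPosition(int(base))
    if off == "?":
        return CodingPosition(int(base), 1 if sign == "+" else -1, offset_unknown=True)
    return CodingPosition(int(base), int(off) if sign == "+" else -int(off))


def parse_c(text: str) -> CodingVariant:
    """Parse a c.-HGVS string into a :class:`CodingVariant`.

    Unknown-breakpoint spans (``-?``/``+?``) are parsed and flagged, not
    rejected.  Raises ValueError for malformed strings.
    """
    raw = text
    norm = _normalize(text)
    if not norm.startswith("c."):
        raise ValueError(f"not a c.-HGVS string: {text!r}")
    m = _C_RE.match(norm)
    if m is None:
        raise ValueError(f"cannot parse HGVS string: {text!r}")
    start = _build_pos(m, "s")
    end = _build_pos(m, "e") or start
    edit = m.group("edit")
    ref = alt = ""
    ins_len = 0
    if ">" in edit:
        kind = "substitution"
        ref, alt = edit.split(">")
    elif edit.startswith("delins"):
        kind = "delins"
        payload = edit[6:]
        if payload.isdigit():
            ins_len = int(payload)
        else:
            alt = payload
            ins_len = len(payload)
    elif edit.startswith("del"):
        kind = "del"
        ref = edit[3:]
    elif edit.startswith("dup"):
        kind = "dup"
        ref = edit[3:]
    else:  # ins
        kind = "ins"
        payload = edit[3:]
        if payload.isdigit():
            ins_len = int(payload)
        else:
            alt = payload
            ins_len = len(payload)
    return CodingVariant(start=start, end=end, edit=kind, ref=ref, alt=alt,
                         inserted_length=ins_len, raw=raw)


_P_DEL_RE = re.compile(
    r"^p\.\(?"
    r"(?P<r1>[A-Z][a-z]{2}|[A-Z])(?P<p1>\d+)"
    r"(?:_(?P<r2>[A-Z][a-z]{2}|[A-Z])(?P<p2>\d+))?"
    r"del"
    r"(?P<mosaic>,=)?"
    r"\)?$"
)


@dataclass(frozen=True)
class ProteinDeletion:
    """A protein-level deletion span p.(Xaa#_Yaa#del[,=])."""

    first_aa: tuple[str, int]
    last_aa: tuple[str, int]
    mosaic: bool = False
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.last_aa[1] < self.first_aa[1]:
            raise ValueError(f"deletion span reversed in {self.raw!r}")

    def format(self) -> str:
        r1, p1 = self.first_aa
        r2, p2 = self.last_aa
        span = f"{as_three_letter(r1)}{p1}"
        if (r2, p2) != (r1, p1):
            span += f"_{as_three_letter(r2)}{p2}"
        return f"p.({span}del{',=' if self.mosaic else ''})"

    def __str__(self) -> str:
        return self.format()


def parse_p_del(text: str) -> ProteinDeletion:
    """Parse a protein deletion ``p.(Tyr2854_Arg2894del)``.

    The trailing ``,=`` (mosaic: both deleted and wildtype product, as for
    a leaky splice variant) sets the ``mosaic`` flag.  Residues are stored
    in one-letter code.
    """
    m = _P_DEL_RE.match(_normalize(text))
    if m is None:
        raise ValueError(f"cannot parse protein deletion: {text!r}")
    r1 = as_one_letter(m.group("r1"))
    p1 = int(m.group("p1"))
    if m.group("r2"):
        r2, p2 = as_one_letter(m.group("r2")), int(m.group("p2"))
    else:
        r2, p2 = r1, p1
    return ProteinDeletion((r1, p1), (r2, p2), mosaic=m.group("mosaic") is not None,
                           raw=text)


def deleted_aa_count(d: ProteinDeletion) -> int:
    """Number of residues removed by a protein deletion span (inclusive)."""
    return d.last_aa[1] - d.first_aa[1] + 1


def is_inframe(deleted_nt: int, inserted_nt: int = 0) -> bool:
    """True when a deletion/insertion preserves the reading frame."""
    if deleted_nt < 0 or inserted_nt < 0:
        raise ValueError("lengths must be non-negative")
    return (deleted_nt - inserted_nt) % 3 == 0


def is_canonical_splice(v: CodingVariant) -> bool:
    """True when the variant touches a canonical splice dinucleotide.

    Canonical means an intron offset of magnitude 1 or 2 at either end of
    the span (the two intronic nucleotides flanking an exon).
    """
    for pos in (v.start, v.end):
        if not pos.offset_unknown and pos.offset != 0 and abs(pos.offset) <= 2:
            return True
    return False
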