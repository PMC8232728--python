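"""Amino-acid residue code handling (one-letter internal canonical form)."""

from __future__ import annotations

from Bio.SeqUtils import seq1, seq3

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def as_one_letter(residue: str) -> str:
    """Normalize a residue given in one- or three-letter code to one-letter.

    Raises ValueError for anything that is not a standard amino acid.
    """
    r = residue.strip()
    if len(r) == 1:
        one = r.upper()
    elif len(r) == 3:
        one = seq1(r)
    else:
        raise ValueError(f"unrecognized residue code: {residue!r}")
    if one not in STANDARD_AA:
        raise ValueError(f"not a standard amino acid: {residue!r}")
    return one


def as_three_letter(residue: str) -> str:
    """One- or three-letter code to capitalized three-letter code."""
    return seq3(as_one_letter(residue))
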