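"""Sequence containers and small DNA utilities.

The package-wide coordinate convention is 0-based half-open; conversion to
GFF3's 1-based closed intervals happens only in the writers (:mod:`heltrace.io`).
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import AlphabetError

DNA_BASES = "ACGT"

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class SequenceRecord:
    """A named DNA (or protein) sequence with optional taxon/region labels."""

    id: str
    seq: str
    taxon: str | None = None
    region: str | None = None

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id, seq=revcomp(self.seq), taxon=self.taxon, region=self.region
        )


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a DNA string with the standard genetic code ('*' for stops)."""
    trimmed = dna[: len(dna) - len(dna) % 3]
    return str(Seq(trimmed).translate())


def validate_dna(seq: str, *, where: str = "sequence") -> None:
    """Raise :class:`AlphabetError` naming the first non-ACGT character."""
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise AlphabetError(
                f"{where} contains non-DNA character {ch!r} at position {i}"
            )


def gc_fraction(seq: str) -> float:
    """G+C fraction over unambiguous (ACGT) positions."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise AlphabetError("sequence has no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC nucleotide pattern into a regex (exact-length match)."""
    parts = []
    for ch in pattern:
        try:
            opts = IUPAC[ch]
        except KeyError:
            raise AlphabetError(f"unknown IUPAC code {ch!r} in pattern {pattern!r}")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def iupac_matches(pattern: str, text: str) -> list[int]:
    """All (possibly overlapping) start positions where `pattern` matches."""
    rx = iupac_regex(pattern)
    return [m.start() for m in re.finditer(f"(?=({rx.pattern}))", text)]


def pairs(b1: str, b2: str) -> bool:
    """Watson-Crick pairing test for two concrete bases."""
    return (b1, b2) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
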