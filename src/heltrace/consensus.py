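"""Degenerate protein-motif consensus for the Rep catalytic core.

Helitron Rep/Helicase proteins carry an HUH-endonuclease (Rep) domain whose
catalytic core is conventionally summarised as three short degenerate motifs.
Patterns here use uppercase letters for exact residues plus three class
symbols: ``h`` (hydrophobic), ``s`` (small), ``x`` (any residue).  The default
consensus ships as an editable YAML file in the package data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_CLASS_SETS = {
    "h": frozenset("AVLIMFWYC"),
    "s": frozenset("AGSTCNDP"),
}


@dataclass
class RepConsensus:
    """An ordered list of degenerate motif patterns with residue-class sets."""

    motifs: list[str]
    class_sets: dict[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SETS)
    )

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.motifs:
            raise ConfigError("consensus must declare at least one motif")
        for pat in self.motifs:
            for ch in pat:
                if ch in self.class_sets:
                    continue
                if ch == "x":
                    continue
                if ch in AMINO_ACIDS and ch.isupper():
                    continue
                raise ConfigError(
                    f"unknown symbol {ch!r} in motif pattern {pat!r}: "
                    "use an uppercase residue, a declared class symbol, or 'x'"
                )

    def matches_at(self, protein: str, pos: int, motif_index: int) -> bool:
        pat = self.motifs[motif_index]
        if pos + len(pat) > len(protein):
            return False
        for k, ch in enumerate(pat):
            aa = protein[pos + k]
            if ch == "x":
                continue
            if ch in self.class_sets:
                if aa not in self.class_sets[ch]:
                    return False
            elif aa != ch:
                return False
        return True


def _from_mapping(data: dict) -> RepConsensus:
    class_sets = {
        sym: frozenset(residues)
        for sym, residues in (data.get("class_sets") or {}).items()
    }
    return RepConsensus(
        motifs=list(data["motifs"]), class_sets=class_sets or dict(DEFAULT_CLASS_SETS)
    )


def load_consensus(path: str | Path) -> RepConsensus:
    """Load a consensus definition from a YAML file."""
    data = yaml.safe_load(Path(path).read_text())
    return _from_mapping(data)


def default_rep_consensus() -> RepConsensus:
    """The packaged three-motif Rep catalytic-core consensus."""
    text = resources.files("heltrace").joinpath("data/rep_consensus.yaml").read_text()
    return _from_mapping(yaml.safe_load(text))
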