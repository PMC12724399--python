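"""Single amino-acid variant identity — the join key across the pipeline.

Variants are identified at the protein level by a compact one-letter HGVS-like
string: ``A341V`` (missense), ``W248*`` (nonsense), ``L266=`` (synonymous).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z*=])$")

MISSENSE = "missense"
NONSENSE = "nonsense"
SYNONYMOUS = "synonymous"


@dataclass(frozen=True, order=True)
class Variant:
    """A single-codon protein change.

    Attributes
    ----------
    position : int
        1-based residue position.
    wt : str
        Wild-type amino acid (one-letter).
    alt : str
        Alternate amino acid; ``*`` for a stop, ``=`` for synonymous.
    """

    position: int
    wt: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt not in AA_ALPHABET:
            raise ValueError(f"invalid wild-type residue {self.wt!r}")
        if self.alt not in AA_ALPHABET + "*=":
            raise ValueError(f"invalid alternate residue {self.alt!r}")
        if self.alt == self.wt:
            raise ValueError(
                f"{self.wt}{self.position}{self.alt}: same-residue change must "
                "be written with alt '='"
            )

    @property
    def consequence(self) -> str:
        if self.alt == "*":
            return NONSENSE
        if self.alt == "=":
            return SYNONYMOUS
        return MISSENSE

    @property
    def hgvs_p(self) -> str:
        return f"{self.wt}{self.position}{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hgvs_p

    @classmethod
    def parse(cls, text: str) -> "Variant":
        """Parse ``A341V`` / ``p.A341V`` / ``W248*`` / ``L266=``."""
        m = _VARIANT_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse variant string {text!r}")
        wt, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        return cls(position=pos, wt=wt, alt=alt)


def consequence_of(hgvs: str) -> str:
    """Consequence class of a variant string without building a Variant."""
    return Variant.parse(hgvs).consequence


def position_of(hgvs: str) -> int:
    return Variant.parse(hgvs).position
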