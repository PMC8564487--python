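"""Peptides, substitutions and anchor maps.

Positions are 1-based throughout (p1..pL), matching the standard
immunology notation for 9-mer epitopes (p2/p3/p5/p9 anchors etc.).
No 0-based API is exposed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .alphabet import (
    AlphabetError,
    NATURAL_RESIDUES,
    NonNaturalRegistry,
    Residue,
)

DEFAULT_LENGTH = 9


@dataclass(frozen=True)
class Peptide:
    """A fixed-length residue string over the natural + registered alphabet."""

    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a peptide must contain at least one residue")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return "".join(r.code for r in self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def at(self, position: int) -> Residue:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.residues[position - 1]

    def replace(self, position: int, new: Residue) -> "Peptide":
        """New peptide with `new` at the 1-based `position`."""
        self.at(position)  # bounds check
        residues = list(self.residues)
        residues[position - 1] = new
        return Peptide(tuple(residues))

    @property
    def is_natural(self) -> bool:
        return all(r.is_natural for r in self.residues)


def parse_peptide(text: str, registry: NonNaturalRegistry | None = None) -> Peptide:
    """Parse a token string into a Peptide.

    Every character must be a natural one-letter code or a token declared
    in `registry`. Errors name the offending token and its 1-based
    position.
    """
    if not text:
        raise AlphabetError("empty peptide string")
    residues = []
    for i, token in enumerate(text.strip(), 1):
        if token in NATURAL_RESIDUES:
            residues.append(NATURAL_RESIDUES[token])
        elif registry is not None and token in registry:
            residues.append(registry.resolve(token))
        else:
            raise AlphabetError(
                f"unknown residue token {token!r} at position {i} in {text!r}"
            )
    return Peptide(tuple(residues))


_SUB_RE = re.compile(r"^(?P<wt>\S)(?P<pos>[1-9]\d*)(?P<new>\S)$")


@dataclass(frozen=True)
class Substitution:
    """A single-position change, printed in wt-letter/position/new-letter form.

    ``conservative`` is metadata assigned by a similarity scheme (see
    :func:`pepscaffold.design.flag_conservative`); None means unassessed.
    """

    wt_residue: Residue
    position: int
    new_residue: Residue
    conservative: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("substitution positions are 1-based")
        if self.wt_residue.code == self.new_residue.code:
            raise ValueError(
                f"substitution at p{self.position} must change the residue "
                f"({self.wt_residue.code!r})"
            )

    @property
    def notation(self) -> str:
        """Canonical string form, e.g. 'V2A', 'H3L', 'Y4W'."""
        return f"{self.wt_residue.code}{self.position}{self.new_residue.code}"

    def __str__(self) -> str:
        return self.notation


def substitution_notation(sub: Substitution) -> str:
    """Canonical wt-letter + position + new-letter string (e.g. 'V2A')."""
    return sub.notation


def parse_substitution(
    text: str, registry: NonNaturalRegistry | None = None
) -> Substitution:
    """Inverse of :func:`substitution_notation`."""
    m = _SUB_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse substitution notation {text!r}")

    def resolve(token: str) -> Residue:
        if token in NATURAL_RESIDUES:
            return NATURAL_RESIDUES[token]
        if registry is not None and token in registry:
            return registry.resolve(token)
        raise AlphabetError(f"unknown residue token {token!r} in {text!r}")

    return Substitution(resolve(m["wt"]), int(m["pos"]), resolve(m["new"]))


@dataclass(frozen=True)
class AnchorMap:
    """Partition of peptide positions into MHC-anchor and TCR-facing sets."""

    allele: str
    length: int
    anchor_positions: frozenset[int]

    def __post_init__(self) -> None:
        all_positions = frozenset(range(1, self.length + 1))
        if not self.anchor_positions <= all_positions:
            raise ValueError(
                f"anchor positions {sorted(self.anchor_positions)} outside "
                f"1..{self.length}"
            )
        if not self.anchor_positions:
            raise ValueError("at least one anchor position is required")

    @property
    def tcr_positions(self) -> frozenset[int]:
        """Complement of the anchors: positions exposed to the TCR."""
        return frozenset(range(1, self.length + 1)) - self.anchor_positions


def anchor_map(positions: Iterable[int], allele: str = "", length: int = DEFAULT_LENGTH) -> AnchorMap:
    return AnchorMap(allele, length, frozenset(positions))


#: The mouse H-2Db 9-mer anchor map: anchors p2,p3,p5,p9; TCR-facing p1,p4,p6,p7,p8.
H2DB_ANCHORS = AnchorMap("H-2Db", 9, frozenset({2, 3, 5, 9}))
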