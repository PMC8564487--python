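"""Amino-acid alphabet and the registry for non-natural residue tokens.

The 20 standard one-letter codes form the *natural* alphabet. Designed
peptides may additionally contain non-natural residues (e.g. the
tryptophan-like residue NAL used at TCR-facing position 4), which have no
standard one-letter code. Such residues must be declared in a
:class:`NonNaturalRegistry` before use: each gets a single display token
that must not collide with the natural letters, plus a human-readable
label and, optionally, a similarity row for scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: The 20 standard amino acids, alphabetical by one-letter code.
NATURAL_AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

_NATURAL_SET = frozenset(NATURAL_AMINO_ACIDS)


class AlphabetError(ValueError):
    """A token could not be resolved in the natural alphabet or registry."""


@dataclass(frozen=True)
class Residue:
    """A single residue: one-letter token plus naturalness and display label."""

    code: str
    is_natural: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.code) != 1:
            raise AlphabetError(f"residue code must be a single token, got {self.code!r}")
        if self.is_natural and self.code not in _NATURAL_SET:
            raise AlphabetError(f"{self.code!r} is not one of the 20 natural amino acids")
        if not self.is_natural and self.code in _NATURAL_SET:
            raise AlphabetError(
                f"non-natural residue token {self.code!r} collides with a natural letter"
            )
        if not self.label:
            object.__setattr__(self, "label", self.code)

    def __str__(self) -> str:
        return self.code


#: Pre-built Residue objects for the natural alphabet.
NATURAL_RESIDUES: Mapping[str, Residue] = {
    code: Residue(code) for code in NATURAL_AMINO_ACIDS
}


@dataclass
class NonNaturalRegistry:
    """Declared non-natural residues, keyed by their display token.

    Tokens are single characters outside the 20 natural letters ('X' is
    reserved for ambiguity in standard sequence formats and is refused).
    A registry entry may carry a per-natural-residue similarity row used
    by scoring code that must handle the non-natural token.
    """

    _entries: dict[str, Residue] = field(default_factory=dict)
    _similarity: dict[str, dict[str, float]] = field(default_factory=dict)

    def register(
        self,
        token: str,
        label: str,
        similarity: Mapping[str, float] | None = None,
    ) -> Residue:
        if len(token) != 1:
            raise AlphabetError(f"registry token must be a single character, got {token!r}")
        if token in _NATURAL_SET:
            raise AlphabetError(
                f"token {token!r} collides with a natural amino-acid letter"
            )
        if token.upper() == "X":
            raise AlphabetError("'X' is reserved for sequence ambiguity; pick another token")
        if token in self._entries and self._entries[token].label != label:
            raise AlphabetError(
                f"token {token!r} already registered with label "
                f"{self._entries[token].label!r}"
            )
        residue = Residue(token, is_natural=False, label=label)
        self._entries[token] = residue
        if similarity is not None:
            self._similarity[token] = dict(similarity)
        return residue

    def resolve(self, token: str) -> Residue:
        """Map a token to a Residue, natural letters included."""
        if token in NATURAL_RESIDUES:
            return NATURAL_RESIDUES[token]
        if token in self._entries:
            return self._entries[token]
        raise AlphabetError(f"unknown residue token {token!r}")

    def __contains__(self, token: str) -> bool:
        return token in self._entries

    def similarity_row(self, token: str) -> dict[str, float] | None:
        return self._similarity.get(token)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self._entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "NonNaturalRegistry":
        """Load a registry from YAML or JSON.

        Expected layout: a list of entries, each with ``token`` and
        ``label`` keys and an optional ``similarity`` mapping.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        registry = cls()
        for entry in data or []:
            registry.register(
                entry["token"], entry["label"], entry.get("similarity")
            )
        return registry


def default_registry() -> NonNaturalRegistry:
    """Registry pre-loaded with NAL, the tryptophan-like non-natural residue.

    NAL carries no standard one-letter code; token '1' is assigned here.
    Its exact chemistry is unspecified beyond being tryptophan-derived, so
    the label carries the name only.
    """
    registry = NonNaturalRegistry()
    registry.register("1", "NAL")
    return registry
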