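"""Scaffold grafting and heteroclitic peptide design.

Three design moves, all returning :class:`DesignResult` records that keep
the full substitution accounting in standard wt-letter/position/new-letter
notation:

* :func:`graft` — impose the allele's anchor-consensus motif on a wild-type
  epitope, leaving every TCR-facing position untouched;
* :func:`point_substitute` — a single heteroclitic change (e.g. Y4W, D4C),
  including registered non-natural residues such as NAL;
* :func:`saturation_library` — the MIX library: every alphabet residue at
  one position (20 members over the natural alphabet, one identical to wt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices

from .alphabet import NATURAL_AMINO_ACIDS, NATURAL_RESIDUES, NonNaturalRegistry, Residue
from .motif import ScaffoldMotif
from .peptide import AnchorMap, Peptide, Substitution, parse_substitution

#: Wild-type epitope fixtures (9-mers, sequences from the companion study):
#: HPV16 E7 49-57 and Trp2 180-188, the two tumor antigens the H-2Db
#: scaffold was designed for.
E7_WT = "RAHYNIVTF"
TRP2_WT = "SVYDFFVWL"

#: Default heteroclitic (INC) variant sets: the named p4 substitutions.
INC_DEFAULTS: dict[str, tuple[str, ...]] = {
    "E7": ("Y4V", "Y4W"),
    "Trp2": ("D4C", "D4Q", "D4W"),
}


@dataclass(frozen=True)
class DesignResult:
    """A designed peptide plus the substitutions that produced it from wt."""

    wt: Peptide
    designed: Peptide
    substitutions: tuple[Substitution, ...]
    design_kind: str  # graft | point | saturation_member

    def __post_init__(self) -> None:
        if len(self.designed) != len(self.wt):
            raise ValueError("designed peptide must match wild-type length")
        changed = {
            p for p in range(1, len(self.wt) + 1)
            if self.wt.at(p).code != self.designed.at(p).code
        }
        listed = {s.position for s in self.substitutions}
        if changed != listed:
            raise ValueError(
                f"substitution list {sorted(listed)} does not match changed "
                f"positions {sorted(changed)}"
            )

    @property
    def notation(self) -> tuple[str, ...]:
        return tuple(s.notation for s in self.substitutions)


def apply_substitutions(wt: Peptide, substitutions: Iterable[Substitution]) -> Peptide:
    """Reconstruct a designed peptide from wt plus a substitution list."""
    designed = wt
    for sub in substitutions:
        if designed.at(sub.position).code != sub.wt_residue.code:
            raise ValueError(
                f"substitution {sub.notation} does not match residue "
                f"{designed.at(sub.position).code!r} at p{sub.position}"
            )
        designed = designed.replace(sub.position, sub.new_residue)
    return designed


def graft(wt: Peptide, motif: ScaffoldMotif, anchors: AnchorMap) -> DesignResult:
    """Impose the scaffold motif's anchor residues on a wild-type epitope.

    The designed peptide carries the motif residue at every anchor position
    and the wild-type residue at every TCR-facing position; substitutions
    list exactly the anchors where the two differed. Grafting is idempotent:
    applying it to its own output yields zero substitutions.
    """
    if len(wt) != motif.length:
        raise ValueError(f"wt length {len(wt)} != motif length {motif.length}")
    if anchors.length != motif.length:
        raise ValueError("anchor map and motif lengths differ")
    if set(motif.fixed) != set(anchors.anchor_positions):
        raise ValueError(
            f"motif fixes positions {sorted(motif.fixed)} but anchors are "
            f"{sorted(anchors.anchor_positions)}"
        )
    for pos in sorted(anchors.anchor_positions):
        if not wt.at(pos).is_natural:
            raise ValueError(f"wt must be natural at anchor p{pos}")

    designed = wt
    substitutions = []
    for pos in sorted(anchors.anchor_positions):
        target = motif.fixed[pos]
        if wt.at(pos).code != target.code:
            substitutions.append(Substitution(wt.at(pos), pos, target))
            designed = designed.replace(pos, target)
    return DesignResult(wt, designed, tuple(substitutions), "graft")


def point_substitute(wt: Peptide, position: int, new: Residue | str) -> DesignResult:
    """Single-position heteroclitic substitution (non-natural residues allowed)."""
    if isinstance(new, str):
        new = NATURAL_RESIDUES[new]
    current = wt.at(position)
    if current.code == new.code:
        raise ValueError(
            f"p{position} already holds {current.code!r}; identity substitution "
            "is a no-op — use the wild-type peptide directly"
        )
    sub = Substitution(current, position, new)
    return DesignResult(wt, wt.replace(position, new), (sub,), "point")


@dataclass(frozen=True)
class PeptideLibrary:
    """A named set of designed peptides (e.g. the p4 saturation MIX library)."""

    name: str
    members: tuple[DesignResult, ...]

    def __post_init__(self) -> None:
        seqs = [str(m.designed) for m in self.members]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"library {self.name!r} members must be distinct")

    def __len__(self) -> int:
        return len(self.members)

    def sequences(self) -> tuple[str, ...]:
        return tuple(str(m.designed) for m in self.members)


def saturation_library(
    wt: Peptide,
    position: int,
    alphabet: Sequence[Residue | str] | None = None,
    name: str = "MIX",
) -> PeptideLibrary:
    """One member per alphabet residue at `position` (default: 20 natural).

    The member carrying the wild-type residue is the wild type itself, with
    an empty substitution list; every other member differs from wt only at
    `position`.
    """
    wt.at(position)  # bounds check
    if alphabet is None:
        alphabet = NATURAL_AMINO_ACIDS
    residues = [NATURAL_RESIDUES[a] if isinstance(a, str) else a for a in alphabet]
    if not residues:
        raise ValueError("alphabet must be non-empty")
    members = []
    for res in residues:
        if res.code == wt.at(position).code:
            members.append(DesignResult(wt, wt, (), "saturation_member"))
        else:
            sub = Substitution(wt.at(position), position, res)
            members.append(
                DesignResult(wt, wt.replace(position, res), (sub,), "saturation_member")
            )
    return PeptideLibrary(name, tuple(members))


def inc_library(
    wt: Peptide,
    notations: Iterable[str],
    registry: NonNaturalRegistry | None = None,
    name: str = "INC",
) -> PeptideLibrary:
    """Named list of point substitutions (the 'mix of selected' variant set)."""
    members = []
    for text in notations:
        sub = parse_substitution(text, registry)
        if wt.at(sub.position).code != sub.wt_residue.code:
            raise ValueError(
                f"substitution {sub.notation} does not match wild-type residue "
                f"{wt.at(sub.position).code!r} at p{sub.position}"
            )
        members.append(point_substitute(wt, sub.position, sub.new_residue))
    return PeptideLibrary(name, tuple(members))


def scaffold_with_point(
    wt: Peptide,
    motif: ScaffoldMotif,
    anchors: AnchorMap,
    position: int,
    new: Residue | str,
) -> DesignResult:
    """Graft followed by a point substitution at a TCR-facing position.

    Used for the composite designs (scaffold + p4 NAL, scaffold + D4C/D4Q);
    the two moves touch disjoint position sets, so order is irrelevant.
    """
    if position in anchors.anchor_positions:
        raise ValueError(
            f"p{position} is an anchor; the point substitution must target a "
            "TCR-facing position"
        )
    grafted = graft(wt, motif, anchors)
    point = point_substitute(grafted.designed, position, new)
    subs = grafted.substitutions + point.substitutions
    return DesignResult(wt, point.designed, tuple(sorted(subs, key=lambda s: s.position)), "graft")


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def flag_conservative(sub: Substitution, scheme: str = "blosum62") -> bool | None:
    """Label a substitution conservative under a similarity scheme.

    Default scheme: BLOSUM62 score > 0 (identity pairs are conservative by
    definition). Substitutions involving non-natural residues return None
    ("unknown"). The scheme name should be recorded alongside the flag in
    any report; qualitative conservativeness calls in the literature do not
    all follow one criterion, so this flag is descriptive metadata only.
    """
    if scheme != "blosum62":
        raise ValueError(f"unknown similarity scheme {scheme!r}")
    if not (sub.wt_residue.is_natural and sub.new_residue.is_natural):
        return None
    if sub.wt_residue.code == sub.new_residue.code:
        return True
    return float(_blosum62()[sub.wt_residue.code, sub.new_residue.code]) > 0


def annotate_conservative(sub: Substitution, scheme: str = "blosum62") -> Substitution:
    """Copy of `sub` with the conservative flag filled in."""
    return Substitution(
        sub.wt_residue, sub.position, sub.new_residue,
        conservative=flag_conservative(sub, scheme),
    )
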