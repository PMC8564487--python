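"""Weighted position frequency matrices and anchor-consensus motifs.

Given a set of same-length strong-binder peptides for one MHC allele, this
module builds a position weight matrix (PWM) with Henikoff & Henikoff
position-based sequence weighting and substitution-matrix pseudocounts,
computes per-position information content for sequence-logo output, and
derives the allele's anchor-consensus *scaffold motif*: the most frequent
residue at each anchor position, wildcards everywhere else (rendered as
lowercase 'x', e.g. ``xALxNxxxL`` for H-2Db 9-mers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import NATURAL_AMINO_ACIDS, NATURAL_RESIDUES, Residue
from .peptide import AnchorMap, Peptide

logger = logging.getLogger(__name__)

ALPHABET: tuple[str, ...] = NATURAL_AMINO_ACIDS
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
N_ALPHABET = len(ALPHABET)
MAX_BITS = float(np.log2(N_ALPHABET))

#: Default pseudocount strength (beta); alpha is effective_n - 1.
DEFAULT_PSEUDOCOUNT = 50.0


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Position x residue profile built from a weighted peptide alignment.

    ``weighted_freq`` holds weighted relative frequencies (rows sum to 1),
    ``prob`` the pseudocount-corrected probabilities (strictly positive when
    pseudocount strength > 0), and ``info_bits`` the per-position information
    content against a flat 1/20 background.
    """

    length: int
    alphabet: tuple[str, ...]
    weighted_freq: np.ndarray
    prob: np.ndarray
    info_bits: np.ndarray
    n_sequences: int
    effective_n: float

    def __post_init__(self) -> None:
        for name in ("weighted_freq", "prob"):
            m = getattr(self, name)
            if m.shape != (self.length, N_ALPHABET):
                raise ValueError(f"{name} must be {self.length}x{N_ALPHABET}")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"rows of {name} must sum to 1")
        if np.any(self.prob < 0):
            raise ValueError("probabilities must be non-negative")
        if np.any(self.info_bits < -1e-12) or np.any(self.info_bits > MAX_BITS + 1e-12):
            raise ValueError(f"information content must lie in [0, {MAX_BITS}]")

    def probability(self, position: int, residue: str | Residue) -> float:
        """Pseudocount-corrected probability at a 1-based position."""
        code = residue.code if isinstance(residue, Residue) else residue
        return float(self.prob[position - 1, _INDEX[code]])

    def argmax_residue(self, position: int) -> Residue:
        """Most probable residue at a 1-based position (ties: first letter)."""
        row = self.prob[position - 1]
        return NATURAL_RESIDUES[ALPHABET[int(np.argmax(row))]]


def _as_index_matrix(peptides: Sequence[Peptide]) -> np.ndarray:
    if not peptides:
        raise ValueError("at least one peptide is required")
    length = len(peptides[0])
    idx = np.empty((len(peptides), length), dtype=np.intp)
    for i, pep in enumerate(peptides):
        if len(pep) != length:
            raise ValueError(
                f"all peptides must share one length; got {len(pep)} != {length} "
                f"for {pep}"
            )
        for j, res in enumerate(pep):
            if not res.is_natural:
                raise ValueError(
                    f"motif construction is over the natural alphabet; "
                    f"{pep} contains non-natural {res.label!r}"
                )
            idx[i, j] = _INDEX[res.code]
    return idx


def sequence_weights(peptides: Sequence[Peptide]) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, mean-normalized.

    At each column a residue observed in s sequences among r distinct
    residues contributes 1/(r*s) to each of those sequences; the per-peptide
    sums are rescaled so the weights average 1. Rare sequences are
    up-weighted, duplicates share identical weight, and a homogeneous set
    gets uniform weights.
    """
    idx = _as_index_matrix(peptides)
    n, length = idx.shape
    weights = np.zeros(n)
    for j in range(length):
        column = idx[:, j]
        codes, inverse, counts = np.unique(column, return_inverse=True, return_counts=True)
        r = len(codes)
        weights += 1.0 / (r * counts[inverse])
    return weights * (n / weights.sum())


@lru_cache(maxsize=None)
def _blosum62_conditional() -> np.ndarray:
    """Conditional matrix q[a, b] ~ P(a | b) recovered from BLOSUM62 scores.

    BLOSUM scores are rounded half-bit log-odds, so 2^(s/2) is proportional
    to the pair target frequency over the product of backgrounds; taking a
    flat background and normalizing each column in `b` yields a deterministic
    conditional substitution profile used for pseudocounts.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    raw = np.empty((N_ALPHABET, N_ALPHABET))
    for a_i, a in enumerate(ALPHABET):
        for b_i, b in enumerate(ALPHABET):
            raw[a_i, b_i] = 2.0 ** (blosum[a, b] / 2.0)
    return raw / raw.sum(axis=0, keepdims=True)


def build_pwm(
    peptides: Sequence[Peptide],
    weights: np.ndarray | None = None,
    pseudocount_strength: float = DEFAULT_PSEUDOCOUNT,
) -> PositionWeightMatrix:
    """Build a PWM from same-length natural peptides.

    Weighted relative frequencies ``f`` are blended with BLOSUM62-derived
    pseudo-frequencies ``g`` as ``(alpha*f + beta*g) / (alpha + beta)`` with
    ``alpha = effective_n - 1`` and ``beta = pseudocount_strength``; with
    beta = 0 (and uniform weights) the probabilities are the raw relative
    frequencies, the mode used by count-based oracles.
    """
    if pseudocount_strength < 0:
        raise ValueError("pseudocount_strength must be non-negative")
    idx = _as_index_matrix(peptides)
    n, length = idx.shape
    if weights is None:
        weights = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n,):
            raise ValueError(f"weights must have shape ({n},), got {weights.shape}")
        if np.any(weights <= 0):
            raise ValueError("weights must be strictly positive")

    freq = np.zeros((length, N_ALPHABET))
    for j in range(length):
        np.add.at(freq[j], idx[:, j], weights)
    freq /= weights.sum()

    # Henikoff heuristic: effective sample size = mean distinct residues/column.
    effective_n = float(np.mean([len(np.unique(idx[:, j])) for j in range(length)]))

    beta = float(pseudocount_strength)
    if beta == 0.0:
        prob = freq.copy()
    else:
        alpha = max(effective_n - 1.0, 0.0)
        pseudo = freq @ _blosum62_conditional().T  # g[p,a] = sum_b f[p,b] q(a|b)
        prob = (alpha * freq + beta * pseudo) / (alpha + beta)

    return PositionWeightMatrix(
        length=length,
        alphabet=ALPHABET,
        weighted_freq=freq,
        prob=prob,
        info_bits=_information(prob),
        n_sequences=n,
        effective_n=effective_n,
    )


def _information(prob: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(prob > 0, prob * np.log2(prob), 0.0)
    entropy = -plogp.sum(axis=1)
    return np.clip(MAX_BITS - entropy, 0.0, MAX_BITS)


def information_content(pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-position information in bits: log2(20) minus the Shannon entropy
    of the corrected probabilities (flat-background Kullback-Leibler form)."""
    return _information(pwm.prob)


@dataclass(frozen=True)
class ScaffoldMotif:
    """Anchor-consensus template: fixed residues at anchors, wildcards elsewhere."""

    length: int
    fixed: dict[int, Residue]

    def __post_init__(self) -> None:
        for pos in self.fixed:
            if not 1 <= pos <= self.length:
                raise ValueError(f"fixed position {pos} outside 1..{self.length}")

    @property
    def wildcard_positions(self) -> frozenset[int]:
        return frozenset(range(1, self.length + 1)) - set(self.fixed)

    @property
    def display(self) -> str:
        """Template string with lowercase 'x' wildcards, e.g. 'xALxNxxxL'."""
        return "".join(
            self.fixed[p].code if p in self.fixed else "x"
            for p in range(1, self.length + 1)
        )

    def __str__(self) -> str:
        return self.display


def motif_from_display(display: str) -> ScaffoldMotif:
    """Parse a template string such as 'xALxNxxxL' (x = wildcard)."""
    fixed = {
        i: NATURAL_RESIDUES[c]
        for i, c in enumerate(display, 1)
        if c != "x"
    }
    return ScaffoldMotif(length=len(display), fixed=fixed)


def anchor_consensus(pwm: PositionWeightMatrix, anchors: AnchorMap) -> ScaffoldMotif:
    """Most-frequent residue at each anchor position; wildcards elsewhere.

    Exact probability ties are broken lexicographically by residue letter
    (the alphabet is sorted) and logged as a warning.
    """
    if pwm.length != anchors.length:
        raise ValueError(
            f"PWM length {pwm.length} != anchor map length {anchors.length}"
        )
    fixed: dict[int, Residue] = {}
    for pos in sorted(anchors.anchor_positions):
        row = pwm.prob[pos - 1]
        best = int(np.argmax(row))
        ties = np.flatnonzero(row == row[best])
        if len(ties) > 1:
            letters = [ALPHABET[t] for t in ties]
            logger.warning(
                "anchor p%d: probability tie among %s; choosing %r (lexicographic)",
                pos, letters, ALPHABET[best],
            )
        fixed[pos] = NATURAL_RESIDUES[ALPHABET[best]]
    return ScaffoldMotif(length=pwm.length, fixed=fixed)
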