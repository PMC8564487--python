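"""Binding comparison utilities: PWM log-odds scoring and affinity fold change.

Two scales coexist and are never mixed in a single ranking:

* IC50-like affinities in nM (lower = stronger binding), typically from an
  external predictor or a binding assay, compared via :func:`fold_change`;
* internal PWM log-odds scores (higher = better motif fit), a lightweight
  surrogate ranking for peptide sets when no predictor output is at hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motif import ALPHABET, N_ALPHABET, PositionWeightMatrix
from .peptide import Peptide

_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class AffinityRecord:
    """An IC50-like affinity in nM; lower values mean stronger binding."""

    peptide_id: str
    affinity_nM: float
    source: str = "user"  # predicted | measured | user

    def __post_init__(self) -> None:
        if not self.affinity_nM > 0:
            raise ValueError(f"affinity must be positive, got {self.affinity_nM}")


@dataclass(frozen=True)
class BindingScore:
    """PWM log-odds score: sum over positions of log2(prob / background)."""

    peptide_id: str
    logodds: float
    percentile: float | None = None


def pwm_score(
    peptide: Peptide,
    pwm: PositionWeightMatrix,
    peptide_id: str | None = None,
) -> BindingScore:
    """Log-odds of a natural peptide under a PWM with flat 1/20 background.

    Additive over positions; the PWM's per-position argmax sequence attains
    the maximal score among all natural sequences of that length.
    """
    if len(peptide) != pwm.length:
        raise ValueError(f"peptide length {len(peptide)} != PWM length {pwm.length}")
    total = 0.0
    for pos, res in enumerate(peptide, 1):
        if not res.is_natural:
            raise ValueError(
                f"cannot PWM-score non-natural residue {res.label!r} at p{pos}; "
                "supply a similarity row in the registry or an explicit affinity"
            )
        p = pwm.prob[pos - 1, _INDEX[res.code]]
        if p <= 0:
            return BindingScore(peptide_id or str(peptide), float("-inf"))
        total += float(np.log2(p * N_ALPHABET))
    return BindingScore(peptide_id or str(peptide), total)


def fold_change(wt_affinity_nM: float, variant_affinity_nM: float) -> float:
    """Affinity improvement of a variant over wild type: wt / variant in nM.

    The ratio is > 1 when the variant binds more strongly (lower nM), so a
    "356.6-fold increase in binding affinity" corresponds to wt 6990 nM vs
    variant 19.6 nM. Report rounded to one decimal in summaries; full
    precision is retained here.
    """
    if not (wt_affinity_nM > 0 and variant_affinity_nM > 0):
        raise ValueError("affinities must be positive nM values")
    return wt_affinity_nM / variant_affinity_nM


def rank_designs(
    records: Sequence[AffinityRecord] | Sequence[BindingScore],
) -> list[AffinityRecord] | list[BindingScore]:
    """Order records best-binder first; ties keep input order (stable).

    Affinities sort ascending (lower nM = stronger); log-odds sort
    descending. Mixing the two record types is an error: the scales are not
    comparable.
    """
    if not records:
        return []
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise TypeError("cannot rank a mixture of affinity and log-odds records")
    if isinstance(records[0], AffinityRecord):
        return sorted(records, key=lambda r: r.affinity_nM)
    if isinstance(records[0], BindingScore):
        return sorted(records, key=lambda r: -r.logodds)
    raise TypeError(f"unsupported record type {kinds.pop().__name__}")
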