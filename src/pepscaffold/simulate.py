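"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and seed (same seed,
byte-identical output) and emulates the statistical structure of one input
regime:

* :func:`sample_binders` — strong-binder 9-mer sets with dominant anchor
  residues over a background distribution, the input to motif building.
  The default anchor profile encodes the canonical H-2Db consensus
  (A at p2, L at p3, N at p5, L at p9), so the end-to-end demo recovers
  the ``xALxNxxxL`` scaffold out of the box.
* :func:`simulate_elispot` — duplicate spot-count tables with a specified
  group x challenge cross-reactivity structure, negative-binomial well
  noise and a negative-control background.
* :func:`simulate_tumor_growth` — exponential caliper growth with a
  multiplicative treatment effect, lognormal measurement noise and
  threshold-crossing death events.
* :func:`simulate_ihc` — lognormal lymphocyte densities with region
  (central tumor vs invasive margin) effects.

Distribution choices (negative binomial for counts, lognormal for
densities, exponential growth) are the simplest structures that exercise
the analytics' floors, sign logic and thresholds; they are not mechanistic
immune models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import NATURAL_AMINO_ACIDS, NATURAL_RESIDUES
from .assays import ElispotRecord, IhcCounts, TumorMeasurement, tumor_volume
from .peptide import Peptide

#: Death/censoring threshold for tumor burden (mm^3).
TUMOR_EVENT_VOLUME = 1500.0

#: Canonical H-2Db 9-mer anchor profile: dominant residue and frequency per anchor.
DEFAULT_ANCHOR_PROFILE: dict[int, tuple[str, float]] = {
    2: ("A", 0.7),
    3: ("L", 0.7),
    5: ("N", 0.8),
    9: ("L", 0.8),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for the strong-binder sampler.

    anchor_profile maps 1-based anchor positions to (dominant residue,
    frequency); the remaining probability mass at an anchor, and all mass at
    non-anchor positions, follows `background` (default: uniform over the
    20 natural residues).
    """

    seed: int = 0
    n: int = 250
    length: int = 9
    anchor_profile: Mapping[int, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHOR_PROFILE)
    )
    background: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.length < 1:
            raise ValueError("n and length must be positive")
        for pos, (residue, freq) in self.anchor_profile.items():
            if not 1 <= pos <= self.length:
                raise ValueError(f"anchor position {pos} outside 1..{self.length}")
            if residue not in NATURAL_RESIDUES:
                raise ValueError(f"unknown anchor residue {residue!r}")
            if not 0 < freq <= 1:
                raise ValueError(f"anchor frequency must lie in (0, 1], got {freq}")


def _background_vector(background: Mapping[str, float] | None) -> np.ndarray:
    if background is None:
        return np.full(len(NATURAL_AMINO_ACIDS), 1.0 / len(NATURAL_AMINO_ACIDS))
    vec = np.array([background.get(aa, 0.0) for aa in NATURAL_AMINO_ACIDS], dtype=float)
    if vec.sum() <= 0:
        raise ValueError("background distribution must have positive mass")
    return vec / vec.sum()


def position_distributions(spec: GeneratorSpec) -> np.ndarray:
    """The generator's own per-position residue distributions (length x 20).

    At an anchor the dominant residue gets its stated frequency and the
    remainder is spread over the background renormalized without it; other
    positions are pure background. This table is the oracle against which
    motif recovery is tested.
    """
    bg = _background_vector(spec.background)
    dist = np.tile(bg, (spec.length, 1))
    index = {aa: i for i, aa in enumerate(NATURAL_AMINO_ACIDS)}
    for pos, (residue, freq) in spec.anchor_profile.items():
        row = bg.copy()
        row[index[residue]] = 0.0
        remainder = row.sum()
        row = row * ((1.0 - freq) / remainder) if remainder > 0 else row
        row[index[residue]] = freq
        dist[pos - 1] = row
    return dist


def sample_binders(spec: GeneratorSpec) -> list[Peptide]:
    """Draw n fixed-length peptides from the spec's position distributions."""
    rng = np.random.default_rng(spec.seed)
    dist = position_distributions(spec)
    columns = [
        rng.choice(len(NATURAL_AMINO_ACIDS), size=spec.n, p=dist[j])
        for j in range(spec.length)
    ]
    idx = np.stack(columns, axis=1)
    return [
        Peptide(tuple(NATURAL_RESIDUES[NATURAL_AMINO_ACIDS[k]] for k in row))
        for row in idx
    ]


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Counts around `mean`: exact in the noiseless limit, else negative binomial.

    `dispersion` d sets the excess variance var = mean + d * mean^2; d = 0
    degenerates to the mean itself (the exact-recovery limit used by tests).
    """
    if mean < 0:
        raise ValueError("count means must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0 or mean == 0:
        return np.full(size, float(mean))
    k = 1.0 / dispersion
    return rng.negative_binomial(k, k / (k + mean), size=size).astype(float)


def simulate_elispot(
    cross_matrix: pd.DataFrame,
    dispersion: float = 0.1,
    negative_mean: float = 5.0,
    n_mice: int = 6,
    seed: int = 0,
) -> list[ElispotRecord]:
    """Duplicate spot-count records for a group x challenge mean-SFC design.

    `cross_matrix` rows are immunogen groups, columns challenge peptides,
    entries the intended mean SFC above background; the self challenge
    (row label == column label) should be the row maximum. Each mouse
    contributes one record per group x challenge with duplicate wells drawn
    around mean + negative background, plus its own control wells.
    """
    if (cross_matrix.values < 0).any():
        raise ValueError("cross-reactivity means must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for group in cross_matrix.index:
        for challenge in cross_matrix.columns:
            mean = float(cross_matrix.loc[group, challenge])
            for mouse in range(n_mice):
                wells = _draw_counts(rng, mean + negative_mean, dispersion, 2)
                control = _draw_counts(rng, negative_mean, dispersion, 1)[0]
                records.append(
                    ElispotRecord(
                        group=str(group),
                        challenge=str(challenge),
                        duplicate_counts=(float(wells[0]), float(wells[1])),
                        negative_control=float(control),
                    )
                )
    return records


def simulate_tumor_growth(
    n_mice: int = 6,
    growth_rate: float = 0.25,
    treatment_factor: float = 0.7,
    schedule_days: Sequence[int] = tuple(range(7, 29, 2)),
    measurement_sd: float = 0.1,
    seed: int = 0,
    initial_diameter: float = 2.0,
    axis_ratio: float = 0.8,
) -> pd.DataFrame:
    """Caliper measurement series for a control and a treated arm.

    The mean largest diameter grows exponentially from `initial_diameter`
    (mm) at `growth_rate` per day (treated arm: rate scaled by
    `treatment_factor`); the smallest diameter is `axis_ratio` times the
    largest. Lognormal noise of sd `measurement_sd` (log scale) perturbs
    each measurement. Volume uses the caliper formula A*B^2/2 and the
    `event` column flags volumes above 1500 mm^3 (counted as death).
    """
    if growth_rate <= 0 or initial_diameter <= 0:
        raise ValueError("growth rate and initial diameter must be positive")
    if not 0 < treatment_factor <= 1:
        raise ValueError("treatment factor must lie in (0, 1]")
    if measurement_sd < 0:
        raise ValueError("measurement sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for arm, factor in (("control", 1.0), ("treated", treatment_factor)):
        rate = growth_rate * factor
        for mouse in range(n_mice):
            for day in schedule_days:
                mean_a = initial_diameter * float(np.exp(rate * day))
                noise = (
                    float(np.exp(rng.normal(0.0, measurement_sd)))
                    if measurement_sd > 0 else 1.0
                )
                a = mean_a * noise
                b = a * axis_ratio
                m = TumorMeasurement(A=a, B=b, day=int(day))
                vol = tumor_volume(m)
                rows.append(
                    {
                        "arm": arm, "mouse": mouse, "day": int(day),
                        "A_mm": m.A, "B_mm": m.B, "volume_mm3": vol,
                        "event": vol > TUMOR_EVENT_VOLUME,
                    }
                )
    return pd.DataFrame(rows)


def expected_event_day(
    growth_rate: float,
    treatment_factor: float = 1.0,
    initial_diameter: float = 2.0,
    axis_ratio: float = 0.8,
    threshold: float = TUMOR_EVENT_VOLUME,
) -> float:
    """Closed-form day at which the noiseless growth curve crosses the
    death threshold: solve A(t) * (r*A(t))^2 / 2 = threshold for t."""
    rate = growth_rate * treatment_factor
    # volume = d0^3 r^2 / 2 * exp(3 rate t)
    v0 = initial_diameter**3 * axis_ratio**2 / 2.0
    return float(np.log(threshold / v0) / (3.0 * rate))


def simulate_ihc(
    group_means: Mapping[str, Mapping[str, Mapping[str, float]]],
    n_samples: int = 6,
    sigma: float = 0.3,
    seed: int = 0,
) -> list[IhcCounts]:
    """Lognormal lymphocyte-density records around group x region means.

    `group_means[group][region][marker]` gives the intended mean density
    (cells/mm^2) for markers 'cd3', 'grzb', 'foxp3' in regions 'CT'/'IM'.
    Draws are mean * exp(sigma*Z - sigma^2/2), so expected values equal the
    specified means and immunoscore signs propagate from (grzb - foxp3).
    A zero mean yields identically zero densities.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for group in sorted(group_means):
        regions = group_means[group]
        for region in sorted(regions):
            markers = regions[region]
            for i in range(n_samples):
                draws = {}
                for marker in ("cd3", "grzb", "foxp3"):
                    mean = float(markers[marker])
                    if mean < 0:
                        raise ValueError("density means must be non-negative")
                    if mean == 0 or sigma == 0:
                        draws[marker] = mean
                    else:
                        z = rng.normal(0.0, 1.0)
                        draws[marker] = mean * float(np.exp(sigma * z - sigma**2 / 2))
                records.append(
                    IhcCounts(
                        sample=f"{group}-{region}-{i}",
                        region=region,
                        cd3=draws["cd3"],
                        grzb=draws["grzb"],
                        foxp3=draws["foxp3"],
                    )
                )
    return records
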