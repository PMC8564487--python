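"""Immunoassay arithmetic over tidy replicate tables.

Covers the readouts of a preclinical peptide-vaccine study:

* IFN-gamma ELISpot: spot-forming counts (duplicate mean minus negative
  control, floored at zero) and cross-reactivity percentages relative to
  the self-immunogen response (set to 100);
* caliper tumor volume A*B^2/2;
* CFSE/PI cytotoxicity with the standard spontaneous-death correction;
* immunohistochemistry: the (GrzB - FOXP3)/CD3 immunoscore ratio with its
  sign interpretation, and percent necrotic area;
* group mean +/- SEM summaries.

All functions are pure; a quantity that an assay cannot define (e.g. a
cross-reactivity percentage when the reference response is zero) raises
:class:`NotEvaluable`, which table-level code reports as '.'.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class NotEvaluable(ValueError):
    """The assay's reference quantity is missing or zero; no value exists."""


@dataclass(frozen=True)
class ElispotRecord:
    """Duplicate spot counts for one immunogen group x challenge peptide."""

    group: str
    challenge: str
    duplicate_counts: tuple[float, float]
    negative_control: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.duplicate_counts) or self.negative_control < 0:
            raise ValueError("spot counts must be non-negative")


def elispot_sfc(record: ElispotRecord) -> float:
    """Spot-forming count: mean of the duplicate wells minus the negative
    control, floored at zero (background above signal is reported as 0)."""
    raw = sum(record.duplicate_counts) / 2.0 - record.negative_control
    if raw < 0:
        logger.info(
            "SFC floored at 0 for %s/%s (background %s above duplicate mean)",
            record.group, record.challenge, record.negative_control,
        )
        return 0.0
    return raw


def cross_reactivity_percent(sfc_challenge: float, sfc_self: float) -> float:
    """Challenge response as a percentage of the self-immunogen response.

    The self-restimulation response defines 100; a zero self response makes
    the percentage undefined (NotEvaluable), matching assay practice.
    """
    if sfc_challenge < 0 or sfc_self < 0:
        raise ValueError("spot-forming counts must be non-negative")
    if sfc_self == 0:
        raise NotEvaluable("self-restimulation SFC is zero; reactivity undefined")
    return 100.0 * sfc_challenge / sfc_self


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement: largest (A) and smallest (B) diameter in mm."""

    A: float
    B: float
    day: int = 0

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("diameters must be non-negative")
        if self.B > self.A:
            logger.warning(
                "day %s: B (%.3g) > A (%.3g); swapping so A is the largest diameter",
                self.day, self.B, self.A,
            )
            a, b = self.B, self.A
            object.__setattr__(self, "A", a)
            object.__setattr__(self, "B", b)


def tumor_volume(m: TumorMeasurement) -> float:
    """Caliper volume in mm^3: A * B^2 / 2."""
    return m.A * m.B * m.B / 2.0


@dataclass(frozen=True)
class IhcCounts:
    """Lymphocyte densities (cells/mm^2) in one tumor region (CT or IM)."""

    sample: str
    region: str  # CT (central tumor) | IM (invasive margin)
    cd3: float
    grzb: float
    foxp3: float

    def __post_init__(self) -> None:
        if min(self.cd3, self.grzb, self.foxp3) < 0:
            raise ValueError("cell densities must be non-negative")
        if self.region not in ("CT", "IM"):
            raise ValueError(f"region must be CT or IM, got {self.region!r}")
        if self.grzb > self.cd3 or self.foxp3 > self.cd3:
            logger.warning(
                "sample %s/%s: marker density exceeds CD3 density "
                "(GrzB %.3g, FOXP3 %.3g, CD3 %.3g)",
                self.sample, self.region, self.grzb, self.foxp3, self.cd3,
            )


#: Sign labels for the immunoscore ratio.
CYTOTOXIC, IMMUNOSUPPRESSIVE, BALANCED = "cytotoxic", "immunosuppressive", "balanced"


def immunoscore_ratio(c: IhcCounts) -> tuple[float, str]:
    """(GrzB - FOXP3) / CD3 with its sign interpretation.

    A positive ratio indicates an active cytotoxic microenvironment, a
    negative one an immunosuppressive microenvironment; zero is balanced.
    """
    if c.cd3 == 0:
        raise NotEvaluable(f"sample {c.sample}/{c.region}: CD3 density is zero")
    ratio = (c.grzb - c.foxp3) / c.cd3
    label = CYTOTOXIC if ratio > 0 else IMMUNOSUPPRESSIVE if ratio < 0 else BALANCED
    return ratio, label


def necrosis_percent(necrosis_area: float, total_area: float) -> float:
    """Necrotic fraction of the tumoral mass, as a percentage."""
    if total_area <= 0:
        raise ValueError("total tumoral mass area must be positive")
    if not 0 <= necrosis_area <= total_area:
        raise ValueError("necrosis area must lie between 0 and the total area")
    return 100.0 * necrosis_area / total_area


def cytotoxicity_percent(
    dead_labeled_targets: float,
    total_labeled_targets: float,
    spontaneous_fraction: float = 0.0,
) -> float:
    """Specific lysis of CFSE-labeled targets, percent, per E:T ratio.

    Standard spontaneous-death correction:
    100 * (dead/total - spontaneous) / (1 - spontaneous), floored at 0.
    """
    if total_labeled_targets <= 0:
        raise NotEvaluable("no labeled target cells")
    if not 0 <= dead_labeled_targets <= total_labeled_targets:
        raise ValueError("dead targets must lie between 0 and the total")
    if not 0 <= spontaneous_fraction < 1:
        raise ValueError("spontaneous death fraction must lie in [0, 1)")
    experimental = dead_labeled_targets / total_labeled_targets
    lysis = 100.0 * (experimental - spontaneous_fraction) / (1.0 - spontaneous_fraction)
    return max(lysis, 0.0)


def group_summary(
    table: pd.DataFrame | Sequence[dict],
    grouping: str | Sequence[str],
    value: str = "value",
) -> pd.DataFrame:
    """Mean and standard error of the mean (sd/sqrt(n)) per group.

    Groups of size 1 report SEM as NaN (not evaluable); empty groups cannot
    occur in a tidy table and groups whose values are all missing are
    dropped with a warning.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    if df.empty:
        raise ValueError("summary requires at least one record")
    keys = [grouping] if isinstance(grouping, str) else list(grouping)
    dropped = df[df[value].isna()]
    if not dropped.empty:
        logger.warning("dropping %d records with missing %r", len(dropped), value)
        df = df.dropna(subset=[value])
    grouped = df.groupby(keys, sort=True)[value]
    out = grouped.agg(mean="mean", sem="sem", n="count").reset_index()
    out.loc[out["n"] == 1, "sem"] = math.nan
    return out


def elispot_report(records: Sequence[ElispotRecord]) -> pd.DataFrame:
    """Tidy SFC + cross-reactivity table from raw duplicate counts.

    For each immunogen group the self challenge (challenge == group) defines
    100%; groups lacking a self row, or with zero self SFC, get NaN
    reactivity (rendered '.' in TSV output).
    """
    rows = []
    sfc_by_group_challenge: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        sfc = elispot_sfc(rec)
        rows.append(
            {"group": rec.group, "challenge": rec.challenge, "sfc": sfc}
        )
        sfc_by_group_challenge.setdefault((rec.group, rec.challenge), []).append(sfc)

    self_mean = {
        group: sum(v) / len(v)
        for (group, challenge), v in sfc_by_group_challenge.items()
        if group == challenge
    }
    for row in rows:
        ref = self_mean.get(row["group"])
        try:
            row["reactivity_pct"] = (
                cross_reactivity_percent(row["sfc"], ref) if ref is not None
                else math.nan
            )
        except NotEvaluable:
            row["reactivity_pct"] = math.nan
    return pd.DataFrame(rows)
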