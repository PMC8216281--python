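"""Well aggregation, plate QC (Z' factor, CV) and hit calling.

Per-bead protein/RNA ratios are averaged within wells (per-bead ratio
first, then the well mean — the per-bead distribution the on-bead assay
provides is preserved).  Control statistics (mean, SD, CV) are computed
between replicate control wells, and assay quality is summarized by the
screening-window coefficient::

    Z' = 1 - 3 (SD_pos + SD_neg) / |Mean_pos - Mean_neg|

Z' > 0.5 indicates an excellent assay window.  Hits are called by two
rules: (a) well mean below the negative-control mean minus k x SD
(default k = 3, between-well SD), and (b) percent inhibition exceeding
k x CV of the negative controls (default k = 6).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import QCError, ZPrimeUndefinedError
from .ringquant import BeadMeasurement

logger = logging.getLogger(__name__)


@dataclass
class WellSummary:
    """Per-well ratio statistics over valid beads."""

    well: str
    n_beads_valid: int
    mean_ratio: float | None
    sd_ratio: float | None
    valid: bool
    relative_ratio: float | None = None
    percent_inhibition: float | None = None
    role: str = ""
    compound: str = ""
    concentration_um: float | None = None


@dataclass
class ControlStats:
    """Between-well statistics of one control role."""

    role: str
    n_wells: int
    mean: float
    sd: float
    cv: float  # percent, 100 * sd / mean
    bead_sd_fallback: bool = False


@dataclass
class HitCall:
    """Hit flags of one test well under the two calling rules."""

    well: str
    compound: str
    concentration_um: float | None
    percent_inhibition: float
    rule_a_hit: bool
    rule_b_hit: bool
    stabilizer: bool = False


def summarize_well(
    measurements: list[BeadMeasurement],
    min_beads: int = 50,
    well: str | None = None,
) -> WellSummary:
    """Mean/SD of the per-bead ratio over valid beads (sample SD, n-1)."""
    wells = {m.well for m in measurements if m.well}
    if well is None:
        well = wells.pop() if len(wells) == 1 else ""
    ratios = [m.ratio for m in measurements if m.valid and m.ratio is not None]
    n = len(ratios)
    if n == 0:
        return WellSummary(well=well, n_beads_valid=0, mean_ratio=None,
                           sd_ratio=None, valid=False)
    mean = sum(ratios) / n
    sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (n - 1)) if n > 1 else 0.0
    return WellSummary(
        well=well,
        n_beads_valid=n,
        mean_ratio=mean,
        sd_ratio=sd,
        valid=n >= min_beads,
    )


def control_stats(wells: list[WellSummary], role: str) -> ControlStats:
    """Between-well mean/SD/CV of one control role.

    Requires at least two valid wells of the role; with exactly one valid
    well the between-bead SD of that well stands in for the between-well
    SD and the result is flagged ``bead_sd_fallback``.
    """
    usable = [w for w in wells if w.role == role and w.valid]
    invalid = [w for w in wells if w.role == role and not w.valid]
    if invalid:
        logger.warning(
            "%d invalid %s well(s) excluded from control statistics: %s",
            len(invalid), role, [w.well for w in invalid],
        )
    if not usable:
        raise QCError(f"no valid wells with role {role!r}")
    means = [w.mean_ratio for w in usable]
    n = len(means)
    mean = sum(means) / n
    if n >= 2:
        sd = math.sqrt(sum((m - mean) ** 2 for m in means) / (n - 1))
        fallback = False
    else:
        sd = usable[0].sd_ratio or 0.0
        fallback = True
        logger.warning(
            "single valid %s well: using between-bead SD as a stand-in "
            "for between-well SD", role,
        )
    cv = 100.0 * sd / mean if mean != 0 else float("inf")
    return ControlStats(role=role, n_wells=n, mean=mean, sd=sd, cv=cv,
                        bead_sd_fallback=fallback)


def z_prime(neg: ControlStats, pos: ControlStats) -> float:
    """Screening-window coefficient from the two control populations."""
    window = abs(pos.mean - neg.mean)
    if window == 0:
        raise ZPrimeUndefinedError(
            "Z' undefined: positive- and negative-control means coincide"
        )
    return 1.0 - 3.0 * (pos.sd + neg.sd) / window


def normalize_and_inhibition(
    wells: list[WellSummary], neg: ControlStats
) -> list[WellSummary]:
    """Attach relative ratio and percent inhibition to each valid well.

    ``relative_ratio = mean_ratio / neg.mean`` and
    ``percent_inhibition = 100 * (1 - relative_ratio)``; inhibition is
    negative for wells where the ratio rises above the negative controls
    (stabilizers).  Modifies the summaries in place and returns them.
    """
    if neg.mean <= 0:
        raise QCError(
            f"cannot normalize: negative-control mean {neg.mean} is not > 0"
        )
    for w in wells:
        if w.mean_ratio is None:
            continue
        w.relative_ratio = w.mean_ratio / neg.mean
        w.percent_inhibition = 100.0 * (1.0 - w.relative_ratio)
    return wells


def call_hits(
    wells: list[WellSummary],
    neg: ControlStats,
    rule_a_k: float = 3.0,
    rule_b_k: float = 6.0,
) -> list[HitCall]:
    """Flag inhibitor hits among non-control wells.

    Rule A: well mean below ``neg.mean - rule_a_k * neg.sd`` (the
    symmetric upper bound flags stabilizers separately, reported via
    ``stabilizer``).  Rule B: percent inhibition above
    ``rule_b_k * neg.cv`` (CV in percent, so with the defaults a 6.7% CV
    gives a 40.2% inhibition threshold).
    """
    calls: list[HitCall] = []
    lower = neg.mean - rule_a_k * neg.sd
    upper = neg.mean + rule_a_k * neg.sd
    for w in wells:
        if w.role != "compound" or not w.valid or w.mean_ratio is None:
            continue
        if w.percent_inhibition is None:
            raise QCError(
                f"well {w.well} has no percent_inhibition; run "
                "normalize_and_inhibition first"
            )
        calls.append(
            HitCall(
                well=w.well,
                compound=w.compound,
                concentration_um=w.concentration_um,
                percent_inhibition=w.percent_inhibition,
                rule_a_hit=w.mean_ratio < lower,
                rule_b_hit=w.percent_inhibition > rule_b_k * neg.cv,
                stabilizer=w.mean_ratio > upper,
            )
        )
    return calls
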