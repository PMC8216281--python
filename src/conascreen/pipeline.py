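"""End-to-end driver: detect -> quantify -> screen -> dose-response.

``run_pipeline`` consumes an image directory plus a plate layout and
writes the analysis artifacts (per-bead CSV, per-well CSV, QC JSON and,
for compounds with enough distinct doses, 4PL fit JSONs) into an output
directory.  All stages are deterministic, so a rerun on identical inputs
reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as detectmod
from . import plateio, ringquant, screen
from .config import RunConfig
from .doseresp import DoseResponseFit, fit_4pl
from .errors import QCError
from .plateio import PlateLayout
from .screen import ControlStats, HitCall, WellSummary
from .synthgen import ROLE_COMPOUND, ROLE_NEGATIVE, ROLE_POSITIVE

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    measurements: pd.DataFrame
    wells: list[WellSummary]
    neg_stats: ControlStats
    pos_stats: ControlStats
    z_prime: float
    hits: list[HitCall]
    fits: dict[str, DoseResponseFit]


def analyze_stacks(
    stacks: dict[tuple[str, int], dict[str, np.ndarray]],
    layout: PlateLayout,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run the full analysis on in-memory image stacks."""
    all_meas: list[ringquant.BeadMeasurement] = []
    for (well, field_id), stack in sorted(stacks.items()):
        ref = stack[config.reference_channel]
        loci = detectmod.detect_beads(ref, config.detect)
        n_flagged = sum(1 for l in loci if l.qc_flags)
        logger.info(
            "well %s field %d: %d beads detected (%d flagged)",
            well, field_id, len(loci), n_flagged,
        )
        all_meas.extend(
            ringquant.measure_field(
                stack,
                loci,
                config.reference_channel,
                config.signal_channel,
                config.quant,
                well=well,
                field_id=field_id,
            )
        )

    wells: list[WellSummary] = []
    for well in layout.wells:
        entry = layout[well]
        summary = screen.summarize_well(
            [m for m in all_meas if m.well == well],
            min_beads=config.screen.min_beads,
            well=well,
        )
        summary.role = entry.role
        summary.compound = entry.compound
        summary.concentration_um = entry.concentration_um
        wells.append(summary)

    neg = screen.control_stats(wells, ROLE_NEGATIVE)
    pos = screen.control_stats(wells, ROLE_POSITIVE)
    zp = screen.z_prime(neg, pos)
    screen.normalize_and_inhibition(wells, neg)
    hits = screen.call_hits(
        wells, neg, config.screen.rule_a_k, config.screen.rule_b_k
    )

    fits: dict[str, DoseResponseFit] = {}
    by_compound: dict[str, list[WellSummary]] = {}
    for w in wells:
        if w.role == ROLE_COMPOUND and w.valid and w.relative_ratio is not None:
            by_compound.setdefault(w.compound, []).append(w)
    for compound, cw in by_compound.items():
        doses = np.array([w.concentration_um for w in cw], dtype=float)
        if np.unique(doses).size < config.min_doses_for_fit:
            continue
        resp = np.array([w.relative_ratio for w in cw], dtype=float)
        fits[compound] = fit_4pl(doses, resp)
        logger.info(
            "compound %s: 4PL IC50 = %.3g uM (converged=%s)",
            compound, fits[compound].ic50, fits[compound].converged,
        )

    channels = [config.reference_channel, config.signal_channel]
    return PipelineResult(
        measurements=plateio.measurements_to_frame(all_meas, channels),
        wells=wells,
        neg_stats=neg,
        pos_stats=pos,
        z_prime=zp,
        hits=hits,
        fits=fits,
    )


def _control_stats_dict(stats: ControlStats) -> dict:
    return {
        "role": stats.role,
        "n_wells": stats.n_wells,
        "mean": stats.mean,
        "sd": stats.sd,
        "cv_percent": stats.cv,
        "bead_sd_fallback": stats.bead_sd_fallback,
    }


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.measurements.to_csv(out / "beads.csv", index=False)
    plateio.wells_to_frame(result.wells, result.hits).to_csv(
        out / "wells.csv", index=False
    )
    plateio.write_json(
        {
            "z_prime": result.z_prime,
            "negative_control": _control_stats_dict(result.neg_stats),
            "positive_control": _control_stats_dict(result.pos_stats),
        },
        out / "qc.json",
    )
    for compound, fit in result.fits.items():
        plateio.write_json(fit.to_dict(), out / f"fit_{compound}.json")


def run_pipeline(
    image_dir: str | Path,
    layout_path: str | Path,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Analyze a plate from disk and write all artifacts.

    Raises :class:`~conascreen.errors.QCError` (among others) when the
    plate cannot be QC'd, e.g. fewer than one valid control well per role.
    """
    layout = plateio.read_layout(layout_path)
    channels = [config.reference_channel, config.signal_channel]
    index = plateio.discover_images(image_dir, channels)
    stacks = {
        key: {ch: plateio.read_image(path) for ch, path in files.items()}
        for key, files in index.items()
    }
    known = set(layout.wells)
    unknown_wells = sorted({w for (w, _) in stacks} - known)
    if unknown_wells:
        raise QCError(f"images found for wells absent from layout: {unknown_wells}")
    result = analyze_stacks(stacks, layout, config)
    write_result(result, out_dir or config.output_dir)
    return result
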