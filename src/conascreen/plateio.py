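"""Plate-layout, image and result-table IO.

Images are single-channel 8/16-bit grayscale TIFFs, one file per
well/field/channel, named ``{well}_{field}_{channel}.tif``.  Layouts and
result tables are plain CSV; concentrations are always in uM and percent
inhibition always on the 0-100 scale.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import BeadLocus
from .errors import ConfigError, IndexingError
from .ringquant import BeadMeasurement
from .screen import HitCall, WellSummary
from .synthgen import PlateSim, ROLE_COMPOUND, ROLE_NEGATIVE, ROLE_POSITIVE

LAYOUT_COLUMNS = ["well", "role", "compound", "concentration_uM"]
_ROLES = {ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_COMPOUND}
DEFAULT_NAME_PATTERN = r"(?P<well>[A-Za-z]\d{1,2})_(?P<field>\d+)_(?P<channel>[^_.]+)\.tif{1,2}$"


@dataclass(frozen=True)
class LayoutEntry:
    well: str
    role: str
    compound: str = ""
    concentration_um: float | None = None


@dataclass
class PlateLayout:
    """Validated well -> role/compound/concentration mapping."""

    entries: list[LayoutEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.well in seen:
                raise ConfigError(f"duplicate well {e.well!r} in layout")
            seen.add(e.well)
            if e.role not in _ROLES:
                raise ConfigError(
                    f"unknown role {e.role!r} for well {e.well!r} "
                    f"(expected one of {sorted(_ROLES)})"
                )
            if e.role == ROLE_COMPOUND:
                if not e.compound or e.concentration_um is None:
                    raise ConfigError(
                        f"compound well {e.well!r} needs both a compound id "
                        "and a concentration_uM"
                    )
            elif e.compound or e.concentration_um is not None:
                raise ConfigError(
                    f"control well {e.well!r} must have empty "
                    "compound/concentration"
                )

    def __getitem__(self, well: str) -> LayoutEntry:
        for e in self.entries:
            if e.well == well:
                return e
        raise KeyError(well)

    @property
    def wells(self) -> list[str]:
        return [e.well for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well": e.well,
                    "role": e.role,
                    "compound": e.compound,
                    "concentration_uM": (
                        "" if e.concentration_um is None else e.concentration_um
                    ),
                }
                for e in self.entries
            ],
            columns=LAYOUT_COLUMNS,
        )


def read_layout(path: str | Path) -> PlateLayout:
    """Read and validate a plate-layout CSV (well,role,compound,concentration_uM)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"layout {path} lacks columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        conc_text = str(row["concentration_uM"]).strip()
        conc = float(conc_text) if conc_text else None
        entries.append(
            LayoutEntry(
                well=str(row["well"]).strip(),
                role=str(row["role"]).strip().lower(),
                compound=str(row["compound"]).strip(),
                concentration_um=conc,
            )
        )
    return PlateLayout(entries)


def write_layout(layout: PlateLayout | pd.DataFrame, path: str | Path) -> None:
    df = layout.to_frame() if isinstance(layout, PlateLayout) else layout
    df.to_csv(path, index=False)


def layout_from_frame(df: pd.DataFrame) -> PlateLayout:
    entries = []
    for _, row in df.iterrows():
        conc = row["concentration_uM"]
        if isinstance(conc, str):
            conc = float(conc) if conc.strip() else None
        elif pd.isna(conc):
            conc = None
        entries.append(
            LayoutEntry(
                well=str(row["well"]),
                role=str(row["role"]).lower(),
                compound=str(row.get("compound", "") or ""),
                concentration_um=conc,
            )
        )
    return PlateLayout(entries)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write one channel as 16-bit grayscale TIFF (AU clipped to uint16)."""
    arr = np.clip(np.round(image), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise IndexingError(f"{path} is not a single-channel 2-D image")
    return img.astype(float)


def image_name(well: str, field: int, channel: str) -> str:
    return f"{well}_{field}_{channel}.tif"


def discover_images(
    directory: str | Path,
    channels: list[str],
    pattern: str = DEFAULT_NAME_PATTERN,
) -> dict[tuple[str, int], dict[str, Path]]:
    """Index ``{well}_{field}_{channel}.tif`` files by (well, field).

    Every (well, field) must provide all configured channels; unparseable
    filenames are skipped with a warning.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IndexingError(f"{directory} is not a directory")
    rx = re.compile(pattern)
    index: dict[tuple[str, int], dict[str, Path]] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".tif", ".tiff"):
            continue
        m = rx.match(path.name)
        if not m:
            warnings.warn(f"skipping unparseable image name {path.name!r}",
                          stacklevel=2)
            continue
        key = (m.group("well"), int(m.group("field")))
        index.setdefault(key, {})[m.group("channel")] = path
    if not index:
        warnings.warn(f"no images found in {directory}", stacklevel=2)
    offenders = [
        f"{well} field {field}: missing {sorted(set(channels) - set(have))}"
        for (well, field), have in sorted(index.items())
        if not set(channels) <= set(have)
    ]
    if offenders:
        raise IndexingError(
            "incomplete channel sets: " + "; ".join(offenders)
        )
    return index


def write_plate_sim(plate: PlateSim, directory: str | Path) -> None:
    """Write a simulated plate: TIFFs, layout CSV and ground-truth CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (well, field), stack in plate.images.items():
        for channel, img in stack.items():
            write_image(img, directory / image_name(well, field, channel))
    write_layout(plate.layout, directory / "layout.csv")
    plate.truth.to_csv(directory / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def loci_to_frame(loci: list[BeadLocus], well: str = "",
                  field: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well": well,
                "field": field,
                "bead_id": l.bead_id,
                "center_row": l.center_row,
                "center_col": l.center_col,
                "radius_px": l.radius_px,
                "qc_flags": ";".join(sorted(l.qc_flags)),
            }
            for l in loci
        ],
        columns=["well", "field", "bead_id", "center_row", "center_col",
                 "radius_px", "qc_flags"],
    )


def frame_to_loci(df: pd.DataFrame) -> list[BeadLocus]:
    return [
        BeadLocus(
            bead_id=int(row.bead_id),
            center_row=float(row.center_row),
            center_col=float(row.center_col),
            radius_px=float(row.radius_px),
            qc_flags=set(str(row.qc_flags).split(";"))
            if isinstance(row.qc_flags, str) and row.qc_flags else set(),
        )
        for row in df.itertuples()
    ]


def measurements_to_frame(
    measurements: list[BeadMeasurement], channels: list[str]
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        row = {"well": m.well, "field": m.field, "bead_id": m.bead_id}
        for ch in channels:
            row[f"ring_{ch}"] = m.ring_intensity.get(ch, float("nan"))
        row["ratio"] = float("nan") if m.ratio is None else m.ratio
        row["valid"] = m.valid
        row["invalid_reason"] = m.invalid_reason
        rows.append(row)
    cols = ["well", "field", "bead_id"] + [f"ring_{c}" for c in channels] \
        + ["ratio", "valid", "invalid_reason"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_measurements(df: pd.DataFrame) -> list[BeadMeasurement]:
    ring_cols = [c for c in df.columns if c.startswith("ring_")]
    out = []
    for row in df.itertuples():
        ratio = getattr(row, "ratio")
        out.append(
            BeadMeasurement(
                bead_id=int(row.bead_id),
                well=str(row.well),
                field=int(row.field),
                ring_intensity={
                    c[len("ring_"):]: float(getattr(row, c)) for c in ring_cols
                },
                ratio=None if pd.isna(ratio) else float(ratio),
                valid=bool(row.valid),
                invalid_reason=str(row.invalid_reason)
                if isinstance(row.invalid_reason, str) else "",
            )
        )
    return out


def wells_to_frame(wells: list[WellSummary],
                   hits: list[HitCall] | None = None) -> pd.DataFrame:
    by_well = {h.well: h for h in hits or []}
    rows = []
    for w in wells:
        h = by_well.get(w.well)
        rows.append(
            {
                "well": w.well,
                "role": w.role,
                "compound": w.compound,
                "concentration_uM": (
                    "" if w.concentration_um is None else w.concentration_um
                ),
                "n_beads": w.n_beads_valid,
                "mean_ratio": w.mean_ratio,
                "sd_ratio": w.sd_ratio,
                "relative_ratio": w.relative_ratio,
                "percent_inhibition": w.percent_inhibition,
                "valid": w.valid,
                "rule_a_hit": h.rule_a_hit if h else "",
                "rule_b_hit": h.rule_b_hit if h else "",
            }
        )
    return pd.DataFrame(rows)


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
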