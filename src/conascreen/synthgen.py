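"""Synthetic two-channel bead-field and screening-plate generator.

The simulator emulates the optical read-out of an on-bead pull-down assay
imaged by confocal nanoscanning: sieved agarose beads of near-uniform
diameter (100-120 um) are imaged in a single confocal plane, so molecules
bound on the bead surface appear as bright fluorescent rings ("halos") on
the bead periphery.  Two channels are rendered: a reference (RNA, e.g.
FITC) channel whose ring amplitude encodes bait loading, and a signal
(protein, e.g. mCherry) channel whose ring amplitude encodes binding.
Inhibitors attenuate the protein ring without affecting the RNA ring, so
the protein/RNA ring-intensity ratio is the screening read-out.

Noiseless pixel model for one channel, summed over beads::

    I(p) = background
         + interior * [dist(p, c) <= R]
         + A_bead * exp(-(dist(p, c) - R)^2 / (2 * sigma_r^2))

followed by optional Gaussian optical blur, then Poisson shot noise on the
signal and additive Gaussian read noise.  Every entry point is seeded and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .errors import ConfigError, PlacementError

# Sieving window of the bead preparation (cell strainer / pore filter).
DIAMETER_MIN_UM = 100.0
DIAMETER_MAX_UM = 120.0

#: Maximum placement attempts per bead before giving up.
_MAX_PLACE_TRIES = 2000


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and bead-population parameters of one simulated field."""

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_size_um: float = 1.0
    n_beads: int = 20
    bead_diameter_mean_um: float = 110.0
    bead_diameter_sd_um: float = 4.0
    allow_border: bool = False
    min_center_separation_factor: float = 1.05
    blank_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.n_beads < 0:
            raise ConfigError("n_beads must be >= 0")
        if self.bead_diameter_sd_um < 0:
            raise ConfigError("bead_diameter_sd_um must be >= 0")
        if not 0.0 <= self.blank_fraction <= 1.0:
            raise ConfigError("blank_fraction must lie in [0, 1]")

    @property
    def radius_range_px(self) -> tuple[float, float]:
        """Admissible bead radius range in pixels under the sieve window."""
        return (
            DIAMETER_MIN_UM / 2.0 / self.pixel_size_um,
            DIAMETER_MAX_UM / 2.0 / self.pixel_size_um,
        )


@dataclass(frozen=True)
class ChannelSpec:
    """Fluorescence model of one detection channel.

    ``ring_amplitude`` is the mean peak height of the peripheral ring above
    background (arbitrary units, AU); ``ring_amplitude_cv`` is the
    bead-to-bead coefficient of variation of that amplitude.
    ``ring_width_sigma_um`` is the radial Gaussian width of the halo.
    """

    name: str
    ring_amplitude: float
    ring_amplitude_cv: float = 0.05
    ring_width_sigma_um: float = 3.0
    interior_level: float = 0.0
    background_level: float = 50.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    blur_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ring_amplitude, self.interior_level,
               self.background_level) < 0:
            raise ConfigError("amplitudes and levels must be >= 0")
        if self.ring_width_sigma_um <= 0:
            raise ConfigError("ring_width_sigma_um must be > 0")
        if self.read_noise_sd < 0 or self.blur_sigma_px < 0:
            raise ConfigError("noise/blur scales must be >= 0")


@dataclass(frozen=True)
class GroundTruthBead:
    """True parameters of one rendered bead (the test oracle)."""

    bead_id: int
    center_row: float
    center_col: float
    radius_px: float
    amplitudes: dict[str, float]  # channel name -> true ring amplitude (AU)
    is_blank: bool = False


def default_channels(
    rna_amplitude: float = 800.0,
    protein_amplitude: float = 600.0,
) -> list[ChannelSpec]:
    """Default FITC (RNA reference) + mCherry (protein signal) pair."""
    return [
        ChannelSpec(name="FITC", ring_amplitude=rna_amplitude),
        ChannelSpec(name="mCherry", ring_amplitude=protein_amplitude),
    ]


def _sample_radii_px(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal diameters within the sieve window, in pixels."""
    if spec.bead_diameter_sd_um == 0:
        d_um = np.full(spec.n_beads, spec.bead_diameter_mean_um)
        return d_um / 2.0 / spec.pixel_size_um
    a = (DIAMETER_MIN_UM - spec.bead_diameter_mean_um) / spec.bead_diameter_sd_um
    b = (DIAMETER_MAX_UM - spec.bead_diameter_mean_um) / spec.bead_diameter_sd_um
    d_um = truncnorm.rvs(
        a, b,
        loc=spec.bead_diameter_mean_um,
        scale=spec.bead_diameter_sd_um,
        size=spec.n_beads,
        random_state=rng,
    )
    return d_um / 2.0 / spec.pixel_size_um


def _place_centers(
    spec: SceneSpec, radii: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample bead centers under the separation constraint."""
    h, w = spec.image_height_px, spec.image_width_px
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        if spec.allow_border:
            lo_r, hi_r, lo_c, hi_c = -r, h + r, -r, w + r
        else:
            lo_r, hi_r, lo_c, hi_c = r, h - r, r, w - r
            if lo_r >= hi_r or lo_c >= hi_c:
                raise PlacementError(
                    f"bead radius {r:.1f} px does not fit in a "
                    f"{h}x{w} image with allow_border=False"
                )
        for _ in range(_MAX_PLACE_TRIES):
            cr = rng.uniform(lo_r, hi_r)
            cc = rng.uniform(lo_c, hi_c)
            ok = all(
                np.hypot(cr - pr, cc - pc)
                >= spec.min_center_separation_factor * (r + radii[j])
                for j, (pr, pc) in enumerate(centers)
            )
            if ok:
                centers.append((cr, cc))
                break
        else:
            raise PlacementError(
                f"could not place bead {i + 1}/{spec.n_beads} after "
                f"{_MAX_PLACE_TRIES} tries under "
                f"min_center_separation_factor="
                f"{spec.min_center_separation_factor}"
            )
    return np.asarray(centers, dtype=float).reshape(len(radii), 2)


def render_bead(
    image: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    amplitude: float,
    interior_level: float,
    ring_sigma_px: float,
) -> None:
    """Add one noiseless bead (interior fill + peripheral ring) in place."""
    h, w = image.shape
    margin = radius_px + 4.0 * ring_sigma_px + 2.0
    r0 = max(0, int(np.floor(center[0] - margin)))
    r1 = min(h, int(np.ceil(center[0] + margin)) + 1)
    c0 = max(0, int(np.floor(center[1] - margin)))
    c1 = min(w, int(np.ceil(center[1] + margin)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1, dtype=float)[:, None]
    cols = np.arange(c0, c1, dtype=float)[None, :]
    dist = np.hypot(rows - center[0], cols - center[1])
    patch = amplitude * np.exp(-((dist - radius_px) ** 2)
                               / (2.0 * ring_sigma_px**2))
    if interior_level:
        patch = patch + interior_level * (dist <= radius_px)
    image[r0:r1, c0:c1] += patch


def render_scene_noiseless(
    spec: SceneSpec,
    channel: ChannelSpec,
    truth: list[GroundTruthBead],
    apply_blur: bool = True,
) -> np.ndarray:
    """Render one channel without shot/read noise."""
    img = np.full(
        (spec.image_height_px, spec.image_width_px),
        float(channel.background_level),
    )
    sigma_px = channel.ring_width_sigma_um / spec.pixel_size_um
    for bead in truth:
        amp = bead.amplitudes.get(channel.name, 0.0)
        interior = 0.0 if bead.is_blank else channel.interior_level
        if amp == 0.0 and interior == 0.0:
            continue
        render_bead(
            img,
            (bead.center_row, bead.center_col),
            bead.radius_px,
            amp,
            interior,
            sigma_px,
        )
    if apply_blur and channel.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, channel.blur_sigma_px)
    return img


def _add_noise(
    img: np.ndarray, channel: ChannelSpec, rng: np.random.Generator
) -> np.ndarray:
    out = img
    if channel.shot_noise:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
    if channel.read_noise_sd > 0:
        out = out + rng.normal(0.0, channel.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def sample_truth(
    spec: SceneSpec,
    channels: list[ChannelSpec],
    rng: np.random.Generator,
) -> list[GroundTruthBead]:
    """Draw the ground-truth bead population for one field."""
    radii = _sample_radii_px(spec, rng)
    centers = _place_centers(spec, radii, rng)
    blanks = rng.random(spec.n_beads) < spec.blank_fraction
    truth: list[GroundTruthBead] = []
    for i in range(spec.n_beads):
        amps: dict[str, float] = {}
        for ch in channels:
            if blanks[i]:
                # A blank bead carries no bait, hence no ring in any channel.
                amps[ch.name] = 0.0
            else:
                a = rng.normal(
                    ch.ring_amplitude,
                    ch.ring_amplitude * ch.ring_amplitude_cv,
                )
                amps[ch.name] = float(max(a, 0.0))
        truth.append(
            GroundTruthBead(
                bead_id=i,
                center_row=float(centers[i, 0]),
                center_col=float(centers[i, 1]),
                radius_px=float(radii[i]),
                amplitudes=amps,
                is_blank=bool(blanks[i]),
            )
        )
    return truth


def generate_scene(
    spec: SceneSpec,
    channels: list[ChannelSpec],
    seed: int | np.random.SeedSequence,
) -> tuple[dict[str, np.ndarray], list[GroundTruthBead]]:
    """Generate one seeded multi-channel field with ground truth.

    Returns a ``{channel name: 2-D float array (AU)}`` stack and the list of
    rendered beads.  Identical ``spec``/``channels``/``seed`` give
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    truth = sample_truth(spec, channels, rng)
    stack: dict[str, np.ndarray] = {}
    for ch in channels:
        img = render_scene_noiseless(spec, ch, truth)
        stack[ch.name] = _add_noise(img, ch, rng)
    return stack, truth


# ---------------------------------------------------------------------------
# Plate-level simulation
# ---------------------------------------------------------------------------

ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_COMPOUND = "compound"


@dataclass(frozen=True)
class BindingModel:
    """Four-parameter logistic bound fraction vs inhibitor concentration.

    ``bound_fraction(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)``
    with ``top`` the uninhibited bound fraction (negative-control level).
    """

    top: float = 1.0
    bottom: float = 0.0
    ic50_um: float = 2.0
    hill: float = 1.0

    def bound_fraction(self, concentration_um: float) -> float:
        if concentration_um < 0:
            raise ConfigError("concentration must be >= 0")
        if concentration_um == 0:
            return self.top
        ratio = (concentration_um / self.ic50_um) ** self.hill
        f = self.bottom + (self.top - self.bottom) / (1.0 + ratio)
        return float(min(max(f, 0.0), 1.0))


@dataclass(frozen=True)
class WellSim:
    """Role assignment of one simulated well."""

    well: str
    role: str
    compound: str = ""
    concentration_um: float | None = None


@dataclass(frozen=True)
class PlateSimSpec:
    """Layout and binding truth of one simulated screening plate."""

    wells: tuple[WellSim, ...]
    binding_models: dict[str, BindingModel] = field(default_factory=dict)
    default_binding_model: BindingModel = field(default_factory=BindingModel)
    positive_bound_fraction: float = 0.29
    signal_channel: str = "mCherry"
    n_fields_per_well: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        names = [w.well for w in self.wells]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate well in plate simulation spec")
        for w in self.wells:
            if w.role not in (ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_COMPOUND):
                raise ConfigError(f"unknown role {w.role!r} for well {w.well}")
            if w.role == ROLE_COMPOUND and w.concentration_um is None:
                raise ConfigError(
                    f"compound well {w.well} is missing a concentration"
                )
        if not 0.0 <= self.positive_bound_fraction <= 1.0:
            raise ConfigError("positive_bound_fraction must lie in [0, 1]")

    def bound_fraction(self, well: WellSim) -> float:
        """True bound fraction of the protein in one well."""
        if well.role == ROLE_NEGATIVE:
            return self.default_binding_model.top
        if well.role == ROLE_POSITIVE:
            return self.positive_bound_fraction
        model = self.binding_models.get(
            well.compound, self.default_binding_model
        )
        return model.bound_fraction(well.concentration_um)


@dataclass
class PlateSim:
    """Simulated plate: images, layout table and per-bead ground truth."""

    images: dict[tuple[str, int], dict[str, np.ndarray]]
    layout: pd.DataFrame
    truth: pd.DataFrame
    channels: list[ChannelSpec]


def generate_screen_plate(
    plate: PlateSimSpec,
    scene: SceneSpec,
    channels: list[ChannelSpec],
) -> PlateSim:
    """Simulate every well/field of a screening plate.

    The signal (protein) channel's mean ring amplitude in each well is the
    base amplitude scaled by that well's true bound fraction; the reference
    (RNA) channel amplitude is constant across wells.  Per-field seeds are
    spawned deterministically from ``plate.seed``.
    """
    ch_names = [c.name for c in channels]
    if plate.signal_channel not in ch_names:
        raise ConfigError(
            f"signal channel {plate.signal_channel!r} not among {ch_names}"
        )
    root = np.random.SeedSequence(plate.seed)
    field_seeds = root.spawn(len(plate.wells) * plate.n_fields_per_well)

    images: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    truth_rows: list[dict] = []
    layout_rows: list[dict] = []
    k = 0
    for well in plate.wells:
        frac = plate.bound_fraction(well)
        well_channels = [
            replace(ch, ring_amplitude=ch.ring_amplitude * frac)
            if ch.name == plate.signal_channel
            else ch
            for ch in channels
        ]
        layout_rows.append(
            {
                "well": well.well,
                "role": well.role,
                "compound": well.compound,
                "concentration_uM": (
                    "" if well.concentration_um is None
                    else well.concentration_um
                ),
            }
        )
        for fld in range(1, plate.n_fields_per_well + 1):
            stack, beads = generate_scene(scene, well_channels, field_seeds[k])
            k += 1
            images[(well.well, fld)] = stack
            for b in beads:
                row = {
                    "well": well.well,
                    "field": fld,
                    "bead_id": b.bead_id,
                    "center_row": b.center_row,
                    "center_col": b.center_col,
                    "radius_px": b.radius_px,
                    "is_blank": b.is_blank,
                }
                for name, amp in b.amplitudes.items():
                    row[f"amplitude_{name}"] = amp
                truth_rows.append(row)
    layout = pd.DataFrame(layout_rows)
    truth = pd.DataFrame(truth_rows)
    return PlateSim(images=images, layout=layout, truth=truth,
                    channels=list(channels))


def default_demo_plate(
    seed: int = 0,
    n_control_wells: int = 6,
    compound_doses_um: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0),
    compound: str = "cmpd-1",
) -> PlateSimSpec:
    """Control plate plus one compound dose series, for demos and smoke runs."""
    wells: list[WellSim] = []
    for i in range(n_control_wells):
        wells.append(WellSim(well=f"A{i + 1:02d}", role=ROLE_NEGATIVE))
    for i in range(n_control_wells):
        wells.append(WellSim(well=f"B{i + 1:02d}", role=ROLE_POSITIVE))
    for i, dose in enumerate(compound_doses_um):
        wells.append(
            WellSim(
                well=f"C{i + 1:02d}",
                role=ROLE_COMPOUND,
                compound=compound,
                concentration_um=float(dose),
            )
        )
    return PlateSimSpec(wells=tuple(wells), seed=seed)
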