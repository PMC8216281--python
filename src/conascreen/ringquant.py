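"""Per-bead ring-intensity quantification and the protein/RNA ratio.

Following the assay's read-out, three chords are laid across each bead
(default angles 0/60/120 degrees).  Each chord's intensity profile shows
two peripheral peaks where it crosses the fluorescent ring; the ring
intensity of a bead in a channel is the mean of those peak heights minus
the field background.  The screening read-out is the ratio of the
protein-channel ring intensity to the RNA-channel ring intensity: an
inhibitor attenuates the protein ring while leaving the RNA ring (bait
loading) unchanged.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .detect import BeadLocus, _parabolic_peak

DEFAULT_ANGLES_DEG = (0.0, 60.0, 120.0)

REASON_BLANK = "blank_bead"
REASON_PEAKS = "peaks_missing"
REASON_FLAGGED = "qc_flagged"


class PeaksMissingError(ValueError):
    """Raised when too few peripheral peaks are available for a bead."""


@dataclass(frozen=True)
class QuantParams:
    """Quantification settings.

    ``peak_window_frac`` sets the half-width of the annular peak-search
    window as a fraction of the bead radius; ``min_peaks`` is the minimum
    number of peripheral peaks (out of 2 x n_angles) required for a valid
    ring-intensity estimate.  ``min_reference_intensity`` (AU, after
    background subtraction) separates loaded beads from blank beads.
    """

    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG
    peak_window_frac: float = 0.2
    min_peaks: int = 4
    min_reference_intensity: float = 50.0
    background_margin_px: float = 10.0
    background_subtract: bool = True


@dataclass
class ProfileSet:
    """Chord intensity profiles of one bead in one channel.

    ``positions`` holds the signed distance (px) of each sample from the
    bead center along the chord; ``peak_heights[i]`` are the two
    peripheral peak heights (NaN when a side is truncated) of profile i.
    """

    bead_id: int
    angles_deg: tuple[float, ...]
    positions: np.ndarray
    profiles: list[np.ndarray]
    peak_heights: np.ndarray  # shape (n_angles, 2)


@dataclass
class BeadMeasurement:
    """Background-subtracted per-channel ring intensities and their ratio."""

    bead_id: int
    well: str = ""
    field: int = 0
    ring_intensity: dict[str, float] = dataclasses.field(default_factory=dict)
    ratio: float | None = None
    valid: bool = True
    invalid_reason: str = ""


def estimate_background(
    image: np.ndarray,
    loci: list[BeadLocus],
    margin_px: float = 10.0,
) -> float:
    """Robust field background: median over pixels away from every bead.

    Pixels closer than ``radius + margin_px`` to any bead center are
    excluded.  If fewer than 1% of pixels survive, the estimate falls back
    to the 5th percentile of the whole image and a warning is emitted.
    """
    image = np.asarray(image, dtype=float)
    mask = np.ones(image.shape, dtype=bool)
    rows = np.arange(image.shape[0], dtype=float)[:, None]
    cols = np.arange(image.shape[1], dtype=float)[None, :]
    for locus in loci:
        r = locus.radius_px + margin_px
        r0 = max(0, int(locus.center_row - r))
        r1 = min(image.shape[0], int(locus.center_row + r) + 2)
        c0 = max(0, int(locus.center_col - r))
        c1 = min(image.shape[1], int(locus.center_col + r) + 2)
        dist = np.hypot(
            rows[r0:r1] - locus.center_row, cols[:, c0:c1] - locus.center_col
        )
        mask[r0:r1, c0:c1] &= dist > r
    n_free = int(mask.sum())
    if n_free < 0.01 * image.size:
        warnings.warn(
            "fewer than 1% of pixels are bead-free; falling back to the "
            "5th percentile of the whole image for background estimation",
            stacklevel=2,
        )
        return float(np.percentile(image, 5.0))
    return float(np.median(image[mask]))


def extract_profiles(
    image: np.ndarray,
    locus: BeadLocus,
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG,
    peak_window_frac: float = 0.2,
) -> ProfileSet:
    """Sample chord intensity profiles through the bead center.

    Each chord runs from ``-(R + w + 2)`` to ``+(R + w + 2)`` pixels from
    the center (w = peak-search half-width) and is sampled at 1-px steps by
    bilinear interpolation.  The two peak heights per chord are the
    sub-pixel maxima within the annular windows ``[R - w, R + w]`` on each
    side; a side whose window leaves the image is marked missing (NaN).
    """
    image = np.asarray(image, dtype=float)
    R = locus.radius_px
    w = peak_window_frac * R
    half = R + w + 2.0
    t = np.arange(-np.ceil(half), np.ceil(half) + 1.0)
    profiles: list[np.ndarray] = []
    peaks = np.full((len(angles_deg), 2), np.nan)
    for k, ang in enumerate(angles_deg):
        theta = np.deg2rad(ang)
        rr = locus.center_row + t * np.sin(theta)
        cc = locus.center_col + t * np.cos(theta)
        inside = (
            (rr >= 0) & (rr <= image.shape[0] - 1)
            & (cc >= 0) & (cc <= image.shape[1] - 1)
        )
        prof = np.full(t.shape, np.nan)
        if inside.any():
            prof[inside] = ndimage.map_coordinates(
                image, np.vstack([rr[inside], cc[inside]]), order=1
            )
        profiles.append(prof)
        for side, sign in enumerate((-1.0, 1.0)):
            sel = (t * sign >= R - w) & (t * sign <= R + w) & inside
            if sel.sum() < 3:
                continue
            idx = np.flatnonzero(sel)
            j = idx[int(np.nanargmax(prof[idx]))]
            if 0 < j < prof.size - 1 and np.isfinite(prof[j - 1:j + 2]).all():
                _, height = _parabolic_peak(prof, j)
            else:
                height = float(prof[j])
            peaks[k, side] = height
    return ProfileSet(
        bead_id=locus.bead_id,
        angles_deg=tuple(angles_deg),
        positions=t,
        profiles=profiles,
        peak_heights=peaks,
    )


def ring_intensity(
    profiles: ProfileSet,
    background: float,
    min_peaks: int = 4,
) -> float:
    """Mean peripheral peak height minus background, clamped at zero."""
    heights = profiles.peak_heights[np.isfinite(profiles.peak_heights)]
    if heights.size < min_peaks:
        raise PeaksMissingError(
            f"only {heights.size} of {profiles.peak_heights.size} "
            f"peripheral peaks available (need >= {min_peaks})"
        )
    return float(max(float(np.mean(heights)) - background, 0.0))


def measure_bead(
    stack: dict[str, np.ndarray],
    locus: BeadLocus,
    backgrounds: dict[str, float],
    reference_channel: str,
    signal_channel: str,
    params: QuantParams = QuantParams(),
    well: str = "",
    field_id: int = 0,
) -> BeadMeasurement:
    """Measure one bead in all channels and form the signal/reference ratio.

    Beads whose reference (RNA) ring intensity falls below
    ``min_reference_intensity`` are invalid with reason ``blank_bead``;
    the ratio is never computed by dividing by zero.
    """
    meas = BeadMeasurement(bead_id=locus.bead_id, well=well, field=field_id)
    if locus.qc_flags:
        meas.valid = False
        meas.invalid_reason = REASON_FLAGGED
        return meas
    for name, image in stack.items():
        prof = extract_profiles(
            image, locus, params.angles_deg, params.peak_window_frac
        )
        bg = backgrounds.get(name, 0.0) if params.background_subtract else 0.0
        try:
            meas.ring_intensity[name] = ring_intensity(
                prof, bg, params.min_peaks
            )
        except PeaksMissingError:
            meas.valid = False
            meas.invalid_reason = REASON_PEAKS
            return meas
    ref = meas.ring_intensity[reference_channel]
    sig = meas.ring_intensity[signal_channel]
    if ref < params.min_reference_intensity:
        meas.valid = False
        meas.invalid_reason = REASON_BLANK
        return meas
    meas.ratio = sig / ref
    return meas


def measure_field(
    stack: dict[str, np.ndarray],
    loci: list[BeadLocus],
    reference_channel: str,
    signal_channel: str,
    params: QuantParams = QuantParams(),
    well: str = "",
    field_id: int = 0,
) -> list[BeadMeasurement]:
    """Estimate per-channel backgrounds once per field, then measure beads."""
    backgrounds = {
        name: estimate_background(img, loci, params.background_margin_px)
        for name, img in stack.items()
    }
    return [
        measure_bead(
            stack, locus, backgrounds, reference_channel, signal_channel,
            params, well=well, field_id=field_id,
        )
        for locus in loci
    ]
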