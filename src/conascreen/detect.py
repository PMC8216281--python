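"""Bead (circle) detection in a reference-channel image.

Beads appear as bright peripheral rings on a darker background.  Detection
thresholds a smoothed copy of the image, fills each closed ring into a
disk, breaks thin bridges between nearly touching beads by morphological
opening, labels the remaining components, and refines each component into
a sub-pixel circle (centroid + radial-profile peak radius).

Detection runs on the reference (RNA) channel by default: every non-blank
bead carries bait RNA and hence a reference ring, while blank beads show
no ring in any channel and are deliberately never detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, measure, segmentation

from .errors import InputError

FLAG_BORDER = "border"
FLAG_OVERLAP = "overlap"
FLAG_SIZE = "size_out_of_range"


@dataclass(frozen=True)
class DetectParams:
    """Tunable parameters of bead detection.

    ``expected_radius_range_px`` should follow from the sieved bead
    diameter window (100-120 um) and the pixel size.  With automatic
    thresholding the threshold sits halfway between the image's robust
    background (median) and its robust maximum, which makes detection
    invariant to rescaling the intensities.
    """

    expected_radius_range_px: tuple[float, float] = (50.0, 60.0)
    smoothing_sigma_px: float = 2.0
    detection_threshold_mode: str = "automatic"  # or "absolute"
    detection_threshold_au: float | None = None
    exclude_border: bool = True
    max_overlap_fraction: float = 0.05
    min_component_area_frac: float = 0.15  # of the min-radius disk area

    def __post_init__(self) -> None:
        rmin, rmax = self.expected_radius_range_px
        if not 0 < rmin < rmax:
            raise InputError("need 0 < min radius < max radius")
        if self.detection_threshold_mode not in ("automatic", "absolute"):
            raise InputError(
                f"unknown threshold mode {self.detection_threshold_mode!r}"
            )
        if (
            self.detection_threshold_mode == "absolute"
            and (self.detection_threshold_au is None
                 or self.detection_threshold_au < 0)
        ):
            raise InputError("absolute mode needs detection_threshold_au >= 0")


@dataclass
class BeadLocus:
    """One detected bead: sub-pixel circle plus QC flags.

    A locus carrying any flag is excluded from measurement by default;
    flagged beads are kept in the output so exclusion stays auditable.
    """

    bead_id: int
    center_row: float
    center_col: float
    radius_px: float
    qc_flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.qc_flags


def radial_profile(
    image: np.ndarray,
    center: tuple[float, float],
    r_max: float,
    bin_width_px: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity vs distance from ``center`` in 1-px annuli."""
    h, w = image.shape
    r0 = max(0, int(np.floor(center[0] - r_max)))
    r1 = min(h, int(np.ceil(center[0] + r_max)) + 1)
    c0 = max(0, int(np.floor(center[1] - r_max)))
    c1 = min(w, int(np.ceil(center[1] + r_max)) + 1)
    rows = np.arange(r0, r1, dtype=float)[:, None]
    cols = np.arange(c0, c1, dtype=float)[None, :]
    dist = np.hypot(rows - center[0], cols - center[1])
    sub = image[r0:r1, c0:c1]
    inside = dist <= r_max
    bins = (dist[inside] / bin_width_px).astype(int)
    vals = sub[inside]
    counts = np.bincount(bins)
    sums = np.bincount(bins, weights=vals)
    with np.errstate(invalid="ignore"):
        prof = sums / np.where(counts > 0, counts, 1)
    radii = (np.arange(prof.size) + 0.5) * bin_width_px
    return radii, prof


def _parabolic_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample apex (offset, height) of a discrete peak at index i."""
    if i <= 0 or i >= y.size - 1:
        return 0.0, float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not a local maximum in the quadratic sense
        return 0.0, float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return delta, float(height)


def _kasa_circle_fit(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit (Kasa) to ring pixels.

    Used for border-clipped beads, where only an arc of the ring is
    visible and centroid/radial-profile refinement would be biased.
    """
    a = np.column_stack([2.0 * rows, 2.0 * cols, np.ones(rows.size)])
    b = rows**2 + cols**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cr, cc, c0 = sol
    radius = float(np.sqrt(max(c0 + cr**2 + cc**2, 0.0)))
    return float(cr), float(cc), radius


def _refine_radius(
    image: np.ndarray,
    center: tuple[float, float],
    params: DetectParams,
) -> float:
    """Bead radius as the sub-pixel argmax of the radial intensity profile."""
    rmin, rmax = params.expected_radius_range_px
    radii, prof = radial_profile(image, center, rmax * 1.25)
    lo = max(1, int(rmin * 0.75))
    window = prof[lo:]
    if window.size == 0:
        return float("nan")
    i = int(np.argmax(window)) + lo
    delta, _ = _parabolic_peak(prof, i)
    return float(radii[i] + delta)


def detect_beads(image: np.ndarray, params: DetectParams) -> list[BeadLocus]:
    """Locate beads in one reference-channel image.

    Returns loci sorted by (center_row, center_col); deterministic for a
    fixed input.  An all-constant image yields an empty list.  Beads that
    touch the image border, overlap a neighbour, or fall outside the
    expected radius range are flagged, not dropped.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InputError("expected a 2-D grayscale image")
    if not np.isfinite(image).all():
        raise InputError("image contains non-finite values")
    rmin, rmax = params.expected_radius_range_px
    if min(image.shape) < 2 * rmax:
        raise InputError(
            f"image {image.shape} smaller than twice the maximum "
            f"bead radius ({rmax} px)"
        )

    smoothed = ndimage.gaussian_filter(image, params.smoothing_sigma_px)
    background = float(np.median(smoothed))
    if params.detection_threshold_mode == "absolute":
        threshold = float(params.detection_threshold_au)
    else:
        high = float(np.percentile(smoothed, 99.9))
        if high - background <= 0:
            return []
        threshold = background + 0.5 * (high - background)

    ring_mask = smoothed > threshold
    if not ring_mask.any():
        return []
    mask = ndimage.binary_fill_holes(ring_mask)
    # Rings of two close (but non-overlapping) beads can both exceed the
    # threshold at their tangent point and merge into one component; a
    # marker-based watershed on the distance transform splits such pairs,
    # since every filled bead contributes its own distance maximum.
    distance = ndimage.distance_transform_edt(mask)
    # Only deep maxima (disk-like interiors) seed the watershed; shallow
    # maxima along border-clipped ring arcs would otherwise shatter them.
    markers_at = feature.peak_local_max(
        distance,
        min_distance=max(1, int(rmin * 0.9)),
        threshold_abs=0.5 * rmin,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(markers_at.T)] = np.arange(1, len(markers_at) + 1)
    labels = segmentation.watershed(-distance, markers, mask=mask)
    # Components without any marker (e.g. unfilled arcs) survive unsplit.
    leftover = measure.label(mask & (labels == 0))
    leftover[leftover > 0] += labels.max()
    labels = labels + leftover

    min_area = params.min_component_area_frac * np.pi * rmin**2
    loci: list[BeadLocus] = []
    h, w = image.shape
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        flags: set[str] = set()
        rr0, cc0, rr1, cc1 = region.bbox
        touches_edge = rr0 <= 0 or cc0 <= 0 or rr1 >= h or cc1 >= w
        equiv_r = float(np.sqrt(region.area / np.pi))
        if touches_edge:
            # Possibly a border-clipped arc: fit the circle to the ring
            # pixels instead of trusting centroid + radial profile.
            sel = ring_mask & (labels == region.label)
            rows_px, cols_px = np.nonzero(sel)
            cr, cc, radius = _kasa_circle_fit(
                rows_px.astype(float), cols_px.astype(float)
            )
            # 1 px tolerance so beads whose ring peak grazes the edge are
            # not spuriously flagged.
            if cr < radius - 1 or cc < radius - 1 \
                    or cr > h - 1 - radius + 1 or cc > w - 1 - radius + 1:
                flags.add(FLAG_BORDER)
        else:
            cr, cc = region.centroid
            if equiv_r > 1.2 * rmax:
                # Fused bead mass: too big to be one bead.
                flags.add(FLAG_OVERLAP)
            radius = _refine_radius(smoothed, (cr, cc), params)
            if not np.isfinite(radius):
                radius = equiv_r
        if not rmin <= radius <= rmax:
            flags.add(FLAG_SIZE)
        loci.append(
            BeadLocus(
                bead_id=-1,
                center_row=float(cr),
                center_col=float(cc),
                radius_px=float(radius),
                qc_flags=flags,
            )
        )

    # Pairwise overlap flag for beads closer than allowed.
    for i, a in enumerate(loci):
        for b in loci[i + 1:]:
            d = np.hypot(a.center_row - b.center_row,
                         a.center_col - b.center_col)
            if d < (1.0 - params.max_overlap_fraction) * (
                a.radius_px + b.radius_px
            ):
                a.qc_flags.add(FLAG_OVERLAP)
                b.qc_flags.add(FLAG_OVERLAP)

    loci.sort(key=lambda x: (x.center_row, x.center_col))
    for i, locus in enumerate(loci):
        locus.bead_id = i
    if not params.exclude_border:
        for locus in loci:
            locus.qc_flags.discard(FLAG_BORDER)
    return loci
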