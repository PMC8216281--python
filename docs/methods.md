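# Methods

## Optical model of the simulator

A bead field is rendered per channel from the noiseless pixel model

    I(p) = B + L·[d(p,c) ≤ R] + A·exp(−(d(p,c) − R)² / (2σ_r²))

summed over beads, where `B` is the field background (AU), `L` the bead
interior (lumen) level, `A` the bead's ring amplitude, `R` its radius
and `σ_r` the radial width of the halo. The image is then optionally
blurred with a Gaussian (optical blur), and noise is added as Poisson
shot noise on the signal followed by additive Gaussian read noise. The
ring-on-a-disk geometry is what a single confocal plane through a
surface-loaded bead produces; the Gaussian radial profile is a
phenomenological stand-in for the section through the thin fluorescent
shell convolved with the point-spread function.

Key defaults (all configurable):

| parameter | default | why |
|---|---|---|
| bead diameter | truncated normal, 110 ± 4 µm on [100, 120] µm | the sieving window of the bead preparation; only the bounds are physical, the mode/SD are a realistic population shape |
| pixel size | 1 µm/px | keeps a 20-bead field at 1024×1024 px; bead ≈ 110 px across |
| ring width σ_r | 3 µm | thin shell relative to the bead |
| interior level | 0 AU | so the ring-peak ratio equals the channel amplitude ratio exactly; real beads show faint interior fill, hence configurable |
| RNA / protein ring amplitude | 800 / 600 AU | mid-range 16-bit signals; peak SNR ≈ 25 under the default noise |
| bead-to-bead amplitude CV | 5% per channel, independent | loading/binding heterogeneity; per-bead ratio CV ≈ 7% |
| background, read noise | 50 AU, 5 AU | dim, slightly noisy background |
| shot noise | Poisson on the full signal | photon statistics; the instrument's true noise model is not published, so Poisson + Gaussian read noise is the standard assumption |
| blur | Gaussian, σ = 1 px | mild optics; applied before noise |
| min center separation | 1.05 × (r₁+r₂) | beads are dispersed, not clumped; overlapping scenes are an opt-in stress mode |
| positive-control bound fraction | 0.29 | the residual binding level implied by the published control ratios (0.288/1.009) |

Placement is rejection sampling (2000 tries per bead) and fails loudly
naming the separation constraint. Blank beads (`blank_fraction`) carry
zero amplitude in **every** channel — a bead without bait RNA captures
no protein either — so they are invisible in the reference channel and
never enter measurement. Every generator entry point takes a seed and
is bit-reproducible; plate simulation spawns per-field seeds from the
plate seed via `numpy.random.SeedSequence`.

### What the simulator does *not* emulate

No 3-D confocal stack or physical PSF, no compound autofluorescence, no
bead autodegradation, no illumination gradients, no well-level handling
effects (between-well variation in a simulated plate is purely bead
sampling). Tests passing on these scenes therefore demonstrate the
correctness of the measurement chain under the stated optical model,
not robustness to every real-microscope artefact.

## Bead detection

The reference (RNA) channel is smoothed (Gaussian, σ = 2 px) and
thresholded halfway between the image median and its 99.9th percentile —
a scale- and shift-invariant rule, so automatic detection is unchanged
by exposure rescaling. Closed rings are filled to disks; a marker-based
watershed on the distance transform separates beads whose above-threshold
rings merge at a tangent point (markers are distance maxima deeper than
half the minimum bead radius, which prevents shallow maxima along
border-clipped arcs from shattering them). Components smaller than 15%
of the minimum-radius disk area are discarded as debris.

Interior components get a sub-pixel center from the filled-disk centroid
and a radius from the parabolic-refined argmax of the radial mean-intensity
profile. Edge-touching components instead get an algebraic (Kåsa)
least-squares circle fit to their ring pixels, because centroid and
radial profile are biased for a clipped arc. QC flags: `border` (fitted
circle leaves the image by > 1 px), `overlap` (component too large to be
one bead, or two fitted circles closer than 0.95× the sum of radii), and
`size_out_of_range` (outside the expected radius window). Flagged beads
are reported but excluded from measurement, keeping exclusion auditable.
On the standard 20-bead scene this recovers every bead with ≤ 0.3 px
center error and ≤ 0.3% radius error.

## Ring quantification

Three chords at 0°/60°/120° are sampled through each bead center at
1-px steps by bilinear interpolation, spanning `±(R + w + 2)` px with
`w = 0.2R` the annular peak-search half-width. On each side of the
center the peak is the sub-pixel (parabolic) maximum within
`[R − w, R + w]`; sides whose window leaves the image are marked
missing, and a bead needs ≥ 4 of its 6 peaks for a valid measurement.
The per-channel ring intensity is the mean peak height minus the field
background (median of pixels farther than radius + 10 px from every
bead; 5th-percentile fallback with a warning if beads tile > 99% of the
field), clamped at zero. Background subtraction can be disabled to
report raw peak heights.

The read-out is formed per bead — ratio = protein ring / RNA ring — and
only then averaged within wells, preserving the per-bead distribution
the on-bead format provides. Beads whose RNA ring is below 50 AU are
invalidated as `blank_bead` rather than risking a division by ~0.
Chord discretisation biases oblique-angle peaks by ≲ 1.3% low; the bias
is common to both channels and cancels in the ratio (median ratio error
≈ 0.1% over noisy scenes).

## Plate statistics and hit calling

Well summaries use the sample (n−1) SD over valid beads and require
`min_beads` (default 50; the published control analyses pooled ≥ 400
beads over 5–6 wells, i.e. ~80/well, and the default keeps a margin
below that). Control statistics are computed **between** replicate
wells, as the published legends state; with a single valid control well
the code falls back to that well's between-bead SD and flags the
fallback in the QC report. Z′ uses the standard formula above and is
exactly invariant under any affine rescaling of the ratios. Percent
inhibition is 100·(1 − well mean / negative-control mean); wells above
the negative controls are reported separately as stabilizers, never as
inhibitor hits.

## Dose–response

The 4PL is fitted by unweighted least squares with log(IC50) as the
internal free parameter — positivity is automatic and rescaling all
doses by c shifts the optimum exactly, giving exact dose-scale
equivariance. Initialisation: top = max response, bottom = min
response, IC50 = geometric mean of the doses bracketing half-response,
hill = 1. Standard errors come from the Gauss–Newton covariance at the
optimum (residual variance · inverse curvature); SE(IC50) is mapped
from the log scale by the delta method. Fits with a singular covariance
are marked not converged; fits whose SE(IC50) exceeds the IC50 are
marked unreliable (typical for two-level data with no intermediate
dose). The Hill slope is freely fitted; zero doses are accepted and
anchor the top plateau.

## Problem sizes used by the test suite

The default validation scene is 20 beads in a 1024×1024 px field at the
default noise (peak SNR ≈ 25); ratio-recovery statistics pool ≥ 100
beads over six such fields. The end-to-end screen check uses 6 negative
+ 6 positive + 1 compound well (80% true inhibition) at 3 fields/well —
about 2,300 measured beads. The rule-A false-positive property is
checked at the measurement level (per-bead ratios drawn from the noise
model and pushed through the same well-summary → control-stats →
hit-call path), 520 null wells of 60 beads against a 24-well control
pool: the property isolates the calling rule's intrinsic false-positive
behaviour, so the control mean/SD are estimated from enough replicate
wells that SD-estimation noise does not dominate the 3×SD tail (with
only 5–6 control wells the exceedance probability of a 3×-sample-SD
bound is ≈ 2% by Student-t tails regardless of assay quality — a
property of small-sample SD estimates, not of this pipeline).

## Known limitations

- Heavily fused bead masses are flagged `overlap` and excluded, not
  declumped.
- Background is estimated per field, assuming uniform illumination at
  20×; strong shading would bias low-signal wells.
- Peak-height statistics are slightly max-biased under noise (picking
  the maximum of noisy samples); the bias largely cancels in the ratio
  but inflates absolute ring intensities by a few percent at low SNR.
- Single-plate statistics only; no multi-plate batch normalisation.
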