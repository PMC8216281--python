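"""Ring quantification: background, chord profiles, peak heights, ratios."""

import warnings

import numpy as np
import pytest

from conascreen import synthgen
from conascreen.detect import BeadLocus, DetectParams, detect_beads
from conascreen.ringquant import (
    REASON_BLANK,
    REASON_FLAGGED,
    PeaksMissingError,
    ProfileSet,
    QuantParams,
    estimate_background,
    extract_profiles,
    measure_bead,
    measure_field,
    ring_intensity,
)
from conftest import match_to_truth


def render_single_bead(amplitudes, radius=55.0, size=400, background=50.0,
                       interior=0.0):
    """One noiseless centered bead; returns (stack, locus)."""
    center = size / 2.0
    spec = synthgen.SceneSpec(image_height_px=size, image_width_px=size,
                              n_beads=0)
    stack = {}
    for name, amp in amplitudes.items():
        ch = synthgen.ChannelSpec(
            name=name, ring_amplitude=amp, ring_amplitude_cv=0.0,
            background_level=background, interior_level=interior,
            read_noise_sd=0.0, shot_noise=False, blur_sigma_px=0.0,
        )
        truth = [synthgen.GroundTruthBead(0, center, center, radius,
                                          {name: amp})]
        stack[name] = synthgen.render_scene_noiseless(spec, ch, truth)
    return stack, BeadLocus(0, center, center, radius)


class TestBackground:
    def test_constant_field(self):
        img = np.full((200, 200), 37.5)
        assert estimate_background(img, []) == 37.5

    def test_recovers_true_background(self, standard_scene, standard_loci):
        _, stack, _ = standard_scene
        est = estimate_background(stack["FITC"], standard_loci)
        assert est == pytest.approx(50.0, rel=0.05)

    def test_fallback_when_beads_tile_field(self):
        img = np.full((120, 120), 10.0)
        loci = [BeadLocus(0, 60.0, 60.0, 100.0)]  # covers everything
        with pytest.warns(UserWarning, match="bead-free"):
            est = estimate_background(img, loci)
        assert est == 10.0


class TestProfiles:
    def test_null_image_gives_zero_profiles(self):
        locus = BeadLocus(0, 100.0, 100.0, 55.0)
        prof = extract_profiles(np.zeros((200, 200)), locus)
        assert len(prof.profiles) == 3
        assert prof.peak_heights.shape == (3, 2)
        assert np.all(prof.peak_heights == 0.0)

    def test_three_angles_six_peaks(self):
        stack, locus = render_single_bead({"X": 1000.0})
        prof = extract_profiles(stack["X"], locus)
        assert prof.angles_deg == (0.0, 60.0, 120.0)
        assert len(prof.profiles) == 3
        assert np.isfinite(prof.peak_heights).sum() == 6

    def test_noiseless_peaks_match_render_model(self):
        """Every chord peak equals background + amplitude within 2%."""
        stack, locus = render_single_bead({"X": 1000.0}, background=50.0)
        prof = extract_profiles(stack["X"], locus)
        assert np.all(np.abs(prof.peak_heights - 1050.0) / 1050.0 <= 0.02)

    def test_truncated_chord_marks_peak_missing(self):
        stack, locus = render_single_bead({"X": 1000.0})
        img = stack["X"][:, int(locus.center_col) - 10:]  # cut left side
        shifted = BeadLocus(0, locus.center_row, 10.0, locus.radius_px)
        prof = extract_profiles(img, shifted, angles_deg=(0.0,))
        assert np.isnan(prof.peak_heights[0, 0])  # left peak gone
        assert np.isfinite(prof.peak_heights[0, 1])


class TestRingIntensity:
    def test_arithmetic(self):
        prof = ProfileSet(0, (0.0, 60.0, 120.0), np.arange(3), [],
                          np.full((3, 2), 1050.0))
        assert ring_intensity(prof, background=50.0) == 1000.0

    def test_clamped_at_zero(self):
        prof = ProfileSet(0, (0.0, 60.0, 120.0), np.arange(3), [],
                          np.full((3, 2), 50.0))
        assert ring_intensity(prof, background=50.0) == 0.0
        assert ring_intensity(prof, background=80.0) == 0.0

    def test_too_few_peaks_raises(self):
        heights = np.full((3, 2), np.nan)
        heights[0, 0] = heights[0, 1] = heights[1, 0] = 1000.0
        prof = ProfileSet(0, (0.0, 60.0, 120.0), np.arange(3), [], heights)
        with pytest.raises(PeaksMissingError):
            ring_intensity(prof, background=0.0)


class TestMeasureBead:
    def test_noiseless_ratio(self):
        stack, locus = render_single_bead({"FITC": 800.0, "mCherry": 400.0})
        meas = measure_bead(stack, locus, {"FITC": 50.0, "mCherry": 50.0},
                            "FITC", "mCherry")
        assert meas.valid
        assert meas.ratio == pytest.approx(0.50, rel=0.02)

    def test_zero_protein_gives_zero_ratio(self):
        stack, locus = render_single_bead({"FITC": 800.0, "mCherry": 0.0})
        meas = measure_bead(stack, locus, {"FITC": 50.0, "mCherry": 50.0},
                            "FITC", "mCherry")
        assert meas.valid
        assert meas.ratio == 0.0

    def test_blank_bead_invalid_not_division_error(self):
        stack, locus = render_single_bead({"FITC": 0.0, "mCherry": 0.0})
        meas = measure_bead(stack, locus, {"FITC": 50.0, "mCherry": 50.0},
                            "FITC", "mCherry")
        assert not meas.valid
        assert meas.invalid_reason == REASON_BLANK
        assert meas.ratio is None

    def test_flagged_locus_not_measured(self):
        stack, locus = render_single_bead({"FITC": 800.0, "mCherry": 400.0})
        locus.qc_flags.add("border")
        meas = measure_bead(stack, locus, {"FITC": 50.0, "mCherry": 50.0},
                            "FITC", "mCherry")
        assert not meas.valid
        assert meas.invalid_reason == REASON_FLAGGED


class TestRecovery:
    def test_ring_intensity_recovery_with_noise(self, standard_scene,
                                                standard_loci):
        """Estimated RNA ring intensity within 10% of truth per bead."""
        _, stack, truth = standard_scene
        meas = measure_field(stack, standard_loci, "FITC", "mCherry")
        loci_by_id = {l.bead_id: l for l in standard_loci}
        checked = 0
        for m in meas:
            if not m.valid:
                continue
            bead = match_to_truth(loci_by_id[m.bead_id], truth)
            assert bead is not None
            est = m.ring_intensity["FITC"]
            assert est == pytest.approx(bead.amplitudes["FITC"], rel=0.10)
            checked += 1
        assert checked >= 15

    def test_ratio_monotone_in_protein_amplitude(self):
        """Noiseless: raising the protein amplitude never lowers the ratio."""
        ratios = []
        for amp in (100.0, 200.0, 400.0, 600.0, 800.0):
            stack, locus = render_single_bead({"FITC": 800.0, "mCherry": amp})
            meas = measure_bead(stack, locus,
                                {"FITC": 50.0, "mCherry": 50.0},
                                "FITC", "mCherry")
            ratios.append(meas.ratio)
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_well_mean_ratio_linear_in_bound_protein(self):
        """Noiseless amplitude sweep: mean ratio linear with R^2 >= 0.98."""
        amps = np.linspace(60.0, 600.0, 8)
        means = []
        for amp in amps:
            stack, locus = render_single_bead({"FITC": 800.0, "mCherry": amp})
            meas = measure_bead(stack, locus,
                                {"FITC": 50.0, "mCherry": 50.0},
                                "FITC", "mCherry")
            means.append(meas.ratio)
        slope, intercept = np.polyfit(amps, means, 1)
        pred = slope * amps + intercept
        ss_res = np.sum((np.array(means) - pred) ** 2)
        ss_tot = np.sum((np.array(means) - np.mean(means)) ** 2)
        assert 1 - ss_res / ss_tot >= 0.98
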