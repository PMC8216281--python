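"""Well aggregation, Z' factor, normalization and hit rules."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conascreen.errors import QCError, ZPrimeUndefinedError
from conascreen.ringquant import BeadMeasurement
from conascreen.screen import (
    ControlStats,
    WellSummary,
    call_hits,
    control_stats,
    normalize_and_inhibition,
    summarize_well,
    z_prime,
)


def beads(ratios, well="A01"):
    return [
        BeadMeasurement(bead_id=i, well=well, ratio=r, valid=True)
        for i, r in enumerate(ratios)
    ]


def well_summary(well, mean, role="compound", sd=0.0, n=100, compound="c",
                 conc=10.0):
    return WellSummary(
        well=well, n_beads_valid=n, mean_ratio=mean, sd_ratio=sd, valid=True,
        role=role, compound=compound if role == "compound" else "",
        concentration_um=conc if role == "compound" else None,
    )


class TestSummarizeWell:
    def test_degenerate_spread(self):
        s = summarize_well(beads([0.7] * 10), min_beads=5)
        assert s.mean_ratio == pytest.approx(0.7)
        assert s.sd_ratio == pytest.approx(0.0, abs=1e-12)
        assert s.valid

    def test_hand_computed_sample_sd(self):
        s = summarize_well(beads([1.0, 0.8, 1.2]), min_beads=3)
        assert s.mean_ratio == pytest.approx(1.0)
        assert s.sd_ratio == pytest.approx(0.2)

    def test_bead_count_floor(self):
        s = summarize_well(beads([1.0] * 10), min_beads=50)
        assert not s.valid
        assert s.n_beads_valid == 10

    def test_invalid_beads_excluded(self):
        ms = beads([1.0, 1.0])
        ms.append(BeadMeasurement(bead_id=9, well="A01", ratio=None,
                                  valid=False, invalid_reason="blank_bead"))
        s = summarize_well(ms, min_beads=2)
        assert s.n_beads_valid == 2

    def test_zero_valid_beads_gives_invalid_summary(self):
        s = summarize_well([], min_beads=1, well="Z99")
        assert not s.valid
        assert s.mean_ratio is None


class TestControlStats:
    def test_identical_wells(self):
        wells = [well_summary(f"A{i}", 1.0, role="negative_control")
                 for i in range(3)]
        cs = control_stats(wells, "negative_control")
        assert (cs.mean, cs.sd, cs.cv) == (1.0, 0.0, 0.0)

    def test_hand_computed(self):
        wells = [well_summary(f"A{i}", m, role="negative_control")
                 for i, m in enumerate([0.9, 1.0, 1.1])]
        cs = control_stats(wells, "negative_control")
        assert cs.mean == pytest.approx(1.0)
        assert cs.sd == pytest.approx(0.1)
        assert cs.cv == pytest.approx(10.0)

    def test_invalid_well_excluded(self):
        wells = [well_summary(f"A{i}", m, role="negative_control")
                 for i, m in enumerate([0.9, 1.1, 5.0])]
        wells[2].valid = False
        cs = control_stats(wells, "negative_control")
        assert cs.n_wells == 2
        assert cs.mean == pytest.approx(1.0)

    def test_singleton_falls_back_to_bead_sd(self):
        wells = [well_summary("A1", 1.0, role="negative_control", sd=0.05)]
        cs = control_stats(wells, "negative_control")
        assert cs.bead_sd_fallback
        assert cs.sd == pytest.approx(0.05)

    def test_no_valid_wells_raises(self):
        with pytest.raises(QCError, match="positive_control"):
            control_stats([], "positive_control")


class TestZPrime:
    def test_focused_library_legend_values(self):
        """Control stats of the focused screen reproduce the printed Z'."""
        neg = ControlStats("negative_control", 5, 0.932, 0.016, 1.75)
        pos = ControlStats("positive_control", 5, 0.124, 0.001, 0.96)
        assert z_prime(neg, pos) == pytest.approx(0.937, abs=0.001)
        assert z_prime(neg, pos) == pytest.approx(0.93, abs=0.01)

    def test_prototype_screen_legend_values(self):
        neg = ControlStats("negative_control", 6, 1.009, 0.067, 6.70)
        pos = ControlStats("positive_control", 6, 0.288, 0.006, 2.18)
        assert z_prime(neg, pos) == pytest.approx(0.696, abs=0.001)
        assert z_prime(neg, pos) == pytest.approx(0.69, abs=0.01)

    def test_noiseless_limit_is_one(self):
        neg = ControlStats("negative_control", 3, 1.0, 0.0, 0.0)
        pos = ControlStats("positive_control", 3, 0.2, 0.0, 0.0)
        assert z_prime(neg, pos) == 1.0

    def test_equal_means_undefined(self):
        neg = ControlStats("negative_control", 3, 0.5, 0.01, 2.0)
        pos = ControlStats("positive_control", 3, 0.5, 0.01, 2.0)
        with pytest.raises(ZPrimeUndefinedError):
            z_prime(neg, pos)

    @given(
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-10.0, 10.0),
    )
    def test_affine_invariance(self, scale, shift):
        """Z' unchanged by rescaling + shifting all well values."""
        neg = ControlStats("negative_control", 5, 1.0, 0.05, 5.0)
        pos = ControlStats("positive_control", 5, 0.3, 0.01, 3.3)
        base = z_prime(neg, pos)
        neg2 = ControlStats("negative_control", 5, scale * 1.0 + shift,
                            scale * 0.05, 0.0)
        pos2 = ControlStats("positive_control", 5, scale * 0.3 + shift,
                            scale * 0.01, 0.0)
        assert z_prime(neg2, pos2) == pytest.approx(base, rel=1e-9)


class TestNormalizeAndHits:
    def test_inhibition_arithmetic(self):
        neg = ControlStats("negative_control", 5, 0.932, 0.016, 1.75)
        wells = [well_summary("C01", 0.124), well_summary("C02", 0.932)]
        normalize_and_inhibition(wells, neg)
        assert wells[0].percent_inhibition == pytest.approx(86.7, abs=0.05)
        assert wells[1].percent_inhibition == pytest.approx(0.0, abs=1e-9)

    def test_inhibition_prototype_controls(self):
        neg = ControlStats("negative_control", 6, 1.009, 0.067, 6.70)
        wells = [well_summary("C01", 0.288)]
        normalize_and_inhibition(wells, neg)
        assert wells[0].percent_inhibition == pytest.approx(71.5, abs=0.05)

    def test_nonpositive_neg_mean_rejected(self):
        neg = ControlStats("negative_control", 5, 0.0, 0.0, 0.0)
        with pytest.raises(QCError):
            normalize_and_inhibition([well_summary("C01", 0.5)], neg)

    def test_rule_a_threshold(self):
        neg = ControlStats("negative_control", 5, 1.00, 0.02, 2.0)
        wells = normalize_and_inhibition(
            [well_summary("C01", 0.50), well_summary("C02", 0.95)], neg
        )
        calls = {h.well: h for h in call_hits(wells, neg)}
        assert calls["C01"].rule_a_hit  # 0.50 < 1.00 - 3*0.02 = 0.94
        assert not calls["C02"].rule_a_hit

    def test_well_at_negative_mean_is_never_a_hit(self):
        neg = ControlStats("negative_control", 5, 1.0, 0.02, 2.0)
        wells = normalize_and_inhibition([well_summary("C01", 1.0)], neg)
        call = call_hits(wells, neg)[0]
        assert not call.rule_a_hit and not call.rule_b_hit

    def test_rule_b_cv_threshold(self):
        """neg CV 6.70% -> threshold 40.2% inhibition with k = 6."""
        neg = ControlStats("negative_control", 6, 1.0, 0.067, 6.70)
        wells = normalize_and_inhibition(
            [well_summary("C01", 0.61), well_summary("C02", 0.55)], neg
        )
        calls = {h.well: h for h in call_hits(wells, neg)}
        assert not calls["C01"].rule_b_hit  # 39% inhibition
        assert calls["C02"].rule_b_hit      # 45% inhibition

    def test_stabilizer_reported_separately(self):
        neg = ControlStats("negative_control", 5, 1.0, 0.02, 2.0)
        wells = normalize_and_inhibition([well_summary("C01", 1.25)], neg)
        call = call_hits(wells, neg)[0]
        assert call.stabilizer
        assert not call.rule_a_hit
        assert call.percent_inhibition < 0

    def test_controls_not_called(self):
        neg = ControlStats("negative_control", 5, 1.0, 0.02, 2.0)
        wells = normalize_and_inhibition(
            [well_summary("A01", 1.0, role="negative_control"),
             well_summary("C01", 0.4)], neg
        )
        assert [h.well for h in call_hits(wells, neg)] == ["C01"]
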