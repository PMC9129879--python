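"""SNP location, peak-area quantification, and standard-curve calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epimemory.allele_quant import (
    calibrate_fraction,
    fit_standard_curve,
    integration_window,
    locate_snp_peak,
    quantify_allele_fraction,
)
from epimemory.errors import (
    AmbiguousLocusError,
    DegenerateSignalError,
    LocusNotFoundError,
    RankDeficiencyError,
    UnusableCurveError,
)
from epimemory.synthetic_data import (
    DEFAULT_LOCUS,
    DESIGN_FRACTIONS,
    TraceGenSpec,
    simulate_trace,
)
from epimemory.trace_io import SNPLocus, TraceSignal

from conftest import make_flat_trace


class TestLocateSnpPeak:
    def test_unique_exact_match(self):
        trace = make_flat_trace("TTGGAACCATT")
        locus = SNPLocus("A", "C", "TTGGA", "CCATT")
        assert locate_snp_peak(trace, locus) == 5

    def test_flanks_absent_raises(self):
        trace = make_flat_trace("GGGGGGGGGG")
        locus = SNPLocus("A", "C", "TTGGA", "CCATT")
        with pytest.raises(LocusNotFoundError):
            locate_snp_peak(trace, locus)

    def test_repeated_context_is_ambiguous(self):
        trace = make_flat_trace("GGACCGGACC")
        locus = SNPLocus("A", "C", "GG", "CC")
        with pytest.raises(AmbiguousLocusError):
            locate_snp_peak(trace, locus)

    def test_recovers_generator_ground_truth_index(self):
        trace, truth = simulate_trace(TraceGenSpec(fraction_primary=0.3, seed=5))
        assert locate_snp_peak(trace, DEFAULT_LOCUS) == truth["snp_index"] == 20


def _oracle_fraction(trace, truth, locus):
    """Direct integration of the generating Gaussian components over the window."""
    lo, hi = integration_window(trace, truth["snp_index"])
    x = np.arange(lo, hi, dtype=float)
    areas = {locus.allele_primary: 0.0, locus.allele_secondary: 0.0}
    for comp in truth["components"]:
        if comp["channel"] in areas:
            areas[comp["channel"]] += float(
                np.sum(
                    comp["amplitude"]
                    * np.exp(-((x - comp["center"]) ** 2) / (2 * comp["sd"] ** 2))
                )
            )
    total = areas[locus.allele_primary] + areas[locus.allele_secondary]
    return areas[locus.allele_primary] / total


class TestQuantifyAlleleFraction:
    def test_single_allele_sample_gives_one(self, locus):
        trace, truth = simulate_trace(TraceGenSpec(fraction_primary=1.0))
        q = quantify_allele_fraction(trace, truth["snp_index"], locus)
        assert q.fraction_primary == 1.0

    def test_symmetric_channels_give_half(self, locus):
        trace, truth = simulate_trace(TraceGenSpec(fraction_primary=0.5))
        q = quantify_allele_fraction(trace, truth["snp_index"], locus)
        assert q.fraction_primary == pytest.approx(0.5, abs=1e-9)

    def test_three_to_one_ratio_matches_gaussian_oracle(self, locus):
        trace, truth = simulate_trace(TraceGenSpec(fraction_primary=0.75, baseline=5.0))
        q = quantify_allele_fraction(trace, truth["snp_index"], locus)
        assert q.fraction_primary == pytest.approx(0.75, abs=0.01)
        assert q.fraction_primary == pytest.approx(
            _oracle_fraction(trace, truth, locus), abs=0.01
        )

    @pytest.mark.parametrize("fraction", DESIGN_FRACTIONS)
    def test_noise_free_quantification_matches_oracle_across_design(self, locus, fraction):
        trace, truth = simulate_trace(TraceGenSpec(fraction_primary=fraction))
        q = quantify_allele_fraction(trace, truth["snp_index"], locus)
        if 0.0 < fraction < 1.0:
            expected = _oracle_fraction(trace, truth, locus)
        else:
            expected = fraction
        assert q.fraction_primary == pytest.approx(expected, abs=0.01)

    def test_degenerate_signal_raises(self, locus):
        trace = make_flat_trace("GGTTATGGT", value=2.0)  # flat: zero corrected area
        with pytest.raises(DegenerateSignalError):
            quantify_allele_fraction(trace, 4, locus)

    @given(fraction=st.floats(0.05, 0.95), scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, fraction, scale):
        trace, truth = simulate_trace(TraceGenSpec(fraction_primary=fraction, seed=9))
        scaled = TraceSignal(
            intensities=trace.intensities * scale,
            called_bases=trace.called_bases,
            peak_positions=trace.peak_positions,
            channel_order=trace.channel_order,
        )
        q0 = quantify_allele_fraction(trace, truth["snp_index"], DEFAULT_LOCUS)
        q1 = quantify_allele_fraction(scaled, truth["snp_index"], DEFAULT_LOCUS)
        assert q1.fraction_primary == pytest.approx(q0.fraction_primary, abs=1e-12)

    @given(fraction=st.floats(0.05, 0.95))
    def test_channel_swap_equivariance(self, fraction):
        trace, truth = simulate_trace(
            TraceGenSpec(fraction_primary=fraction, noise_sd=0.05, seed=11)
        )
        swapped = SNPLocus(
            allele_primary=DEFAULT_LOCUS.allele_secondary,
            allele_secondary=DEFAULT_LOCUS.allele_primary,
            flank_left=DEFAULT_LOCUS.flank_left,
            flank_right=DEFAULT_LOCUS.flank_right,
        )
        q = quantify_allele_fraction(trace, truth["snp_index"], DEFAULT_LOCUS)
        q_swapped = quantify_allele_fraction(trace, truth["snp_index"], swapped)
        assert q_swapped.fraction_primary == pytest.approx(
            1.0 - q.fraction_primary, abs=1e-12
        )


class TestStandardCurve:
    def test_identity_line(self):
        pairs = [(f, f) for f in (0.0, 0.3, 0.7, 1.0)]
        curve = fit_standard_curve(pairs)
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_nine_point_design_identity(self):
        curve = fit_standard_curve([(f, f) for f in DESIGN_FRACTIONS])
        assert curve.slope == pytest.approx(1.0)

    def test_exact_affine_line_recovered(self):
        pairs = [(f, 0.9 * f + 0.05) for f in DESIGN_FRACTIONS]
        curve = fit_standard_curve(pairs)
        assert curve.slope == pytest.approx(0.9)
        assert curve.intercept == pytest.approx(0.05)

    def test_rank_deficiency(self):
        with pytest.raises(RankDeficiencyError):
            fit_standard_curve([(0.5, 0.4), (0.5, 0.6)])
        with pytest.raises(RankDeficiencyError):
            fit_standard_curve([(0.5, 0.4)])


class TestCalibrateFraction:
    def test_identity_curve_is_identity(self):
        curve = fit_standard_curve([(f, f) for f in (0.0, 0.5, 1.0)])
        cal = calibrate_fraction(curve, 0.37)
        assert cal.value == pytest.approx(0.37)
        assert not cal.clamped

    def test_affine_inversion(self):
        curve = fit_standard_curve([(f, 0.9 * f + 0.05) for f in (0.0, 0.5, 1.0)])
        assert calibrate_fraction(curve, 0.5).value == pytest.approx(0.5)

    def test_clamping_is_flagged(self):
        curve = fit_standard_curve([(f, f + 0.2) for f in (0.0, 0.5, 0.8)])
        cal = calibrate_fraction(curve, 0.1)
        assert cal.value == 0.0
        assert cal.clamped

    def test_non_positive_slope_rejected(self):
        curve = fit_standard_curve([(0.0, 1.0), (1.0, 0.0)])
        with pytest.raises(UnusableCurveError):
            calibrate_fraction(curve, 0.5)
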