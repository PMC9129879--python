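"""Replication-dilution / reader-writer mark-persistence model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epimemory.errors import IdentifiabilityError, ValidationError
from epimemory.inheritance import (
    ChipTimecourse,
    MarkDecayParams,
    classify_heritability,
    expected_signal,
    fit_decay,
    half_life,
    mark_fraction,
    persistence_generations,
    simulate_locus_divisions,
)
from epimemory.synthetic_data import ChipGenSpec, simulate_chip_timecourse

TD = 120.0


def params(s0=10.0, bg=1.0, m=0.0, k=0.0):
    return MarkDecayParams(
        s0=s0, background=bg, doubling_time=TD, maintenance_prob=m, removal_rate=k
    )


class TestMarkFraction:
    def test_passive_dilution_halves_per_doubling(self):
        assert mark_fraction(params(), TD) == pytest.approx(0.5)

    def test_perfect_maintenance_is_flat(self):
        for t in (0.0, 100.0, 1e4):
            assert mark_fraction(params(m=1.0), t) == 1.0

    def test_partial_maintenance_closed_form(self):
        # ((1 + 0.5) / 2)^2 = 0.5625
        assert mark_fraction(params(m=0.5), 2 * TD) == pytest.approx(0.5625)

    def test_expected_signal_examples(self):
        assert expected_signal(params(s0=10.0, bg=0.0), 480.0) == pytest.approx(0.625)
        assert expected_signal(params(m=0.7, k=0.01), 0.0) == pytest.approx(11.0)
        assert expected_signal(params(s0=10.0, bg=2.0, m=1.0), 600.0) == pytest.approx(12.0)

    def test_half_life_equals_doubling_time_for_passive(self):
        assert half_life(params()) == pytest.approx(TD)

    def test_half_life_infinite_for_perfect_maintenance(self):
        assert math.isinf(half_life(params(m=1.0)))

    @given(
        m=st.floats(0.0, 0.99),
        k=st.floats(0.0, 0.01),
    )
    def test_signal_strictly_decreasing_for_imperfect_maintenance(self, m, k):
        # t range kept where the decaying term stays above float resolution
        p = params(m=m, k=k)
        t = np.linspace(0.0, 3 * TD, 10)
        sig = expected_signal(p, t)
        assert np.all(np.diff(sig) < 0)

    def test_half_life_increasing_in_maintenance(self):
        grid = np.linspace(0.0, 0.99, 12)
        hl = [half_life(params(m=mi)) for mi in grid]
        assert all(b > a for a, b in zip(hl, hl[1:]))


class TestDivisionSimulator:
    def test_perfect_maintenance_never_loses_marks(self):
        traj = simulate_locus_divisions(params(m=1.0), 100, 5, seed=1)
        assert np.all(traj == 1.0)

    def test_first_division_halves_without_maintenance(self):
        traj = simulate_locus_divisions(params(), 10_000, 1, seed=2)
        assert traj[1] == pytest.approx(0.5, abs=0.015)  # 3 binomial sd

    def test_mean_over_seeds_matches_closed_form(self):
        m = 0.5
        fractions = np.array(
            [simulate_locus_divisions(params(m=m), 50, 2, seed=s)[2] for s in range(1000)]
        )
        assert fractions.mean() == pytest.approx(0.5625, abs=0.01)

    def test_trajectory_mean_matches_closed_form_every_division(self):
        m = 0.3
        n_div = 5
        trajs = np.array(
            [simulate_locus_divisions(params(m=m), 200, n_div, seed=s) for s in range(300)]
        )
        mean_traj = trajs.mean(axis=0)
        for g in range(n_div + 1):
            expected = ((1 + m) / 2) ** g
            mc_se = trajs[:, g].std(ddof=1) / math.sqrt(len(trajs)) + 1e-9
            assert abs(mean_traj[g] - expected) < 4 * mc_se

    def test_invalid_nucleosome_count(self):
        with pytest.raises(ValidationError):
            simulate_locus_divisions(params(), 0, 3)


class TestFitDecay:
    def test_recovers_passive_dilution_noise_free(self):
        tc, _ = simulate_chip_timecourse(ChipGenSpec(params=params(), noise_sd=0.0))
        fit = fit_decay(tc, TD, model="maintenance")
        assert fit.params.maintenance_prob <= 0.02
        assert half_life(fit.params) == pytest.approx(TD, rel=0.01)

    def test_flat_data_implies_near_perfect_maintenance(self):
        tc, _ = simulate_chip_timecourse(ChipGenSpec(params=params(m=1.0), noise_sd=0.0))
        fit = fit_decay(tc, TD, model="maintenance")
        assert fit.params.maintenance_prob >= 0.98

    def test_recovers_removal_rate_within_10_percent(self):
        p = params(k=0.05)
        tc, _ = simulate_chip_timecourse(
            ChipGenSpec(params=p, noise_sd=0.0, timepoints=(0, 15, 30, 60, 120, 240))
        )
        fit = fit_decay(tc, TD, model="maintenance_plus_removal")
        assert fit.params.removal_rate == pytest.approx(0.05, rel=0.10)

    def test_recovers_linear_parameters(self):
        tc, _ = simulate_chip_timecourse(
            ChipGenSpec(params=params(s0=7.0, bg=2.0, m=0.6), noise_sd=0.0)
        )
        fit = fit_decay(tc, TD, model="maintenance")
        assert fit.params.s0 == pytest.approx(7.0, rel=0.05)
        assert fit.params.background == pytest.approx(2.0, rel=0.05)

    def test_too_few_timepoints_is_identifiability_error(self):
        tc = ChipTimecourse(times=[0.0, 60.0], signals=[10.0, 8.0], sems=[0.1, 0.1])
        with pytest.raises(IdentifiabilityError):
            fit_decay(tc, TD, model="maintenance")

    def test_deterministic_given_inputs(self):
        tc, _ = simulate_chip_timecourse(ChipGenSpec(params=params(m=0.8), seed=3))
        f1 = fit_decay(tc, TD, model="maintenance_plus_removal")
        f2 = fit_decay(tc, TD, model="maintenance_plus_removal")
        assert f1.params == f2.params


class TestPersistenceGenerations:
    def test_flat_signal_through_eight_hours_is_four_generations(self):
        times = np.arange(0.0, 481.0, 60.0)
        tc = ChipTimecourse(
            times=times,
            signals=np.full(len(times), 8.0),
            sems=np.full(len(times), 0.5),
            control_signals=np.full(len(times), 1.0),
        )
        res = persistence_generations(tc, TD)
        assert res.t_star == 480.0
        assert res.generations == pytest.approx(4.0)

    def test_signal_below_threshold_everywhere_is_zero(self):
        times = np.array([0.0, 120.0, 240.0])
        tc = ChipTimecourse(
            times=times,
            signals=np.array([0.9, 0.8, 0.85]),
            sems=np.full(3, 0.2),
            control_signals=np.full(3, 1.0),
        )
        res = persistence_generations(tc, TD)
        assert res.generations == 0.0

    def test_eightfold_signal_persists_three_generations_under_dilution(self):
        threshold = 1.0
        times = np.arange(0.0, 481.0, 120.0)
        tc = ChipTimecourse(
            times=times,
            signals=8.0 * threshold * 0.5 ** (times / TD) + 0.2,
            sems=np.zeros(len(times)),
            control_signals=np.full(len(times), 0.2),
        )
        res = persistence_generations(tc, TD, threshold=threshold)
        assert res.generations == pytest.approx(3.0)

    def test_requires_background_source(self):
        tc = ChipTimecourse(times=[0.0, 60.0, 120.0], signals=[3, 2, 1], sems=[0, 0, 0])
        with pytest.raises(ValidationError):
            persistence_generations(tc, TD)


class TestClassifyHeritability:
    @pytest.mark.parametrize(
        "gen_params, expected",
        [
            (params(m=0.95), "heritable"),
            (params(), "passive_dilution"),
            (params(k=0.03), "active_removal"),
        ],
    )
    def test_regimes_recovered_at_5pct_noise(self, gen_params, expected):
        tc, _ = simulate_chip_timecourse(
            ChipGenSpec(params=gen_params, noise_sd=0.05, seed=17)
        )
        report = classify_heritability(tc, TD)
        assert report.label == expected
        assert set(report.fits) == {
            "dilution_only",
            "maintenance",
            "maintenance_plus_removal",
        }
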