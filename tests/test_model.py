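"""Closed-form cell-cycle model: age distribution, marker-frequency
relations, per-age replication state and their mutual consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from oricycle import (
    CellCycleParams,
    age_cdf,
    age_pdf,
    c_period_from_ratio,
    circular_age_distance,
    d_period,
    mean_genome_equivalents,
    model_initiation_age,
    ori_ter_ratio,
    origins_per_cell,
    period_from_frequency,
    sample_ages,
    state_at_age,
)

LN2 = math.log(2)

params_strategy = st.builds(
    CellCycleParams,
    tau=st.floats(10.0, 120.0),
    c_period=st.floats(5.0, 90.0),
    d_period=st.floats(0.0, 60.0),
)


class TestAgeDistribution:
    def test_density_endpoints_and_normalization(self):
        assert age_pdf(0.0) == pytest.approx(2 * LN2)
        assert age_pdf(1.0 - 1e-12) == pytest.approx(LN2, rel=1e-9)
        total, _ = quad(age_pdf, 0, 1)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_cdf_matches_numeric_integral_of_pdf(self):
        assert age_cdf(0.0) == 0.0
        assert age_cdf(1.0) == pytest.approx(1.0)
        for a in np.linspace(0.05, 0.99, 9):
            num, _ = quad(age_pdf, 0, a)
            assert abs(age_cdf(a) - num) < 1e-9
        assert age_cdf(0.5) == pytest.approx(2 * (1 - 2**-0.5), abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_out_of_range_age_rejected(self, bad):
        with pytest.raises(ValueError):
            age_pdf(bad)

    def test_sampled_ages_follow_cdf(self):
        ages = sample_ages(100_000, seed=7)
        grid = np.linspace(0, 1, 201)
        empirical = np.searchsorted(np.sort(ages), grid) / len(ages)
        analytic = np.array([age_cdf(a) for a in grid])
        assert np.max(np.abs(empirical - analytic)) < 0.01


class TestMarkerFrequencyRelations:
    def test_ratio_special_cases(self, recwarn):
        assert ori_ter_ratio(CellCycleParams(25, 0, 10)) == 1.0
        assert ori_ter_ratio(CellCycleParams(25, 25, 10)) == 2.0

    def test_ratio_matches_measured_wildtype_row(self):
        # tau back-solved from the printed ratio reproduces the printed ratio
        p = CellCycleParams(tau=24.02, c_period=43.8, d_period=23.7)
        assert ori_ter_ratio(p) == pytest.approx(3.54, abs=0.01)
        assert c_period_from_ratio(3.54, 24.02) == pytest.approx(43.8, abs=0.1)

    def test_c_period_inversion_cases(self):
        assert c_period_from_ratio(2.0, 25.0) == 25.0
        assert c_period_from_ratio(1.0, 25.0) == 0.0
        with pytest.raises(ValueError):
            c_period_from_ratio(0.9, 25.0)

    def test_origins_per_cell_cases(self):
        assert origins_per_cell(CellCycleParams(30, 20, 10)) == pytest.approx(2.0)
        p = CellCycleParams(24.02, 43.8, 23.7)
        assert origins_per_cell(p) == pytest.approx(7.0, abs=0.1)

    @pytest.mark.parametrize(
        "origins,tau,c,expected",
        [(7.0, 24.02, 43.8, 23.6), (5.5, 24.98, 34.3, 27.2)],
    )
    def test_d_period_reproduces_published_rows(self, origins, tau, c, expected):
        d, ok = d_period(origins, tau, c)
        assert ok
        assert d == pytest.approx(expected, abs=0.3)

    def test_negative_d_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="negative"):
            d, ok = d_period(1.5, 20.0, 40.0)
        assert d < 0 and not ok

    @settings(derandomize=True, max_examples=200)
    @given(params_strategy)
    def test_period_ratio_round_trips(self, p):
        assert c_period_from_ratio(ori_ter_ratio(p), p.tau) == pytest.approx(
            p.c_period, rel=1e-12, abs=1e-12
        )
        d, _ = d_period(origins_per_cell(p), p.tau, p.c_period)
        assert d == pytest.approx(p.d_period, rel=1e-9, abs=1e-9)


class TestInitiationAgeAndState:
    def test_initiation_age_cases(self):
        assert model_initiation_age(CellCycleParams(20, 25, 15)) == pytest.approx(0.0)
        assert model_initiation_age(CellCycleParams(20, 20, 10)) == pytest.approx(0.5)
        p = CellCycleParams(24.02, 43.8, 23.7)
        assert model_initiation_age(p) == pytest.approx(0.19, abs=0.005)

    def test_initiation_age_against_lineage_timing(self, wt_params):
        # an origin firing at a_i must run C then wait D, landing exactly on
        # a division (integer age on the lineage clock)
        a_i = model_initiation_age(wt_params)
        cycles_to_division = a_i + wt_params.rounds
        assert cycles_to_division == pytest.approx(round(cycles_to_division))

    def test_single_round_regime(self):
        p = CellCycleParams(tau=60.0, c_period=30.0, d_period=20.0)
        a_i = model_initiation_age(p)
        s = state_at_age(a_i + 0.01, p)
        assert s.origins == 2 and s.fork_pairs == 1
        assert state_at_age(a_i - 0.01, p).origins == 1

    def test_multifork_origins_at_mid_cycle(self, wt_params):
        assert state_at_age(0.5, wt_params).origins == 8

    def test_origins_double_once_per_cycle(self, wt_params):
        ages = np.linspace(0, 0.999, 400)
        origins = np.array([state_at_age(a, wt_params).origins for a in ages])
        assert np.all(np.diff(origins) >= 0)
        assert origins[-1] == 2 * origins[0]

    def test_division_symmetry_of_dna_content(self, wt_params):
        g0 = state_at_age(1e-9, wt_params).genome_equivalents
        g1 = state_at_age(1 - 1e-9, wt_params).genome_equivalents
        assert g1 == pytest.approx(2 * g0, rel=1e-5)

    def test_genome_equivalents_continuous_in_age(self, wt_params):
        ages = np.linspace(0, 0.999, 2000)
        g = np.array([state_at_age(a, wt_params).genome_equivalents for a in ages])
        # piecewise-smooth: no jump anywhere near the (bounded) slope scale
        assert np.max(np.abs(np.diff(g))) < 0.02


class TestMeanGenomeEquivalents:
    def test_closed_form_limits(self):
        assert mean_genome_equivalents(CellCycleParams(30, 30, 0)) == pytest.approx(
            1 / LN2, rel=1e-12
        )
        with pytest.warns(UserWarning, match="degenerate"):
            p = CellCycleParams(30, 0, 0)
        assert mean_genome_equivalents(p) == pytest.approx(1.0)

    def test_closed_form_equals_age_average(self, wt_params):
        num, _ = quad(
            lambda a: age_pdf(a) * state_at_age(a, wt_params).genome_equivalents,
            0,
            1,
            limit=200,
        )
        assert mean_genome_equivalents(wt_params) == pytest.approx(num, rel=1e-6)

    def test_closed_form_matches_monte_carlo(self, wt_params):
        ages = sample_ages(100_000, seed=3)
        mc = np.mean([state_at_age(a, wt_params).genome_equivalents for a in ages])
        assert mc == pytest.approx(mean_genome_equivalents(wt_params), rel=0.01)


class TestPeriodFromFrequency:
    def test_endpoints_and_inverse(self):
        assert period_from_frequency(1.0) == pytest.approx(0.0)
        assert period_from_frequency(0.0) == pytest.approx(1.0)
        # numeric inversion oracle: fraction of cells older than a1
        a1 = period_from_frequency(0.8)
        assert a1 == pytest.approx(0.152, abs=0.001)
        frac, _ = quad(age_pdf, a1, 1)
        assert frac == pytest.approx(0.8, abs=1e-9)
        with pytest.raises(ValueError):
            period_from_frequency(1.2)


def test_circular_age_distance_wraps():
    assert circular_age_distance(0.93, 0.08) == pytest.approx(0.15)
    assert circular_age_distance(0.2, 0.2) == 0.0
    assert circular_age_distance(0.0, 0.5) == pytest.approx(0.5)
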