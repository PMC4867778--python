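"""Life-table construction, Sullivan health expectancies, and derived ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import multimorb as mm


class TestDeathProb:
    def test_zero_rate_gives_zero(self):
        q = mm.death_prob(np.array([0.0, 0.0, 1.0]))
        assert q[0] == 0.0

    def test_literal_formula(self):
        q = mm.death_prob(np.array([0.1, 0.0, 1.0]))
        assert q[0] == pytest.approx(0.1 / 1.05)

    def test_standard_convention_includes_band_width(self):
        q = mm.death_prob(np.array([0.1, 0.0, 1.0]), band_width=5, convention="abridged_standard")
        assert q[0] == pytest.approx(0.5 / 1.25)

    def test_huge_rate_is_capped_at_one(self, caplog):
        with caplog.at_level("WARNING"):
            q = mm.death_prob(np.array([50.0, 1.0]))
        assert q[0] == 1.0
        assert any("capped" in r.message for r in caplog.records)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mm.death_prob(np.array([-0.1, 1.0]))

    def test_final_band_forced_closed(self):
        assert mm.death_prob(np.array([0.0, 0.0, 0.2]))[-1] == 1.0


class TestBuildLifeTable:
    def test_hand_computed_no_early_mortality(self):
        ell, big_l, e = mm.build_life_table(np.array([0.0, 0.0, 1.0]), band_width=5)
        assert np.allclose(ell, [1.0, 1.0, 1.0])
        assert np.allclose(big_l, [5.0, 5.0, 2.5])
        assert e[0] == pytest.approx(12.5)

    def test_hand_computed_with_mortality(self):
        ell, big_l, e = mm.build_life_table(np.array([0.1, 0.2, 1.0]), band_width=5)
        assert np.allclose(ell, [1.0, 0.9, 0.72])
        assert np.allclose(big_l, [4.75, 4.05, 1.8])
        assert e[0] == pytest.approx(10.6)

    def test_immediate_death_leaves_half_band(self):
        _, _, e = mm.build_life_table(np.ones(4), band_width=5)
        assert e[0] == pytest.approx(2.5)

    def test_open_table_rejected(self):
        with pytest.raises(ValueError, match="final band"):
            mm.build_life_table(np.array([0.1, 0.5]))

    def test_matches_cohort_microsimulation(self):
        """1e6 simulated lifelines with uniform-within-band deaths agree to < 0.05 y."""
        rng = np.random.default_rng(123)
        q = np.array([0.02, 0.05, 0.1, 0.3, 1.0])
        n_band = 5.0
        _, _, e = mm.build_life_table(q, band_width=n_band)
        n = 1_000_000
        alive = np.ones(n, dtype=bool)
        years = np.zeros(n)
        for x, qx in enumerate(q):
            dies = alive & (rng.random(n) < qx)
            # the half-interval assumption corresponds to uniform death times
            years[dies] = x * n_band + rng.random(int(dies.sum())) * n_band
            alive &= ~dies
        assert e[0] == pytest.approx(years.mean(), abs=0.05)


class TestSullivan:
    def test_full_health_recovers_total_expectancy(self):
        q = np.array([0.1, 0.2, 1.0])
        ell, big_l, e = mm.build_life_table(q, band_width=5)
        pi = np.zeros((3, 3))
        pi[:, 0] = 1.0
        hle1, hle2 = mm.sullivan_hle(pi, ell, big_l)
        assert hle1 == pytest.approx(e[0]) and hle2 == pytest.approx(e[0])

    def test_no_multimorbidity_makes_hle2_equal_e(self):
        q = np.array([0.1, 0.2, 1.0])
        ell, big_l, e = mm.build_life_table(q, band_width=5)
        pi = np.column_stack([np.full(3, 0.3), np.full(3, 0.7), np.zeros(3)])
        _, hle2 = mm.sullivan_hle(pi, ell, big_l)
        assert hle2 == pytest.approx(e[0])

    def test_hand_computed_weighted_sum(self):
        q = np.array([0.1, 0.2, 1.0])
        ell, big_l, _ = mm.build_life_table(q, band_width=5)  # L = 4.75, 4.05, 1.8
        pi0 = np.array([1.0, 0.5, 0.2])
        pi = np.column_stack([pi0, 1.0 - pi0, np.zeros(3)])
        hle1, _ = mm.sullivan_hle(pi, ell, big_l)
        assert hle1 == pytest.approx(4.75 + 0.5 * 4.05 + 0.2 * 1.8)  # 7.135

    def test_sum_runs_from_current_band(self):
        q = np.array([0.1, 0.2, 1.0])
        ell, big_l, e = mm.build_life_table(q, band_width=5)
        pi = np.zeros((3, 3))
        pi[:, 0] = 1.0
        hle1, _ = mm.sullivan_hle(pi, ell, big_l, from_band=1)
        assert hle1 == pytest.approx(e[1])
        assert hle1 <= e[0] + 5.0  # bounded by remaining bands, not inflated by band 0


class TestComplexMorbidityRatio:
    @pytest.mark.parametrize(
        "e,h1,h2,printed",
        [(82.9, 56.7, 71.8, 0.73), (76.1, 53.0, 66.0, 0.78), (86.2, 60.2, 76.3, 0.62)],
    )
    def test_reported_decile_values(self, e, h1, h2, printed):
        assert mm.complex_morbidity_ratio(e, h1, h2) == pytest.approx(printed, abs=0.01)

    def test_zero_numerator(self):
        assert mm.complex_morbidity_ratio(70.0, 50.0, 70.0) == 0.0

    def test_equal_hles_is_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(mm.complex_morbidity_ratio(80.0, 60.0, 60.0))


class TestWindowProportion:
    @pytest.mark.parametrize("hle2,expected", [(67.0, 0.8), (60.0, 1.0), (80.0, 0.0),
                                               (65.0, 1.0), (75.0, 0.0)])
    def test_piecewise_values(self, hle2, expected):
        assert mm.multimorbidity_window_proportion(hle2) == pytest.approx(expected)

    def test_monotone_nonincreasing_in_hle2(self):
        h = np.linspace(55, 85, 301)
        m = mm.multimorbidity_window_proportion(h)
        assert np.all(np.diff(m) <= 1e-12)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            mm.multimorbidity_window_proportion(70.0, window=(75.0, 65.0))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**9))
def test_ordering_invariant_on_random_rates(seed):
    """HLE1 <= HLE2 <= E for arbitrary valid rate surfaces."""
    rng = np.random.default_rng(seed)
    rho = rng.gamma(1.0, 0.05, size=(2, 3, 18))
    pi = rng.dirichlet((1.0, 1.0, 1.0), size=(2, 3, 18))
    res = mm.life_table_draws(rho, pi)
    assert np.all(res.hle1 <= res.hle2 + 1e-9)
    assert np.all(res.hle2 <= res.e0 + 1e-9)
    assert np.all((res.m2 >= 0) & (res.m2 <= 1))


def test_increasing_multimorbidity_weakly_decreases_hle2(rng):
    rho = rng.gamma(1.0, 0.05, size=(1, 1, 18))
    pi = rng.dirichlet((2.0, 2.0, 2.0), size=(1, 1, 18))
    base = mm.life_table_draws(rho, pi).hle2[0, 0]
    pi2 = pi.copy()
    pi2[0, 0, 5] = [pi[0, 0, 5, 0] / 2, pi[0, 0, 5, 1] / 2,
                    pi[0, 0, 5, 2] + (pi[0, 0, 5, 0] + pi[0, 0, 5, 1]) / 2]
    assert mm.life_table_draws(rho, pi2).hle2[0, 0] <= base + 1e-12


def test_draws_frame_layout(rng):
    rho = rng.gamma(1.0, 0.05, size=(4, 3, 18))
    pi = rng.dirichlet((1, 1, 1), size=(4, 3, 18))
    res = mm.life_table_draws(rho, pi)
    df = res.to_frame()
    assert set(df.columns) == {"area_id", "draw", "E0", "HLE1", "HLE2", "M1", "M2"}
    assert len(df) == 12
    summ = mm.summarize_life_tables(res)
    assert np.all(summ["E0_lo"] <= summ["E0_mean"] + 1e-12)
    assert np.all(summ["E0_mean"] <= summ["E0_hi"] + 1e-12)
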