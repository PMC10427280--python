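import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from shortlist import (
    AdoptionParams,
    adoption_probability,
    draw_pools,
    partial_correlation,
    run_sweep,
    simulate_matrix,
    sweep_conditions,
)

unit = st.floats(0, 1)
nonneg = st.floats(0, 5)


class TestAdoptionParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(e=-1, s=1), dict(e=1, s=-0.1), dict(e=1, s=1, rho=1.5),
                   dict(e=1, s=1, n_items=1)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AdoptionParams(**kwargs)


class TestDrawPools:
    def test_everything_on_unit_interval(self, rng):
        params = AdoptionParams(e=1, s=1, rho=0.5, n_items=300, n_collections=150)
        items, cols = draw_pools(params, rng)
        for arr in (items.prevalence, items.appeal, cols.capacity):
            assert ((arr >= 0) & (arr <= 1)).all()
        assert len(cols.capacity) == 150

    def test_rho_one_makes_appeal_track_prevalence(self, rng):
        params = AdoptionParams(e=1, s=1, rho=1.0, n_items=100)
        items, _ = draw_pools(params, rng)
        assert stats.spearmanr(items.prevalence, items.appeal).statistic == pytest.approx(1.0)

    def test_rho_zero_leaves_appeal_independent(self, rng):
        params = AdoptionParams(e=1, s=1, rho=0.0, n_items=200)
        items, _ = draw_pools(params, rng)
        r = stats.spearmanr(items.prevalence, items.appeal).statistic
        assert abs(r) < 0.05

    @pytest.mark.parametrize("rho", [0.0, 0.25, 0.5, 0.75])
    def test_realized_rank_correlation_within_tolerance(self, rng, rho):
        params = AdoptionParams(e=1, s=1, rho=rho, n_items=120)
        items, _ = draw_pools(params, rng)
        r = stats.spearmanr(items.prevalence, items.appeal).statistic
        assert abs(r - rho) <= 0.05

    def test_appeal_margin_stays_uniform(self, rng):
        """Copula mixing must not distort the appeal distribution."""
        params = AdoptionParams(e=1, s=1, rho=0.75, n_items=400)
        items, _ = draw_pools(params, rng, tol=None)
        assert stats.kstest(items.appeal, "uniform").pvalue > 0.01


class TestAdoptionProbability:
    def test_weighted_average_algebra(self):
        # full capacity kills the shortlist term: (0.5*1 + 0 + 0) / 2
        assert adoption_probability(1, 0, 1, e=0.5, s=1) == pytest.approx(0.25)
        # zero capacity, zero prevalence: pure shortlist weight
        assert adoption_probability(0, 0, 1, e=0.2, s=0.3) == pytest.approx(0.3 / 0.7)
        # pure shortlist regime saturates: e=0 leaves only the appeal term
        assert adoption_probability(0, 1, 1, e=0, s=1) == pytest.approx(1.0)
        # capacity and shortlist terms trade off: all-ones inputs average 2/3
        assert adoption_probability(1, 1, 1, e=1, s=1) == pytest.approx(2 / 3)

    def test_no_forces_means_no_adoption(self):
        assert adoption_probability(0.5, 0.5, 0.5, e=0, s=0) == 0.0

    @given(unit, unit, unit, st.floats(0.001, 5), st.floats(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_always_a_probability(self, k, p, a, e, s):
        val = adoption_probability(k, p, a, e, s)
        assert 0.0 <= val <= 1.0

    @given(unit, unit, unit, unit, st.floats(0.001, 5), st.floats(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_prevalence_and_appeal(self, k, p, a, delta, e, s):
        base = adoption_probability(k, p, a, e, s)
        assert adoption_probability(k, min(1, p + delta), a, e, s) >= base - 1e-12
        assert adoption_probability(k, p, min(1, a + delta), e, s) >= base - 1e-12

    @given(unit, unit, unit, unit, st.floats(0.001, 5), st.floats(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_capacity_when_encounter_dominates(self, k, p, a, delta, e, s):
        if e >= s * a:
            base = adoption_probability(k, p, a, e, s)
            up = adoption_probability(min(1, k + delta), p, a, e, s)
            assert up >= base - 1e-12

    def test_scale_invariance_in_e_and_s(self):
        assert adoption_probability(0.3, 0.6, 0.8, e=0.1, s=0.2) == pytest.approx(
            adoption_probability(0.3, 0.6, 0.8, e=1.0, s=2.0)
        )


class TestSimulateMatrix:
    def test_no_forces_gives_empty_matrix(self, rng):
        params = AdoptionParams(e=0, s=0, n_items=10, n_collections=10)
        m = simulate_matrix(params, rng)
        assert m.cells.sum() == 0

    def test_cellwise_frequency_matches_probability(self):
        params = AdoptionParams(e=1, s=1, rho=0.5, n_items=6, n_collections=6, seed=3)
        rng = np.random.default_rng(3)
        m, items, cols = simulate_matrix(params, rng, return_pools=True)
        P = adoption_probability(
            cols.capacity[:, None], items.prevalence[None, :],
            items.appeal[None, :], params.e, params.s,
        )
        rng2 = np.random.default_rng(99)
        counts = np.zeros_like(P)
        n = 1000
        for _ in range(n):
            counts += rng2.random(P.shape) < P
        assert np.abs(counts / n - P).max() < 0.06

    def test_seeded_simulation_reproduces(self):
        params = AdoptionParams(e=1, s=1, rho=0.5, n_items=20, n_collections=20, seed=9)
        assert simulate_matrix(params) == simulate_matrix(params)


class TestPartialCorrelation:
    def test_uncorrelated_control_reduces_to_pearson(self, rng):
        x = rng.standard_normal(200)
        y = x + rng.standard_normal(200)
        z = rng.standard_normal(200)  # independent of both
        raw = stats.pearsonr(x, y).statistic
        part = partial_correlation(x, y, z)
        assert not part.degenerate
        assert part.value == pytest.approx(raw, abs=0.05)

    def test_degenerate_when_y_equals_z(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        res = partial_correlation(x, y, y)
        assert res.degenerate
        assert np.isnan(res.value)

    def test_matches_independent_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        z = np.array([0.0, 0.0, 1.0, 1.0])
        expected = pg.partial_corr(
            data=__import__("pandas").DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z",
        )["r"].iloc[0]
        got = partial_correlation(x, y, z)
        assert got.value == pytest.approx(expected, abs=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            partial_correlation([1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestSweep:
    def test_default_grid_enumerates_320_conditions(self):
        assert len(sweep_conditions()) == 320

    def test_sweep_matches_manual_decomposition(self):
        res = run_sweep(e_grid=[1.0], s_grid=[1.0], rho_grid=[0.5],
                        n_reps=3, size=20, seed=4)
        assert len(res.conditions) == 1
        rng = np.random.default_rng(np.random.SeedSequence(4, spawn_key=(0,)))
        from shortlist import nodf
        params = AdoptionParams(e=1.0, s=1.0, rho=0.5, n_items=20, n_collections=20)
        manual = np.mean([nodf(simulate_matrix(params, rng)).nodf_total for _ in range(3)])
        assert res.conditions["mean_nodf"].iloc[0] == pytest.approx(manual)

    def test_seeded_sweep_reproduces(self):
        kwargs = dict(e_grid=[1.0], s_grid=[0.5], rho_grid=[0.0, 0.5, 1.0],
                      n_reps=2, size=15, seed=8)
        a = run_sweep(**kwargs)
        b = run_sweep(**kwargs)
        assert a.conditions.equals(b.conditions)
        assert a.summary.equals(b.summary)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            run_sweep(e_grid=[], n_reps=1, size=10)

    def test_nodf_increases_with_selection_when_shortlist_active(self):
        """With e = s the coupling between selection level and mean NODF
        should be strongly positive even in a scaled-down sweep."""
        res = run_sweep(e_grid=[1.0], s_grid=[1.0], rho_grid=[0.0, 0.25, 0.5, 0.75, 1.0],
                        n_reps=8, size=60, seed=12)
        assert res.summary["r"].iloc[0] > 0.7
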