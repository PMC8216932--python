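import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import elevpart as ep
from elevpart.mde import Domain, _coverage_counts


def brute_force_expected(sizes, D):
    """Independent oracle: enumerate every feasible placement per species and
    average site coverage over the uniform placement distribution."""
    expected = np.zeros(D)
    for r in sizes:
        cover = np.zeros(D)
        placements = list(range(D - r + 1))
        for start in placements:
            cover[start : start + r] += 1
        expected += cover / len(placements)
    return expected


class TestRanges:
    def test_interior_gap_interpolated(self):
        # presences at positions 2 and 5 (1-based) in a 6-site domain
        inc = np.zeros((6, 1), dtype=int)
        inc[[1, 4], 0] = 1
        occ = ep.OccurrenceMatrix(
            sites=list("abcdef"), species=["x"], incidence=inc,
            elevations=np.arange(6.0),
        )
        (rng,) = ep.compute_ranges(occ)
        assert (rng.lo, rng.hi, rng.r) == (2, 5, 4)

    @pytest.mark.parametrize(
        "positions,expected_r", [([2], 1), (list(range(10)), 10)]
    )
    def test_extreme_ranges(self, positions, expected_r):
        inc = np.zeros((10, 1), dtype=int)
        inc[positions, 0] = 1
        occ = ep.OccurrenceMatrix(
            sites=[f"s{i}" for i in range(10)], species=["x"], incidence=inc,
            elevations=np.arange(10.0),
        )
        assert ep.compute_ranges(occ)[0].r == expected_r


class TestAnalyticExpectation:
    def test_full_domain_range(self):
        assert np.allclose(ep.analytic_expected_richness([5], Domain(5)), 1.0)

    def test_single_site_range_uniform(self):
        assert np.allclose(ep.analytic_expected_richness([1], Domain(5)), 0.2)

    def test_matches_enumeration_oracle(self):
        # D=4, r=2: three feasible placements covering sites (1,2),(2,3),(3,4)
        got = ep.analytic_expected_richness([2], Domain(4))
        assert np.allclose(got, [1 / 3, 2 / 3, 2 / 3, 1 / 3])
        rng = np.random.default_rng(3)
        for _ in range(20):
            D = int(rng.integers(1, 15))
            sizes = rng.integers(1, D + 1, size=rng.integers(1, 10))
            assert np.allclose(
                ep.analytic_expected_richness(sizes, Domain(D)),
                brute_force_expected(sizes, D),
            )

    def test_oversized_range_rejected(self):
        with pytest.raises(ValueError):
            ep.analytic_expected_richness([6], Domain(5))

    @given(st.integers(1, 20), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_mean(self, D, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, D + 1, size=int(rng.integers(1, 12)))
        e = ep.analytic_expected_richness(sizes, Domain(D))
        # symmetric about the domain midpoint for any range-size multiset
        assert np.allclose(e, e[::-1])
        # mean over sites equals total occupied site-slots / D exactly
        assert e.mean() == pytest.approx(sizes.sum() / D)


class TestMonteCarlo:
    def test_single_site_domain_degenerate(self):
        pred = ep.simulate_null([1, 1, 1], Domain(1), n_reps=50, seed=0)
        assert np.allclose(pred.mean_richness, 3)
        assert np.allclose(pred.ci_lo, 3) and np.allclose(pred.ci_hi, 3)

    def test_replicates_conserve_occupied_slots(self):
        sizes = [3, 1, 4, 2]
        pred = ep.simulate_null(sizes, Domain(6), n_reps=200, seed=5,
                                keep_replicates=True)
        assert np.all(pred.replicates.sum(axis=1) == sum(sizes))

    def test_mean_converges_to_analytic(self):
        # randomized small instances: deviation within 3 Monte Carlo SEs
        rng = np.random.default_rng(12)
        n_reps = 10_000
        for _ in range(5):
            D = int(rng.integers(3, 13))
            sizes = rng.integers(1, D + 1, size=int(rng.integers(2, 21)))
            pred = ep.simulate_null(sizes, Domain(D), n_reps=n_reps,
                                    seed=int(rng.integers(2**31)),
                                    keep_replicates=True)
            exact = ep.analytic_expected_richness(sizes, Domain(D))
            se = pred.replicates.std(axis=0, ddof=1) / np.sqrt(n_reps)
            assert np.all(np.abs(pred.mean_richness - exact) <= 3 * np.maximum(se, 1e-12))

    def test_fixed_seed_bit_identical(self):
        a = ep.simulate_null([2, 3], Domain(5), n_reps=500, seed=9, keep_replicates=True)
        b = ep.simulate_null([2, 3], Domain(5), n_reps=500, seed=9, keep_replicates=True)
        assert np.array_equal(a.replicates, b.replicates)
        assert np.array_equal(a.mean_richness, b.mean_richness)

    def test_band_contains_mean(self):
        pred = ep.simulate_null([2, 2, 4], Domain(7), n_reps=2000, seed=1)
        assert np.all(pred.ci_lo <= pred.mean_richness + 1e-12)
        assert np.all(pred.mean_richness <= pred.ci_hi + 1e-12)

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            ep.simulate_null([1], Domain(3), n_reps=0)


class TestObservedOnPredicted:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r2, p = ep.regress_observed_on_predicted(x, x)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        obs = np.array([2.0, 4.0, 5.0, 9.0])
        prd = np.array([1.0, 2.0, 3.0, 4.0])
        r2, p = ep.regress_observed_on_predicted(obs, prd)
        # closed-form oracle via the normal equations
        b = np.cov(obs, prd, ddof=1)[0, 1] / np.var(prd, ddof=1)
        resid = obs - (obs.mean() + b * (prd - prd.mean()))
        r2_hand = 1 - resid @ resid / ((obs - obs.mean()) @ (obs - obs.mean()))
        assert r2 == pytest.approx(r2_hand)

    def test_null_distribution_of_p(self):
        # independent observed/predicted: R^2 near 0, p roughly uniform
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            obs = rng.standard_normal(50)
            prd = rng.standard_normal(50)
            r2, p = ep.regress_observed_on_predicted(obs, prd)
            ps.append(p)
        ps = np.array(ps)
        assert np.mean(ps < 0.05) < 0.12  # ~5% expected
        assert abs(ps.mean() - 0.5) < 0.1

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            ep.regress_observed_on_predicted([1, 2, 3], [4, 4, 4])


def test_coverage_counts_symmetry():
    for D in range(1, 12):
        for r in range(1, D + 1):
            c = _coverage_counts(D, r)
            assert np.array_equal(c, c[::-1])
            assert c.sum() == r * (D - r + 1)


def test_study_scale_null_is_hump_shaped(study_like):
    occ, *_ = study_like
    pred = ep.mde_predict(occ, n_reps=3000, seed=0)
    e = pred.mean_richness
    mid, edge = e[len(e) // 2], (e[0] + e[-1]) / 2
    assert mid > edge  # ranges overlap most near the domain centre
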