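"""Closed-form model: tip counts, module counts, leaf censuses, trunk profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trunkmodel import (
    GrowthParams,
    TreeMetadata,
    TrunkParams,
    carrying_capacity,
    dead_leaf_count,
    expected_tips,
    height_to_cycles,
    leaf_census,
    live_leaf_count,
    module_count,
    trunk_fraction,
    trunk_profile,
)

TOY = GrowthParams(alpha=1.0, d=1.0, mu=2.0, l_g=1)


def growth_params_strategy(max_lg: int = 6) -> st.SearchStrategy:
    return st.builds(
        GrowthParams,
        alpha=st.floats(0.5, 1e4),
        d=st.floats(0.5, 3.5),
        mu=st.floats(1.05, 4.0),
        l_g=st.integers(0, max_lg),
    )


class TestCarryingCapacityAndTips:
    def test_linear_capacity(self):
        assert carrying_capacity(GrowthParams(1.0, 1.0, 2.0, 0), 3) == 4.0

    def test_balsam_poplar_exponent(self):
        # alpha=2, d=1.4, n=9: direct arbitrary-precision evaluation of 2*10**1.4
        gp = GrowthParams(alpha=2.0, d=1.4, mu=2.0, l_g=0)
        assert carrying_capacity(gp, 9) == pytest.approx(2.0 * 10.0 ** 1.4, rel=1e-12)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            carrying_capacity(TOY, -1)
        with pytest.raises(ValueError):
            expected_tips(TOY, -1)

    def test_tips_toy_sequence(self):
        # mu=2, alpha=1, d=1: 2**n overtakes n+1 at n=2
        assert [expected_tips(TOY, n) for n in range(4)] == pytest.approx([1, 2, 3, 4])

    def test_tips_unconstrained_regime(self):
        gp = GrowthParams(alpha=1e6, d=1.0, mu=2.0, l_g=0)
        assert expected_tips(gp, 10) == pytest.approx(1024.0)

    def test_tips_both_branches_evaluated(self):
        gp = GrowthParams(alpha=3.0, d=1.4, mu=1.8, l_g=0)
        expected = min(1.8 ** 12, 3.0 * 13.0 ** 1.4)
        assert expected_tips(gp, 12) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(gp=growth_params_strategy())
    def test_tips_non_decreasing(self, gp):
        b = [expected_tips(gp, n) for n in range(0, 60)]
        assert all(b2 >= b1 - 1e-12 * abs(b1) for b1, b2 in zip(b, b[1:]))


class TestModuleCount:
    def test_toy_values(self):
        assert module_count(TOY, 1, 3) == pytest.approx(4.0 / 3.0)
        assert module_count(TOY, 2, 3) == pytest.approx(2.0)
        # l = n counts the tips themselves: g(n, n) = b(n) / b(0)
        assert module_count(TOY, 3, 3) == pytest.approx(4.0)

    def test_out_of_domain_is_zero(self):
        assert module_count(TOY, 0, 3) == 0.0
        assert module_count(TOY, 4, 3) == 0.0
        assert module_count(TOY, -2, 3) == 0.0

    def test_geometric_regime(self):
        gp = GrowthParams(alpha=1e9, d=1.0, mu=2.0, l_g=0)
        for l, n in [(1, 5), (4, 9), (7, 7)]:
            assert module_count(gp, l, n) == pytest.approx(2.0 ** l, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(gp=growth_params_strategy(), n=st.integers(2, 40), l=st.integers(1, 40))
    def test_at_least_one_and_non_increasing_in_age(self, gp, n, l):
        # g(l, m) >= 1 on its domain and never grows as the tree ages
        l = min(l, n)
        values = [module_count(gp, l, m) for m in range(l, n + 1)]
        assert all(v >= 1.0 - 1e-12 for v in values)
        assert all(v2 <= v1 * (1 + 1e-12) for v1, v2 in zip(values, values[1:]))


class TestLeafCensus:
    def test_live_toy_whole_tree(self):
        # g(2,3) + g(3,3) = 2 + 4 (leaves older than l_g=1 are gone)
        assert live_leaf_count(TOY, 0, 3) == pytest.approx(6.0)

    def test_live_immortal_leaves_count_every_module(self):
        gp = GrowthParams(alpha=1.0, d=1.0, mu=2.0, l_g=10)
        total = sum(module_count(gp, l, 3) for l in range(1, 4))
        assert live_leaf_count(gp, 0, 3) == pytest.approx(total)

    def test_live_at_top_equals_tips(self):
        for gp in (TOY, GrowthParams(2.0, 1.6, 1.8, 5)):
            for n in (3, 8):
                assert live_leaf_count(gp, n, n) == pytest.approx(expected_tips(gp, n))

    def test_above_top_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert live_leaf_count(TOY, 5, 3) == 0.0
        with pytest.warns(UserWarning):
            assert dead_leaf_count(TOY, 5, 3) == 0.0

    def test_dead_toy_value_confirmed_by_simulator(self):
        # Frozen from the deterministic agent oracle's dead-pipe census:
        # thinning losses 5/3 plus the aged-out distance-1 cohort 4/3.
        assert dead_leaf_count(TOY, 1, 3) == pytest.approx(3.0)
        assert dead_leaf_count(TOY, 0, 3) == pytest.approx(3.0)

    def test_dead_no_losses_in_unconstrained_immortal_limit(self):
        gp = GrowthParams(alpha=1e9, d=1.0, mu=2.0, l_g=50)
        for h in range(0, 8):
            assert dead_leaf_count(gp, h, 8) == pytest.approx(0.0, abs=1e-9)

    def test_dead_empty_above_top(self):
        assert dead_leaf_count(TOY, 3, 3) == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(gp=growth_params_strategy(), n=st.integers(2, 25))
    def test_conservation_and_monotonicity(self, gp, n):
        # F_S + F_H equals the leaves ever formed at distance >= h, and both
        # censuses shrink as the cut moves up the tree.
        f_s, f_h = leaf_census(gp, n)
        ever = np.array(
            [sum(module_count(gp, l, l) for l in range(max(h, 1), n + 1)) for h in range(n + 1)]
        )
        np.testing.assert_allclose(f_s + f_h, ever, rtol=1e-9)
        assert np.all(np.diff(f_s) <= 1e-9 * np.maximum(f_s[:-1], 1.0))
        assert np.all(np.diff(f_h) <= 1e-9 * np.maximum(f_h[:-1], 1.0))
        assert np.all(f_h >= -1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(gp=growth_params_strategy(), n=st.integers(2, 25))
    def test_vectorised_census_matches_scalar_sums(self, gp, n):
        f_s, f_h = leaf_census(gp, n)
        # abs floor absorbs cancellation in the scalar double sum when large
        # nearly-equal module counts are differenced in the thinning terms
        for h in range(0, n + 1, max(1, n // 5)):
            assert f_s[h] == pytest.approx(live_leaf_count(gp, h, n), rel=1e-9, abs=1e-6)
            assert f_h[h] == pytest.approx(dead_leaf_count(gp, h, n), rel=1e-9, abs=1e-6)


class TestTrunkFraction:
    def test_whole_stem_is_trunk_when_kappa_one(self):
        tp = TrunkParams(kappa=1.0, c_S=1.0, c_H=1.0)
        assert trunk_fraction(tp, 37.5) == 1.0

    def test_no_ramifications_below(self):
        tp = TrunkParams(kappa=0.3, c_S=1.0, c_H=1.0)
        assert trunk_fraction(tp, 1.0) == 1.0

    def test_three_ramifications(self):
        tp = TrunkParams(kappa=0.5, c_S=1.0, c_H=1.0)
        assert trunk_fraction(tp, 8.0) == pytest.approx(0.125)

    def test_below_one_module_count_rejected(self):
        tp = TrunkParams(kappa=0.5, c_S=1.0, c_H=1.0)
        with pytest.raises(ValueError):
            trunk_fraction(tp, 0.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(kappa=st.floats(1e-6, 1.0), g=st.floats(1.0, 1e8))
    def test_fraction_in_unit_interval(self, kappa, g):
        tp = TrunkParams(kappa=kappa, c_S=1.0, c_H=1.0)
        assert 0.0 < trunk_fraction(tp, g) <= 1.0


class TestHeightToCycles:
    def test_endpoints_and_rounding(self):
        meta = TreeMetadata(age_years=20.0, height=20.0, cycles_per_year=2)
        assert meta.n_cycles == 40
        assert height_to_cycles(0.0, meta) == 0
        assert height_to_cycles(20.0, meta) == 40
        assert height_to_cycles(1.3, meta) == 3  # round(2.6) half up

    def test_outside_tree_rejected(self):
        meta = TreeMetadata(age_years=20.0, height=20.0, cycles_per_year=2)
        for z in (-0.1, 20.5):
            with pytest.raises(ValueError):
                height_to_cycles(z, meta)


class TestTrunkProfile:
    def _toy_meta(self):
        # n = 3 growth cycles over a 3-unit-tall tree: one module per unit
        return TreeMetadata(age_years=1.5, height=3.0, cycles_per_year=2, breast_height=0.9)

    def test_composition_of_prior_oracles(self):
        meta = self._toy_meta()
        tp = TrunkParams(kappa=0.5, c_S=1.0, c_H=1.0)
        prof = trunk_profile(TOY, tp, meta, [1.0, 2.0])
        # h=1: 0.5**log2(4/3) * (F_S, F_H) = 0.75 * (6, 3)
        # h=2: 0.5**log2(2)   * (F_S, F_H) = 0.5 * (6, 1)
        np.testing.assert_allclose(prof.sapwood_areas, [4.5, 3.0], rtol=1e-12)
        np.testing.assert_allclose(prof.heartwood_areas, [2.25, 0.5], rtol=1e-12)

    def test_kappa_one_collapses_to_stem_profile(self):
        meta = self._toy_meta()
        tp = TrunkParams(kappa=1.0, c_S=2.0, c_H=3.0)
        prof = trunk_profile(TOY, tp, meta, [1.0, 2.0])
        f_s, f_h = leaf_census(TOY, 3)
        np.testing.assert_allclose(prof.sapwood_areas, 2.0 * f_s[[1, 2]], rtol=1e-12)
        np.testing.assert_allclose(prof.heartwood_areas, 3.0 * f_h[[1, 2]], rtol=1e-12)

    def test_zero_heartwood_pipe_area(self):
        meta = self._toy_meta()
        tp = TrunkParams(kappa=0.7, c_S=1.0, c_H=0.0)
        prof = trunk_profile(TOY, tp, meta, [1.0, 2.0])
        assert np.all(prof.heartwood_areas == 0.0)

    def test_below_breast_height_rejected(self):
        meta = self._toy_meta()
        tp = TrunkParams(kappa=0.5, c_S=1.0, c_H=1.0)
        with pytest.raises(ValueError, match="breast height"):
            trunk_profile(TOY, tp, meta, [0.5, 1.0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(gp=growth_params_strategy(), kappa=st.floats(0.2, 1.0))
    def test_trunk_never_exceeds_stem_and_area_decreases(self, gp, kappa):
        meta = TreeMetadata(age_years=10.0, height=12.0, cycles_per_year=2)
        tp = TrunkParams(kappa=kappa, c_S=0.7, c_H=0.4)
        zs = np.linspace(meta.breast_height, meta.height * 0.95, 9)
        prof = trunk_profile(gp, tp, meta, zs)
        f_s, f_h = leaf_census(gp, meta.n_cycles)
        h_idx = [height_to_cycles(z, meta) for z in zs]
        stem_s = 0.7 * f_s[h_idx]
        stem_h = 0.4 * f_h[h_idx]
        assert np.all(prof.sapwood_areas <= stem_s * (1 + 1e-12))
        assert np.all(prof.heartwood_areas <= stem_h * (1 + 1e-12))
        total = stem_s + stem_h
        assert np.all(np.diff(total) <= 1e-9 * np.maximum(total[:-1], 1e-300))


class TestDomainTypes:
    def test_growth_params_validation(self):
        with pytest.raises(ValueError):
            GrowthParams(alpha=0.0, d=1.0, mu=2.0, l_g=0)
        with pytest.raises(ValueError):
            GrowthParams(alpha=1.0, d=1.0, mu=1.0, l_g=0)
        with pytest.raises(ValueError):
            GrowthParams(alpha=1.0, d=1.0, mu=2.0, l_g=-1)

    def test_trunk_params_validation(self):
        with pytest.raises(ValueError):
            TrunkParams(kappa=0.0, c_S=1.0, c_H=1.0)
        with pytest.raises(ValueError):
            TrunkParams(kappa=1.2, c_S=1.0, c_H=1.0)

    def test_metadata_validation(self):
        with pytest.raises(ValueError):
            TreeMetadata(age_years=0.5, height=20.0, cycles_per_year=1)  # n < 2
        with pytest.raises(ValueError):
            TreeMetadata(age_years=20.0, height=1.0, cycles_per_year=2)  # breast >= height
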