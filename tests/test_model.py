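"""Right-hand-side correctness and structural invariants of both model variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phageweapons import (
    CommunityParams,
    InvalidStateError,
    LifeHistoryTraits,
    ModelState,
    NutrientParams,
    ParameterError,
    carrying_capacity,
    glv_phage_rhs,
    nutrient_rhs,
)
from phageweapons import _kernels


class TestGLVRhs:
    def test_extinction_fixed_point(self, fixed_traits, community):
        d = glv_phage_rhs(ModelState(0, 0, 0, 0, 0, 0), fixed_traits, community)
        assert d.to_array().tolist() == [0.0] * 6

    def test_carrying_capacity_fixed_point(self, fixed_traits, community):
        # Single strain at K = -r/mu with no induction sits still.
        traits = LifeHistoryTraits(**{**fixed_traits.as_dict(), "kappa": 0.0})
        K = 0.9 / 4e-10
        d = glv_phage_rhs(ModelState(K, 0, 0, 0, 0, 0), traits, community)
        assert d.F == pytest.approx(0.0, abs=1e-6 * K)
        assert d.to_array()[1:].tolist() == [0.0] * 5

    def test_hand_evaluated_derivatives(self, fixed_traits, community):
        # Term-by-term hand evaluation at (F, B) = (1e5, 9e5), everything else 0:
        # shared growth term r + mu*S = 0.9 - 4e-10 * 1e6 = 0.8996
        # dF = 1e5 * (0.8996 - 1e-4)   = 89950
        # dB = 9e5 * 0.8996            = 809640
        # dFt = kappa * F              = 10
        d = glv_phage_rhs(ModelState(1e5, 9e5, 0, 0, 0, 0), fixed_traits, community)
        assert d.F == pytest.approx(89950.0, rel=1e-12)
        assert d.B == pytest.approx(809640.0, rel=1e-12)
        assert d.N == 0.0
        assert d.P == 0.0
        assert d.Btilde == 0.0
        assert d.Ftilde == pytest.approx(10.0, rel=1e-12)

    def test_phage_terms_hand_evaluated(self, fixed_traits, community):
        # With free phage and committed cells present, check every phage flux:
        # state (F, B, N, P, Bt, Ft) = (1e5, 2e5, 5e4, 1e6, 1e3, 2e3)
        s = ModelState(1e5, 2e5, 5e4, 1e6, 1e3, 2e3)
        d = glv_phage_rhs(s, fixed_traits, community)
        S = 1e5 + 2e5 + 5e4 + 1e3 + 2e3
        g = 0.9 - 4e-10 * S
        aP = 1e-8 * 1e6
        assert d.F == pytest.approx(1e5 * (g - 1e-4), rel=1e-12)
        assert d.B == pytest.approx(2e5 * (g - aP), rel=1e-12)
        assert d.N == pytest.approx(2e5 * aP * 0.5 + 5e4 * (g - 1e-4), rel=1e-12)
        assert d.P == pytest.approx(100 * 0.505 * 3e3 - aP * 2e5 - 0.05 * 1e6, rel=1e-12)
        assert d.Btilde == pytest.approx(1e-4 * 5e4 + 1e-8 * 0.5 * 2e5 * 1e6 - 0.505 * 1e3,
                                         rel=1e-12)
        assert d.Ftilde == pytest.approx(1e-4 * 1e5 - 0.505 * 2e3, rel=1e-12)

    def test_pi_one_stops_new_lysogens(self, fixed_traits, community):
        traits = LifeHistoryTraits(**{**fixed_traits.as_dict(), "pi": 1.0})
        d = glv_phage_rhs(ModelState(0, 1e5, 0, 1e6, 0, 0), traits, community)
        assert d.N == 0.0

    def test_novel_kappa_override(self, fixed_traits, community):
        fast = LifeHistoryTraits(**{**fixed_traits.as_dict(), "kappa": 0.5})
        s = ModelState(1e5, 0, 1e5, 0, 0, 0)
        d = glv_phage_rhs(s, fixed_traits, community, novel_traits=fast)
        base = glv_phage_rhs(s, fixed_traits, community)
        # Novel lysogens induce at their own (faster) rate; the focal strain is untouched.
        assert d.F == base.F
        assert d.Btilde - base.Btilde == pytest.approx((0.5 - 1e-4) * 1e5, rel=1e-9)

    def test_negative_state_rejected(self):
        with pytest.raises(InvalidStateError):
            ModelState(-1.0, 0, 0, 0, 0, 0)
        with pytest.raises(InvalidStateError):
            ModelState(float("nan"), 0, 0, 0, 0, 0)

    def test_kernel_matches_public_rhs(self, fixed_traits, community):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(0, 1e9, size=6)
            d_pub = glv_phage_rhs(ModelState.from_array(y), fixed_traits, community)
            d_ker = _kernels.glv_rhs(
                y, 0.0, community.r, community.scalar_mu,
                fixed_traits.kappa, fixed_traits.kappa, fixed_traits.lam,
                fixed_traits.alpha, fixed_traits.delta, fixed_traits.beta,
                fixed_traits.pi, 1.0,
            )
            np.testing.assert_allclose(d_pub.to_array(), d_ker, rtol=1e-13)

    def test_matrix_mu_uniform_matches_scalar(self, fixed_traits):
        scalar = CommunityParams(r=0.9, mu=-4e-10)
        matrix = CommunityParams(r=0.9, mu=np.full((5, 5), -4e-10))
        s = ModelState(1e5, 2e5, 5e4, 1e6, 1e3, 2e3)
        np.testing.assert_allclose(
            glv_phage_rhs(s, fixed_traits, scalar).to_array(),
            glv_phage_rhs(s, fixed_traits, matrix).to_array(),
            rtol=1e-13,
        )


class TestNutrientRhs:
    def test_no_growth_without_nutrient(self, fixed_traits, community, nutrient):
        s = ModelState(1e5, 0, 0, 0, 0, 0, R=0.0)
        d = nutrient_rhs(s, fixed_traits, community, nutrient)
        assert d.F == pytest.approx(-fixed_traits.kappa * 1e5, rel=1e-12)
        assert d.R == 0.0

    def test_saturating_limit(self, fixed_traits, community):
        # R >> k so g -> 1: per-capita growth approaches r.
        traits = LifeHistoryTraits(**{**fixed_traits.as_dict(), "kappa": 0.0})
        nut = NutrientParams(k=1e-6, yield_per_cell=5e-9, R0=1.0)
        d = nutrient_rhs(ModelState(1e5, 0, 0, 0, 0, 0, R=1.0), traits, community, nut)
        assert d.F == pytest.approx(0.9 * 1e5, rel=1e-5)

    def test_hand_evaluated_derivatives(self, fixed_traits, community):
        # (F, B, R) = (1e5, 9e5, 10), k = 1: g = 10/11, rg = 9/11.
        nut = NutrientParams(k=1.0, yield_per_cell=5e-9, R0=10.0)
        d = nutrient_rhs(ModelState(1e5, 9e5, 0, 0, 0, 0, R=10.0),
                         fixed_traits, community, nut)
        rg = 0.9 * 10 / 11
        assert d.F == pytest.approx(1e5 * (rg - 1e-4), rel=1e-12)
        assert d.B == pytest.approx(9e5 * rg, rel=1e-12)
        assert d.Ftilde == pytest.approx(10.0, rel=1e-12)
        assert d.R == pytest.approx(-5e-9 * rg * 1e6, rel=1e-12)

    def test_missing_nutrient_component_rejected(self, fixed_traits, community, nutrient):
        with pytest.raises(InvalidStateError):
            nutrient_rhs(ModelState(1e5, 0, 0, 0, 0, 0), fixed_traits, community, nutrient)


class TestCarryingCapacity:
    @pytest.mark.parametrize(
        "r,mu,expected",
        [(0.9, -4e-10, 2.25e9), (0.0, -1e-9, 0.0), (1.0, -1.0, 1.0)],
    )
    def test_values(self, r, mu, expected):
        assert carrying_capacity(CommunityParams(r=r, mu=mu)) == pytest.approx(expected)

    def test_zero_mu_has_no_capacity(self):
        with pytest.raises(ParameterError):
            carrying_capacity(CommunityParams(r=0.9, mu=0.0))


nonneg = st.floats(min_value=0.0, max_value=1e10, allow_nan=False)
traits_st = st.builds(
    LifeHistoryTraits,
    pi=st.floats(0.0, 1.0),
    kappa=st.floats(0.0, 0.9),
    lam=st.floats(0.0, 1.0),
    alpha=st.floats(0.0, 1e-6),
    delta=st.floats(0.0, 0.9),
    beta=st.floats(0.0, 1010.0),
)


class TestInvariants:
    @settings(derandomize=True, max_examples=80)
    @given(y=st.tuples(nonneg, nonneg, nonneg, nonneg, nonneg, nonneg), traits=traits_st)
    def test_finite_derivatives_and_boundary_inflow(self, y, traits):
        community = CommunityParams(r=0.9, mu=-4e-10)
        d = glv_phage_rhs(ModelState(*y), traits, community).to_array()
        assert np.all(np.isfinite(d))
        # On the boundary, compartments with no outflow cannot be pushed negative:
        # N, Bt accept only inflows when zero; P likewise when B is present.
        s = ModelState(*y)
        if s.N == 0:
            assert d[2] >= 0
        if s.Btilde == 0:
            assert d[4] >= 0
        if s.Ftilde == 0:
            assert d[5] >= 0
        if s.P == 0:
            assert d[3] >= 0

    def test_exchangeable_strains_without_phage(self, community):
        # With phage processes off, F and B follow identical laws: swapping
        # their initial abundances swaps the derivatives exactly.
        traits = LifeHistoryTraits(pi=0.5, kappa=0.0, lam=0.505, alpha=0.0,
                                   delta=0.0, beta=0.0)
        d1 = glv_phage_rhs(ModelState(1e5, 9e5, 0, 0, 0, 0), traits, community)
        d2 = glv_phage_rhs(ModelState(9e5, 1e5, 0, 0, 0, 0), traits, community)
        assert d1.F == d2.B and d1.B == d2.F
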