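"""PEI metrics and trajectory summaries against hand-computed values."""

import math

import numpy as np
import pytest

from phageweapons import (
    CompetitionSetup,
    LifeHistoryTraits,
    MetricError,
    ModelState,
    PairedOutcome,
    Trajectory,
    carrying_capacity,
    final_total_density,
    focal_frequency,
    integrate,
    pei_frequency,
    pei_log_fold_change,
    pei_relative_fitness,
    phage_output,
    run_competition_pair,
)


def make_traj(initial, final, lysogen=True, traits=None, community=None):
    """Hand-built two-point trajectory for metric unit tests."""
    from phageweapons import CommunityParams

    traits = traits or LifeHistoryTraits(pi=0.5, kappa=1e-4, lam=0.505,
                                         alpha=1e-8, delta=0.05, beta=100.0)
    community = community or CommunityParams()
    setup = CompetitionSetup(focal_fraction=0.5, total_N0=sum(initial[:3]) + initial[4] + initial[5],
                             focal_is_lysogen=lysogen)
    states = np.array([initial, final], dtype=float)
    return Trajectory(times=np.array([0.0, 24.0]), states=states, setup=setup,
                      focal_traits=traits, community=community)


class TestFocalFrequency:
    def test_hand_arithmetic(self):
        assert focal_frequency(ModelState(600, 200, 200, 0, 0, 0)) == pytest.approx(0.6)

    def test_fixation_and_symmetry(self):
        assert focal_frequency(ModelState(42, 0, 0, 0, 0, 0)) == 1.0
        assert focal_frequency(ModelState(5, 5, 0, 0, 0, 0)) == 0.5

    def test_induced_counting_convention(self):
        s = ModelState(100, 100, 0, 0, 50, 50)
        assert focal_frequency(s, include_induced=True) == pytest.approx(0.5)
        assert focal_frequency(s, include_induced=False) == pytest.approx(0.5)
        s2 = ModelState(100, 100, 0, 0, 0, 100)
        assert focal_frequency(s2, include_induced=True) == pytest.approx(2 / 3)
        assert focal_frequency(s2, include_induced=False) == pytest.approx(0.5)

    def test_empty_community_undefined(self):
        with pytest.raises(MetricError):
            focal_frequency(ModelState(0, 0, 0, 1e5, 0, 0))


class TestPeiFrequency:
    def test_hand_arithmetic(self):
        lys = make_traj([100, 900, 0, 0, 0, 0], [600, 200, 200, 0, 0, 0], lysogen=True)
        wt = make_traj([100, 900, 0, 0, 0, 0], [500, 500, 0, 0, 0, 0], lysogen=False)
        assert pei_frequency(PairedOutcome(lys, wt)) == pytest.approx(0.1)

    def test_identical_runs_are_neutral(self):
        a = make_traj([100, 900, 0, 0, 0, 0], [500, 500, 0, 0, 0, 0], lysogen=True)
        b = make_traj([100, 900, 0, 0, 0, 0], [500, 500, 0, 0, 0, 0], lysogen=False)
        assert pei_frequency(PairedOutcome(a, b)) == 0.0

    def test_high_induction_is_costly_when_rare(self, fixed_traits, community):
        traits = LifeHistoryTraits(**{**fixed_traits.as_dict(), "kappa": 0.9})
        pair = run_competition_pair(CompetitionSetup(focal_fraction=0.1), traits, community)
        assert pei_frequency(pair) < 0


class TestRelativeFitness:
    def test_equal_growth(self):
        lys = make_traj([10, 10, 0, 0, 0, 0], [1000, 1000, 0, 0, 0, 0], lysogen=True)
        wt = make_traj([10, 10, 0, 0, 0, 0], [1000, 1000, 0, 0, 0, 0], lysogen=False)
        fit = pei_relative_fitness(PairedOutcome(lys, wt))
        assert fit.v == pytest.approx(1.0)
        assert fit.v_wt == pytest.approx(1.0)

    def test_log_ratio_identity(self):
        e = math.e
        lys = make_traj([10, 10, 0, 0, 0, 0], [10 * e**2, 10 * e, 0, 0, 0, 0], lysogen=True)
        wt = make_traj([10, 10, 0, 0, 0, 0], [10 * e, 10 * e, 0, 0, 0, 0], lysogen=False)
        assert pei_relative_fitness(PairedOutcome(lys, wt)).v == pytest.approx(2.0)

    def test_background_lineage_includes_novel_lysogens(self):
        # N counts towards the background lineage's Malthusian growth.
        lys = make_traj([10, 10, 0, 0, 0, 0], [100, 50, 50, 0, 0, 0], lysogen=True)
        wt = make_traj([10, 10, 0, 0, 0, 0], [100, 100, 0, 0, 0, 0], lysogen=False)
        assert pei_relative_fitness(PairedOutcome(lys, wt)).v == pytest.approx(1.0)

    def test_sign_tracks_phage_benefit(self, fixed_traits, community):
        # A beneficial phage lifts the focal lineage's Malthusian growth
        # above the background's (v > 1); a high-induction phage drops it
        # below.  The phage-free reference stays at exactly v = 1.
        pair = run_competition_pair(CompetitionSetup(focal_fraction=0.3),
                                    fixed_traits, community)
        fit = pei_relative_fitness(pair)
        assert fit.v > 1.0
        assert fit.v_wt == pytest.approx(1.0, abs=1e-9)
        costly = LifeHistoryTraits(**{**fixed_traits.as_dict(), "kappa": 0.2})
        pair2 = run_competition_pair(CompetitionSetup(focal_fraction=0.01),
                                     costly, community)
        assert pei_relative_fitness(pair2).v < 1.0


class TestLogFoldChange:
    def test_identical_runs(self):
        a = make_traj([100, 900, 0, 0, 0, 0], [500, 500, 0, 0, 0, 0], lysogen=True)
        b = make_traj([100, 900, 0, 0, 0, 0], [500, 500, 0, 0, 0, 0], lysogen=False)
        assert pei_log_fold_change(PairedOutcome(a, b)) == 0.0

    def test_doubling_definition(self):
        lys = make_traj([100, 900, 0, 0, 0, 0], [200, 900, 0, 0, 0, 0], lysogen=True)
        wt = make_traj([100, 900, 0, 0, 0, 0], [100, 900, 0, 0, 0, 0], lysogen=False)
        pair = PairedOutcome(lys, wt)
        assert pei_log_fold_change(pair) == pytest.approx(math.log(2))
        assert pei_log_fold_change(pair, contrast=False) == pytest.approx(math.log(2))

    def test_maximized_when_rare(self, fixed_traits, community):
        vals = []
        for f0 in (0.01, 0.5, 0.99):
            pair = run_competition_pair(CompetitionSetup(focal_fraction=f0),
                                        fixed_traits, community)
            vals.append(pei_log_fold_change(pair))
        assert vals[0] == max(vals)


class TestPhageOutput:
    def test_inert_lysogen_produces_nothing(self, community):
        traits = LifeHistoryTraits(pi=0.5, kappa=0.0, lam=0.505, alpha=1e-8,
                                   delta=0.05, beta=100.0)
        traj = integrate(CompetitionSetup(focal_fraction=0.5), traits, community)
        out = phage_output(traj)
        assert out.final_free == 0.0
        assert out.cumulative_produced == 0.0

    def test_single_burst_closed_form(self, community):
        # One committed cell lysing completely with no absorption or decay
        # must release exactly beta virions.
        traits = LifeHistoryTraits(pi=0.5, kappa=0.0, lam=0.505, alpha=0.0,
                                   delta=0.0, beta=100.0)
        traj = integrate(
            CompetitionSetup(focal_fraction=0.5, horizon=48.0),
            traits, community, y0=np.array([0.0, 0.0, 0.0, 0.0, 1.0, 0.0]),
        )
        out = phage_output(traj)
        assert out.final_free == pytest.approx(100.0, rel=1e-4)
        # Cumulative production uses trapezoidal quadrature on the 0.2-h
        # output grid, so it carries O(h^2) quadrature error.
        assert out.cumulative_produced == pytest.approx(100.0, rel=2e-3)

    def test_cumulative_bounds_final(self, pair_fixed_01):
        out = phage_output(pair_fixed_01.lysogen_run)
        assert out.cumulative_produced >= out.final_free > 0


class TestFinalDensity:
    def test_single_strain_reaches_capacity(self, fixed_traits, community):
        traits = LifeHistoryTraits(**{**fixed_traits.as_dict(), "kappa": 0.0})
        traj = integrate(CompetitionSetup(focal_fraction=1.0), traits, community)
        K = carrying_capacity(community)
        assert final_total_density(traj) == pytest.approx(K, rel=1e-4)

    def test_nutrient_density_rank(self, fixed_traits, community, nutrient):
        lo = integrate(CompetitionSetup(focal_fraction=0.01, model_variant="nutrient"),
                       fixed_traits, community, nutrient)
        hi = integrate(CompetitionSetup(focal_fraction=0.99, model_variant="nutrient"),
                       fixed_traits, community, nutrient)
        assert final_total_density(lo) < final_total_density(hi)

    def test_glv_density_flat_across_ratios(self, fixed_traits, community):
        lo = integrate(CompetitionSetup(focal_fraction=0.01), fixed_traits, community)
        hi = integrate(CompetitionSetup(focal_fraction=0.99), fixed_traits, community)
        a, b = final_total_density(lo), final_total_density(hi)
        assert abs(a - b) / b < 0.01
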