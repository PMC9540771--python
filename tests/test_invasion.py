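"""Mutant invasion fitness, selection gradient, singular strategies."""

import numpy as np
import pytest

from phenovir.core import v2_end_of_season
from phenovir.dynamics import resident_equilibrium
from phenovir.invasion import (
    BoundaryDiagnosis,
    InvasionProblem,
    MutantTraits,
    SingularStrategy,
    find_singular_strategy,
    mutant_end_of_season,
    pip_grid,
    selection_gradient,
)


@pytest.fixture(scope="module")
def equilibrium(baseline):
    return resident_equilibrium(baseline)


@pytest.fixture(scope="module")
def optimum_T32(baseline):
    return find_singular_strategy(baseline.replace(T=3.2))


@pytest.fixture(scope="module")
def optimum_T40(baseline):
    return find_singular_strategy(baseline.replace(T=4.0))


class TestMutantFitness:
    def test_reduces_to_resident_in_empty_environment(self, baseline):
        mutant = MutantTraits.from_resident(baseline)
        got = mutant_end_of_season(
            baseline, v_star=0.0, mutant=mutant, v1m0=baseline.v_init
        )
        expected = v2_end_of_season(baseline.host, baseline.season, baseline.traits)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_trivial_zeros(self, baseline, equilibrium):
        sterile = MutantTraits.from_resident(baseline, beta=0.0)
        assert mutant_end_of_season(baseline, equilibrium.v_star, sterile) == 0.0
        late = MutantTraits.from_resident(baseline, tau=baseline.T + 0.5)
        with pytest.warns(RuntimeWarning):
            assert mutant_end_of_season(baseline, equilibrium.v_star, late) == 0.0

    def test_resident_is_neutral_at_its_own_equilibrium(self, baseline, equilibrium):
        # vanishing-density limit: per-capita seasonal growth of a mutant
        # identical to the resident equals one at the resident equilibrium
        problem = InvasionProblem(baseline, equilibrium.v_star, v1m0=1e-6)
        growth = problem.per_capita_growth(baseline.tau)
        assert growth == pytest.approx(1.0, abs=1e-6)


class TestSelectionGradient:
    def test_positive_below_optimum(self, baseline):
        g = selection_gradient(baseline.replace(T=4.0), tau_r=2.2)
        assert g.value > 0 and not g.one_sided

    def test_sign_change_across_optimum(self, baseline, optimum_T32):
        p = baseline.replace(T=3.2)
        tau_star = optimum_T32.tau_star
        assert selection_gradient(p, tau_r=tau_star - 0.2).value > 0
        assert selection_gradient(p, tau_r=tau_star + 0.2).value < 0

    def test_near_zero_at_optimum(self, baseline, optimum_T32):
        p = baseline.replace(T=3.2)
        g = selection_gradient(p, tau_r=optimum_T32.tau_star)
        scale = abs(selection_gradient(p, tau_r=optimum_T32.tau_star - 0.3).value)
        assert abs(g.value) < 1e-3 * scale

    def test_one_sided_stencil_at_regime_boundary(self, baseline):
        boundary = baseline.T - baseline.t_l
        g = selection_gradient(baseline, tau_r=boundary + 1e-5)
        assert g.one_sided

    def test_nonpersistent_resident_rejected(self, baseline):
        with pytest.raises(ValueError):
            selection_gradient(baseline.replace(beta=0.001), tau_r=1.5)


class TestSingularStrategy:
    def test_optimum_is_interior_and_stable(self, optimum_T32):
        ss = optimum_T32
        assert isinstance(ss, SingularStrategy)
        assert 0.0 < ss.tau_star < 3.2
        assert ss.is_ess and ss.second_derivative < 0
        assert ss.is_convergence_stable
        assert ss.v_star > 1.0

    def test_longer_seasons_favor_longer_delays(self, optimum_T32, optimum_T40):
        assert optimum_T40.tau_star > optimum_T32.tau_star

    def test_sterile_parasite_has_no_singular_point(self, baseline):
        res = find_singular_strategy(baseline.replace(beta=0.0))
        assert isinstance(res, BoundaryDiagnosis)
        assert "persistent" in res.reason

    def test_invalid_bracket_rejected(self, baseline):
        with pytest.raises(ValueError):
            find_singular_strategy(baseline, bracket=(2.0, 1.0))


class TestPairwiseInvasibility:
    def test_diagonal_neutral_and_optimum_uninvadable(self, baseline, optimum_T32):
        p = baseline.replace(T=3.2)
        tau_star = optimum_T32.tau_star
        taus = np.array([tau_star - 0.4, tau_star - 0.15, tau_star, tau_star + 0.15])
        mat = pip_grid(p, taus, taus)
        # diagonal: mutant identical to resident is neutral (self-shading only)
        assert np.all(np.abs(np.diag(mat)) < 1e-6)
        # column at the optimum: no mutant grid point invades
        col = mat[2, :]
        assert np.all(col < 1e-6)
        # convergence stability: mutants between resident and optimum invade
        assert mat[0, 1] > 0  # resident below optimum, mutant closer to it
        assert mat[3, 2] > 0  # resident above optimum, mutant closer to it

    def test_grid_outside_season_rejected(self, baseline):
        with pytest.raises(ValueError):
            pip_grid(baseline, [0.5, 3.5], [1.0])
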