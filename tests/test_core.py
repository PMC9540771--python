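"""Within-season solution: closed forms, oracle agreement, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenovir.core import (
    HostParams,
    ModelParams,
    ParasiteTraits,
    SeasonConfig,
    emergence_rate,
    numeric_season_oracle,
    s_of_t,
    v1_of_t,
    v2_end_of_season,
)


def _v2_pair(p: ModelParams, grid_size=100_000):
    analytic = v2_end_of_season(p.host, p.season, p.traits)
    oracle = numeric_season_oracle(p.host, p.season, p.traits, grid_size=grid_size)
    return analytic, oracle.v2_end


class TestEmergenceRate:
    @pytest.mark.parametrize(
        "t, t_l, expected",
        [(0.5, 1.0, 1.0), (1.5, 1.0, 0.0), (0.0, 2.0, 0.5), (2.0, 2.0, 0.5)],
    )
    def test_uniform_density(self, t, t_l, expected):
        assert emergence_rate(t, t_l) == expected

    def test_integrates_to_one_over_any_season(self):
        for t_l in (0.3, 1.0, 2.5):
            grid = np.linspace(0, 4.0, 400_001)
            total = np.trapezoid(emergence_rate(grid, t_l), grid)
            assert total == pytest.approx(1.0, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            emergence_rate(-0.1, 1.0)
        with pytest.raises(ValueError):
            emergence_rate(0.5, 0.0)


class TestFreeParasiteDecay:
    @pytest.mark.parametrize(
        "t, v_init, delta, expected",
        [(0.0, 7.3, 2.0, 7.3), (1.0, 1.0, 0.0, 1.0), (0.5, 1.0, 2.0, np.exp(-1.0))],
    )
    def test_closed_form(self, t, v_init, delta, expected):
        assert v1_of_t(t, v_init, delta) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            v1_of_t(-1.0, 1.0, 2.0)


class TestSusceptibleDensity:
    def test_starts_at_zero(self, baseline):
        assert s_of_t(0.0, baseline.host, baseline.season, baseline.traits) == 0.0

    def test_uninfected_closed_form(self):
        # without infection, the linear ODE has an elementary solution
        host = HostParams(s_hat=1e8, t_l=1.0, mu=0.5)
        season = SeasonConfig(T=3.0, v_init=0.0)
        traits = ParasiteTraits(tau=1.5, alpha=1e-8, beta=200.0, delta=2.0)
        t = 2.0
        expected = 1e8 * np.exp(-0.5 * t) * (np.exp(0.5 * 1.0) - 1.0) / (0.5 * 1.0)
        assert s_of_t(t, host, season, traits) == pytest.approx(expected, rel=1e-10)

    def test_all_hosts_emerge_when_nothing_kills_them(self):
        host = HostParams(s_hat=1e8, t_l=1.0, mu=0.0)
        season = SeasonConfig(T=3.0, v_init=0.0)
        traits = ParasiteTraits(tau=1.5, alpha=1e-8, beta=200.0, delta=2.0)
        for t in (1.0, 1.7, 3.0):
            assert s_of_t(t, host, season, traits) == pytest.approx(1e8, rel=1e-10)

    def test_continuous_at_emergence_end(self, baseline):
        h, se, tr = baseline.host, baseline.season, baseline.traits
        lo = s_of_t(baseline.t_l - 1e-9, h, se, tr)
        hi = s_of_t(baseline.t_l + 1e-9, h, se, tr)
        assert hi == pytest.approx(lo, rel=1e-6)

    def test_outside_season_rejected(self, baseline):
        with pytest.raises(ValueError):
            s_of_t(baseline.T + 0.1, baseline.host, baseline.season, baseline.traits)


class TestEndOfSeasonProgeny:
    def test_trivial_zeros(self, baseline):
        h, se = baseline.host, baseline.season
        no_progeny = ParasiteTraits(tau=1.5, alpha=1e-8, beta=0.0, delta=2.0)
        assert v2_end_of_season(h, se, no_progeny) == 0.0
        empty = SeasonConfig(T=3.0, v_init=0.0)
        assert v2_end_of_season(h, empty, baseline.traits) == 0.0

    def test_vanishing_transmission_limit(self, baseline):
        h, se = baseline.host, baseline.season
        vals = [
            v2_end_of_season(
                h, se, ParasiteTraits(tau=1.5, alpha=a, beta=200.0, delta=2.0)
            )
            for a in (1e-10, 1e-12, 1e-14)
        ]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-3

    def test_late_killer_releases_nothing(self, baseline):
        h, se = baseline.host, baseline.season
        late = ParasiteTraits(tau=3.5, alpha=1e-8, beta=200.0, delta=2.0)
        with pytest.warns(RuntimeWarning):
            assert v2_end_of_season(h, se, late) == 0.0

    @pytest.mark.parametrize("tau", [1.5, 2.5])  # both phenological regimes
    def test_matches_direct_integration(self, baseline, tau):
        p = baseline.replace(tau=tau)
        analytic, oracle = _v2_pair(p, grid_size=1_000_000)
        assert analytic == pytest.approx(oracle, rel=1e-6)

    def test_regime_continuity(self, baseline):
        # tau crossing T - t_l switches the piecewise branch of s
        boundary = baseline.T - baseline.t_l
        eps = 1e-4
        lo = v2_end_of_season(
            baseline.host, baseline.season, baseline.replace(tau=boundary - eps).traits
        )
        hi = v2_end_of_season(
            baseline.host, baseline.season, baseline.replace(tau=boundary + eps).traits
        )
        assert hi == pytest.approx(lo, rel=1e-3)

    def test_monotone_in_progeny_number_and_cohort_size(self, baseline):
        vals_beta = [
            v2_end_of_season(
                baseline.host, baseline.season, baseline.replace(beta=b).traits
            )
            for b in (50.0, 200.0, 800.0)
        ]
        assert vals_beta[0] < vals_beta[1] < vals_beta[2]
        vals_shat = [
            v2_end_of_season(
                baseline.replace(s_hat=s).host, baseline.season, baseline.traits
            )
            for s in (1e7, 1e8, 1e9)
        ]
        assert vals_shat[0] < vals_shat[1] < vals_shat[2]

    @pytest.mark.parametrize("c", [1e2, 1e4])
    def test_scaling_invariance_of_per_capita_output(self, c):
        # (s_hat, alpha, v_hat) -> (s_hat/c, c*alpha, v_hat/c) preserves
        # per-capita hazards, hence per-capita progeny output
        p = ModelParams(v_init=1e8)
        q = p.replace(s_hat=p.s_hat / c, alpha=p.alpha * c, v_init=p.v_init / c)
        out_p = v2_end_of_season(p.host, p.season, p.traits) / p.v_init
        out_q = v2_end_of_season(q.host, q.season, q.traits) / q.v_init
        assert out_q == pytest.approx(out_p, rel=1e-9)

    @settings(max_examples=12, deadline=None)
    @given(
        tau_frac=st.floats(0.15, 0.9),
        t_l=st.floats(0.3, 1.5),
        span=st.floats(0.8, 2.5),
        delta=st.floats(1.0, 4.0),
        mu=st.floats(0.1, 1.0),
        log_v=st.floats(0.0, 8.0),
    )
    def test_analytic_agrees_with_oracle_everywhere(
        self, tau_frac, t_l, span, delta, mu, log_v
    ):
        T = t_l + span
        p = ModelParams(
            t_l=t_l, T=T, tau=tau_frac * T, delta=delta, mu=mu, v_init=10.0**log_v
        )
        analytic, oracle = _v2_pair(p, grid_size=100_000)
        assert analytic == pytest.approx(oracle, rel=1e-5)


class TestNumericOracle:
    def test_grid_size_validated(self, baseline):
        with pytest.raises(ValueError):
            numeric_season_oracle(
                baseline.host, baseline.season, baseline.traits, grid_size=100
            )

    def test_uninfected_matches_closed_form_on_grid(self):
        host = HostParams(s_hat=1e8, t_l=1.0, mu=0.5)
        season = SeasonConfig(T=3.0, v_init=0.0)
        traits = ParasiteTraits(tau=1.5, alpha=1e-8, beta=200.0, delta=2.0)
        traj = numeric_season_oracle(host, season, traits, grid_size=10_000)
        t = traj.times
        with np.errstate(invalid="ignore"):
            expected = np.where(
                t <= 1.0,
                (1e8 / 0.5) * (1.0 - np.exp(-0.5 * t)),
                1e8 * np.exp(-0.5 * t) * (np.exp(0.5) - 1.0) / 0.5,
            )
        mask = t > 0.01  # skip relative comparison at tiny densities
        np.testing.assert_allclose(traj.s_vals[mask], expected[mask], rtol=1e-8)
        assert traj.v2_end == 0.0

    def test_trajectory_invariants(self, baseline):
        traj = numeric_season_oracle(
            baseline.host, baseline.season, baseline.traits, grid_size=5_000
        )
        assert np.all(traj.s_vals >= 0)
        assert np.all(traj.v1_vals >= 0)
        assert np.all(np.diff(traj.v1_vals) <= 0)
        assert np.all(traj.v2_vals[traj.times < baseline.tau] == 0.0)
        assert traj.v2_end == traj.v2_vals[-1]

    def test_csv_export(self, baseline, tmp_path):
        import pandas as pd

        traj = numeric_season_oracle(
            baseline.host, baseline.season, baseline.traits, grid_size=1_000
        )
        path = tmp_path / "season.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "s", "v1", "v2"]
        assert len(df) == len(traj.times)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"s_hat": 0.0},
            {"t_l": -1.0},
            {"mu": -0.1},
            {"alpha": 0.0},
            {"delta": 0.0},
            {"tau": 0.0},
            {"v_init": -1.0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_emergence_period_cannot_exceed_season(self):
        with pytest.raises(ValueError):
            ModelParams(t_l=3.5, T=3.0)

    def test_roundtrip_dict(self, baseline):
        assert ModelParams.from_dict(baseline.to_dict()) == baseline
        with pytest.raises(ValueError):
            ModelParams.from_dict({"bogus": 1.0})
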