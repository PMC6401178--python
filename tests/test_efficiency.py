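"""Species detection efficiency E(g, k, J, M) and allocation ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import ednaoccupancy as eo
from ednaoccupancy.efficiency import (
    closed_form_efficiency,
    efficiency_for_draw,
    efficiency_grid,
    replicate_tradeoff_report,
)
from ednaoccupancy.model import PosteriorSamples
from ednaoccupancy.simulate import ParameterSet


def make_params(psi=0.9, theta=0.3, K=3, sigmas=(0.0, 0.0, 0.0, 0.0), I=2, J=2):
    """ParameterSet whose group-level psi/theta are the given constants."""
    return ParameterSet(
        alpha_g=np.full(2, logit(psi)),
        alpha_f=np.zeros((2, J)),
        alpha_s=np.zeros(I),
        alpha_fs=np.zeros((I, J)),
        beta_g=np.full(2, logit(theta)),
        beta_t=np.zeros((2, K)),
        beta_s=np.zeros(I),
        beta_ts=np.zeros((I, K)),
        sigma_s=np.full(2, sigmas[0]),
        sigma_fs=np.full(2, sigmas[1]),
        tau_s=np.full(2, sigmas[2]),
        tau_ts=np.full(2, sigmas[3]),
    )


def degenerate_samples(psi=0.9, theta=0.3, K=3, n_draws=5):
    """Posterior with identical draws and zero community variances."""
    p = make_params(psi=psi, theta=theta, K=K)
    draws = {}
    for name in PosteriorSamples.PARAM_NAMES:
        arr = getattr(p, name)
        draws[name] = np.broadcast_to(arr, (2, n_draws) + arr.shape).copy()
    s = PosteriorSamples(
        draws=draws, group=np.array([1, 2]), species_ids=["a", "b"],
        temperatures_c=np.array([58.0, 59.0, 60.0]),
    )
    s.attach_derived()
    return s


class TestClosedForm:
    def test_single_filter_two_replicates(self):
        # 1 - (1 - 1*(1 - 0.5^2)) = 0.75
        assert closed_form_efficiency(1.0, 0.5, J=1, M=2) == pytest.approx(0.75)

    def test_no_occurrence_no_efficiency(self):
        assert closed_form_efficiency(0.0, 0.9, J=4, M=8) == 0.0

    def test_two_filters_three_replicates(self):
        expected = 1.0 - (1.0 - 0.9 * (1.0 - 0.7**3)) ** 2
        assert closed_form_efficiency(0.9, 0.3, J=2, M=3) == pytest.approx(expected)

    def test_empty_designs_are_zero(self):
        assert closed_form_efficiency(0.9, 0.3, J=0, M=5) == 0.0
        assert closed_form_efficiency(0.9, 0.3, J=5, M=0) == 0.0


class TestEfficiencyForDraw:
    def test_zero_variance_matches_closed_form_exactly(self):
        params = make_params(psi=0.9, theta=0.3)
        for g in (1, 2):
            for J, M in [(1, 1), (2, 3), (8, 16)]:
                val = efficiency_for_draw(params, g, 0, J, M, n_community=10, seed=0)
                assert val == pytest.approx(
                    closed_form_efficiency(0.9, 0.3, J, M), abs=1e-12
                )

    def test_empty_design_is_exact_zero(self):
        params = make_params(sigmas=(1, 1, 1, 1))
        assert efficiency_for_draw(params, 1, 0, 0, 5, seed=1) == 0.0
        assert efficiency_for_draw(params, 1, 0, 5, 0, seed=1) == 0.0

    def test_monte_carlo_tracks_closed_form_with_small_variance(self):
        params = make_params(psi=0.85, theta=0.35, sigmas=(0.05, 0.05, 0.05, 0.05))
        val = efficiency_for_draw(params, 2, 1, 4, 4, n_community=20000, seed=2)
        assert val == pytest.approx(closed_form_efficiency(0.85, 0.35, 4, 4), abs=0.02)

    def test_monotone_in_J_and_M_under_common_random_numbers(self):
        rng_params = make_params(psi=0.7, theta=0.25, sigmas=(1.0, 0.8, 1.0, 0.6))
        for g in (1, 2):
            by_m = [
                efficiency_for_draw(rng_params, g, 0, 4, M, n_community=500, seed=3)
                for M in range(0, 12)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(by_m, by_m[1:]))
            by_j = [
                efficiency_for_draw(rng_params, g, 0, J, 3, n_community=500, seed=3)
                for J in range(0, 9)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(by_j, by_j[1:]))

    def test_bad_arguments_rejected(self):
        params = make_params()
        with pytest.raises(ValueError):
            efficiency_for_draw(params, 3, 0, 1, 1)
        with pytest.raises(ValueError):
            efficiency_for_draw(params, 1, 0, -1, 1)


class TestJMEquivalence:
    def test_exact_identity_when_psi_is_one(self):
        """With full filtration occupancy, E depends on (J, M) only through
        J*M: 1 - ((1-theta)^M)^J."""
        for theta in (0.2, 0.5):
            for J, M in [(8, 2), (4, 4), (6, 2)]:
                a = closed_form_efficiency(1.0, theta, J, M)
                b = closed_form_efficiency(1.0, theta, J // 2, 2 * M)
                assert a == pytest.approx(b, abs=1e-12)

    def test_high_occupancy_monte_carlo_equivalence(self):
        """Near-saturated occurrence: halving filters while doubling PCR
        replicates leaves E virtually identical (within Monte-Carlo error)."""
        params = make_params(psi=0.995, theta=0.3, sigmas=(0.2, 0.2, 0.5, 0.3))
        for J, M in [(8, 2), (4, 4), (2, 8)]:
            a = efficiency_for_draw(params, 2, 0, J, M, n_community=20000, seed=4)
            b = efficiency_for_draw(params, 2, 0, J // 2, 2 * M, n_community=20000, seed=4)
            assert a == pytest.approx(b, abs=0.02)


class TestEfficiencyGrid:
    def test_zero_filters_gives_zero_grid(self):
        grid = efficiency_grid(
            degenerate_samples(), temperatures=(58.0,), J_values=(0,), M_values=(1, 2),
            n_community=10, seed=0,
        )
        assert (grid["median"] == 0).all()

    def test_degenerate_posterior_equals_closed_form_everywhere(self):
        grid = efficiency_grid(
            degenerate_samples(psi=0.9, theta=0.3),
            temperatures=(58.0, 60.0), J_values=(1, 2, 4), M_values=(1, 3, 5),
            n_community=10, seed=0,
        )
        for _, row in grid.iterrows():
            expected = closed_form_efficiency(0.9, 0.3, int(row["J"]), int(row["M"]))
            assert row["median"] == pytest.approx(expected, abs=1e-12)
            assert row["lo95"] == pytest.approx(expected, abs=1e-12)

    def test_grid_values_are_probabilities_and_deterministic(self):
        samples = degenerate_samples()
        # perturb draws so intervals are non-trivial
        rng = np.random.default_rng(0)
        samples.draws["beta_g"] = samples.draws["beta_g"] + rng.normal(
            0, 0.3, samples.draws["beta_g"].shape
        )
        samples.draws["tau_ts"] = np.abs(rng.normal(0.5, 0.1, samples.draws["tau_ts"].shape))
        g1 = efficiency_grid(samples, temperatures=(59.0,), J_values=(2, 4),
                             M_values=(1, 2, 4), n_community=50, seed=5)
        g2 = efficiency_grid(samples, temperatures=(59.0,), J_values=(2, 4),
                             M_values=(1, 2, 4), n_community=50, seed=5)
        pd.testing.assert_frame_equal(g1, g2)
        assert ((g1["median"] >= 0) & (g1["median"] <= 1)).all()
        assert (g1["lo95"] <= g1["hi95"]).all()

    def test_unknown_temperature_rejected(self):
        with pytest.raises(ValueError, match="not in the fitted levels"):
            efficiency_grid(degenerate_samples(), temperatures=(99.0,))


class TestTradeoffReport:
    def _jm_grid(self):
        rows = []
        for J in (1, 2, 4):
            for M in (1, 2, 4):
                E = 1 - 0.5 ** (J * M)  # depends on J*M only
                rows.append((1, 58.0, J, M, E, E, E))
        return pd.DataFrame(
            rows, columns=["group", "temperature_c", "J", "M", "median", "lo95", "hi95"]
        )

    def test_tie_break_prefers_fewer_filters(self):
        report = replicate_tradeoff_report(self._jm_grid(), total_budget=4)
        top = report.iloc[0]
        assert top["J"] * top["M"] == 4 and top["J"] == 1

    def test_single_feasible_allocation(self):
        grid = self._jm_grid()
        only = grid[(grid["J"] == 1) & (grid["M"] == 1)]
        report = replicate_tradeoff_report(only, total_budget=1)
        assert len(report) == 1

    def test_empty_feasible_set_raises(self):
        grid = self._jm_grid()
        with pytest.raises(ValueError, match="no allocation"):
            replicate_tradeoff_report(grid[grid["J"] == 4], total_budget=2)

    def test_top_allocations_share_maximal_budget_use(self):
        report = replicate_tradeoff_report(self._jm_grid(), total_budget=8)
        best = report.iloc[0]
        assert best["J"] * best["M"] == 8


def test_efficiency_from_fit_favours_more_replicates(small_fit):
    """On a fitted synthetic posterior, the efficiency surface increases
    with PCR replication and the tradeoff report uses the full budget."""
    samples = small_fit["model"].samples_
    temps = tuple(samples.temperatures_c[:1])
    grid = efficiency_grid(samples, temperatures=temps, J_values=(1, 2, 4),
                           M_values=(1, 2, 4, 8), n_community=200, seed=6,
                           max_draws=100)
    for (g, t, J), sub in grid.groupby(["group", "temperature_c", "J"]):
        med = sub.sort_values("M")["median"].to_numpy()
        assert (np.diff(med) >= -1e-9).all()
    report = replicate_tradeoff_report(grid, total_budget=8)
    top = report[report["rank"] == 1]
    assert (top["J"] * top["M"] == 8).all()


class TestClosedFormProperties:
    """Bounds and monotonicity of the closed-form efficiency (hypothesis)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        psi=st.floats(0.0, 1.0),
        theta=st.floats(0.0, 1.0),
        J=st.integers(0, 10),
        M=st.integers(0, 12),
    )
    def test_bounded_and_monotone(self, psi, theta, J, M):
        e = closed_form_efficiency(psi, theta, J, M)
        assert 0.0 <= e <= 1.0
        assert closed_form_efficiency(psi, theta, J + 1, M) >= e - 1e-12
        assert closed_form_efficiency(psi, theta, J, M + 1) >= e - 1e-12
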