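"""Likelihood correctness against brute-force z-marginalisation oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import binom

import ednaoccupancy as eo
from ednaoccupancy.datasets import DetectionDataset
from ednaoccupancy.model import (
    PriorSpec,
    cell_marginal_loglik,
    complete_data_logpost,
    full_conditional_z,
    parameter_log_prior,
    total_marginal_loglik,
)
from ednaoccupancy.simulate import ParameterSet, build_probabilities


def brute_force_cell(x_row, M_row, psi, theta_row) -> float:
    """Independent oracle: enumerate z in {0, 1} with scipy binomials."""
    terms = []
    for z in (0, 1):
        p_z = psi if z == 1 else 1.0 - psi
        like = np.prod(binom.pmf(x_row, M_row, np.asarray(theta_row) * z))
        terms.append(p_z * like)
    return math.log(sum(terms))


def _toy_dataset(I, J, K, seed):
    rng = np.random.default_rng(seed)
    M = rng.integers(1, 4, size=(I, J, K))
    group = np.r_[np.ones(max(1, I // 2), int), np.full(I - max(1, I // 2), 2, int)]
    params = ParameterSet(
        alpha_g=rng.normal(0, 1, 2),
        alpha_f=rng.normal(0, 1, (2, J)),
        alpha_s=rng.normal(0, 1, I),
        alpha_fs=rng.normal(0, 0.5, (I, J)),
        beta_g=rng.normal(0, 1, 2),
        beta_t=rng.normal(0, 1, (2, K)),
        beta_s=rng.normal(0, 1, I),
        beta_ts=rng.normal(0, 0.5, (I, K)),
        sigma_s=np.array([1.0, 1.0]),
        sigma_fs=np.array([0.5, 0.5]),
        tau_s=np.array([1.0, 1.0]),
        tau_ts=np.array([0.5, 0.5]),
    )
    psi, theta = build_probabilities(params, group)
    z = rng.binomial(1, psi)
    x = rng.binomial(M, theta[:, None, :] * z[:, :, None])
    ds = DetectionDataset(
        x=x, M=M, species_ids=[f"s{i}" for i in range(I)], group=group,
        temperatures_c=54.0 + np.arange(K),
    )
    return ds, params, psi, theta


class TestCellMarginal:
    def test_two_branch_sum_by_hand(self):
        # psi * Binom(0|2,0.5) + (1-psi) = 0.5*0.25 + 0.5
        val = cell_marginal_loglik(np.array([0]), np.array([2]), 0.5, np.array([0.5]))
        assert val == pytest.approx(math.log(0.625), abs=1e-12)

    def test_occupied_branch_only_when_detected(self):
        x, M, th = np.array([1, 0]), np.array([3, 3]), np.array([0.4, 0.2])
        val = cell_marginal_loglik(x, M, 1.0, th)
        expected = float(np.log(binom.pmf(x, M, th)).sum())
        assert val == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_oracle(self):
        x = np.array([2, 0, 1])
        M = np.array([5, 5, 4])
        th = np.array([0.3, 0.2, 0.4])
        assert cell_marginal_loglik(x, M, 0.7, th) == pytest.approx(
            brute_force_cell(x, M, 0.7, th), abs=1e-10
        )

    def test_m_zero_levels_contribute_unit_factor(self):
        val = cell_marginal_loglik(np.array([0, 0]), np.array([0, 0]), 0.5, np.array([0.5, 0.5]))
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError, match="0 <= x <= M"):
            cell_marginal_loglik(np.array([3]), np.array([2]), 0.5, np.array([0.5]))
        with pytest.raises(ValueError, match="non-finite"):
            cell_marginal_loglik(np.array([np.nan]), np.array([2]), 0.5, np.array([0.5]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cell_marginal_loglik(np.array([0]), np.array([2]), 1.5, np.array([0.5]))


class TestTotalMarginal:
    def test_all_M_zero_dataset_scores_zero(self):
        ds, params, _, _ = _toy_dataset(2, 2, 2, seed=0)
        empty = DetectionDataset(
            x=np.zeros_like(ds.x), M=np.zeros_like(ds.M),
            species_ids=ds.species_ids, group=ds.group,
            temperatures_c=ds.temperatures_c,
        )
        assert total_marginal_loglik(empty, params) == pytest.approx(0.0, abs=1e-9)

    def test_single_cell_additivity_base_case(self):
        ds, params, psi, theta = _toy_dataset(1, 1, 3, seed=1)
        expected = cell_marginal_loglik(ds.x[0, 0], ds.M[0, 0], psi[0, 0], theta[0])
        assert total_marginal_loglik(ds, params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("I,J,K,seed", [(3, 2, 2, 2), (2, 3, 1, 3), (1, 2, 3, 4)])
    def test_exhaustive_z_marginalisation(self, I, J, K, seed):
        """exp(total loglik) equals the sum over all 2^(I*J) latent
        configurations of the complete-data likelihood."""
        ds, params, psi, theta = _toy_dataset(I, J, K, seed)
        logliks = []
        for zf in itertools.product((0, 1), repeat=I * J):
            z = np.array(zf).reshape(I, J)
            p = theta[:, None, :] * z[:, :, None]
            with np.errstate(divide="ignore"):
                like = binom.logpmf(ds.x, ds.M, p).sum()
                prior_z = (z * np.log(psi) + (1 - z) * np.log1p(-psi)).sum()
            logliks.append(like + prior_z)
        oracle = logsumexp(logliks)
        assert total_marginal_loglik(ds, params) == pytest.approx(oracle, abs=1e-10)

    def test_shape_mismatch_raises(self):
        ds, params, _, _ = _toy_dataset(3, 2, 2, seed=5)
        ds2, _, _, _ = _toy_dataset(2, 2, 2, seed=5)
        with pytest.raises(ValueError, match="shapes"):
            total_marginal_loglik(ds2, params)

    def test_monotone_in_theta_for_all_detections(self):
        ds, params, _, _ = _toy_dataset(2, 2, 2, seed=6)
        full = DetectionDataset(
            x=ds.M.copy(), M=ds.M, species_ids=ds.species_ids, group=ds.group,
            temperatures_c=ds.temperatures_c,
        )
        lls = []
        for shift in (-1.0, 0.0, 1.0, 2.0):
            p = ParameterSet.from_dict(params.to_dict())
            p.beta_g = p.beta_g + shift
            lls.append(total_marginal_loglik(full, p))
        assert lls == sorted(lls)

    def test_species_relabelling_invariance(self):
        ds, params, _, _ = _toy_dataset(4, 2, 2, seed=7)
        perm = np.array([2, 0, 3, 1])
        ds2 = DetectionDataset(
            x=ds.x[perm], M=ds.M[perm],
            species_ids=[ds.species_ids[i] for i in perm], group=ds.group[perm],
            temperatures_c=ds.temperatures_c,
        )
        d = params.to_dict()
        for key in ("alpha_s", "alpha_fs", "beta_s", "beta_ts"):
            d[key] = np.asarray(d[key])[perm]
        params2 = ParameterSet.from_dict(d)
        assert total_marginal_loglik(ds, params) == pytest.approx(
            total_marginal_loglik(ds2, params2), rel=1e-12
        )


class TestCompleteDataLogpost:
    def test_bernoulli_terms_for_all_zero_state(self):
        ds, params, _, _ = _toy_dataset(2, 3, 1, seed=8)
        empty = DetectionDataset(
            x=np.zeros_like(ds.x), M=ds.M, species_ids=ds.species_ids,
            group=ds.group, temperatures_c=ds.temperatures_c,
        )
        z = np.zeros((2, 3), dtype=int)
        priors = PriorSpec()
        psi, theta = build_probabilities(params, ds.group)
        expected = (
            np.log1p(-psi).sum()
            + binom.logpmf(0, empty.M, 0.0).sum()  # = 0
            + parameter_log_prior(params, priors, ds.group)
        )
        assert complete_data_logpost(empty, params, z, priors) == pytest.approx(
            expected, rel=1e-9
        )

    def test_impossible_configuration_is_minus_infinity(self):
        ds, params, _, _ = _toy_dataset(2, 2, 2, seed=9)
        ds.x[0, 0, 0] = 1
        ds.M[0, 0, 0] = max(ds.M[0, 0, 0], 1)
        z = np.ones((2, 2), dtype=int)
        z[0, 0] = 0
        assert complete_data_logpost(ds, params, z, PriorSpec()) == -math.inf

    def test_marginalisation_identity(self):
        """Summing exp(complete-data log posterior) over all z equals
        exp(marginal loglik + parameter log prior)."""
        ds, params, _, _ = _toy_dataset(2, 2, 2, seed=10)
        priors = PriorSpec()
        lps = [
            complete_data_logpost(ds, params, np.array(zf).reshape(2, 2), priors)
            for zf in itertools.product((0, 1), repeat=4)
        ]
        lhs = logsumexp([lp for lp in lps if lp > -math.inf])
        rhs = total_marginal_loglik(ds, params) + parameter_log_prior(
            params, priors, ds.group
        )
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_invalid_z_shape_rejected(self):
        ds, params, _, _ = _toy_dataset(2, 2, 2, seed=11)
        with pytest.raises(ValueError, match="binary"):
            complete_data_logpost(ds, params, np.zeros((3, 2), int), PriorSpec())


class TestFullConditionalZ:
    def test_detection_forces_occurrence(self):
        assert full_conditional_z(np.array([0, 2]), np.array([3, 3]), 0.1, np.array([0.5, 0.5])) == 1.0

    def test_hand_bayes_computation(self):
        # psi=0.5, theta=0.5, M=1, x=0 -> 0.25 / (0.25 + 0.5) = 1/3
        val = full_conditional_z(np.array([0]), np.array([1]), 0.5, np.array([0.5]))
        assert val == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_uninformative_detection_returns_psi(self):
        val = full_conditional_z(np.array([0, 0]), np.array([4, 4]), 0.37, np.array([0.0, 0.0]))
        assert val == pytest.approx(0.37, abs=1e-6)


class TestCellMarginalProperties:
    """Randomised agreement with the enumeration oracle (hypothesis)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        psi=st.floats(0.01, 0.99),
        m_frac=st.lists(
            st.tuples(st.integers(0, 5), st.floats(0, 1), st.floats(0.02, 0.98)),
            min_size=1,
            max_size=4,
        ),
    )
    def test_matches_bruteforce_for_random_cells(self, psi, m_frac):
        M = np.array([m for m, _, _ in m_frac])
        x = np.array([int(round(f * m)) for m, f, _ in m_frac])
        theta = np.array([t for _, _, t in m_frac])
        ours = cell_marginal_loglik(x, M, psi, theta)
        assert ours == pytest.approx(brute_force_cell(x, M, psi, theta), abs=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        psi=st.floats(0.01, 0.99),
        theta=st.floats(0.0, 0.98),
        M=st.integers(1, 6),
    )
    def test_z_conditional_is_probability_consistent_with_bayes(self, psi, theta, M):
        p = full_conditional_z(np.array([0]), np.array([M]), psi, np.array([theta]))
        assert 0.0 <= p <= psi + 1e-9
        miss = (1 - theta) ** M
        expected = psi * miss / (psi * miss + (1 - psi))
        assert p == pytest.approx(expected, abs=1e-6)
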