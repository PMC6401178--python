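"""Likelihoods, priors and the posterior sampler for the occupancy model.

The observation model is zero-inflated Binomial: the latent indicator z_ij
(species i's eDNA occurs on filter j) is shared across all temperature
levels of a filter, so the marginal cell likelihood is

    psi_ij * prod_k Binom(x_ijk | M_ijk, theta_ik)  +  (1 - psi_ij) * 1{x_ij. = 0}

Posterior sampling uses Gibbs data augmentation: z_ij is drawn from its
closed-form Bernoulli full conditional, and the logit-scale effects and the
variance components are updated by adaptive random-walk Metropolis steps.
Blocks that are conditionally independent (species random effects,
species-by-filter and species-by-temperature interactions) are proposed and
accepted elementwise in vectorised form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator

from .datasets import DetectionDataset
from .simulate import ParameterSet, build_probabilities

PROB_FLOOR = 1e-12  # probabilities clipped away from {0,1} inside logs


def _logsig(eta: np.ndarray) -> np.ndarray:
    """log(expit(eta)), stable for large |eta|."""
    return -np.logaddexp(0.0, -np.asarray(eta, dtype=float))


def _clip_prob(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), PROB_FLOOR, 1.0 - PROB_FLOOR)


def _binom_logpmf(x: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p = _clip_prob(p)
    return (
        gammaln(n + 1.0)
        - gammaln(x + 1.0)
        - gammaln(n - x + 1.0)
        + x * np.log(p)
        + (n - x) * np.log1p(-p)
    )


# -- prior and sampler configuration ---------------------------------------


@dataclass
class PriorSpec:
    """Weakly-informative priors for the fixed parameters.

    fixed_effect_sd
        SD of the mean-zero normal prior on logit-scale fixed effects
        (group intercepts, filter and temperature effects).
    sd_prior, sd_scale
        Prior on the random-effect SDs: "uniform" (default) is flat on
        (0, sd_scale] with sd_scale = 5 — the customary vague choice for
        logit-scale SDs in community occupancy models, and it pins down the
        intercept/SD ridge that binary occurrence data leave otherwise
        unidentified; "half_cauchy" uses a half-Cauchy with that scale
        (customary sd_scale = 2.5), scale-free but prone to that ridge.
    constraint
        "sum_to_zero": filter and temperature fixed effects sum to zero
        within each group (identifiable; the default).  "unconstrained":
        all effects free under the wide prior — mirrors a plain BUGS-style
        specification; monitor only psi/theta in that mode.
    """

    fixed_effect_sd: float = 10.0
    sd_prior: str = "uniform"
    sd_scale: float = 5.0
    constraint: str = "sum_to_zero"

    def __post_init__(self) -> None:
        if self.fixed_effect_sd <= 0 or self.sd_scale <= 0:
            raise ValueError("prior scales must be positive")
        if self.sd_prior not in ("uniform", "half_cauchy"):
            raise ValueError(f"unknown sd_prior: {self.sd_prior!r}")
        if self.constraint not in ("sum_to_zero", "unconstrained"):
            raise ValueError(f"unknown constraint mode: {self.constraint!r}")

    def sd_logpdf(self, s) -> np.ndarray:
        """Log prior density of a random-effect SD (elementwise)."""
        s = np.asarray(s, dtype=float)
        if self.sd_prior == "uniform":
            return np.where(
                (s > 0) & (s <= self.sd_scale), -math.log(self.sd_scale), -np.inf
            )
        return _half_cauchy_logpdf(s, self.sd_scale)


@dataclass
class SamplerConfig:
    """MCMC run lengths.  The default is the scaled-down testing protocol;
    :meth:`paper_protocol` gives 3 chains x 100,000 iterations after 100,000
    burn-in, thinned at 100."""

    n_chains: int = 3
    n_burnin: int = 2000
    n_iter: int = 2000
    thin: int = 2
    seed: int = 0
    store_z: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")
        if self.thin < 1 or self.n_iter < self.thin:
            raise ValueError("need thin >= 1 and n_iter >= thin")

    @classmethod
    def paper_protocol(cls, seed: int = 0) -> "SamplerConfig":
        return cls(n_chains=3, n_burnin=100_000, n_iter=100_000, thin=100, seed=seed)

    @property
    def n_draws(self) -> int:
        return self.n_iter // self.thin


# -- likelihood functions ---------------------------------------------------


def cell_marginal_loglik(
    x_row: np.ndarray, M_row: np.ndarray, psi_ij: float, theta_row: np.ndarray
) -> float:
    """Marginal log-likelihood of one (species, filter) cell, z summed out.

    ``x_row``/``M_row``/``theta_row`` run over temperature levels.  Computed
    in log space via log-sum-exp of the occupied and unoccupied branches;
    levels with M = 0 contribute a unit factor.
    """
    x_row = np.atleast_1d(np.asarray(x_row, dtype=float))
    M_row = np.atleast_1d(np.asarray(M_row, dtype=float))
    theta_row = np.atleast_1d(np.asarray(theta_row, dtype=float))
    if not (
        np.isfinite(x_row).all()
        and np.isfinite(M_row).all()
        and np.isfinite(theta_row).all()
        and np.isfinite(psi_ij)
    ):
        raise ValueError("non-finite input to cell_marginal_loglik")
    if ((x_row < 0) | (x_row > M_row)).any():
        raise ValueError("x must satisfy 0 <= x <= M")
    if not (0.0 <= psi_ij <= 1.0) or ((theta_row < 0) | (theta_row > 1)).any():
        raise ValueError("psi and theta must lie in [0, 1]")
    psi = float(_clip_prob(psi_ij))
    log_occ = math.log(psi) + float(_binom_logpmf(x_row, M_row, theta_row).sum())
    if (x_row > 0).any():
        return log_occ
    return float(np.logaddexp(log_occ, math.log1p(-psi)))


def total_marginal_loglik(dataset: DetectionDataset, params: ParameterSet) -> float:
    """Sum of cell marginal log-likelihoods over all (species, filter) cells."""
    if (params.I, params.J, params.K) != (dataset.I, dataset.J, dataset.K):
        raise ValueError("parameter shapes do not match the dataset")
    psi, theta = build_probabilities(params, dataset.group)
    psi = _clip_prob(psi)
    S = _binom_logpmf(dataset.x, dataset.M, theta[:, None, :]).sum(axis=2)  # (I, J)
    log_occ = np.log(psi) + S
    all_zero = dataset.x.sum(axis=2) == 0
    log_unocc = np.where(all_zero, np.log1p(-psi), -np.inf)
    return float(np.logaddexp(log_occ, log_unocc).sum())


def full_conditional_z(
    x_row: np.ndarray, M_row: np.ndarray, psi_ij: float, theta_row: np.ndarray
) -> float:
    """Bernoulli probability of z_ij = 1 given data and probabilities.

    Any detection forces z = 1; otherwise
    p = psi * prod_k (1-theta_k)^{M_k} / (psi * prod_k (1-theta_k)^{M_k} + 1 - psi).
    """
    x_row = np.atleast_1d(np.asarray(x_row, dtype=float))
    M_row = np.atleast_1d(np.asarray(M_row, dtype=float))
    theta_row = _clip_prob(np.atleast_1d(theta_row))
    if (x_row > 0).any():
        return 1.0
    psi = float(_clip_prob(psi_ij))
    log_p1 = math.log(psi) + float((M_row * np.log1p(-theta_row)).sum())
    log_p0 = math.log1p(-psi)
    return float(np.exp(log_p1 - np.logaddexp(log_p1, log_p0)))


def _half_cauchy_logpdf(s: np.ndarray, scale: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return math.log(2.0 / (math.pi * scale)) - np.log1p((s / scale) ** 2)


def parameter_log_prior(
    params: ParameterSet, priors: PriorSpec, group: np.ndarray
) -> float:
    """Log density of random effects given SDs, plus fixed-effect and SD priors.

    The fixed-effect prior is evaluated on every filter/temperature effect
    entry regardless of constraint mode (under sum-to-zero it acts on the
    constrained values).
    """
    g = np.asarray(group, dtype=int) - 1
    s0 = priors.fixed_effect_sd

    def _norm(v: np.ndarray, sd: np.ndarray) -> float:
        sd = np.broadcast_to(np.asarray(sd, dtype=float), np.shape(v))
        return float(
            (-0.5 * math.log(2 * math.pi) - np.log(sd) - 0.5 * (v / sd) ** 2).sum()
        )

    lp = 0.0
    for v in (params.alpha_g, params.beta_g, params.alpha_f, params.beta_t):
        lp += _norm(v, s0)
    lp += _norm(params.alpha_s, params.sigma_s[g])
    lp += _norm(params.alpha_fs, params.sigma_fs[g][:, None])
    lp += _norm(params.beta_s, params.tau_s[g])
    lp += _norm(params.beta_ts, params.tau_ts[g][:, None])
    for sd in (params.sigma_s, params.sigma_fs, params.tau_s, params.tau_ts):
        lp += float(priors.sd_logpdf(sd).sum())
    return lp


def complete_data_logpost(
    dataset: DetectionDataset,
    params: ParameterSet,
    z: np.ndarray,
    priors: PriorSpec | None = None,
) -> float:
    """Log joint density of data, latent occurrence states and parameters.

    Returns ``-inf`` (not an exception) when z = 0 coincides with a positive
    detection count, the impossible configuration under a no-false-positive
    model.
    """
    priors = priors or PriorSpec()
    z = np.asarray(z)
    if z.shape != (dataset.I, dataset.J) or not np.isin(z, (0, 1)).all():
        raise ValueError("z must be a binary (I, J) array")
    if ((z == 0) & (dataset.x.sum(axis=2) > 0)).any():
        return -math.inf
    psi, theta = build_probabilities(params, dataset.group)
    psi = _clip_prob(psi)
    det = float(
        (z[:, :, None] * _binom_logpmf(dataset.x, dataset.M, theta[:, None, :])).sum()
    )
    occ = float((z * np.log(psi) + (1 - z) * np.log1p(-psi)).sum())
    return det + occ + parameter_log_prior(params, priors, dataset.group)


# -- posterior container ----------------------------------------------------


@dataclass
class PosteriorSamples:
    """Per-chain posterior draws.

    ``draws`` maps parameter names to arrays of shape (n_chains, n_draws,
    *param_shape).  Derived probability-scale quantities psi (I, J) and
    theta (I, K) are included.  Names in exported tables are 1-based, e.g.
    ``alpha_g[1]`` or ``beta_t[2,5]``.
    """

    draws: dict[str, np.ndarray]
    group: np.ndarray
    species_ids: list[str]
    temperatures_c: np.ndarray
    config: dict = field(default_factory=dict)

    PARAM_NAMES = (
        "alpha_g",
        "alpha_f",
        "alpha_s",
        "alpha_fs",
        "beta_g",
        "beta_t",
        "beta_s",
        "beta_ts",
        "sigma_s",
        "sigma_fs",
        "tau_s",
        "tau_ts",
    )
    MONITORED = (
        "alpha_g",
        "alpha_f",
        "beta_g",
        "beta_t",
        "sigma_s",
        "sigma_fs",
        "tau_s",
        "tau_ts",
        "psi",
        "theta",
    )

    @property
    def n_chains(self) -> int:
        return self.draws["alpha_g"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["alpha_g"].shape[1]

    def parameter_set(self, chain: int, draw: int) -> ParameterSet:
        """Materialise one draw as a :class:`ParameterSet`."""
        return ParameterSet(
            **{name: self.draws[name][chain, draw] for name in self.PARAM_NAMES}
        )

    def iter_draws(self) -> Iterator[ParameterSet]:
        for c in range(self.n_chains):
            for d in range(self.n_draws):
                yield self.parameter_set(c, d)

    def scalar_draws(self, names: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
        """Flatten parameters to named scalars -> (n_chains, n_draws) arrays."""
        names = names or self.PARAM_NAMES + ("psi", "theta")
        out: dict[str, np.ndarray] = {}
        for name in names:
            arr = self.draws[name]
            shape = arr.shape[2:]
            if shape == ():
                out[name] = arr
                continue
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for pos in range(flat.shape[2]):
                idx = np.unravel_index(pos, shape)
                label = ",".join(str(i + 1) for i in idx)
                out[f"{name}[{label}]"] = flat[:, :, pos]
        return out

    def monitored_scalars(self) -> dict[str, np.ndarray]:
        """Scalars gated for convergence: fixed effects, variance components
        and all probability-scale psi/theta (latent z and the species random
        effects are excluded)."""
        return self.scalar_draws(self.MONITORED)

    def to_dataframe(self, include_derived: bool = False) -> pd.DataFrame:
        names = self.PARAM_NAMES + (("psi", "theta") if include_derived else ())
        scalars = self.scalar_draws(names)
        n_c, n_d = self.n_chains, self.n_draws
        data = {
            "chain": np.repeat(np.arange(1, n_c + 1), n_d),
            "draw": np.tile(np.arange(1, n_d + 1), n_c),
        }
        for key, arr in scalars.items():
            data[key] = arr.reshape(-1)
        return pd.DataFrame(data)

    def save(self, prefix) -> list:
        """Write ``<prefix>.tsv`` (columnar draws) + ``<prefix>.json`` manifest.

        Derived psi/theta are recomputed on load rather than stored."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tsv = prefix.with_suffix(".tsv")
        self.to_dataframe().to_csv(tsv, sep="\t", index=False, float_format="%.10g")
        manifest = {
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "group": self.group.tolist(),
            "species_ids": list(self.species_ids),
            "temperatures_c": self.temperatures_c.tolist(),
            "config": self.config,
        }
        js = prefix.with_suffix(".json")
        js.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        return [tsv, js]

    @classmethod
    def load(cls, prefix) -> "PosteriorSamples":
        import json
        import re
        from pathlib import Path

        prefix = Path(prefix)
        manifest = json.loads(prefix.with_suffix(".json").read_text())
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        n_c, n_d = manifest["n_chains"], manifest["n_draws"]
        group = np.asarray(manifest["group"])
        cols: dict[str, list] = {}
        for col in df.columns:
            if col in ("chain", "draw"):
                continue
            m = re.match(r"([a-z_]+)(?:\[([\d,]+)\])?$", col)
            cols.setdefault(m.group(1), []).append(col)
        I = group.shape[0]
        shapes = {
            "alpha_g": (2,),
            "beta_g": (2,),
            "sigma_s": (2,),
            "sigma_fs": (2,),
            "tau_s": (2,),
            "tau_ts": (2,),
            "alpha_s": (I,),
            "beta_s": (I,),
        }
        draws: dict[str, np.ndarray] = {}
        for name, columns in cols.items():
            vals = df[columns].to_numpy().reshape(n_c, n_d, len(columns))
            if name in ("alpha_f", "alpha_fs", "beta_t", "beta_ts"):
                n_rows = 2 if name in ("alpha_f", "beta_t") else I
                shape = (n_rows, len(columns) // n_rows)
            else:
                shape = shapes[name]
            draws[name] = vals.reshape(n_c, n_d, *shape)
        samples = cls(
            draws=draws,
            group=group,
            species_ids=manifest["species_ids"],
            temperatures_c=np.asarray(manifest["temperatures_c"]),
            config=manifest.get("config", {}),
        )
        samples.attach_derived()
        return samples

    def attach_derived(self) -> None:
        """(Re)compute psi/theta draws from the parameter draws."""
        g = self.group.astype(int) - 1
        d = self.draws
        eta_psi = (
            d["alpha_g"][:, :, g, None]
            + d["alpha_f"][:, :, g, :]
            + d["alpha_s"][:, :, :, None]
            + d["alpha_fs"]
        )
        eta_theta = (
            d["beta_g"][:, :, g, None]
            + d["beta_t"][:, :, g, :]
            + d["beta_s"][:, :, :, None]
            + d["beta_ts"]
        )
        d["psi"] = expit(eta_psi)
        d["theta"] = expit(eta_theta)


# -- the sampler ------------------------------------------------------------


class _ChainRunner:
    """Single-chain sampler: Gibbs for z, adaptive Metropolis-within-Gibbs
    for the logit effects and variance components.

    The filter-by-species interaction enters the likelihood only through the
    single Bernoulli observation z_ij of its cell, which makes naive data
    augmentation for it prone to sign-locking in a saturated minor mode.  It
    is therefore marginalised out of the running chain by Gauss-Hermite
    quadrature — the occupancy likelihood uses the marginal occurrence
    probability  psi*_ij = E_a[ expit(base_ij + a) ],  a ~ N(0, sigma_fs^2)
    — and a value of the interaction is drawn from its exact univariate
    conditional (via a fine grid) only when a draw is recorded.  The
    temperature-by-species interaction sees J*M Bernoulli trials per cell
    and is sampled by ordinary augmentation.
    """

    ADAPT_TARGET = 0.44
    INIT_RETRIES = 10
    GH_POINTS = 21

    def __init__(
        self,
        dataset: DetectionDataset,
        priors: PriorSpec,
        rng: np.random.Generator,
    ) -> None:
        self.x = dataset.x.astype(float)
        self.M = dataset.M.astype(float)
        self.I, self.J, self.K = dataset.I, dataset.J, dataset.K
        self.g = dataset.group_index
        self.rows = [np.where(self.g == 0)[0], np.where(self.g == 1)[0]]
        self.any_det = dataset.x.sum(axis=2) > 0
        self.priors = priors
        self.rng = rng
        self.constrained = priors.constraint == "sum_to_zero"
        self.Wj = self.J - 1 if self.constrained else self.J
        self.Wk = self.K - 1 if self.constrained else self.K
        gh_x, gh_w = np.polynomial.hermite.hermgauss(self.GH_POINTS)
        self.gh_u = math.sqrt(2.0) * gh_x  # N(0,1) nodes
        self.gh_w = gh_w / math.sqrt(math.pi)
        self._init_state()

    # state ---------------------------------------------------------------
    def _init_state(self) -> None:
        for attempt in range(self.INIT_RETRIES):
            self.ag = np.zeros(2)
            self.af = np.zeros((2, self.Wj))
            self.as_ = np.zeros(self.I)
            self.bg = np.zeros(2)
            self.bt = np.zeros((2, self.Wk))
            self.bs = np.zeros(self.I)
            self.bts = np.zeros((self.I, self.K))
            self.sds = np.ones((4, 2))  # sigma_s, sigma_fs, tau_s, tau_ts
            self.z = np.where(
                self.any_det, 1, (self.rng.random((self.I, self.J)) < 0.5)
            ).astype(float)
            # empirical-logit intercept starts keep the burn-in near the
            # dominant mode instead of letting interactions absorb the mean
            for gi in (0, 1):
                r = self.rows[gi]
                if r.size == 0:
                    continue
                occ = np.clip(self.any_det[r].mean(), 0.02, 0.98)
                self.ag[gi] = math.log(occ / (1.0 - occ))
                m_occ = (self.M[r] * self.any_det[r][:, :, None]).sum()
                x_occ = (self.x[r] * self.any_det[r][:, :, None]).sum()
                rate = np.clip(x_occ / max(m_occ, 1.0), 0.02, 0.98)
                self.bg[gi] = math.log(rate / (1.0 - rate))
            self._refresh_etas()
            self._refresh_det_stats()
            if np.isfinite(self._occ_ll_rows(self.base_psi, np.arange(self.I))) and np.isfinite(
                self._det_ll(self.eta_theta).sum()
            ):
                return
        raise RuntimeError("failed to find a finite starting density")

    def _full(self, free: np.ndarray, width: int) -> np.ndarray:
        if not self.constrained:
            return free
        if width <= 1:
            return np.zeros((2, width))
        return np.concatenate([free, -free.sum(axis=1, keepdims=True)], axis=1)

    def af_full(self) -> np.ndarray:
        return self._full(self.af, self.J)

    def bt_full(self) -> np.ndarray:
        return self._full(self.bt, self.K)

    def _refresh_etas(self) -> None:
        # occupancy "base" excludes the marginalised filter-by-species term
        self.base_psi = (
            self.ag[self.g][:, None] + self.af_full()[self.g, :] + self.as_[:, None]
        )
        self.eta_theta = (
            self.bg[self.g][:, None]
            + self.bt_full()[self.g, :]
            + self.bs[:, None]
            + self.bts
        )

    def _refresh_det_stats(self) -> None:
        self.N_ik = np.einsum("ijk,ij->ik", self.M, self.z)
        self.y_ik = np.einsum("ijk,ij->ik", self.x, self.z)

    # occupancy likelihood with the interaction integrated out --------------
    def _psi_marg(self, base: np.ndarray, sig: np.ndarray) -> np.ndarray:
        """Marginal occurrence probability: base (..., ) plus N(0, sig^2)
        noise pushed through the inverse logit, by Gauss-Hermite."""
        vals = expit(base[..., None] + sig[..., None] * self.gh_u)
        return _clip_prob(vals @ self.gh_w)

    def _sig_fs(self, r: np.ndarray) -> np.ndarray:
        return self.sds[1, self.g[r]]

    def _occ_ll_rows(
        self, base_rows: np.ndarray, r: np.ndarray, sig: np.ndarray | None = None
    ) -> float:
        """Occupancy log-likelihood of full rows r given their base block."""
        sig = self._sig_fs(r) if sig is None else sig
        psi = self._psi_marg(base_rows, sig[:, None])
        zr = self.z[r]
        return float((zr * np.log(psi) + (1.0 - zr) * np.log1p(-psi)).sum())

    def _occ_ll_block(self, base_block: np.ndarray, r: np.ndarray, cols: np.ndarray) -> float:
        sig = self._sig_fs(r)
        psi = self._psi_marg(base_block, sig[:, None])
        zb = self.z[np.ix_(r, cols)]
        return float((zb * np.log(psi) + (1.0 - zb) * np.log1p(-psi)).sum())

    def _occ_ll_per_row(self, base: np.ndarray) -> np.ndarray:
        psi = self._psi_marg(base, self._sig_fs(np.arange(self.I))[:, None])
        return (self.z * np.log(psi) + (1.0 - self.z) * np.log1p(-psi)).sum(axis=1)

    # detection likelihood pieces ------------------------------------------
    def _det_ll(self, eta: np.ndarray) -> np.ndarray:
        return self.y_ik * _logsig(eta) + (self.N_ik - self.y_ik) * _logsig(-eta)

    def _det_ll_sub(self, eta_sub: np.ndarray, idx) -> float:
        y, N = self.y_ik[idx], self.N_ik[idx]
        return float((y * _logsig(eta_sub) + (N - y) * _logsig(-eta_sub)).sum())

    # Gibbs step for z ------------------------------------------------------
    def update_z(self) -> None:
        log1m_theta = _logsig(-self.eta_theta)  # (I, K)
        s = np.einsum("ijk,ik->ij", self.M, log1m_theta)
        psi = self._psi_marg(self.base_psi, self._sig_fs(np.arange(self.I))[:, None])
        lp1 = np.log(psi) + s
        lp0 = np.log1p(-psi)
        p1 = np.exp(lp1 - np.logaddexp(lp1, lp0))
        draw = self.rng.random((self.I, self.J)) < p1
        self.z = np.where(self.any_det, 1.0, draw.astype(float))
        self._refresh_det_stats()

    # Metropolis blocks ------------------------------------------------------
    def _accept(self, log_ratio: np.ndarray) -> np.ndarray:
        return np.log(self.rng.random(np.shape(log_ratio))) < log_ratio

    def _mh_intercept(self, which: str, step: np.ndarray, gamma: float | None) -> None:
        s0 = self.priors.fixed_effect_sd
        for gi in (0, 1):
            r = self.rows[gi]
            if r.size == 0:
                continue
            d = step[gi] * self.rng.standard_normal()
            if which == "ag":
                dll = self._occ_ll_rows(self.base_psi[r] + d, r) - self._occ_ll_rows(
                    self.base_psi[r], r
                )
                vec = self.ag
            else:
                dll = self._det_ll_sub(self.eta_theta[r] + d, r) - self._det_ll_sub(
                    self.eta_theta[r], r
                )
                vec = self.bg
            dll += -0.5 * ((vec[gi] + d) ** 2 - vec[gi] ** 2) / s0**2
            acc = bool(self._accept(dll))
            if acc:
                vec[gi] += d
                (self.base_psi if which == "ag" else self.eta_theta)[r] += d
            if gamma is not None:
                step[gi] *= math.exp(gamma * (float(acc) - self.ADAPT_TARGET))

    def _mh_fixed_effect(self, which: str, step: np.ndarray, gamma: float | None) -> None:
        """Componentwise update of filter (occupancy) or temperature
        (detection) fixed effects; under sum-to-zero, moving free component
        j also moves the last component in the opposite direction."""
        if which == "af":
            free, n_cols = self.af, self.J
        else:
            free, n_cols = self.bt, self.K
        width = free.shape[1]
        s0 = self.priors.fixed_effect_sd
        for gi in (0, 1):
            r = self.rows[gi]
            if r.size == 0 or width == 0:
                continue
            full_row = self._full(free, n_cols)[gi] if self.constrained else None
            for jf in range(width):
                d = step[gi, jf] * self.rng.standard_normal()
                if self.constrained:
                    cols = np.array([jf, n_cols - 1])
                    deltas = np.array([d, -d])
                    prior_cur = full_row[cols]
                else:
                    cols = np.array([jf])
                    deltas = np.array([d])
                    prior_cur = free[gi, cols]
                idx = np.ix_(r, cols)
                if which == "af":
                    sub = self.base_psi[idx]
                    dll = self._occ_ll_block(sub + deltas, r, cols) - self._occ_ll_block(
                        sub, r, cols
                    )
                else:
                    sub = self.eta_theta[idx]
                    dll = self._det_ll_sub(sub + deltas, idx) - self._det_ll_sub(sub, idx)
                dll += (
                    -0.5
                    * (((prior_cur + deltas) ** 2).sum() - (prior_cur**2).sum())
                    / s0**2
                )
                acc = bool(self._accept(dll))
                if acc:
                    free[gi, jf] += d
                    if self.constrained:
                        full_row[cols] += deltas
                    if which == "af":
                        self.base_psi[idx] = sub + deltas
                    else:
                        self.eta_theta[idx] = sub + deltas
                if gamma is not None:
                    step[gi, jf] *= math.exp(gamma * (float(acc) - self.ADAPT_TARGET))

    def _mh_species(self, which: str, step: np.ndarray, gamma: float | None) -> None:
        """Vectorised independent updates of the per-species random effects."""
        d = step * self.rng.standard_normal(self.I)
        if which == "as":
            vec, sd = self.as_, self.sds[0]
            dll = self._occ_ll_per_row(self.base_psi + d[:, None]) - self._occ_ll_per_row(
                self.base_psi
            )
        else:
            vec, sd = self.bs, self.sds[2]
            dll = (self._det_ll(self.eta_theta + d[:, None]) - self._det_ll(self.eta_theta)).sum(
                axis=1
            )
        sd_i = sd[self.g]
        dll += -0.5 * ((vec + d) ** 2 - vec**2) / sd_i**2
        acc = self._accept(dll)
        vec += d * acc
        if which == "as":
            self.base_psi += (d * acc)[:, None]
        else:
            self.eta_theta += (d * acc)[:, None]
        if gamma is not None:
            step *= np.exp(gamma * (acc.astype(float) - self.ADAPT_TARGET))

    def _mh_bts(self, step: np.ndarray, gamma: float | None) -> None:
        """Vectorised elementwise updates of temperature-by-species effects."""
        D = step * self.rng.standard_normal(self.bts.shape)
        prop_eta = self.eta_theta + D
        dll = self._det_ll(prop_eta) - self._det_ll(self.eta_theta)
        sd_i = self.sds[3][self.g][:, None]
        dll += -0.5 * ((self.bts + D) ** 2 - self.bts**2) / sd_i**2
        acc = self._accept(dll)
        self.bts += D * acc
        self.eta_theta += D * acc
        if gamma is not None:
            step *= np.exp(gamma * (acc.astype(float) - self.ADAPT_TARGET))

    def _mh_sigma_fs(self, step: np.ndarray, gamma: float | None) -> None:
        """Log-scale MH for the marginalised interaction SD; smooth because
        the interaction is integrated out of the likelihood."""
        for gi in (0, 1):
            r = self.rows[gi]
            if r.size == 0:
                continue
            s = self.sds[1, gi]
            d = step[gi] * self.rng.standard_normal()
            s_new = s * math.exp(d)
            sig_new = np.full(r.size, s_new)
            dll = self._occ_ll_rows(self.base_psi[r], r, sig=sig_new) - self._occ_ll_rows(
                self.base_psi[r], r
            )
            dll += float(self.priors.sd_logpdf(s_new) - self.priors.sd_logpdf(s)) + d
            acc = bool(self._accept(dll))
            if acc:
                self.sds[1, gi] = s_new
            if gamma is not None:
                step[gi] *= math.exp(gamma * (float(acc) - self.ADAPT_TARGET))

    def _effects_for_sd(self, comp: int, gi: int) -> np.ndarray:
        r = self.rows[gi]
        return (self.as_[r], None, self.bs[r], self.bts[r].ravel())[comp]

    def _mh_sds(self, step: np.ndarray, gamma: float | None) -> None:
        """Centred conditional update of sigma_s, tau_s, tau_ts given their
        effects (sigma_fs is handled by :meth:`_mh_sigma_fs`)."""
        for comp in (0, 2, 3):
            for gi in (0, 1):
                v = self._effects_for_sd(comp, gi)
                if v is None or v.size == 0:
                    continue
                ssq = float((v**2).sum())
                n = v.size
                u = math.log(self.sds[comp, gi])

                def logpost(u_: float) -> float:
                    s = math.exp(u_)
                    return (
                        -n * u_
                        - 0.5 * ssq / s**2
                        + float(self.priors.sd_logpdf(s))
                        + u_  # Jacobian of the log transform
                    )

                d = step[comp, gi] * self.rng.standard_normal()
                dll = logpost(u + d) - logpost(u)
                acc = bool(self._accept(dll))
                if acc:
                    self.sds[comp, gi] = math.exp(u + d)
                if gamma is not None:
                    step[comp, gi] *= math.exp(gamma * (float(acc) - self.ADAPT_TARGET))

    def _mh_sds_noncentered(self, step: np.ndarray, gamma: float | None) -> None:
        """Interweaved non-centred SD update: rescale a group's random effects
        together with their SD (standardised effects held fixed), so the SD
        mixes even when the effects are weakly identified by the data."""
        for comp in (0, 2, 3):
            for gi in (0, 1):
                r = self.rows[gi]
                if r.size == 0:
                    continue
                s = self.sds[comp, gi]
                d = step[comp, gi] * self.rng.standard_normal()
                c = math.exp(d)
                if comp == 0:
                    delta = ((c - 1.0) * self.as_[r])[:, None]
                    dll = self._occ_ll_rows(self.base_psi[r] + delta, r) - self._occ_ll_rows(
                        self.base_psi[r], r
                    )
                elif comp == 2:
                    delta = ((c - 1.0) * self.bs[r])[:, None]
                    dll = self._det_ll_sub(self.eta_theta[r] + delta, r) - self._det_ll_sub(
                        self.eta_theta[r], r
                    )
                else:
                    delta = (c - 1.0) * self.bts[r]
                    dll = self._det_ll_sub(self.eta_theta[r] + delta, r) - self._det_ll_sub(
                        self.eta_theta[r], r
                    )
                dll += float(self.priors.sd_logpdf(s * c) - self.priors.sd_logpdf(s)) + d
                acc = bool(self._accept(dll))
                if acc:
                    self.sds[comp, gi] = s * c
                    if comp == 0:
                        self.as_[r] = self.as_[r] * c
                        self.base_psi[r] = self.base_psi[r] + delta
                    elif comp == 2:
                        self.bs[r] = self.bs[r] * c
                        self.eta_theta[r] = self.eta_theta[r] + delta
                    else:
                        self.bts[r] = self.bts[r] * c
                        self.eta_theta[r] = self.eta_theta[r] + delta
                if gamma is not None:
                    step[comp, gi] *= math.exp(gamma * (float(acc) - self.ADAPT_TARGET))

    def _mh_ridge(self, which: str, step: np.ndarray, gamma: float | None) -> None:
        """Translate a group intercept against its species effects.  The
        linear predictor is unchanged, so only prior terms enter; this mixes
        the flat intercept/species-effect ridge that appears when the data
        saturate (e.g. every filter-level state occupied)."""
        if which == "a":
            vec, eff, sd_row = self.ag, self.as_, self.sds[0]
        else:
            vec, eff, sd_row = self.bg, self.bs, self.sds[2]
        s0 = self.priors.fixed_effect_sd
        for gi in (0, 1):
            r = self.rows[gi]
            if r.size == 0:
                continue
            d = step[gi] * self.rng.standard_normal()
            dll = -0.5 * ((vec[gi] + d) ** 2 - vec[gi] ** 2) / s0**2
            v = eff[r]
            dll += float((-0.5 * (((v - d) ** 2) - v**2) / sd_row[gi] ** 2).sum())
            acc = bool(self._accept(dll))
            if acc:
                vec[gi] += d
                eff[r] = v - d
            if gamma is not None:
                step[gi] *= math.exp(gamma * (float(acc) - self.ADAPT_TARGET))

    def _mh_ridge_bts(self, step: np.ndarray, gamma: float | None) -> None:
        """Translate each species detection effect against its interaction
        row (linear predictor invariant; prior terms only)."""
        d = step * self.rng.standard_normal(self.I)
        sde = self.sds[2][self.g]
        sdm = self.sds[3][self.g]
        dll = -0.5 * ((self.bs + d) ** 2 - self.bs**2) / sde**2
        dll += (-0.5 * ((self.bts - d[:, None]) ** 2 - self.bts**2)).sum(axis=1) / sdm**2
        acc = self._accept(dll)
        self.bs += d * acc
        self.bts -= (d * acc)[:, None]
        if gamma is not None:
            step *= np.exp(gamma * (acc.astype(float) - self.ADAPT_TARGET))

    # recording ---------------------------------------------------------------
    def _draw_afs(self) -> np.ndarray:
        """Sample the filter-by-species interaction from its exact univariate
        conditional per cell (fine-grid inverse CDF); used only for recorded
        draws, never fed back into the chain."""
        sig = self._sig_fs(np.arange(self.I))[:, None]  # (I, 1)
        grid = np.linspace(-5.0, 5.0, 81)  # standardised support
        a = sig[..., None] * grid  # (I, 1, G) -> broadcast over J
        eta = self.base_psi[:, :, None] + a
        p = _clip_prob(expit(eta))
        loglik = self.z[:, :, None] * np.log(p) + (1.0 - self.z[:, :, None]) * np.log1p(-p)
        logw = loglik - 0.5 * grid**2
        logw -= logw.max(axis=2, keepdims=True)
        w = np.exp(logw)
        cdf = np.cumsum(w, axis=2)
        cdf /= cdf[:, :, -1:]
        u = self.rng.random((self.I, self.J, 1))
        idx = (cdf < u).sum(axis=2)
        # linear jitter within the selected grid cell
        lo = grid[np.clip(idx - 1, 0, 80)]
        hi = grid[idx]
        frac = self.rng.random((self.I, self.J))
        return (lo + frac * (hi - lo)) * sig

    # main loop --------------------------------------------------------------
    def run(self, config: SamplerConfig) -> dict[str, np.ndarray]:
        steps = {
            "ag": np.full(2, 0.3),
            "af": np.full((2, self.Wj), 0.3),
            "as": np.full(self.I, 0.5),
            "bg": np.full(2, 0.3),
            "bt": np.full((2, self.Wk), 0.3),
            "bs": np.full(self.I, 0.5),
            "bts": np.full((self.I, self.K), 0.8),
            "sds": np.full((4, 2), 0.5),
            "sds_nc": np.full((4, 2), 0.5),
            "sig_fs": np.full(2, 0.5),
            "ridge_a": np.full(2, 0.5),
            "ridge_b": np.full(2, 0.5),
            "ridge_bts": np.full(self.I, 0.5),
        }
        rec: dict[str, list] = {name: [] for name in PosteriorSamples.PARAM_NAMES}
        rec["psi"] = []
        rec["theta"] = []
        if config.store_z:
            rec["z"] = []
        total = config.n_burnin + config.n_iter
        for it in range(total):
            burnin = it < config.n_burnin
            gamma = min(0.25, (1.0 + it) ** -0.6) if burnin else None
            self.update_z()
            self._mh_intercept("ag", steps["ag"], gamma)
            self._mh_fixed_effect("af", steps["af"], gamma)
            self._mh_species("as", steps["as"], gamma)
            self._mh_intercept("bg", steps["bg"], gamma)
            self._mh_fixed_effect("bt", steps["bt"], gamma)
            self._mh_species("bs", steps["bs"], gamma)
            self._mh_bts(steps["bts"], gamma)
            self._mh_sds(steps["sds"], gamma)
            self._mh_sds_noncentered(steps["sds_nc"], gamma)
            self._mh_sigma_fs(steps["sig_fs"], gamma)
            self._mh_ridge("a", steps["ridge_a"], gamma)
            self._mh_ridge("b", steps["ridge_b"], gamma)
            self._mh_ridge_bts(steps["ridge_bts"], gamma)
            if not burnin and (it - config.n_burnin + 1) % config.thin == 0:
                afs = self._draw_afs()
                rec["alpha_g"].append(self.ag.copy())
                rec["alpha_f"].append(self.af_full().copy())
                rec["alpha_s"].append(self.as_.copy())
                rec["alpha_fs"].append(afs)
                rec["beta_g"].append(self.bg.copy())
                rec["beta_t"].append(self.bt_full().copy())
                rec["beta_s"].append(self.bs.copy())
                rec["beta_ts"].append(self.bts.copy())
                rec["sigma_s"].append(self.sds[0].copy())
                rec["sigma_fs"].append(self.sds[1].copy())
                rec["tau_s"].append(self.sds[2].copy())
                rec["tau_ts"].append(self.sds[3].copy())
                rec["psi"].append(expit(self.base_psi + afs))
                rec["theta"].append(expit(self.eta_theta))
                if config.store_z:
                    rec["z"].append(self.z.copy().astype(int))
        return {k: np.stack(v) for k, v in rec.items()}


def sample_posterior(
    dataset: DetectionDataset,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorSamples:
    """Draw from the posterior of the occupancy model on ``dataset``.

    Per-chain seeds are derived deterministically from ``config.seed``.
    """
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    if (dataset.M > 0).sum() == 0:
        raise ValueError("dataset has no usable replicates (all M = 0)")
    seed_seq = np.random.SeedSequence(config.seed)
    chain_draws: list[dict[str, np.ndarray]] = []
    for child in seed_seq.spawn(config.n_chains):
        runner = _ChainRunner(dataset, priors, np.random.default_rng(child))
        chain_draws.append(runner.run(config))
    draws = {
        name: np.stack([cd[name] for cd in chain_draws])
        for name in chain_draws[0]
    }
    return PosteriorSamples(
        draws=draws,
        group=dataset.group.copy(),
        species_ids=list(dataset.species_ids),
        temperatures_c=dataset.temperatures_c.copy(),
        config={
            "n_chains": config.n_chains,
            "n_burnin": config.n_burnin,
            "n_iter": config.n_iter,
            "thin": config.thin,
            "seed": config.seed,
            "constraint": priors.constraint,
            "fixed_effect_prior_sd": priors.fixed_effect_sd,
            "sd_prior_scale": priors.sd_scale,
        },
    )


class OccupancyModel(BaseEstimator):
    """Multispecies occupancy model estimator (scikit-learn style).

    ``fit`` takes a :class:`DetectionDataset` and runs the MCMC sampler;
    fitted attributes are ``samples_`` (posterior draws), ``summary_``
    (median / 95% CrI / R-hat table), ``max_rhat_`` and ``converged_``
    (the R-hat < ``rhat_threshold`` gate over the monitored parameters).

    Parameters mirror :class:`PriorSpec` and :class:`SamplerConfig`; defaults
    are the scaled-down testing protocol, ``full_protocol=True`` switches to
    3 chains x 100,000 iterations after 100,000 burn-in, thinned at 100.
    """

    def __init__(
        self,
        n_chains: int = 3,
        n_burnin: int = 2000,
        n_iter: int = 2000,
        thin: int = 2,
        seed: int = 0,
        fixed_effect_prior_sd: float = 10.0,
        sd_prior_scale: float = 2.5,
        constraint: str = "sum_to_zero",
        full_protocol: bool = False,
        store_z: bool = False,
        rhat_threshold: float = 1.1,
        rhat_method: str = "rank",
    ) -> None:
        self.n_chains = n_chains
        self.n_burnin = n_burnin
        self.n_iter = n_iter
        self.thin = thin
        self.seed = seed
        self.fixed_effect_prior_sd = fixed_effect_prior_sd
        self.sd_prior_scale = sd_prior_scale
        self.constraint = constraint
        self.full_protocol = full_protocol
        self.store_z = store_z
        self.rhat_threshold = rhat_threshold
        self.rhat_method = rhat_method

    def _priors(self) -> PriorSpec:
        return PriorSpec(
            fixed_effect_sd=self.fixed_effect_prior_sd,
            sd_scale=self.sd_prior_scale,
            constraint=self.constraint,
        )

    def _config(self) -> SamplerConfig:
        if self.full_protocol:
            cfg = SamplerConfig.paper_protocol(seed=self.seed)
            cfg.store_z = self.store_z
            return cfg
        return SamplerConfig(
            n_chains=self.n_chains,
            n_burnin=self.n_burnin,
            n_iter=self.n_iter,
            thin=self.thin,
            seed=self.seed,
            store_z=self.store_z,
        )

    def fit(self, X: DetectionDataset, y=None) -> "OccupancyModel":
        from .diagnostics import convergence_gate, summarize

        if not isinstance(X, DetectionDataset):
            raise TypeError("X must be a DetectionDataset")
        X.validate()
        self.samples_ = sample_posterior(X, self._priors(), self._config())
        self.summary_ = summarize(self.samples_, rhat_method=self.rhat_method)
        gate = convergence_gate(
            self.samples_, threshold=self.rhat_threshold, method=self.rhat_method
        )
        self.converged_ = gate.passed
        self.max_rhat_ = gate.max_rhat
        self.gate_report_ = gate
        return self

    def score(self, X: DetectionDataset, y=None) -> float:
        """Mean marginal log-likelihood of X over posterior draws (thinned)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "samples_")
        draws = list(self.samples_.iter_draws())
        step = max(1, len(draws) // 50)
        lls = [total_marginal_loglik(X, p) for p in draws[::step]]
        return float(np.mean(lls))
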