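"""Convergence assessment and posterior summarisation.

Inference is gated on the potential scale reduction factor: every monitored
parameter must have R-hat < 1.1 (fixed effects, variance components and the
probability-scale psi/theta; latent states and species random effects are
not gated).  Two R-hat variants are provided: the classical split-chain
estimator and the rank-normalised split estimator (default), which also
folds the draws to catch scale differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .model import PosteriorSamples


def _split_chains(chains: np.ndarray) -> np.ndarray:
    """Split each chain in half: (..., m, n) -> (..., 2m, n//2)."""
    n = chains.shape[-1]
    half = n // 2
    first = chains[..., :half]
    second = chains[..., n - half :]
    return np.concatenate([first, second], axis=-2)

def _classical_rhat(chains: np.ndarray) -> np.ndarray:
    """Gelman-Rubin statistic on (..., m, n) chain arrays (no splitting)."""
    n = chains.shape[-1]
    means = chains.mean(axis=-1)
    W = chains.var(axis=-1, ddof=1).mean(axis=-1)
    B_over_n = means.var(axis=-1, ddof=1)  # = B / n
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    zero_var = ~np.isfinite(rhat) | (var_plus == 0)
    if np.any(zero_var & (var_plus == 0)):
        warnings.warn("zero total variance encountered in R-hat", RuntimeWarning)
        rhat = np.where(var_plus == 0, np.nan, rhat)
    return rhat


def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    """Pooled average ranks mapped through the normal quantile function.

    The Blom offset keeps the transform strictly inside the unit interval."""
    from scipy.stats import rankdata

    shape = chains.shape
    flat = chains.reshape(*shape[:-2], -1)
    ranks = rankdata(flat, axis=-1, method="average")
    u = (ranks - 3.0 / 8.0) / (flat.shape[-1] + 1.0 / 4.0)
    return ndtri(u).reshape(shape)


def rhat(chains: np.ndarray, method: str = "rank") -> float | np.ndarray:
    """Potential scale reduction factor.

    Parameters
    ----------
    chains
        Array of shape (n_chains, n_draws) or (..., n_chains, n_draws) with
        at least two chains of at least four draws each.
    method
        "classical": Gelman-Rubin on whole chains (lower bound
        sqrt((n-1)/n) with n draws per chain).  "rank" (default): maximum of
        the rank-normalised split R-hat of the draws and of the draws folded
        around their median.

    Returns NaN (with a warning) when the total variance is zero.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim < 2 or chains.shape[-2] < 2 or chains.shape[-1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    if not np.isfinite(chains).all():
        raise ValueError("chains contain non-finite draws")
    if method == "classical":
        out = _classical_rhat(chains)
    elif method == "rank":
        split = _split_chains(chains)
        bulk = _classical_rhat(_rank_normalize(split))
        folded = np.abs(split - np.median(split, axis=(-2, -1), keepdims=True))
        tail = _classical_rhat(_rank_normalize(folded))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.fmax(bulk, tail)
    else:
        raise ValueError(f"unknown R-hat method: {method!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class GateReport:
    """Outcome of the R-hat convergence gate."""

    passed: bool
    threshold: float
    max_rhat: float
    offenders: list[str] = field(default_factory=list)
    rhat: dict[str, float] = field(default_factory=dict)

    def __str__(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        msg = f"convergence gate {verdict}: max R-hat = {self.max_rhat:.4f} (threshold {self.threshold})"
        if self.offenders:
            shown = ", ".join(self.offenders[:10])
            more = "" if len(self.offenders) <= 10 else f" (+{len(self.offenders) - 10} more)"
            msg += f"; offenders: {shown}{more}"
        return msg


def _stacked_monitored(samples: PosteriorSamples) -> tuple[list[str], np.ndarray]:
    scalars = samples.monitored_scalars()
    names = list(scalars)
    return names, np.stack([scalars[n] for n in names])  # (P, m, n)


def convergence_gate(
    samples: PosteriorSamples, threshold: float = 1.1, method: str = "rank"
) -> GateReport:
    """Check R-hat < threshold for every monitored parameter.

    Parameters with zero variance (NaN R-hat) are ignored: a pinned
    parameter carries no evidence of non-convergence.
    """
    names, stacked = _stacked_monitored(samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = rhat(stacked, method=method)
    values = np.atleast_1d(values)
    finite = np.isfinite(values)
    bad = finite & (values >= threshold)
    offenders = [names[i] for i in np.where(bad)[0]]
    max_rhat = float(np.nanmax(values)) if finite.any() else float("nan")
    return GateReport(
        passed=not bad.any(),
        threshold=threshold,
        max_rhat=max_rhat,
        offenders=offenders,
        rhat={n: float(v) for n, v in zip(names, values)},
    )


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size (via arviz), reported but never gated on."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(chains, dtype=float)))


def summarize(
    samples: PosteriorSamples,
    rhat_method: str = "rank",
    include_ess: bool = False,
) -> pd.DataFrame:
    """Posterior median, central 95% credible interval and R-hat per scalar.

    Quantiles use linear interpolation on the pooled draws of all chains, so
    the table is reproducible bit-for-bit for fixed draws.  Derived psi/theta
    rows are on the probability scale.
    """
    scalars = samples.scalar_draws()
    names = list(scalars)
    stacked = np.stack([scalars[n] for n in names])  # (P, m, n)
    pooled = stacked.reshape(len(names), -1)
    med = np.median(pooled, axis=1)
    lo, hi = np.quantile(pooled, [0.025, 0.975], axis=1, method="linear")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rh = np.atleast_1d(rhat(stacked, method=rhat_method))
    out = pd.DataFrame(
        {"median": med, "q2.5": lo, "q97.5": hi, "rhat": rh}, index=pd.Index(names, name="parameter")
    )
    if include_ess:
        out["ess"] = [effective_sample_size(stacked[i]) for i in range(len(names))]
    return out
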