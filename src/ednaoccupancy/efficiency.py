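"""Species detection efficiency E(g, k, J, M) and replicate-allocation ranking.

E(g, k, J, M) is the expected proportion of group-g species detected at
least once in a hypothetical experiment with J filter replicates and M PCR
replicates per filter at annealing temperature k.  For a hypothetical new
species of group g with occurrence probability psi_j on filter j and
detection probability theta at temperature k,

    P(detected) = 1 - prod_j [ 1 - psi_j * (1 - (1 - theta)^M) ],

and E averages this over the community distribution of species: species
effects and species-by-unit interactions are drawn fresh from their
mean-zero normals with the posterior draw's variance components.
Hypothetical filters are exchangeable, so their fixed effects sit at the
constrained mean of zero while fresh filter-by-species interactions are
drawn per filter; the temperature fixed effect is the estimated one at the
requested level, with a fresh temperature-by-species interaction.  This
reconstruction is isolated in :func:`efficiency_for_draw` so it can be
swapped out wholesale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import PosteriorSamples
from .simulate import ParameterSet


def closed_form_efficiency(psi: float, theta: float, J: int, M: int) -> float:
    """E for a degenerate community (all variances zero): every species shares
    the same psi and theta, so E = 1 - (1 - psi * (1 - (1-theta)^M))^J."""
    if J < 0 or M < 0:
        raise ValueError("J and M must be non-negative")
    per_filter = psi * (1.0 - (1.0 - theta) ** M)
    return float(1.0 - (1.0 - per_filter) ** J)


def _community_std_normals(
    rng: np.random.Generator, n_community: int, max_J: int
) -> dict[str, np.ndarray]:
    """Standard-normal community draws, shared across (J, M) grid cells so
    efficiencies are compared under common random numbers."""
    return {
        "alpha_s": rng.standard_normal(n_community),
        "beta_s": rng.standard_normal(n_community),
        "alpha_fs": rng.standard_normal((n_community, max_J)),
        "beta_ts": rng.standard_normal(n_community),
    }


def _efficiency_curves(
    params: ParameterSet,
    g: int,
    k_index: int,
    J_values: np.ndarray,
    M_values: np.ndarray,
    community: dict[str, np.ndarray],
) -> np.ndarray:
    """E over a (J, M) grid for one posterior draw and one community draw set.

    Returns an array of shape (len(J_values), len(M_values)).
    """
    gi = g - 1
    variances = (
        params.sigma_s[gi],
        params.sigma_fs[gi],
        params.tau_s[gi],
        params.tau_ts[gi],
    )
    theta_eta0 = params.beta_g[gi] + params.beta_t[gi, k_index]
    if max(variances) == 0.0:
        psi = float(expit(params.alpha_g[gi]))
        theta = float(expit(theta_eta0))
        return np.array(
            [[closed_form_efficiency(psi, theta, J, M) for M in M_values] for J in J_values],
            dtype=float,
        )
    max_J = int(J_values.max(initial=0))
    psi_j = expit(
        params.alpha_g[gi]
        + params.sigma_s[gi] * community["alpha_s"][:, None]
        + params.sigma_fs[gi] * community["alpha_fs"][:, :max_J]
    )  # (n, max_J)
    theta = expit(
        theta_eta0
        + params.tau_s[gi] * community["beta_s"]
        + params.tau_ts[gi] * community["beta_ts"]
    )  # (n,)
    out = np.empty((len(J_values), len(M_values)), dtype=float)
    for mi, M in enumerate(M_values):
        detect_given_occ = 1.0 - (1.0 - theta) ** M  # (n,)
        miss = 1.0 - psi_j * detect_given_occ[:, None]  # (n, max_J)
        log_miss = np.cumsum(np.log(np.clip(miss, 1e-300, 1.0)), axis=1)
        for ji, J in enumerate(J_values):
            if J == 0 or M == 0:
                out[ji, mi] = 0.0
            else:
                out[ji, mi] = float(np.mean(1.0 - np.exp(log_miss[:, J - 1])))
    return out


def efficiency_for_draw(
    params: ParameterSet,
    g: int,
    k_index: int,
    J: int,
    M: int,
    n_community: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo estimate of E(g, k, J, M) for one parameter draw.

    ``k_index`` is 0-based into the temperature axis.  With all community
    variances zero the closed form is returned exactly (no sampling).
    Designs with J = 0 or M = 0 have efficiency exactly 0.
    """
    if g not in (1, 2):
        raise ValueError("g must be 1 or 2")
    if J < 0 or M < 0 or n_community < 1:
        raise ValueError("J, M must be >= 0 and n_community >= 1")
    if J == 0 or M == 0:
        return 0.0
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    community = _community_std_normals(rng, n_community, J)
    curves = _efficiency_curves(
        params, g, k_index, np.array([J]), np.array([M]), community
    )
    return float(curves[0, 0])


def efficiency_grid(
    samples: PosteriorSamples,
    temperatures: tuple[float, ...] = (58.0, 59.0, 60.0),
    J_values: tuple[int, ...] = (2, 4, 6, 8),
    M_values: tuple[int, ...] = tuple(range(1, 17)),
    n_community: int = 1000,
    seed: int = 0,
    max_draws: int | None = None,
) -> pd.DataFrame:
    """Posterior median and 95% interval of E over a (g, k, J, M) grid.

    One community draw set is generated per posterior draw and shared across
    all (J, M) cells (common random numbers), which makes E monotone in J
    and M within a draw.  ``max_draws`` thins the posterior evenly when set.

    Returns a long-format frame with columns group, temperature_c, J, M,
    median, lo95, hi95; metadata (seed, n_community, n_draws) in ``attrs``.
    """
    temps = np.asarray(samples.temperatures_c, dtype=float)
    k_indices = []
    for t in temperatures:
        hits = np.where(np.isclose(temps, t))[0]
        if hits.size == 0:
            raise ValueError(f"temperature {t} degC not in the fitted levels")
        k_indices.append(int(hits[0]))
    J_arr = np.asarray(sorted(set(J_values)), dtype=int)
    M_arr = np.asarray(sorted(set(M_values)), dtype=int)
    draws = list(samples.iter_draws())
    if max_draws is not None and len(draws) > max_draws:
        idx = np.linspace(0, len(draws) - 1, max_draws).astype(int)
        draws = [draws[i] for i in idx]
    rng = np.random.default_rng(seed)
    max_J = int(J_arr.max(initial=0))
    # E values per draw: (n_draws, n_groups, n_temps, n_J, n_M)
    E = np.empty((len(draws), 2, len(k_indices), len(J_arr), len(M_arr)))
    for di, params in enumerate(draws):
        community = _community_std_normals(rng, n_community, max(max_J, 1))
        for gi, g in enumerate((1, 2)):
            for ki, k_index in enumerate(k_indices):
                E[di, gi, ki] = _efficiency_curves(
                    params, g, k_index, J_arr, M_arr, community
                )
    med = np.median(E, axis=0)
    lo, hi = np.quantile(E, [0.025, 0.975], axis=0, method="linear")
    rows = []
    for gi, g in enumerate((1, 2)):
        for ki, t in enumerate(temperatures):
            for ji, J in enumerate(J_arr):
                for mi, M in enumerate(M_arr):
                    rows.append(
                        (g, float(t), int(J), int(M),
                         med[gi, ki, ji, mi], lo[gi, ki, ji, mi], hi[gi, ki, ji, mi])
                    )
    out = pd.DataFrame(
        rows, columns=["group", "temperature_c", "J", "M", "median", "lo95", "hi95"]
    )
    out.attrs.update(
        {"seed": seed, "n_community": n_community, "n_draws": len(draws)}
    )
    return out


def replicate_tradeoff_report(grid: pd.DataFrame, total_budget: int) -> pd.DataFrame:
    """Rank (J, M) allocations with J*M <= budget by posterior-median E.

    Ties in median E are broken in favour of fewer filter replicates (the
    costlier step to add).  Works on one (group, temperature) slice or on a
    whole grid, ranking within each (group, temperature) combination.
    """
    feasible = grid[(grid["J"] * grid["M"] <= total_budget) & (grid["J"] > 0) & (grid["M"] > 0)]
    if feasible.empty:
        raise ValueError(f"no allocation with J*M <= {total_budget} in the grid")
    ranked = feasible.sort_values(
        ["group", "temperature_c", "median", "J"],
        ascending=[True, True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    ranked["rank"] = ranked.groupby(["group", "temperature_c"]).cumcount() + 1
    return ranked


def plot_efficiency(grid: pd.DataFrame, path) -> None:
    """Line plot of median E vs M per (group, temperature, J), PNG export."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    temps = sorted(grid["temperature_c"].unique())
    fig, axes = plt.subplots(
        2, len(temps), figsize=(4 * len(temps), 7), sharey=True, squeeze=False
    )
    group_names = {1: "cartilaginous", 2: "bony"}
    for gi, g in enumerate((1, 2)):
        for ti, t in enumerate(temps):
            ax = axes[gi][ti]
            sub = grid[(grid["group"] == g) & (grid["temperature_c"] == t)]
            for J, js in sub.groupby("J"):
                js = js.sort_values("M")
                ax.plot(js["M"], js["median"], label=f"J={J}")
                ax.fill_between(js["M"], js["lo95"], js["hi95"], alpha=0.15)
            ax.set_title(f"{group_names[g]}, {t:g} degC")
            ax.set_xlabel("PCR replicates M")
            ax.set_ylim(0, 1.02)
    axes[0][0].set_ylabel("species detection efficiency E")
    axes[1][0].set_ylabel("species detection efficiency E")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
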