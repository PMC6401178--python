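"""Shared fixtures: programmatically generated read-count tables and a
session-scoped small MCMC fit reused by the sampler and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ednaoccupancy as eo
from ednaoccupancy.datasets import SpeciesCatalogue


def make_read_count_table(
    n_species: int = 65,
    n_filters: int = 8,
    n_temperatures: int = 14,
    n_pcr: int = 5,
    n_failed: int = 7,
    seed: int = 0,
    control_rate: float = 0.15,
) -> pd.DataFrame:
    """Raw per-library read counts for a fully crossed replication design.

    Each (filter, temperature) cell carries ``n_pcr`` sample replicates plus
    one negative control (so n_pcr + 1 libraries per cell).  ``n_failed``
    sample replicates, chosen at random, are flagged as failed.
    """
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1:03d}" for i in range(n_species)]
    temps = 54.0 + np.arange(n_temperatures)
    rows = []
    for j in range(1, n_filters + 1):
        for t in temps:
            ctrl = int(rng.poisson(2))
            rows.append(("__control__", j, t, 0, ctrl, True, False))
            for rep in range(1, n_pcr + 1):
                for sp in species:
                    detected = rng.random() < 0.6
                    reads = int(rng.poisson(40)) if detected else int(
                        rng.poisson(control_rate)
                    )
                    rows.append((sp, j, t, rep, reads, False, False))
    df = pd.DataFrame(
        rows,
        columns=[
            "species_id",
            "filter",
            "temperature_c",
            "pcr_rep",
            "reads",
            "is_control",
            "is_failed",
        ],
    )
    # flag whole PCR replicates (all species of one (filter, temp, rep)) failed
    cells = df[~df["is_control"]][["filter", "temperature_c", "pcr_rep"]].drop_duplicates()
    picked = cells.sample(n=n_failed, random_state=seed)
    key = ["filter", "temperature_c", "pcr_rep"]
    failed_idx = df.merge(picked.assign(_f=True), on=key, how="left")["_f"].notna()
    df.loc[failed_idx.to_numpy() & ~df["is_control"].to_numpy(), "is_failed"] = True
    return df


@pytest.fixture(scope="session")
def paper_scale_table() -> pd.DataFrame:
    # 65 observed species of which 62 are in the tank catalogue
    return make_read_count_table()


@pytest.fixture(scope="session")
def tank_catalogue() -> SpeciesCatalogue:
    species = [f"sp{i + 1:03d}" for i in range(62)]
    group = np.r_[np.ones(12, dtype=int), np.full(50, 2, dtype=int)]
    return SpeciesCatalogue(species, group)


@pytest.fixture()
def small_table() -> pd.DataFrame:
    """Hand-sized table: 3 species x 2 filters x 2 temperatures x 5 reps."""
    return make_read_count_table(
        n_species=3, n_filters=2, n_temperatures=2, n_pcr=5, n_failed=2, seed=7
    )


@pytest.fixture()
def small_catalogue() -> SpeciesCatalogue:
    return SpeciesCatalogue(["sp001", "sp002"], np.array([1, 2]))


@pytest.fixture(scope="session")
def small_fit():
    """Scaled-down MCMC fit of a well-specified simulated dataset
    (12 species x 4 filters x 4 temperature levels x 5 PCR replicates)."""
    scenario = eo.paper_scale_scenario(
        seed=3, n_species=12, n_group1=4, n_filters=4, n_temperatures=4
    )
    dataset, truth, z = eo.simulate_dataset(scenario)
    model = eo.OccupancyModel(
        n_chains=3, n_burnin=2500, n_iter=2500, thin=5, seed=7
    ).fit(dataset)
    return {"scenario": scenario, "dataset": dataset, "truth": truth, "model": model}
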