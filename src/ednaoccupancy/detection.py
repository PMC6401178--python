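"""Reduction of per-replicate read counts to detection/non-detection data.

A record is a single PCR library: one (species, filter, temperature, PCR
replicate) with its read count.  Each (filter, temperature) cell additionally
carries exactly one non-template negative control whose read count sets the
detection threshold for every replicate in the cell: a replicate detects a
species when its read count is *strictly greater* than the control's (ties
are non-detections).  Species absent from the tank catalogue are removed
before modelling, as are PCR replicates flagged as failed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import DetectionDataset, SpeciesCatalogue

READ_COLUMNS = (
    "species_id",
    "filter",
    "temperature_c",
    "pcr_rep",
    "reads",
    "is_control",
    "is_failed",
)

CELL = ["filter", "temperature_c"]


def validate_read_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Check column presence and basic invariants; return a typed copy."""
    missing = set(READ_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"read-count table is missing columns: {sorted(missing)}")
    out = table.copy()
    out["species_id"] = out["species_id"].astype(str)
    out["reads"] = out["reads"].astype(int)
    out["is_control"] = out["is_control"].astype(bool)
    out["is_failed"] = out["is_failed"].astype(bool)
    if (out["reads"] < 0).any():
        raise ValueError("read counts must be non-negative")
    controls = out[out["is_control"]]
    n_per_cell = controls.groupby(CELL).size()
    if (n_per_cell > 1).any():
        bad = n_per_cell[n_per_cell > 1].index.tolist()
        raise ValueError(f"more than one negative control in cell(s): {bad}")
    return out


def load_read_counts(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return validate_read_counts(pd.read_csv(path, sep=sep))


def _control_map(table: pd.DataFrame) -> pd.Series:
    """Negative-control read count per (filter, temperature_c) cell."""
    controls = table[table["is_control"]]
    return controls.set_index(CELL)["reads"]


def threshold_detections(
    table: pd.DataFrame, mode: str = "control"
) -> pd.Series:
    """Binary detection indicator for every non-control, non-failed record.

    mode="control": detected iff reads strictly exceed the matched negative
    control of the record's (filter, temperature) cell.  mode="any": detected
    iff reads > 0, ignoring controls (a sensitivity-analysis option; no
    equivalence with the control rule is asserted).

    Returns a Series aligned to the qualifying rows of ``table``.
    """
    if mode not in ("control", "any"):
        raise ValueError(f"unknown thresholding mode: {mode!r}")
    table = validate_read_counts(table)
    samples = table[~table["is_control"] & ~table["is_failed"]]
    if mode == "any":
        return (samples["reads"] > 0).astype(int)
    ctrl = _control_map(table)
    keys = pd.MultiIndex.from_frame(samples[CELL])
    have = keys.isin(ctrl.index)
    if not have.all():
        cell = tuple(samples[CELL].iloc[int(np.argmin(have))])
        raise ValueError(
            f"no matched negative control for cell (filter={cell[0]}, "
            f"temperature_c={cell[1]})"
        )
    thresholds = ctrl.loc[keys].to_numpy()
    return pd.Series(
        (samples["reads"].to_numpy() > thresholds).astype(int), index=samples.index
    )


def filter_to_catalogue(
    table: pd.DataFrame, catalogue: SpeciesCatalogue
) -> pd.DataFrame:
    """Drop records of species absent from the tank catalogue.

    Negative-control records are always kept.  The number of removed species
    is recorded in ``result.attrs["n_species_removed"]``.  Raises if no
    sample record survives (nothing analysable).
    """
    keep = table["species_id"].isin(catalogue.species_ids) | table["is_control"]
    out = table[keep].copy()
    removed = set(table.loc[~table["is_control"], "species_id"]) - set(
        catalogue.species_ids
    )
    if out[~out["is_control"]].empty:
        raise ValueError("no species in the table appears in the catalogue")
    out.attrs["n_species_removed"] = len(removed)
    out.attrs["species_removed"] = sorted(removed)
    return out


def drop_failed_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Remove records of PCR replicates flagged as failed."""
    out = table[~table["is_failed"]].copy()
    out.attrs["n_failed_removed"] = int(table["is_failed"].sum())
    return out


def flag_low_read_replicates(
    table: pd.DataFrame, min_total_reads: int
) -> pd.DataFrame:
    """Optional helper: flag PCR replicates whose total reads fall below a cutoff.

    Failure identification is normally upstream metadata (the ``is_failed``
    column); this helper sets the flag for replicates whose summed reads over
    species are below ``min_total_reads``.  Disabled unless called explicitly.
    """
    out = table.copy()
    samples = out[~out["is_control"]]
    totals = samples.groupby(CELL + ["pcr_rep"])["reads"].transform("sum")
    low = totals < min_total_reads
    out.loc[samples.index[low], "is_failed"] = True
    return out


def collapse_to_dataset(
    table: pd.DataFrame,
    catalogue: SpeciesCatalogue,
    threshold_mode: str = "control",
) -> DetectionDataset:
    """Reduce raw read counts to the binomial detection dataset.

    Applies catalogue filtering, failed-replicate removal and control
    thresholding, then sums detections per (species, filter, temperature)
    cell: x_ijk = detections, M_ijk = usable non-control replicates.  Species
    are indexed in catalogue order; temperatures ascending; cells with no
    usable replicate keep M = 0.
    """
    table = validate_read_counts(table)
    table = filter_to_catalogue(table, catalogue)
    n_removed = table.attrs["n_species_removed"]
    table = drop_failed_replicates(table)
    n_failed = table.attrs["n_failed_removed"]
    indicator = threshold_detections(table, mode=threshold_mode)
    samples = table.loc[indicator.index]

    species_ids = list(catalogue.species_ids)
    filters = np.sort(table["filter"].unique())
    temps = np.sort(table["temperature_c"].unique())
    sp_idx = {s: a for a, s in enumerate(species_ids)}
    f_idx = {f: a for a, f in enumerate(filters)}
    t_idx = {t: a for a, t in enumerate(temps)}

    I, J, K = len(species_ids), len(filters), len(temps)
    x = np.zeros((I, J, K), dtype=int)
    M = np.zeros((I, J, K), dtype=int)
    ii = samples["species_id"].map(sp_idx).to_numpy()
    jj = samples["filter"].map(f_idx).to_numpy()
    kk = samples["temperature_c"].map(t_idx).to_numpy()
    np.add.at(x, (ii, jj, kk), indicator.to_numpy())
    np.add.at(M, (ii, jj, kk), 1)
    if ((x < 0) | (x > M)).any():
        raise RuntimeError("internal error: collapsed x exceeds M")

    return DetectionDataset(
        x=x,
        M=M,
        species_ids=species_ids,
        group=catalogue.group.copy(),
        temperatures_c=temps,
        filter_labels=filters,
        provenance={
            "n_species_removed": int(n_removed),
            "n_failed_replicates_removed": int(n_failed),
            "threshold_mode": threshold_mode,
            "n_records_collapsed": int(len(samples)),
        },
    )


class DetectionDataReducer(BaseEstimator, TransformerMixin):
    """Transformer from a raw read-count table to a :class:`DetectionDataset`.

    Parameters
    ----------
    catalogue
        Tank species catalogue; species outside it are removed.
    threshold_mode
        "control" (reads must strictly exceed the cell's negative control)
        or "any" (any read counts as a detection).
    low_read_cutoff
        If set, additionally flags replicates with total reads below the
        cutoff as failed before reduction.  Off by default.
    """

    def __init__(
        self,
        catalogue: SpeciesCatalogue | None = None,
        threshold_mode: str = "control",
        low_read_cutoff: int | None = None,
    ) -> None:
        self.catalogue = catalogue
        self.threshold_mode = threshold_mode
        self.low_read_cutoff = low_read_cutoff

    def fit(self, X: pd.DataFrame, y=None) -> "DetectionDataReducer":
        validate_read_counts(X)
        if self.catalogue is None:
            raise ValueError("a SpeciesCatalogue is required")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> DetectionDataset:
        if self.low_read_cutoff is not None:
            X = flag_low_read_replicates(X, self.low_read_cutoff)
        dataset = collapse_to_dataset(
            X, self.catalogue, threshold_mode=self.threshold_mode
        )
        self.provenance_ = dataset.provenance
        return dataset


# -- design arithmetic -----------------------------------------------------


def library_design_size(
    n_filters: int = 8, n_pcr_replicates: int = 6, n_temperatures: int = 14
) -> int:
    """Number of PCR library slots in a fully crossed replication design.

    The default corresponds to 8 filter replicates x 6 PCR replicates (one of
    which is a non-template blank) x 14 annealing-temperature levels = 672.
    """
    if min(n_filters, n_pcr_replicates, n_temperatures) < 1:
        raise ValueError("design dimensions must be positive")
    return n_filters * n_pcr_replicates * n_temperatures


def read_partition_percentages(
    n_assigned: int, n_tank: int, n_absent: int
) -> dict[str, float]:
    """Percentages of taxonomically assigned reads from tank vs absent species."""
    if n_tank + n_absent != n_assigned:
        raise ValueError("tank + absent read counts must equal assigned reads")
    if n_assigned <= 0:
        raise ValueError("assigned read count must be positive")
    return {
        "tank_percent": 100.0 * n_tank / n_assigned,
        "absent_percent": 100.0 * n_absent / n_assigned,
    }
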