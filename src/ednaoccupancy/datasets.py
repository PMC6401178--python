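"""Core data containers: the species catalogue and the reduced detection dataset.

The detection dataset holds, for every species i, filter replicate j and
annealing-temperature level k, the number of PCR replicates that detected the
species (``x``) and the number of usable PCR replicates (``M``).  Cells whose
replicates were all discarded keep ``M = 0`` and are skipped by the
likelihood; arrays stay rectangular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CARTILAGINOUS = 1
BONY = 2


@dataclass
class SpeciesCatalogue:
    """Tank species list with group labels (1 = cartilaginous, 2 = bony).

    Species order in the catalogue fixes the species indexing (1..I) of every
    downstream array.
    """

    species_ids: list[str]
    group: np.ndarray  # (I,) int, values in {1, 2}

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        if len(self.species_ids) != len(set(self.species_ids)):
            raise ValueError("species_id values must be unique")
        if self.group.shape != (len(self.species_ids),):
            raise ValueError("group must have one entry per species")
        if not np.isin(self.group, (CARTILAGINOUS, BONY)).all():
            raise ValueError("group labels must be 1 (cartilaginous) or 2 (bony)")

    def __len__(self) -> int:
        return len(self.species_ids)

    def group_of(self, species_id: str) -> int:
        return int(self.group[self.species_ids.index(species_id)])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpeciesCatalogue":
        missing = {"species_id", "group"} - set(df.columns)
        if missing:
            raise ValueError(f"catalogue is missing columns: {sorted(missing)}")
        return cls(df["species_id"].astype(str).tolist(), df["group"].to_numpy())

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesCatalogue":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species_id": self.species_ids, "group": self.group})


@dataclass
class DetectionDataset:
    """Detection counts x_ijk and usable replicate totals M_ijk.

    Arrays are 0-based internally; exported tables carry 1-based filter labels
    and temperatures in degrees Celsius.
    """

    x: np.ndarray  # (I, J, K) int
    M: np.ndarray  # (I, J, K) int
    species_ids: list[str]
    group: np.ndarray  # (I,) int in {1, 2}
    temperatures_c: np.ndarray  # (K,) float, ascending
    filter_labels: np.ndarray | None = None  # (J,) labels, default 1..J
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        self.M = np.asarray(self.M, dtype=int)
        self.group = np.asarray(self.group, dtype=int)
        self.temperatures_c = np.asarray(self.temperatures_c, dtype=float)
        if self.filter_labels is None:
            self.filter_labels = np.arange(1, self.x.shape[1] + 1)
        self.filter_labels = np.asarray(self.filter_labels)
        self.validate()

    # -- shape helpers -----------------------------------------------------
    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return self.x.shape[0]

    @property
    def J(self) -> int:
        return self.x.shape[1]

    @property
    def K(self) -> int:
        return self.x.shape[2]

    @property
    def group_index(self) -> np.ndarray:
        """0-based group index per species (group label minus one)."""
        return self.group - 1

    def validate(self) -> None:
        if self.x.shape != self.M.shape or self.x.ndim != 3:
            raise ValueError("x and M must be 3-d arrays of identical shape")
        if len(self.species_ids) != self.I or self.group.shape != (self.I,):
            raise ValueError("species_ids/group inconsistent with x")
        if self.temperatures_c.shape != (self.K,):
            raise ValueError("temperatures_c inconsistent with x")
        if len(np.unique(self.temperatures_c)) != self.K:
            raise ValueError("temperature map must be injective")
        if (self.M < 0).any():
            raise ValueError("M must be non-negative")
        if ((self.x < 0) | (self.x > self.M)).any():
            raise ValueError("x must satisfy 0 <= x <= M elementwise")
        if not np.isin(self.group, (CARTILAGINOUS, BONY)).all():
            raise ValueError("group labels must be 1 or 2")

    # -- serialisation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: species_id, filter, temperature_c, x, M."""
        i, j, k = np.meshgrid(
            np.arange(self.I), np.arange(self.J), np.arange(self.K), indexing="ij"
        )
        return pd.DataFrame(
            {
                "species_id": np.asarray(self.species_ids)[i.ravel()],
                "filter": np.asarray(self.filter_labels)[j.ravel()],
                "temperature_c": self.temperatures_c[k.ravel()],
                "x": self.x.ravel(),
                "M": self.M.ravel(),
            }
        )

    def save(self, prefix: str | Path) -> list[Path]:
        """Write ``<prefix>.tsv`` (long format) and ``<prefix>.json`` sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tsv = prefix.with_suffix(".tsv")
        self.to_frame().to_csv(tsv, sep="\t", index=False)
        sidecar = {
            "n_species": self.I,
            "n_filters": self.J,
            "n_temperatures": self.K,
            "species_ids": list(self.species_ids),
            "group": self.group.tolist(),
            "temperatures_c": self.temperatures_c.tolist(),
            "filter_labels": np.asarray(self.filter_labels).tolist(),
            "provenance": self.provenance,
        }
        js = prefix.with_suffix(".json")
        js.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
        return [tsv, js]

    @classmethod
    def load(cls, prefix: str | Path) -> "DetectionDataset":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        I, J, K = meta["n_species"], meta["n_filters"], meta["n_temperatures"]
        sp_idx = {s: a for a, s in enumerate(meta["species_ids"])}
        f_idx = {f: a for a, f in enumerate(meta["filter_labels"])}
        t_idx = {t: a for a, t in enumerate(meta["temperatures_c"])}
        x = np.zeros((I, J, K), dtype=int)
        M = np.zeros((I, J, K), dtype=int)
        ii = df["species_id"].astype(str).map(sp_idx).to_numpy()
        jj = df["filter"].map(f_idx).to_numpy()
        kk = df["temperature_c"].astype(float).map(t_idx).to_numpy()
        x[ii, jj, kk] = df["x"].to_numpy()
        M[ii, jj, kk] = df["M"].to_numpy()
        return cls(
            x=x,
            M=M,
            species_ids=meta["species_ids"],
            group=np.asarray(meta["group"]),
            temperatures_c=np.asarray(meta["temperatures_c"]),
            filter_labels=np.asarray(meta["filter_labels"]),
            provenance=meta.get("provenance", {}),
        )
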