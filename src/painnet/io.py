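"""Projection-table and brain-area-catalog I/O.

Connectivity data enter the pipeline as two plain CSV files:

``areas.csv``
    One row per brain area: ``acronym,name,group,x,y,z`` where ``group`` is
    one of the three anatomical divisions (CH cerebrum, BS brain stem, CB
    cerebellum) and ``x,y,z`` are injection coordinates in atlas
    micrometers (or abstract units for synthetic data).

``projections.csv``
    One row per tracing experiment and target:
    ``source,target,hemisphere,experiment_id,volume`` where ``volume`` is
    the normalized projection volume — total segmented axonal signal in the
    target divided by the injection-site volume — and ``hemisphere`` is
    ``ipsi`` or ``contra`` relative to the injection site.

Replicate experiments for a source area are combined by arithmetic
averaging of their normalized volumes, after which the table holds at most
one value per (source, target, hemisphere) triple.  Missing pairs are
treated as zero-strength, not missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "HEMISPHERES",
    "GROUPS",
    "BrainAreaCatalog",
    "ProjectionTable",
    "LateralitySummary",
    "ProjectionFormatError",
    "ProjectionValidationError",
    "read_area_catalog",
    "read_projection_table",
    "write_projection_table",
    "aggregate_experiments",
    "laterality_summary",
]

HEMISPHERES = ("ipsi", "contra")
GROUPS = ("CH", "BS", "CB")

_PROJECTION_COLUMNS = ["source", "target", "hemisphere", "experiment_id", "volume"]
_CATALOG_COLUMNS = ["acronym", "name", "group", "x", "y", "z"]


class ProjectionFormatError(ValueError):
    """The file does not have the expected columns / dialect."""


class ProjectionValidationError(ValueError):
    """The file parsed but violates a data invariant."""


@dataclass
class BrainAreaCatalog:
    """Area metadata: acronym, full name, anatomical group, 3-D coordinate."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CATALOG_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ProjectionFormatError(f"area catalog missing columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)
        if self.frame["acronym"].duplicated().any():
            dupes = sorted(self.frame.loc[self.frame["acronym"].duplicated(), "acronym"])
            raise ProjectionValidationError(f"duplicate acronyms in catalog: {dupes}")
        bad_group = sorted(set(self.frame["group"]) - set(GROUPS))
        if bad_group:
            raise ProjectionValidationError(f"unknown anatomical groups: {bad_group}")
        coords = self.frame[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            bad = self.frame.loc[~np.isfinite(coords).all(axis=1), "acronym"].tolist()
            raise ProjectionValidationError(f"non-finite coordinates for areas: {bad}")

    @classmethod
    def from_csv(cls, path) -> "BrainAreaCatalog":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def acronyms(self) -> list[str]:
        return self.frame["acronym"].tolist()

    def __contains__(self, acronym: str) -> bool:
        return acronym in set(self.frame["acronym"])

    def __len__(self) -> int:
        return len(self.frame)

    def coords(self) -> dict[str, np.ndarray]:
        return {
            row.acronym: np.array([row.x, row.y, row.z], dtype=float)
            for row in self.frame.itertuples()
        }

    def group_of(self, acronym: str) -> str:
        sel = self.frame.loc[self.frame["acronym"] == acronym, "group"]
        if sel.empty:
            raise KeyError(acronym)
        return sel.iloc[0]


@dataclass
class ProjectionTable:
    """Long-form projection records plus the catalog they resolve against.

    ``records`` columns: source, target, hemisphere, experiment_id, volume.
    Extra columns (e.g. a mutant-line tag) are carried through untouched and
    ignored by all computations.
    """

    records: pd.DataFrame
    catalog: BrainAreaCatalog = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _PROJECTION_COLUMNS if c not in self.records.columns]
        if missing:
            raise ProjectionFormatError(f"projection table missing columns: {missing}")
        self.records = self.records.reset_index(drop=True)
        vols = self.records["volume"].to_numpy(dtype=float)
        if (vols < 0).any() or not np.isfinite(vols).all():
            row = int(np.flatnonzero((vols < 0) | ~np.isfinite(vols))[0])
            raise ProjectionValidationError(
                f"row {row}: volume {vols[row]!r} is negative or non-finite"
            )
        bad_hemi = sorted(set(self.records["hemisphere"]) - set(HEMISPHERES))
        if bad_hemi:
            raise ProjectionValidationError(f"unknown hemisphere labels: {bad_hemi}")
        known = set(self.catalog.acronyms)
        areas = set(self.records["source"]) | set(self.records["target"])
        unknown = sorted(areas - known)
        if unknown:
            raise ProjectionValidationError(
                f"acronyms not in catalog: {unknown}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_aggregated(self) -> bool:
        return not self.records.duplicated(["source", "target", "hemisphere"]).any()


class LateralitySummary(NamedTuple):
    ipsi_fraction: float
    contra_fraction: float
    ipsi_contra_volume_ratio: float


def read_projection_table(path, catalog: BrainAreaCatalog) -> ProjectionTable:
    """Read a projections CSV; all validation happens at construction."""
    frame = pd.read_csv(path, dtype={"experiment_id": str})
    frame["experiment_id"] = frame.get("experiment_id", pd.Series(dtype=str)).fillna("")
    return ProjectionTable(frame, catalog)


def write_projection_table(table: ProjectionTable, path) -> None:
    # %.10g keeps the round-trip lossless well past 6 significant digits
    table.records.to_csv(path, index=False, float_format="%.10g")


def aggregate_experiments(table: ProjectionTable) -> ProjectionTable:
    """Average replicate experiments per (source, target, hemisphere).

    Idempotent: aggregating an already aggregated table is the identity (up
    to the cleared experiment_id).  Extra columns are dropped because their
    meaning across replicates is undefined.
    """
    agg = (
        table.records.groupby(["source", "target", "hemisphere"], as_index=False, sort=True)[
            "volume"
        ]
        .mean()
        .assign(experiment_id="")
    )[_PROJECTION_COLUMNS]
    return ProjectionTable(agg, table.catalog)


def laterality_summary(
    table: ProjectionTable, detection_threshold: float = 1e-4
) -> LateralitySummary:
    """Hemisphere balance of the aggregated table.

    Fractions count connections at or above the minimal true-positive level
    (default 1e-4) and sum to one; the volume ratio totals all records with
    no threshold.  A zero contralateral total yields an infinite ratio.
    """
    if len(table) == 0:
        raise ProjectionValidationError("laterality of an empty table is undefined")
    if not table.is_aggregated:
        raise ProjectionValidationError("aggregate the table before summarizing laterality")
    rec = table.records
    above = rec[rec["volume"] >= detection_threshold]
    n_above = len(above)
    if n_above == 0:
        raise ProjectionValidationError(
            f"no connections at or above detection threshold {detection_threshold}"
        )
    n_ipsi = int((above["hemisphere"] == "ipsi").sum())
    ipsi_total = rec.loc[rec["hemisphere"] == "ipsi", "volume"].sum()
    contra_total = rec.loc[rec["hemisphere"] == "contra", "volume"].sum()
    ratio = ipsi_total / contra_total if contra_total > 0 else math.inf
    return LateralitySummary(n_ipsi / n_above, 1.0 - n_ipsi / n_above, float(ratio))


def read_area_catalog(path) -> BrainAreaCatalog:
    return BrainAreaCatalog.from_csv(path)
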