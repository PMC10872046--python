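"""Occurrence preparation: presence gridding, delimitation, effort balancing.

Raw occurrence records (one row per observation) are reduced to
species x cell x period presences on the analysis grid, species without a
southern T1 distribution center are removed, and recording-effort imbalance
between the two periods is corrected by repeatedly subsampling the
second-period presences down to first-period totals within latitudinal
zones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edgeshift._seeds import subseed
from edgeshift.grid import GridSpec

PRESENCE_COLUMNS = ["species_id", "cell_id", "easting_m", "northing_m", "period"]


def grid_presences(
    records: pd.DataFrame,
    spec: GridSpec,
    period_windows: dict[str, tuple[int, int]],
    report: dict | None = None,
) -> pd.DataFrame:
    """Convert records to deduplicated per-period grid-cell presences.

    A record whose year falls inside a period window (inclusive) is
    assigned that period; records outside every window are dropped, as are
    records outside the grid extent (counts go into ``report``).  One
    presence row is kept per (species, cell, period) regardless of record
    multiplicity, with coordinates replaced by the cell centroid.
    """
    df = records.copy()
    year = df["year"].to_numpy()
    period = np.full(len(df), "", dtype=object)
    for label, (y0, y1) in period_windows.items():
        inside = (year >= y0) & (year <= y1)
        period[inside] = label
    df["period"] = period
    n_outside_window = int((period == "").sum())
    df = df[df["period"] != ""]

    cell = spec.cell_index(df["easting_m"].to_numpy(), df["northing_m"].to_numpy())
    n_outside_grid = int((cell == -1).sum())
    df = df.assign(cell_id=cell)[lambda d: d["cell_id"] >= 0]

    pres = df[["species_id", "cell_id", "period"]].drop_duplicates(ignore_index=True)
    cx, cy = spec.cell_centroid(pres["cell_id"].to_numpy())
    pres["easting_m"] = cx
    pres["northing_m"] = cy
    pres = pres[PRESENCE_COLUMNS]
    if report is not None:
        report["records_outside_period_windows"] = n_outside_window
        report["records_outside_grid"] = n_outside_grid
        report["n_presences"] = {
            k: int(v) for k, v in pres["period"].value_counts().items()
        }
    return pres


def filter_southern_species(
    presences: pd.DataFrame,
    northing_threshold: float = 7_000_000.0,
    center: str = "mean",
    report: dict | None = None,
) -> set[str]:
    """Species whose T1 distribution center lies south of the threshold.

    The center point is the unweighted mean (or, optionally, median) of a
    species' T1 presence-cell northings; species with center >= the
    threshold are removed, as are species with no T1 presences (both are
    listed in ``report``).
    """
    if center not in ("mean", "median"):
        raise ValueError(f"unknown center method {center!r}")
    if presences.empty:
        warnings.warn("empty presence table: no species retained", stacklevel=2)
        return set()
    t1 = presences[presences["period"] == "T1"]
    centers = t1.groupby("species_id")["northing_m"].agg(center)
    retained = set(centers.index[centers < northing_threshold])
    all_species = set(presences["species_id"].unique())
    if report is not None:
        report["removed_northern"] = sorted(
            centers.index[centers >= northing_threshold]
        )
        report["removed_no_T1"] = sorted(all_species - set(centers.index))
        report["n_retained"] = len(retained)
    return retained


@dataclass(frozen=True)
class ZonePartition:
    """Contiguous latitudinal zones defined by strictly increasing breaks.

    ``breaks`` holds n_zones + 1 northings covering the study extent; zone i
    is ``[breaks[i], breaks[i+1])`` (the last zone closed above).
    """

    breaks: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breaks) < 2 or np.any(np.diff(self.breaks) <= 0):
            raise ValueError("zone breaks must be strictly increasing, >= 2 values")

    @classmethod
    def equal_width(cls, y_min: float, y_max: float, n_zones: int = 5) -> "ZonePartition":
        return cls(tuple(np.linspace(y_min, y_max, n_zones + 1)))

    @property
    def n_zones(self) -> int:
        return len(self.breaks) - 1

    def zone_of(self, northing) -> np.ndarray:
        """Zone index per northing; -1 outside the partition."""
        y = np.asarray(northing, dtype=float)
        z = np.searchsorted(self.breaks, y, side="right") - 1
        z = np.where(y == self.breaks[-1], self.n_zones - 1, z)  # top edge closed
        return np.where((z >= 0) & (z < self.n_zones), z, -1)


@dataclass
class ReplicateSet:
    """One balanced replicate: T1 plus the zone-subsampled T2 presences."""

    index: int
    presences: pd.DataFrame
    zone_counts: pd.DataFrame  # per zone: n_T1, n_T2_available, n_T2_kept
    seed: int


def balance_effort(
    presences: pd.DataFrame,
    zones: ZonePartition,
    n_replicates: int = 5,
    seed: int = 0,
) -> list[ReplicateSet]:
    """Equalize T1/T2 presence totals per latitudinal zone by subsampling T2.

    Within each zone the T2 presences, pooled across species, are sampled
    without replacement down to the zone's pooled T1 count; T1 is never
    modified and nothing is upsampled (a zone with fewer T2 than T1
    presences keeps all its T2 rows, with a warning).  Repeated
    ``n_replicates`` times with distinct sub-seeds; fully deterministic
    given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    zone = zones.zone_of(presences["northing_m"].to_numpy())
    if np.any(zone == -1):
        raise ValueError("some presences fall outside the zone partition")
    t1 = presences[presences["period"] == "T1"]
    t2 = presences[presences["period"] == "T2"]
    zone_t1 = zone[(presences["period"] == "T1").to_numpy()]
    zone_t2 = zone[(presences["period"] == "T2").to_numpy()]

    counts = []
    for z in range(zones.n_zones):
        n1 = int((zone_t1 == z).sum())
        n2 = int((zone_t2 == z).sum())
        counts.append({"zone": z, "n_T1": n1, "n_T2_available": n2})
        if n2 < n1:
            warnings.warn(
                f"zone {z}: only {n2} T2 presences for {n1} T1 presences; "
                "keeping all T2 (no upsampling)",
                stacklevel=2,
            )

    replicates: list[ReplicateSet] = []
    for r in range(1, n_replicates + 1):
        rep_seed = subseed(seed, f"balance-replicate-{r}")
        rng = np.random.default_rng(rep_seed)
        keep_parts = []
        kept_counts = []
        for z, c in enumerate(counts):
            in_zone = np.flatnonzero(zone_t2 == z)
            k = min(c["n_T1"], c["n_T2_available"])
            chosen = rng.choice(in_zone, size=k, replace=False) if k else in_zone[:0]
            keep_parts.append(np.sort(chosen))
            kept_counts.append({**c, "n_T2_kept": k})
        keep = np.concatenate(keep_parts) if keep_parts else np.array([], dtype=int)
        rep = pd.concat([t1, t2.iloc[keep]], ignore_index=True)
        replicates.append(
            ReplicateSet(
                index=r,
                presences=rep,
                zone_counts=pd.DataFrame(kept_counts),
                seed=rep_seed,
            )
        )
    return replicates


def balance_effort_records(
    records: pd.DataFrame,
    spec: GridSpec,
    period_windows: dict[str, tuple[int, int]],
    zones: ZonePartition,
    n_replicates: int = 5,
    seed: int = 0,
) -> list[ReplicateSet]:
    """Record-level variant: subsample raw T2 records, then grid presences.

    Alternative order of operations to :func:`balance_effort` (which
    subsamples after presence conversion, the default reading).  Each
    replicate's records are converted with :func:`grid_presences`.
    """
    df = records.copy()
    year = df["year"].to_numpy()
    period = np.full(len(df), "", dtype=object)
    for label, (y0, y1) in period_windows.items():
        period[(year >= y0) & (year <= y1)] = label
    df["period"] = period
    df = df[df["period"] != ""].reset_index(drop=True)
    zone = zones.zone_of(df["northing_m"].to_numpy())
    t1_mask = (df["period"] == "T1").to_numpy()
    replicates: list[ReplicateSet] = []
    for r in range(1, n_replicates + 1):
        rep_seed = subseed(seed, f"balance-records-replicate-{r}")
        rng = np.random.default_rng(rep_seed)
        keep = t1_mask.copy()
        kept_counts = []
        for z in range(zones.n_zones):
            n1 = int((t1_mask & (zone == z)).sum())
            t2_idx = np.flatnonzero(~t1_mask & (zone == z))
            k = min(n1, t2_idx.size)
            chosen = rng.choice(t2_idx, size=k, replace=False) if k else t2_idx[:0]
            keep[chosen] = True
            kept_counts.append(
                {"zone": z, "n_T1": n1, "n_T2_available": t2_idx.size, "n_T2_kept": k}
            )
        pres = grid_presences(df[keep], spec, period_windows)
        replicates.append(
            ReplicateSet(
                index=r,
                presences=pres,
                zone_counts=pd.DataFrame(kept_counts),
                seed=rep_seed,
            )
        )
    return replicates
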