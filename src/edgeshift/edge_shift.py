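"""Range-edge shift estimation from per-period presence northings.

The northern range edge is operationalized as the tau-quantile (defaults
0.9 and 0.75) of a species' presence-cell northings.  With time period as a
two-level factor, the quantile-regression fit decomposes into per-period
sample quantiles, so the edge shift is simply the difference of the two
tau-quantiles; uncertainty comes from a stratified percentile bootstrap.

The sample quantile follows the linear-programming vertex convention of
quantile regression: for sorted values y_(1) <= ... <= y_(n), the edge is
y_(n*tau) when n*tau is an integer (lower endpoint of the flat check-loss
minimum) and y_(ceil(n*tau)) otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EdgeEstimate:
    """Per-species edge positions and shift for one tau."""

    species_id: str
    tau: float
    edge_T1_m: float
    edge_T2_m: float
    shift_km: float
    ci_low_km: float
    ci_high_km: float
    n_T1: int
    n_T2: int
    n_replicates: int = 1


def _order_index(n: int, tau: float) -> int:
    """0-based order-statistic index of the tau-quantile minimizer."""
    m = n * tau
    nearest = round(m)
    if abs(m - nearest) < 1e-9 and nearest >= 1:  # n*tau integer: lower endpoint
        return int(nearest) - 1
    return int(np.ceil(m)) - 1


def quantile_edge(northings, tau: float) -> float:
    """Check-loss-minimizing tau-quantile of a sample.

    Returns a minimizer of sum_i rho_tau(y_i - q) with
    rho_tau(u) = u * (tau - 1[u < 0]); when the minimum is an interval the
    lower endpoint is returned.
    """
    y = np.asarray(northings, dtype=float)
    if y.size == 0:
        raise ValueError("quantile_edge requires a non-empty sample")
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    return float(np.sort(y)[_order_index(y.size, tau)])


def estimate_shift(
    presences_T1,
    presences_T2,
    tau: float = 0.9,
    species_id: str = "",
    ci: str = "bootstrap",
    B: int = 1000,
    seed: int = 0,
    min_support: int = 5,
) -> EdgeEstimate:
    """Edge shift (km) between periods with a 95% bootstrap CI.

    The confidence interval is a stratified percentile bootstrap: northings
    are resampled with replacement within each period, the shift recomputed
    ``B`` times, and the 2.5/97.5 percentiles taken (widened, if necessary,
    to contain the point estimate).  ``ci='none'`` skips the bootstrap and
    reports NaN bounds.
    """
    y1 = np.asarray(presences_T1, dtype=float)
    y2 = np.asarray(presences_T2, dtype=float)
    if y1.size < min_support or y2.size < min_support:
        raise ValueError(
            f"support below threshold ({y1.size}, {y2.size}) < {min_support}"
        )
    e1 = quantile_edge(y1, tau)
    e2 = quantile_edge(y2, tau)
    shift_km = (e2 - e1) / 1000.0
    if ci == "none":
        lo = hi = float("nan")
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        i1 = _order_index(y1.size, tau)
        i2 = _order_index(y2.size, tau)
        b1 = np.sort(rng.choice(y1, size=(B, y1.size), replace=True), axis=1)[:, i1]
        b2 = np.sort(rng.choice(y2, size=(B, y2.size), replace=True), axis=1)[:, i2]
        shifts = (b2 - b1) / 1000.0
        lo, hi = np.percentile(shifts, [2.5, 97.5])
        lo = min(float(lo), shift_km)
        hi = max(float(hi), shift_km)
    else:
        raise ValueError(f"unknown CI method {ci!r}")
    return EdgeEstimate(
        species_id=species_id,
        tau=tau,
        edge_T1_m=e1,
        edge_T2_m=e2,
        shift_km=shift_km,
        ci_low_km=lo,
        ci_high_km=hi,
        n_T1=int(y1.size),
        n_T2=int(y2.size),
    )


def average_replicates(estimates: list[EdgeEstimate]) -> EdgeEstimate:
    """Arithmetic mean of replicate estimates (point and CI endpoints)."""
    if not estimates:
        raise ValueError("cannot average an empty replicate list")
    first = estimates[0]
    if any(e.species_id != first.species_id or e.tau != first.tau for e in estimates):
        raise ValueError("replicates must share species and tau")
    mean = lambda attr: float(np.mean([getattr(e, attr) for e in estimates]))
    return replace(
        first,
        edge_T1_m=mean("edge_T1_m"),
        edge_T2_m=mean("edge_T2_m"),
        shift_km=mean("shift_km"),
        ci_low_km=mean("ci_low_km"),
        ci_high_km=mean("ci_high_km"),
        n_T1=int(np.mean([e.n_T1 for e in estimates])),
        n_T2=int(np.mean([e.n_T2 for e in estimates])),
        n_replicates=len(estimates),
    )


def classify_shift(e: EdgeEstimate) -> str:
    """'northward' / 'southward' if the 95% CI excludes zero, else 'none'."""
    if e.ci_low_km > 0:
        return "northward"
    if e.ci_high_km < 0:
        return "southward"
    return "none"


def estimate_shifts_table(
    replicates,
    tau: float = 0.9,
    species: set[str] | None = None,
    ci: str = "bootstrap",
    B: int = 1000,
    seed: int = 0,
    min_support: int = 5,
    report: dict | None = None,
) -> pd.DataFrame:
    """Replicate-averaged edge estimates for every adequately sampled species.

    ``replicates`` is a list of presence tables (or ``ReplicateSet``
    objects); species with fewer than ``min_support`` presences in either
    period of any replicate are skipped and listed in ``report``.
    """
    tables = [getattr(r, "presences", r) for r in replicates]
    if species is None:
        species = set(tables[0]["species_id"].unique())
    skipped: list[str] = []
    rows = []
    for i, sp in enumerate(sorted(species)):
        per_rep: list[EdgeEstimate] = []
        ok = True
        for j, tab in enumerate(tables):
            sub = tab[tab["species_id"] == sp]
            y1 = sub.loc[sub["period"] == "T1", "northing_m"].to_numpy()
            y2 = sub.loc[sub["period"] == "T2", "northing_m"].to_numpy()
            if y1.size < min_support or y2.size < min_support:
                ok = False
                break
            per_rep.append(
                estimate_shift(
                    y1, y2, tau, species_id=sp, ci=ci, B=B,
                    seed=seed + 1009 * i + j, min_support=min_support,
                )
            )
        if not ok:
            skipped.append(sp)
            continue
        e = average_replicates(per_rep)
        rows.append(
            {
                "species_id": e.species_id,
                "tau": e.tau,
                "edge_T1_m": e.edge_T1_m,
                "edge_T2_m": e.edge_T2_m,
                "shift_km": e.shift_km,
                "ci_low_km": e.ci_low_km,
                "ci_high_km": e.ci_high_km,
                "class": classify_shift(e),
                "n_T1": e.n_T1,
                "n_T2": e.n_T2,
                "n_replicates": e.n_replicates,
            }
        )
    if report is not None:
        report["skipped_low_support"] = skipped
    return pd.DataFrame(rows)


def summarize_shifts(
    estimates: pd.DataFrame,
    group_labels: dict[str, str] | None = None,
    midyears: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-group mean shifts and northward speeds, plus an overall row.

    ``midyears`` maps each group to the (T1, T2) mid-years used to convert
    mean shift into speed (km/yr).  The overall mean shift is the
    species-count-weighted mean of the group means; the overall speed is
    the count-weighted mean of group speeds.
    """
    df = estimates.copy()
    if group_labels is not None:
        df["group"] = df["species_id"].map(group_labels)
        if df["group"].isna().any():
            missing = df.loc[df["group"].isna(), "species_id"].tolist()
            raise ValueError(f"species without group label: {missing}")
    elif "group" not in df.columns:
        df["group"] = "all"
    midyears = midyears or {}
    rows = []
    for group, sub in df.groupby("group", sort=True):
        if sub.empty:
            warnings.warn(f"group {group!r} has no species; omitted", stacklevel=2)
            continue
        mean_shift = float(sub["shift_km"].mean())
        row = {"group": group, "n": len(sub), "mean_shift_km": mean_shift}
        if group in midyears:
            m1, m2 = midyears[group]
            if not m2 > m1:
                raise ValueError(f"midyears for {group!r} must satisfy T2 > T1")
            row["span_yr"] = m2 - m1
            row["speed_km_per_yr"] = mean_shift / (m2 - m1)
        rows.append(row)
    out = pd.DataFrame(rows)
    n_total = out["n"].sum()
    overall = {
        "group": "overall",
        "n": int(n_total),
        "mean_shift_km": float((out["mean_shift_km"] * out["n"]).sum() / n_total),
    }
    if "speed_km_per_yr" in out.columns and out["speed_km_per_yr"].notna().all():
        overall["speed_km_per_yr"] = float(
            (out["speed_km_per_yr"] * out["n"]).sum() / n_total
        )
    return pd.concat([out, pd.DataFrame([overall])], ignore_index=True)
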