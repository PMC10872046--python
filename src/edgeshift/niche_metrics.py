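"""Species-level climatic niche metrics from a continent-scale atlas.

For each species, the climate values of its occupied grid cells summarize
the realized niche: the mean (for temperature, the species temperature
index, STI), the SD (absolute niche breadth) and the CV = SD/mean (relative
breadth).  The CV of mean annual temperature divides by the mean expressed
in Kelvin so that it stays positive and scale-meaningful near 0 degC.
Range size is the count of occupied cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

KELVIN_OFFSET = 273.15
VARIABLES = ("MAT", "GDD5", "PREC", "SWC")


def range_size(atlas: pd.DataFrame, species_id: str) -> int:
    """Number of distinct occupied grid cells for a species."""
    occ = atlas.loc[atlas["species_id"] == species_id, "cell_id"]
    if occ.empty:
        raise KeyError(f"species {species_id!r} not present in the atlas")
    return int(occ.nunique())


def niche_stats(
    atlas: pd.DataFrame,
    climate: pd.DataFrame,
    species_id: str,
    variable: str,
    ddof: int = 1,
) -> tuple[float, float, float]:
    """(mean, SD, CV) of one climate variable over a species' occupied cells.

    Cells without a value for the variable are dropped.  SD is the sample
    SD by default (``ddof=1``; set 0 for the population convention).  CV is
    SD divided by the mean, with the mean converted to Kelvin for MAT.
    Species with fewer than two valued cells get NaN SD and CV with a
    warning.
    """
    occ = atlas.loc[atlas["species_id"] == species_id, "cell_id"].drop_duplicates()
    if occ.empty:
        raise KeyError(f"species {species_id!r} not present in the atlas")
    vals = (
        climate.set_index("cell_id")[variable].reindex(occ).dropna().to_numpy(float)
    )
    if vals.size == 0:
        raise ValueError(f"no climate values of {variable!r} for {species_id!r}")
    mean = float(np.mean(vals))
    if vals.size < 2:
        warnings.warn(
            f"species {species_id!r}: single valued cell for {variable!r}; "
            "SD/CV undefined",
            stacklevel=2,
        )
        return mean, float("nan"), float("nan")
    sd = float(np.std(vals, ddof=ddof))
    basis = mean + KELVIN_OFFSET if variable == "MAT" else mean
    cv = sd / basis if basis != 0 else float("nan")
    return mean, sd, float(cv)


def niche_metrics_table(
    atlas: pd.DataFrame,
    climate: pd.DataFrame,
    variables: tuple[str, ...] = VARIABLES,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-species table of mean/sd/cv per variable plus range size."""
    rows = []
    for sp in sorted(atlas["species_id"].unique()):
        row: dict = {"species_id": sp, "range_size": range_size(atlas, sp)}
        for var in variables:
            mean, sd, cv = niche_stats(atlas, climate, sp, var, ddof=ddof)
            row[f"mean_{var}"] = mean
            row[f"sd_{var}"] = sd
            row[f"cv_{var}"] = cv
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_model_table(
    edges: pd.DataFrame,
    niches: pd.DataFrame,
    traits: pd.DataFrame,
    thermal_var: str = "MAT",
    moisture_var: str = "SWC",
    breadth_kind: str = "SD",
    weight_kind: str = "ci_width",
    report: dict | None = None,
) -> pd.DataFrame:
    """One regression row per species: shift, weight, niche metrics, traits.

    The response is ``shift_km``; the regression weight is the inverse of
    the 95% CI width (``weight_kind='ci_half_width'`` uses the half-width
    instead).  ``Tmean``/``Tbreadth`` come from ``thermal_var`` and
    ``Mmean``/``Mbreadth`` from ``moisture_var``, with breadth taken as the
    SD or the CV per ``breadth_kind``.  Species with a non-positive CI
    width or any missing covariate are dropped and reported.
    """
    if breadth_kind not in ("SD", "CV"):
        raise ValueError(f"breadth_kind must be 'SD' or 'CV', got {breadth_kind!r}")
    if thermal_var not in ("MAT", "GDD5"):
        raise ValueError(f"thermal_var must be 'MAT' or 'GDD5', got {thermal_var!r}")
    if moisture_var not in ("SWC", "PREC"):
        raise ValueError(f"moisture_var must be 'SWC' or 'PREC', got {moisture_var!r}")
    b = "sd" if breadth_kind == "SD" else "cv"

    df = edges[["species_id", "shift_km", "ci_low_km", "ci_high_km"]].merge(
        niches, on="species_id", how="inner"
    )
    trait_cols = [c for c in traits.columns if c != "species_id"]
    df = df.merge(traits, on="species_id", how="left")

    width = df["ci_high_km"] - df["ci_low_km"]
    bad_width = width <= 0
    if bad_width.any():
        dropped = df.loc[bad_width, "species_id"].tolist()
        warnings.warn(
            f"dropping {len(dropped)} species with non-positive CI width",
            stacklevel=2,
        )
        if report is not None:
            report["dropped_nonpositive_ci"] = dropped
        df = df[~bad_width]
        width = width[~bad_width]
    scale = 2.0 if weight_kind == "ci_half_width" else 1.0
    if weight_kind not in ("ci_width", "ci_half_width"):
        raise ValueError(f"unknown weight_kind {weight_kind!r}")

    out = pd.DataFrame(
        {
            "species_id": df["species_id"],
            "shift_km": df["shift_km"],
            "weight": scale / width,
            "Tmean": df[f"mean_{thermal_var}"],
            "Tbreadth": df[f"{b}_{thermal_var}"],
            "Mmean": df[f"mean_{moisture_var}"],
            "Mbreadth": df[f"{b}_{moisture_var}"],
            "range_size": df["range_size"],
        }
    )
    for c in trait_cols:
        out[c] = df[c].to_numpy()
    complete = out.notna().all(axis=1)
    if (~complete).any():
        dropped = out.loc[~complete, "species_id"].tolist()
        warnings.warn(
            f"dropping {len(dropped)} species with missing covariates", stacklevel=2
        )
        if report is not None:
            report["dropped_missing_covariates"] = dropped
    return out[complete].reset_index(drop=True)
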