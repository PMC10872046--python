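"""Synthetic occurrence, climate, atlas and trait generators with known truth.

The generators emulate the data situation of a boreal range-shift study:
a ~1,100 km latitudinal study domain gridded at 10 x 10 km, two observation
periods with strongly inflated recording effort in the second, species whose
true northern-edge shifts follow a linear model in (z-scored) climatic-niche
covariates plus Gaussian noise, and a coarse continent-scale climate grid
from which niche metrics are measured.

Everything is deterministic given its seed; identical calls reproduce
identical tables bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edgeshift.grid import GridSpec

CLIMATE_VARS = ("MAT", "GDD5", "PREC", "SWC")


class ConfigurationError(ValueError):
    """Raised for inconsistent generator parameters."""


# ---------------------------------------------------------------------------
# climate grid


@dataclass(frozen=True)
class ClimateGradients:
    """Latitudinal climate gradients plus i.i.d. Gaussian noise.

    ``MAT`` (mean annual temperature, degC) falls linearly with northing at
    ``mat_lapse_per_m`` (default -1 degC / 100 km).  ``GDD5`` (growing degree
    days above 5 degC) is a clamped linear function of MAT,
    ``max(0, gdd5_slope * MAT + gdd5_intercept)``.  ``PREC`` (annual
    precipitation, mm) and ``SWC`` (soil water content, fraction of the
    upper horizon) follow their own linear gradients; SWC is clipped to
    [0, 1] and PREC to >= 0.  Gradients are anchored at the grid's southern
    edge (``y_min``).
    """

    mat_south: float = 5.5
    mat_lapse_per_m: float = -1.0e-5
    mat_noise_sd: float = 0.0
    gdd5_slope: float = 150.0
    gdd5_intercept: float = 500.0
    prec_south: float = 650.0
    prec_slope_per_m: float = -1.0e-4
    prec_noise_sd: float = 0.0
    swc_south: float = 0.25
    swc_slope_per_m: float = 5.0e-8
    swc_noise_sd: float = 0.0


#: Continent-scale defaults: a wide thermal span (about 17 .. -5 degC over
#: 3,000 km) with noisy moisture fields, so species niches of realistic
#: breadth fit inside the grid.
CONTINENT_GRADIENTS = ClimateGradients(
    mat_south=17.0,
    mat_lapse_per_m=-22.0 / 3.0e6,
    mat_noise_sd=0.8,
    prec_south=700.0,
    prec_slope_per_m=-5.0e-5,
    prec_noise_sd=120.0,
    swc_south=0.18,
    swc_slope_per_m=8.0e-8,
    swc_noise_sd=0.06,
)

#: CGRS-like continent grid: 50 x 60 cells of 50 km.
CONTINENT_GRID = GridSpec(0.0, 0.0, 2.5e6, 3.0e6, cell_size=50_000.0)

#: Finnish-style study grid: 20 x 110 cells of 10 km spanning northings
#: 6.6e6 .. 7.7e6 m (an 1,100 km latitudinal gradient).
STUDY_GRID = GridSpec(200_000.0, 6_600_000.0, 400_000.0, 7_700_000.0, 10_000.0)


def simulate_climate_grid(
    spec: GridSpec,
    gradients: ClimateGradients = ClimateGradients(),
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-level climate table with latitudinal gradients and noise.

    Returns one row per grid cell with columns
    ``cell_id, easting_m, northing_m, MAT, GDD5, PREC, SWC``.
    """
    rng = np.random.default_rng(seed)
    cx, cy = spec.centroids()
    dy = cy - spec.y_min
    n = spec.n_cells
    mat = gradients.mat_south + gradients.mat_lapse_per_m * dy
    if gradients.mat_noise_sd > 0:
        mat = mat + rng.normal(0.0, gradients.mat_noise_sd, n)
    gdd5 = np.maximum(0.0, gradients.gdd5_slope * mat + gradients.gdd5_intercept)
    prec = gradients.prec_south + gradients.prec_slope_per_m * dy
    if gradients.prec_noise_sd > 0:
        prec = prec + rng.normal(0.0, gradients.prec_noise_sd, n)
    prec = np.maximum(0.0, prec)
    swc = gradients.swc_south + gradients.swc_slope_per_m * dy
    if gradients.swc_noise_sd > 0:
        swc = swc + rng.normal(0.0, gradients.swc_noise_sd, n)
    swc = np.clip(swc, 0.0, 1.0)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n, dtype=np.int64),
            "easting_m": cx,
            "northing_m": cy,
            "MAT": mat,
            "GDD5": gdd5,
            "PREC": prec,
            "SWC": swc,
        }
    )


# ---------------------------------------------------------------------------
# species pool

#: Uniform ranges for per-species niche means and SDs (true parameters).
DEFAULT_NICHE_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "MAT": {"mean": (2.0, 12.0), "sd": (1.0, 4.0)},
    "SWC": {"mean": (0.2, 0.45), "sd": (0.03, 0.12)},
    "PREC": {"mean": (450.0, 750.0), "sd": (40.0, 120.0)},
}

#: Categorical trait level frequencies (Lepidoptera-style defaults:
#: overwintering stage and voltinism class).
DEFAULT_TRAIT_FREQUENCIES: dict[str, dict[str, float]] = {
    "wintering_mode": {"adult": 0.4, "egg": 0.15, "larva": 0.3, "pupa": 0.15},
    "n_generations_class": {"one_or_less": 0.7, "two_or_more": 0.3},
}

#: Shift model: positive baseline northward shift, narrower thermal niches
#: shifting further north (-30 km per SD-unit of thermal breadth).
DEFAULT_EFFECT_MODEL: dict[str, float] = {"intercept": 30.0, "sd_MAT": -30.0}

_CONTINUOUS_COVARIATES = (
    "mean_MAT",
    "sd_MAT",
    "mean_SWC",
    "sd_SWC",
    "mean_PREC",
    "sd_PREC",
    "body_size",
    "range_size_target",
)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1) if x.size > 1 else 0.0
    centered = x - np.mean(x)
    return centered / sd if sd > 0 else np.zeros_like(centered)


def simulate_species_pool(
    n_species: int,
    niche_distributions: dict | None = None,
    trait_frequencies: dict | None = None,
    effect_model: dict[str, float] | None = None,
    shift_noise_sd: float = 20.0,
    seed: int = 0,
    edge_range: tuple[float, float] = (6.9e6, 7.35e6),
    detection_effort_ratio: float = 3.0,
    body_size_lognorm: tuple[float, float] = (3.0, 0.4),
    range_size_range: tuple[int, int] = (500, 2500),
) -> pd.DataFrame:
    """Draw a species pool with niche parameters, traits and true shifts.

    Each species receives a niche mean and SD per climate variable (uniform
    draws from ``niche_distributions``), categorical traits (multinomial
    draws from ``trait_frequencies``), a lognormal body size, a target
    European range size, a T1 edge northing, and a true shift

    ``true_shift_km = beta_0 + sum_j beta_j * z(covariate_j) + eps``,

    with continuous covariates z-scored across the pool and
    ``eps ~ Normal(0, shift_noise_sd**2)``.  Deterministic given ``seed``.
    """
    if n_species < 1:
        raise ConfigurationError("n_species must be >= 1")
    if shift_noise_sd < 0:
        raise ConfigurationError("shift_noise_sd must be >= 0")
    niche_distributions = niche_distributions or DEFAULT_NICHE_DISTRIBUTIONS
    trait_frequencies = trait_frequencies or DEFAULT_TRAIT_FREQUENCIES
    effect_model = dict(DEFAULT_EFFECT_MODEL if effect_model is None else effect_model)

    for trait, freqs in trait_frequencies.items():
        total = float(sum(freqs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"trait frequencies for {trait!r} sum to {total}, not 1"
            )

    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray | list] = {
        "species_id": [f"sp{i:04d}" for i in range(n_species)]
    }
    for var, dists in niche_distributions.items():
        lo, hi = dists["mean"]
        out[f"mean_{var}"] = rng.uniform(lo, hi, n_species)
        lo, hi = dists["sd"]
        out[f"sd_{var}"] = rng.uniform(lo, hi, n_species)
    for trait, freqs in trait_frequencies.items():
        levels = list(freqs)
        probs = np.array([freqs[l] for l in levels], dtype=float)
        out[trait] = [levels[i] for i in rng.choice(len(levels), n_species, p=probs)]
    mu, sigma = body_size_lognorm
    out["body_size"] = rng.lognormal(mu, sigma, n_species)
    out["range_size_target"] = rng.integers(
        range_size_range[0], range_size_range[1] + 1, n_species
    )
    out["true_edge_T1_m"] = rng.uniform(edge_range[0], edge_range[1], n_species)

    truth = pd.DataFrame(out)
    shift = np.full(n_species, float(effect_model.pop("intercept", 0.0)))
    for key, beta in effect_model.items():
        if key not in truth.columns or key not in _CONTINUOUS_COVARIATES:
            raise ConfigurationError(f"unknown effect-model covariate {key!r}")
        shift = shift + beta * _zscore(truth[key].to_numpy(dtype=float))
    if shift_noise_sd > 0:
        shift = shift + rng.normal(0.0, shift_noise_sd, n_species)
    truth["true_shift_km"] = shift
    truth["detection_effort_ratio"] = float(detection_effort_ratio)
    return truth


# ---------------------------------------------------------------------------
# occurrences


@dataclass(frozen=True)
class EffortSpec:
    """Per-period recording effort.

    ``rate`` is the detection probability of an occupied cell per year.
    ``north_multiplier`` scales the rate across the latitudinal extent: the
    rate at the northern grid edge is ``rate * north_multiplier`` while the
    southern edge keeps ``rate`` (1.0 = spatially uniform effort).  With
    ``n_bands`` set, the gradient is piecewise-constant over that many
    equal-width latitudinal bands (recorder activity organized by region)
    instead of varying continuously; band means match the linear profile's
    endpoints.  Rates are clipped to [0, 1].
    """

    rate: float
    north_multiplier: float = 1.0
    n_bands: int | None = None

    def rate_at(self, northing: np.ndarray, spec: GridSpec) -> np.ndarray:
        frac = (np.asarray(northing, dtype=float) - spec.y_min) / (
            spec.y_max - spec.y_min
        )
        if self.n_bands is not None:
            band = np.clip(
                np.floor(frac * self.n_bands), 0, self.n_bands - 1
            )
            frac = band / max(self.n_bands - 1, 1)
        return np.clip(self.rate * (1.0 + (self.north_multiplier - 1.0) * frac), 0, 1)


def simulate_occurrences(
    truth: pd.DataFrame,
    spec: GridSpec = STUDY_GRID,
    period_windows: dict[str, tuple[int, int]] | None = None,
    effort: dict[str, EffortSpec | float] | None = None,
    occupancy_prob: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Thinned occurrence records south of each species' (moving) edge.

    Per species a single occupancy realization is drawn (each grid cell
    south of the species' northernmost edge is occupied with probability
    ``occupancy_prob``); the T1 support is the occupied cells south of the
    T1 edge and the T2 support those south of
    ``true_edge_T1_m + 1000 * true_shift_km``.  Each occupied cell is then
    detected independently in each year of a period window with the
    period's (possibly latitude-dependent) effort rate; every detection
    yields one record at the cell centroid.

    Species whose edge falls outside the grid extent in either period are
    skipped with a warning and listed in ``df.attrs['skipped_species']``.
    """
    period_windows = period_windows or {"T1": (1992, 1996), "T2": (2013, 2017)}
    if len(period_windows) != 2:
        raise ConfigurationError("exactly two period windows are required")
    (p1, w1), (p2, w2) = period_windows.items()
    if not (w1[1] < w2[0] or w2[1] < w1[0]):
        raise ConfigurationError("period windows must be disjoint")
    effort = effort or {p1: EffortSpec(0.1), p2: EffortSpec(0.3)}
    effort = {
        k: (v if isinstance(v, EffortSpec) else EffortSpec(float(v)))
        for k, v in effort.items()
    }
    for k, e in effort.items():
        if e.rate <= 0:
            raise ConfigurationError(f"effort rate for {k} must be > 0")

    rng = np.random.default_rng(seed)
    cx, cy = spec.centroids()
    rows: list[pd.DataFrame] = []
    skipped: list[str] = []
    for sp in truth.itertuples(index=False):
        e1 = float(sp.true_edge_T1_m)
        e2 = e1 + 1000.0 * float(sp.true_shift_km)
        if not all(spec.y_min < e <= spec.y_max for e in (e1, e2)):
            warnings.warn(
                f"species {sp.species_id}: edge outside grid extent, skipped",
                stacklevel=2,
            )
            skipped.append(sp.species_id)
            continue
        occupied = rng.random(spec.n_cells) < occupancy_prob
        for period, window in period_windows.items():
            edge = e1 if period == p1 else e2
            support = occupied & (cy < edge)
            idx = np.flatnonzero(support)
            if idx.size == 0:
                continue
            years = np.arange(window[0], window[1] + 1)
            p = effort[period].rate_at(cy[idx], spec)
            detected = rng.random((idx.size, years.size)) < p[:, None]
            ci, yi = np.nonzero(detected)
            if ci.size == 0:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "species_id": sp.species_id,
                        "easting_m": cx[idx[ci]],
                        "northing_m": cy[idx[ci]],
                        "year": years[yi],
                    }
                )
            )
    if rows:
        records = pd.concat(rows, ignore_index=True)
    else:
        records = pd.DataFrame(
            columns=["species_id", "easting_m", "northing_m", "year"]
        )
    records.attrs["skipped_species"] = skipped
    return records


# ---------------------------------------------------------------------------
# continent-scale atlas


def simulate_european_atlas(
    truth: pd.DataFrame,
    climate: pd.DataFrame,
    seed: int = 0,
    kernel_vars: tuple[str, ...] = ("MAT", "SWC"),
) -> pd.DataFrame:
    """Continent-scale occupancy consistent with each species' niche.

    For each species, ``range_size_target`` cells are drawn with replacement
    with weights proportional to a Gaussian niche kernel over
    ``kernel_vars`` (centered on the species' true niche mean with its true
    niche SD) and de-duplicated, so the climate values over occupied cells
    approximate the species' stated niche.  Returns ``species_id, cell_id``
    occupancy rows.
    """
    rng = np.random.default_rng(seed)
    values = {v: climate[v].to_numpy(dtype=float) for v in kernel_vars}
    cell_ids = climate["cell_id"].to_numpy()
    frames = []
    for sp in truth.itertuples(index=False):
        logw = np.zeros(len(cell_ids))
        for v in kernel_vars:
            mu = float(getattr(sp, f"mean_{v}"))
            sd = float(getattr(sp, f"sd_{v}"))
            logw -= 0.5 * ((values[v] - mu) / max(sd, 1e-12)) ** 2
        w = np.exp(logw - logw.max())
        w /= w.sum()
        draws = rng.choice(len(cell_ids), size=int(sp.range_size_target), p=w)
        occ = np.unique(cell_ids[draws])
        frames.append(pd.DataFrame({"species_id": sp.species_id, "cell_id": occ}))
    return pd.concat(frames, ignore_index=True)


def traits_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Trait table view of the pool (species_id, traits, body size)."""
    return truth[
        ["species_id", "wintering_mode", "n_generations_class", "body_size"]
    ].copy()
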