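"""Verification experiments: worked examples, oracles, calibration studies.

These routines recompute, from scratch, the quantities that validate the
pipeline: the published-style group-summary arithmetic, the model-selection
replay on printed per-size AIC vectors, exhaustive oracle comparisons for
the quantile and WLS estimators, the effort-bias-removal simulation, the
shift-coefficient recovery study, and bootstrap CI calibration.  They are
shared by the test suite, the analysis drivers and the acceptance script.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import optimize

import edgeshift as es
from edgeshift._seeds import subseed
from edgeshift.edge_shift import estimate_shift, quantile_edge, summarize_shifts
from edgeshift.shift_model import best_subsets, per_size_best, select_final
from edgeshift.synthetic import STUDY_GRID, EffortSpec

# Published group-level inputs: per-taxon mean northern-edge shift of the
# 0.9 quantile (km), species counts, and atlas/period mid-years.
TAXON_MEAN_SHIFTS_KM = {"moth": 24.4, "butterfly": 43.1, "bird": 33.2}
TAXON_COUNTS = {"moth": 239, "butterfly": 57, "bird": 87}
TAXON_MIDYEARS = {
    "moth": (1994.0, 2015.0),
    "butterfly": (1994.0, 2015.0),
    "bird": (1981.5, 2008.0),
}

# Published per-size best-subsets AIC vectors (sizes 1..8) per taxon.
PUBLISHED_PER_SIZE_AICS = {
    "moth": [2911.2071, 2894.5814, 2888.1533, 2887.7337, 2887.3376,
             2888.7340, 2890.3699, 2892.1833],
    "bird": [992.2917, 987.7673, 983.1005, 983.7848, 984.0905,
             985.6845, 987.1365, 989.0148],
    "butterfly": [673.4953, 675.0447, 674.8316, 675.7916, 677.6021,
                  678.9105, 680.8292, 682.8228],
}

PERIODS = {"T1": (1992, 1996), "T2": (2013, 2017)}

MODEL_CANDIDATES = (
    "Tmean", "Tbreadth", "Mmean", "Mbreadth",
    "wintering_mode", "n_generations_class", "body_size", "range_size",
)


def group_summary_from_taxon_means() -> pd.DataFrame:
    """Group summary built from the published taxon means and counts.

    Expands each taxon mean into its species count and summarizes, so the
    overall species-count-weighted mean and the per-taxon speeds come out
    of the summary operation itself.
    """
    rows = [
        {"species_id": f"{g}{i}", "group": g, "shift_km": TAXON_MEAN_SHIFTS_KM[g]}
        for g in TAXON_MEAN_SHIFTS_KM
        for i in range(TAXON_COUNTS[g])
    ]
    return summarize_shifts(pd.DataFrame(rows), midyears=TAXON_MIDYEARS)


def selection_replay() -> dict[str, int]:
    """Chosen model size per taxon from the printed per-size AIC vectors."""
    return {
        taxon: select_final(list(enumerate(aics, start=1)), delta=2.0).size
        for taxon, aics in PUBLISHED_PER_SIZE_AICS.items()
    }


# ---------------------------------------------------------------------------
# estimator oracles


def _check_loss_quantile(values: np.ndarray, tau: float) -> float:
    best_q, best_loss = None, np.inf
    for q in np.sort(np.unique(values)):
        u = values - q
        loss = float(np.sum(u * (tau - (u < 0))))
        if loss < best_loss - 1e-12:
            best_q, best_loss = float(q), loss
    return best_q

def quantile_oracle_agreement(
    max_n: int = 12, alphabet: int = 6, taus: tuple[float, ...] = (0.75, 0.9)
) -> dict:
    """Compare quantile_edge with exhaustive check-loss minimization.

    Enumerates every multiset of sizes 1..max_n over {1..alphabet} (the
    quantile is permutation invariant, so multisets cover all samples) and
    counts agreements with the grid-search oracle.
    """
    checked = mismatches = 0
    for n in range(1, max_n + 1):
        for sample in itertools.combinations_with_replacement(
            range(1, alphabet + 1), n
        ):
            y = np.asarray(sample, dtype=float)
            for tau in taus:
                checked += 1
                if quantile_edge(y, tau) != _check_loss_quantile(y, tau):
                    mismatches += 1
    return {"checked": checked, "mismatches": mismatches,
            "agreement": 1.0 - mismatches / checked}


def wls_oracle_max_gap(n_designs: int = 100, seed: int = 0) -> float:
    """Max coefficient gap between wls_fit and direct loss minimization.

    Fits random small weighted designs both ways: the closed-form QR path
    and BFGS minimization of the weighted squared loss with exact gradient.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_designs):
        n, p = 25, 3
        tab = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)]
        )
        beta = rng.normal(size=p)
        tab["shift_km"] = tab.to_numpy() @ beta + rng.normal(0, 0.5, n)
        tab["weight"] = rng.uniform(0.5, 2.0, n)
        m = es.wls_fit(tab, tuple(f"x{j}" for j in range(p)))
        d = m.design
        loss = lambda b: float(np.sum(d.w * (d.y - d.X @ b) ** 2))
        grad = lambda b: -2 * d.X.T @ (d.w * (d.y - d.X @ b))
        res = optimize.minimize(
            loss, np.zeros(m.k), jac=grad, method="BFGS",
            options={"gtol": 1e-13, "maxiter": 2000},
        )
        worst = max(worst, float(np.max(np.abs(res.x - m.params.to_numpy()))))
    return worst


# ---------------------------------------------------------------------------
# simulation studies

#: Study conditions of the bias-removal experiment: uniform T1 effort,
#: 3x-inflated T2 effort with a coarse (zone-band) south-to-north doubling
#: of recorder activity, no true shifts.
BIAS_EFFORT = {
    "T1": EffortSpec(0.05),
    "T2": EffortSpec(0.1, north_multiplier=2.0, n_bands=5),
}


def bias_removal_experiment(seed: int, n_species: int = 200) -> dict:
    """Mean estimated shift with and without effort balancing, no true shift.

    Simulates zero-shift species under T2 effort inflated 3x with a
    latitudinal gradient, then estimates per-species 0.9-quantile shifts
    (a) after five-replicate zone balancing and (b) on the raw presences.
    Reports each arm's across-species mean shift and the standard error of
    that mean.
    """
    truth = es.simulate_species_pool(
        n_species, effect_model={"intercept": 0.0}, shift_noise_sd=0.0,
        seed=subseed(seed, "bias-pool"),
    )
    occ = es.simulate_occurrences(
        truth, STUDY_GRID, PERIODS, BIAS_EFFORT,
        seed=subseed(seed, "bias-occurrences"),
    )
    pres = es.grid_presences(occ, STUDY_GRID, PERIODS)
    zones = es.ZonePartition.equal_width(STUDY_GRID.y_min, STUDY_GRID.y_max, 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reps = es.balance_effort(pres, zones, 5, seed=subseed(seed, "bias-balance"))
        balanced = es.estimate_shifts_table(reps, tau=0.9, ci="none")
        unbalanced = es.estimate_shifts_table([pres], tau=0.9, ci="none")
    out = {}
    for label, df in (("balanced", balanced), ("unbalanced", unbalanced)):
        mean = float(df["shift_km"].mean())
        se = float(df["shift_km"].std(ddof=1) / np.sqrt(len(df)))
        out[label] = {"mean_km": mean, "se_km": se, "n_species": len(df),
                      "within_1_se_of_zero": bool(abs(mean) <= se)}
    return out


def truth_model_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Regression table built from generator truth (unit weights)."""
    return pd.DataFrame(
        {
            "shift_km": truth["true_shift_km"],
            "weight": 1.0,
            "Tmean": truth["mean_MAT"],
            "Tbreadth": truth["sd_MAT"],
            "Mmean": truth["mean_SWC"],
            "Mbreadth": truth["sd_SWC"],
            "wintering_mode": truth["wintering_mode"],
            "n_generations_class": truth["n_generations_class"],
            "body_size": truth["body_size"],
            "range_size": truth["range_size_target"],
        }
    )


def recovery_experiment(
    seed: int, n_runs: int = 100, n_species: int = 240,
    beta_tbreadth: float = -30.0, noise_sd: float = 20.0,
) -> dict:
    """Recovery of the thermal-niche-breadth effect by best-subsets + AIC.

    Each run draws a species pool whose true shifts follow
    ``30 - 30 * z(thermal breadth) + Normal(0, 20)``, enumerates all 256
    candidate models and applies the parsimony rule; reports how often the
    chosen model includes thermal breadth and the mean recovered
    (standardized) coefficient.
    """
    rng = np.random.default_rng(subseed(seed, "recovery"))
    included = 0
    coefs = []
    for _ in range(n_runs):
        truth = es.simulate_species_pool(
            n_species,
            effect_model={"intercept": 30.0, "sd_MAT": beta_tbreadth},
            shift_noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        tab = truth_model_table(truth)
        cands = best_subsets(tab, MODEL_CANDIDATES)
        sel = select_final(per_size_best(cands), delta=2.0)
        if "Tbreadth" in sel.chosen.predictors:
            included += 1
            coefs.append(float(sel.chosen.model.params["Tbreadth"]))
    return {
        "n_runs": n_runs,
        "selected_fraction": included / n_runs,
        "mean_coefficient": float(np.mean(coefs)) if coefs else float("nan"),
        "true_coefficient": beta_tbreadth,
    }


def coverage_experiment(
    seed: int, n_sims: int = 1000, n: int = 50, B: int = 1000, tau: float = 0.9
) -> dict:
    """Bootstrap CI calibration under the no-shift null.

    Draws both periods' northings from the same continuous uniform
    distribution (n per period) and records how often the 95% bootstrap CI
    for the tau-quantile shift covers the true value zero.
    """
    rng = np.random.default_rng(subseed(seed, "coverage"))
    covered = 0
    for _ in range(n_sims):
        y1 = rng.uniform(0.0, 1e6, n)
        y2 = rng.uniform(0.0, 1e6, n)
        e = estimate_shift(
            y1, y2, tau, ci="bootstrap", B=B, seed=int(rng.integers(2**31))
        )
        if e.ci_low_km <= 0.0 <= e.ci_high_km:
            covered += 1
    return {"n_sims": n_sims, "coverage": covered / n_sims}
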