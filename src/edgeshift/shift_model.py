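"""Weighted regression of range shifts on niche metrics and traits.

Implements the full model-selection protocol: weighted least squares with
z-scored continuous covariates and treatment-coded factors, exhaustive
enumeration of all predictor subsets (factors enter as blocks), a
parsimony rule that only accepts a larger model if its AIC is at least
``delta`` (default 2) units below the smaller candidates, drop-one tables,
residual/collinearity/influence diagnostics, and prediction profiles on
the original covariate scale.

Conventions match common statistical practice for weighted ``lm``-style
fits: the Gaussian log-likelihood is

    llf = 0.5 * (sum(log w_i) - n * (log 2*pi + 1 + log(RSS_w / n)))

with RSS_w the weighted residual sum of squares, and the AIC counts the
error variance as an estimated parameter, ``AIC = -2*llf + 2*(k + 1)``
where ``k`` is the number of regression coefficients including the
intercept.  Note that this log-likelihood is invariant under rescaling all
weights by a constant, so coefficients, R-squared and AIC are too.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the aliased columns."""


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _Design:
    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    names: list[str]  # per column, 'Intercept' first
    blocks: dict[str, list[int]]  # predictor -> column indices
    cont_stats: dict[str, tuple[float, float]]  # predictor -> (mean, sd)
    cat_levels: dict[str, list[str]]  # predictor -> level order (ref first)


def _is_continuous(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col)


def _build_design(
    table: pd.DataFrame,
    predictors: tuple[str, ...],
    response: str,
    weights: str | None,
    reference_levels: dict[str, list[str]] | None,
    standardize: bool = True,
) -> _Design:
    reference_levels = reference_levels or {}
    y = table[response].to_numpy(dtype=float)
    w = (
        table[weights].to_numpy(dtype=float)
        if weights is not None
        else np.ones(len(table))
    )
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    cols = [np.ones(len(table))]
    names = ["Intercept"]
    blocks: dict[str, list[int]] = {}
    cont_stats: dict[str, tuple[float, float]] = {}
    cat_levels: dict[str, list[str]] = {}
    for p in predictors:
        col = table[p]
        if _is_continuous(col):
            x = col.to_numpy(dtype=float)
            mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
            if sd == 0:
                raise ValueError(f"continuous predictor {p!r} has zero variance")
            cont_stats[p] = (mean, sd)
            cols.append((x - mean) / sd if standardize else x)
            blocks[p] = [len(names)]
            names.append(p)
        else:
            if p in reference_levels:
                levels = list(reference_levels[p])
                observed = set(col.astype(str))
                if observed - set(levels):
                    raise ValueError(
                        f"levels {observed - set(levels)} of {p!r} missing from "
                        "declared order"
                    )
            else:
                levels = sorted(col.astype(str).unique())
            cat_levels[p] = levels
            idxs = []
            for level in levels[1:]:
                cols.append((col.astype(str) == level).to_numpy(dtype=float))
                idxs.append(len(names))
                names.append(f"{p}[{level}]")
            blocks[p] = idxs
    X = np.column_stack(cols)
    return _Design(X, y, w, names, blocks, cont_stats, cat_levels)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedModel:
    """A weighted least-squares fit with the full criterion family."""

    predictors: tuple[str, ...]
    response: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n: int
    k: int  # estimated regression coefficients incl. intercept
    loglik: float
    aic: float
    r2: float
    adj_r2: float
    pred_r2: float
    rss_w: float
    tss_w: float
    residuals: np.ndarray
    fitted: np.ndarray
    leverage: np.ndarray
    weights: np.ndarray
    design: _Design = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    weights_col: str | None = None
    reference_levels: dict | None = None


def _aliased_columns(Xw: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(Xw)
    tol = np.abs(R).max() * max(Xw.shape) * np.finfo(float).eps
    return [names[j] for j in range(Xw.shape[1]) if abs(R[j, j]) <= tol]


def _fit_design(
    d: _Design,
    predictors: tuple[str, ...],
    response: str,
    data: pd.DataFrame,
    weights_col: str | None,
    reference_levels: dict | None,
) -> FittedModel:
    n, k = d.X.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    sw = np.sqrt(d.w)
    Xw = d.X * sw[:, None]
    yw = d.y * sw
    Q, R = np.linalg.qr(Xw)
    if np.linalg.matrix_rank(Xw) < k:
        raise RankDeficientError(
            f"rank-deficient design; aliased columns: {_aliased_columns(Xw, d.names)}"
        )
    beta = np.linalg.solve(R, Q.T @ yw)
    fitted = d.X @ beta
    resid = d.y - fitted
    rss_w = float(np.sum(d.w * resid**2))
    ybar_w = float(np.sum(d.w * d.y) / np.sum(d.w))
    tss_w = float(np.sum(d.w * (d.y - ybar_w) ** 2))
    r2 = 1.0 - rss_w / tss_w if tss_w > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    leverage = np.sum(Q**2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        press_w = float(np.sum(d.w * (resid / (1.0 - leverage)) ** 2))
        pred_r2 = 1.0 - press_w / tss_w if tss_w > 0 else 0.0
        loglik = 0.5 * (
            np.sum(np.log(d.w)) - n * (np.log(2 * np.pi) + 1 + np.log(rss_w / n))
        )
    aic = -2.0 * loglik + 2.0 * (k + 1)
    sigma2 = rss_w / (n - k)
    Rinv = np.linalg.solve(R, np.eye(k))
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)
    idx = pd.Index(d.names)
    return FittedModel(
        predictors=predictors,
        response=response,
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        n=n,
        k=k,
        loglik=float(loglik),
        aic=float(aic),
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        rss_w=rss_w,
        tss_w=tss_w,
        residuals=resid,
        fitted=fitted,
        leverage=leverage,
        weights=d.w,
        design=d,
        data=data,
        weights_col=weights_col,
        reference_levels=reference_levels,
    )


def wls_fit(
    table: pd.DataFrame,
    predictors,
    response: str = "shift_km",
    weights: str | None = "weight",
    reference_levels: dict[str, list[str]] | None = None,
    standardize: bool = True,
) -> FittedModel:
    """Weighted least squares of ``response`` on the given predictors.

    Continuous predictors are z-scored (sample SD) before fitting;
    categorical predictors are treatment-coded against the first level of
    the declared order in ``reference_levels`` (alphabetical otherwise).
    ``weights=None`` fits with unit weights.
    """
    predictors = tuple(predictors)
    if weights is not None and weights not in table.columns:
        raise KeyError(f"weight column {weights!r} not in table")
    d = _build_design(table, predictors, response, weights, reference_levels,
                      standardize)
    return _fit_design(d, predictors, response, table, weights, reference_levels)


# ---------------------------------------------------------------------------
# best subsets + selection


@dataclass
class CandidateModel:
    predictors: tuple[str, ...]
    size: int
    model: FittedModel | None
    error: str | None = None
    best_in_size: bool = False

    @property
    def aic(self) -> float:
        return self.model.aic if self.model is not None else float("inf")

    @property
    def r2(self) -> float:
        return self.model.r2 if self.model is not None else float("-inf")


def best_subsets(
    table: pd.DataFrame,
    candidates,
    response: str = "shift_km",
    weights: str | None = "weight",
    reference_levels: dict[str, list[str]] | None = None,
) -> list[CandidateModel]:
    """Fit one weighted model per predictor subset (2^p in total).

    Multi-level factors enter or leave as blocks.  The intercept-only model
    (size 0) is included.  Subsets whose fit fails are recorded with the
    error and enumeration continues.  Within each size the best model by
    R-squared is flagged ``best_in_size``.
    """
    candidates = tuple(candidates)
    full = _build_design(table, candidates, response, weights, reference_levels)
    out: list[CandidateModel] = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            cols = [0] + [j for p in subset for j in full.blocks[p]]
            sub = _Design(
                X=full.X[:, cols],
                y=full.y,
                w=full.w,
                names=[full.names[j] for j in cols],
                blocks={p: list(range(*_span(full, subset, p))) for p in subset},
                cont_stats={p: full.cont_stats[p] for p in subset
                            if p in full.cont_stats},
                cat_levels={p: full.cat_levels[p] for p in subset
                            if p in full.cat_levels},
            )
            try:
                m = _fit_design(sub, subset, response, table, weights,
                                reference_levels)
                out.append(CandidateModel(subset, size, m))
            except (ValueError, np.linalg.LinAlgError) as exc:
                out.append(CandidateModel(subset, size, None, error=str(exc)))
    for size in range(len(candidates) + 1):
        in_size = [c for c in out if c.size == size and c.model is not None]
        if in_size:
            max(in_size, key=lambda c: c.r2).best_in_size = True
    return out


def _span(full: _Design, subset: tuple[str, ...], pred: str) -> tuple[int, int]:
    """Column index span of ``pred`` inside the subset design (after slicing)."""
    start = 1
    for p in subset:
        width = len(full.blocks[p])
        if p == pred:
            return start, start + width
        start += width
    raise KeyError(pred)


def per_size_best(candidates: list[CandidateModel]) -> list[CandidateModel]:
    """The flagged best model per non-empty subset size, ordered by size."""
    return sorted(
        (c for c in candidates if c.best_in_size and c.size >= 1),
        key=lambda c: c.size,
    )


@dataclass
class SelectionResult:
    chosen: object
    size: int
    aic: float
    delta: float
    trace: pd.DataFrame  # size, aic, delta_aic, chosen flag


def _size_aic(item) -> tuple[int, float]:
    if isinstance(item, tuple) and len(item) == 2:
        return int(item[0]), float(item[1])
    return int(item.size), float(item.aic)


def select_final(per_size_bests, delta: float = 2.0) -> SelectionResult:
    """Parsimony rule: smallest model within ``delta`` AIC of the minimum.

    Given the best model per subset size, the chosen model is the one with
    the fewest predictors whose AIC is at most ``min(AIC) + delta``; a
    larger model is only preferred when its AIC is more than ``delta``
    units lower than every smaller candidate.  Size ties break toward the
    lower AIC.
    """
    items = list(per_size_bests)
    if not items:
        raise ValueError("empty candidate list")
    sizes_aics = [_size_aic(it) for it in items]
    if not all(np.isfinite(a) for _, a in sizes_aics):
        raise ValueError("non-finite AIC among candidates")
    min_aic = min(a for _, a in sizes_aics)
    eligible = [
        (s, a, it) for (s, a), it in zip(sizes_aics, items) if a <= min_aic + delta
    ]
    s, a, chosen = min(eligible, key=lambda t: (t[0], t[1]))
    trace = pd.DataFrame(
        {
            "size": [s_ for s_, _ in sizes_aics],
            "aic": [a_ for _, a_ in sizes_aics],
            "delta_aic": [a_ - min_aic for _, a_ in sizes_aics],
            "chosen": [it is chosen for it in items],
        }
    )
    return SelectionResult(chosen=chosen, size=s, aic=a, delta=delta, trace=trace)


# ---------------------------------------------------------------------------
# drop1, diagnostics, profiles


def drop1(model: FittedModel) -> pd.DataFrame:
    """Single-term deletions: ddf, increase in weighted RSS, RSS, AIC.

    Each predictor (a factor as a block) is removed in turn and the model
    refitted on the same rows; the table reports the lost degrees of
    freedom, the increase in weighted residual sum of squares, the reduced
    model's RSS and its AIC (same likelihood convention as the full fit).
    The first row is the unchanged model (``<none>``).
    """
    if not model.predictors:
        raise ValueError("drop1 requires a model with at least one predictor")
    rows = [
        {"dropped": "<none>", "ddf": 0, "delta_ss": np.nan,
         "rss": model.rss_w, "aic": model.aic}
    ]
    for p in model.predictors:
        reduced = wls_fit(
            model.data,
            tuple(q for q in model.predictors if q != p),
            response=model.response,
            weights=model.weights_col,
            reference_levels=model.reference_levels,
        )
        rows.append(
            {
                "dropped": p,
                "ddf": model.k - reduced.k,
                "delta_ss": reduced.rss_w - model.rss_w,
                "rss": reduced.rss_w,
                "aic": reduced.aic,
            }
        )
    return pd.DataFrame(rows)


def diagnostics(model: FittedModel, cooks_flag_factor: float = 4.0) -> dict:
    """Residual, collinearity and influence checks for a fitted model.

    Returns Shapiro-Wilk on the weighted residuals, a Breusch-Pagan
    heteroscedasticity test, generalized variance inflation factors per
    predictor block (determinant formula on the correlation matrix of the
    non-intercept design columns), and Cook's distances with rows flagged
    above ``cooks_flag_factor / n``.
    """
    n, k = model.n, model.k
    if n < 3:
        warnings.warn("diagnostics skipped: fewer than 3 observations", stacklevel=2)
        return {"skipped": True}
    ew = np.sqrt(model.weights) * model.residuals
    sh_stat, sh_p = stats.shapiro(ew)
    from statsmodels.stats.diagnostic import het_breuschpagan

    if k > 1:
        bp_stat, bp_p, _, _ = het_breuschpagan(ew, model.design.X)
    else:
        bp_stat, bp_p = float("nan"), float("nan")

    gvif: dict[str, float] = {}
    nonint = model.design.X[:, 1:]
    if nonint.shape[1] >= 1 and len(model.predictors) >= 1:
        if nonint.shape[1] == 1 or len(model.predictors) == 1:
            gvif = {p: 1.0 for p in model.predictors}
        else:
            corr = np.corrcoef(nonint, rowvar=False)
            det_all = np.linalg.det(corr)
            for p in model.predictors:
                idx = [j - 1 for j in model.design.blocks[p]]
                other = [j for j in range(nonint.shape[1]) if j not in idx]
                det_b = np.linalg.det(corr[np.ix_(idx, idx)])
                det_o = np.linalg.det(corr[np.ix_(other, other)])
                gvif[p] = float(det_b * det_o / det_all)

    sigma2 = model.rss_w / (n - k)
    h = model.leverage
    with np.errstate(divide="ignore", invalid="ignore"):
        cooks = (ew**2 * h) / (k * sigma2 * (1.0 - h) ** 2)
    threshold = cooks_flag_factor / n
    return {
        "shapiro": {"statistic": float(sh_stat), "pvalue": float(sh_p)},
        "breusch_pagan": {"statistic": float(bp_stat), "pvalue": float(bp_p)},
        "gvif": gvif,
        "cooks_distance": cooks,
        "cooks_threshold": threshold,
        "influential": np.flatnonzero(cooks > threshold).tolist(),
    }


def predict_profile(
    model: FittedModel, focus_variable: str, n_points: int = 100
) -> pd.DataFrame:
    """Predicted response along one continuous covariate.

    The focus variable runs over a grid from its observed minimum to
    maximum (original units) while every other continuous covariate is held
    at its mean; one curve is produced per combination of levels of the
    categorical predictors in the model.
    """
    if focus_variable not in model.design.cont_stats:
        raise ValueError(
            f"{focus_variable!r} is not a continuous predictor of this model"
        )
    mean, sd = model.design.cont_stats[focus_variable]
    raw = model.data[focus_variable].to_numpy(dtype=float)
    grid = np.linspace(raw.min(), raw.max(), n_points)
    zgrid = (grid - mean) / sd

    cat_preds = [p for p in model.predictors if p in model.design.cat_levels]
    combos = list(
        itertools.product(*[model.design.cat_levels[p] for p in cat_preds])
    ) or [()]
    frames = []
    for combo in combos:
        X = np.zeros((n_points, model.k))
        X[:, 0] = 1.0
        X[:, model.design.blocks[focus_variable][0]] = zgrid
        for p, level in zip(cat_preds, combo):
            levels = model.design.cat_levels[p]
            if level != levels[0]:
                col = model.design.blocks[p][levels.index(level) - 1]
                X[:, col] = 1.0
        pred = X @ model.params.to_numpy()
        frame = pd.DataFrame({focus_variable: grid, "predicted": pred})
        for p, level in zip(cat_preds, combo):
            frame[p] = level
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
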