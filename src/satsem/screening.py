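"""Classical-test-theory item screening for ordinal satisfaction surveys.

Eight criteria, each yielding a per-item flag (a raised flag marks the item
as a deletion candidate):

* floor / ceiling effect: >= 20% of observed responses at the scale
  minimum / maximum;
* extreme-group t-test: no significant difference (Welch, alpha = 0.05)
  on the item between the top-27% and bottom-27% respondents ranked by
  total score;
* item-dimension correlation < 0.6 (Pearson, self-inclusive dimension
  total by default);
* item-total correlation < 0.4;
* Cronbach's alpha: removing the item raises its dimension's alpha by
  more than a configurable margin (default +0.01);
* stepwise regression (forward entry p < 0.05, backward removal p > 0.10)
  of the dimension total on its items: items never entering are flagged;
* exploratory factor analysis (principal-axis + varimax): maximum
  absolute rotated loading < 0.4.

Missing data are handled listwise within each computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model_spec import ModelDefinition
from .synthetic import SurveyDataset

__all__ = [
    "floor_ceiling",
    "extreme_group_ttest",
    "item_correlations",
    "cronbach_alpha",
    "alpha_if_deleted",
    "stepwise_select",
    "stepwise_flags",
    "principal_axis_factoring",
    "varimax",
    "efa_flags",
    "ctt_flag_table",
]


# ---------------------------------------------------------------------------
# Sensitivity criteria
# ---------------------------------------------------------------------------

def floor_ceiling(d: SurveyDataset, item: str, threshold: float = 0.20):
    """Proportions of observed responses at the scale bounds.

    Returns (floor_proportion, ceiling_proportion, floor_flag, ceiling_flag);
    a flag is raised at proportion >= `threshold`.
    """
    col = d.responses[item].dropna()
    if col.empty:
        raise ValueError(f"item {item!r} has no observed responses")
    lo, hi = d.scale
    p_floor = float((col == lo).mean())
    p_ceil = float((col == hi).mean())
    return p_floor, p_ceil, p_floor >= threshold, p_ceil >= threshold


def reverse_keyed_latents(m: ModelDefinition) -> set:
    """First-order latents hypothesized to oppose the satisfaction core:
    any construct touched by a negative-sign structural path (e.g. public
    complaints).  Their items are reverse-scored before totals are formed."""
    out = set()
    for p in m.paths:
        if p.hypothesized_sign < 0:
            out.add(p.source if m.latent(p.source).role != "endogenous"
                    else p.target)
    return out


def keyed_dataset(d: SurveyDataset, m: ModelDefinition) -> SurveyDataset:
    """Copy of the dataset with reverse-keyed items flipped
    (x -> min + max - x) so that all items point toward satisfaction."""
    rev = reverse_keyed_latents(m)
    if not rev:
        return d
    lo, hi = d.scale
    resp = d.responses.copy()
    for lv_name in rev:
        for it in m.latent(lv_name).indicators:
            if it in resp.columns:
                resp[it] = lo + hi - resp[it]
    return SurveyDataset(responses=resp, group=d.group,
                         true_latent_scores=d.true_latent_scores,
                         scale=d.scale)


def total_scores(d: SurveyDataset, items=None) -> pd.Series:
    """Listwise total score: row sums over `items` for rows with every
    one of them observed (NaN elsewhere)."""
    sub = d.responses if items is None else d.responses[list(items)]
    complete = sub.notna().all(axis=1)
    out = sub.sum(axis=1)
    out[~complete] = np.nan
    return out


def extreme_group_ttest(d: SurveyDataset, item: str, totals: pd.Series = None,
                        share: float = 0.27, alpha: float = 0.05):
    """Welch t-test of the item between the top and bottom `share`
    respondents ranked by total score.

    The flag is raised when the groups do NOT differ (p > alpha), i.e.
    the item fails to discriminate extreme satisfaction groups.  Returns
    (t, p, flag, note); degenerate zero-variance groups raise the flag
    with a "degenerate" note.
    """
    if totals is None:
        totals = total_scores(d)
    valid = d.responses[item].notna() & totals.notna()
    x = d.responses[item][valid].to_numpy(dtype=float)
    t_ = totals[valid].to_numpy(dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("too few respondents for extreme-group comparison")
    k = int(np.ceil(share * n))
    order = np.argsort(t_, kind="stable")
    low, high = x[order[:k]], x[order[-k:]]
    if low.std(ddof=1) == 0 and high.std(ddof=1) == 0:
        return np.nan, np.nan, True, "degenerate"
    t_stat, p = stats.ttest_ind(high, low, equal_var=False)
    return float(t_stat), float(p), bool(p > alpha), ""


# ---------------------------------------------------------------------------
# Correlation criteria
# ---------------------------------------------------------------------------

def item_correlations(d: SurveyDataset, item: str, m: ModelDefinition,
                      corrected: bool = False,
                      dim_threshold: float = 0.6, total_threshold: float = 0.4):
    """Pearson correlations of the item with its dimension total and the
    all-item total.

    `corrected=True` excludes the item from its dimension total (SPSS
    "corrected item-total" convention); the default is self-inclusive.
    Returns (r_dimension, r_total, dim_flag, total_flag).
    """
    dim = m.first_order_of_item(item)
    dim_items = list(m.latent(dim).indicators)
    if corrected:
        dim_items = [i for i in dim_items if i != item]
    x = d.responses[item]
    if x.std() == 0 or x.dropna().nunique() < 2:
        raise ValueError(f"item {item!r} has zero variance")

    def _corr(target_items):
        if not target_items:
            return np.nan
        tot = total_scores(d, target_items)
        valid = x.notna() & tot.notna()
        if valid.sum() < 3 or tot[valid].std() == 0:
            return np.nan
        return float(np.corrcoef(x[valid], tot[valid])[0, 1])

    r_dim = 1.0 if (not corrected and dim_items == [item]) else _corr(dim_items)
    r_tot = _corr(m.all_indicators)
    return (r_dim, r_tot,
            bool(r_dim < dim_threshold) if np.isfinite(r_dim) else None,
            bool(r_tot < total_threshold) if np.isfinite(r_tot) else None)


# ---------------------------------------------------------------------------
# Internal consistency
# ---------------------------------------------------------------------------

def cronbach_alpha(items: pd.DataFrame) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / variance of total),
    computed on listwise-complete rows."""
    X = items.dropna().to_numpy(dtype=float)
    k = X.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def alpha_if_deleted(d: SurveyDataset, m: ModelDefinition,
                     margin: float = 0.01) -> pd.DataFrame:
    """Per item: its dimension's alpha, alpha with the item removed, and a
    flag when removal raises alpha by more than `margin`.  Items in
    dimensions with fewer than 3 items get a None flag (removal leaves a
    single item, so alpha-if-deleted is undefined)."""
    rows = []
    for lv in m.latents:
        if lv.order != "first":
            continue
        its = list(lv.indicators)
        a_full = cronbach_alpha(d.responses[its]) if len(its) >= 2 else np.nan
        for it in its:
            if len(its) < 3:
                rows.append({"item": it, "alpha_dimension": a_full,
                             "alpha_without": np.nan, "alpha_flag": None})
                continue
            rest = [j for j in its if j != it]
            a_wo = cronbach_alpha(d.responses[rest])
            rows.append({"item": it, "alpha_dimension": a_full,
                         "alpha_without": a_wo,
                         "alpha_flag": bool(a_wo - a_full > margin)})
    return pd.DataFrame(rows).set_index("item")


# ---------------------------------------------------------------------------
# Stepwise regression
# ---------------------------------------------------------------------------

def stepwise_select(y: pd.Series, X: pd.DataFrame,
                    sle: float = 0.05, sls: float = 0.10) -> list:
    """Forward-entry / backward-removal stepwise OLS.

    At each step the candidate with the smallest entry p-value below `sle`
    enters (ties by column order); entered variables with removal p above
    `sls` are dropped.  Candidates whose entry test is undefined (perfect
    fit already reached, or zero partial variance) cannot enter.
    Returns the selected column names in entry order.
    """
    import statsmodels.api as sm

    frame = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    yv = frame["__y__"]
    Xv = frame[X.columns]
    y_var = float(yv.var(ddof=1))
    selected: list = []
    while True:
        changed = False
        # stop entry once the fit is numerically saturated (residual
        # variance at rounding level) — nothing real is left to explain
        if selected:
            resid = sm.OLS(yv, sm.add_constant(Xv[selected])).fit().resid
            if float(resid.var(ddof=0)) < 1e-10 * max(y_var, 1e-300):
                break
        # forward
        best_p, best_c = None, None
        for c in Xv.columns:
            if c in selected:
                continue
            design = sm.add_constant(Xv[selected + [c]])
            try:
                fit = sm.OLS(yv, design).fit()
                p = fit.pvalues[c]
            except Exception:
                continue
            if not np.isfinite(p):
                continue
            if p < sle and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is not None:
            selected.append(best_c)
            changed = True
        # backward
        while len(selected) > 0:
            design = sm.add_constant(Xv[selected])
            fit = sm.OLS(yv, design).fit()
            pvals = fit.pvalues[selected]
            worst = pvals.idxmax()
            if np.isfinite(pvals[worst]) and pvals[worst] > sls:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return selected


def stepwise_flags(d: SurveyDataset, m: ModelDefinition,
                   sle: float = 0.05, sls: float = 0.10,
                   dependent_items: dict = None) -> pd.Series:
    """Per-dimension stepwise screening: dependent = the dimension's total
    score, candidates = its items; items never entering the final model
    are flagged.

    `dependent_items` optionally maps a dimension name to the item subset
    defining its total (default: all of its items, the self-inclusive
    convention).  Single-item dimensions are never flagged.
    """
    flags = {}
    dependent_items = dependent_items or {}
    for lv in m.latents:
        if lv.order != "first":
            continue
        its = list(lv.indicators)
        if len(its) == 1:
            flags[its[0]] = False
            continue
        dep = dependent_items.get(lv.name, its)
        y = total_scores(d, dep)
        if len(d.responses) <= len(its):
            raise ValueError(
                f"dimension {lv.name}: fewer respondents than candidates")
        chosen = stepwise_select(y, d.responses[its], sle=sle, sls=sls)
        for it in its:
            flags[it] = it not in chosen
    return pd.Series(flags, name="stepwise_flag")


# ---------------------------------------------------------------------------
# Exploratory factor analysis
# ---------------------------------------------------------------------------

def principal_axis_factoring(R: np.ndarray, n_factors: int,
                             max_iter: int = 200, tol: float = 1e-6):
    """Iterated principal-axis extraction from a correlation matrix.

    Communalities start at squared multiple correlations and are iterated
    until stable.  Returns (loadings p x f, converged)."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 0.995)
    loadings = None
    converged = False
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[idx], 0.0, None)
        loadings = vecs[:, idx] * np.sqrt(lam)
        new_h2 = np.clip((loadings**2).sum(axis=1), 0.0, 0.995)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            converged = True
            break
        h2 = new_h2
    return loadings, converged


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-8):
    """Kaiser-normalized varimax rotation (via statsmodels)."""
    from statsmodels.multivariate.factor_rotation import rotate_factors

    L = np.asarray(loadings, dtype=float).copy()
    p, f = L.shape
    if f < 2:
        return L
    comm = np.sqrt((L**2).sum(axis=1))
    comm[comm == 0] = 1.0
    Ln = L / comm[:, None]
    rotated, _T = rotate_factors(Ln, "varimax", max_tries=max_iter, tol=tol)
    return rotated * comm[:, None]


def efa_flags(d: SurveyDataset, m: ModelDefinition, n_factors: int = None,
              threshold: float = 0.4, method: str = "paf") -> pd.DataFrame:
    """Factor-analytic screening: items whose maximum absolute rotated
    loading falls below `threshold` are flagged.

    method="paf" (default) is iterated principal-axis extraction;
    method="pca" uses the unreduced correlation matrix.  Non-convergent
    extraction marks items "indeterminate" (None flag) rather than
    deleting them.
    """
    items = [i for i in m.all_indicators if i in d.responses.columns]
    X = d.responses[items].dropna()
    if n_factors is None:
        n_factors = sum(
            1 for lv in m.latents
            if lv.order == "first" and len(lv.indicators) >= 2)
    R = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    if method == "pca":
        vals, vecs = np.linalg.eigh(R)
        idx = np.argsort(vals)[::-1][:n_factors]
        loadings, converged = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None)), True
    else:
        loadings, converged = principal_axis_factoring(R, n_factors)
    rotated = varimax(loadings)
    max_load = np.abs(rotated).max(axis=1)
    return pd.DataFrame({
        "max_loading": max_load,
        "efa_flag": [None if not converged else bool(v < threshold)
                     for v in max_load],
    }, index=items)


# ---------------------------------------------------------------------------
# Assembled flag table
# ---------------------------------------------------------------------------

def ctt_flag_table(d: SurveyDataset, m: ModelDefinition,
                   alpha_margin: float = 0.01,
                   ttest_na_latents=("PC",),
                   efa_method: str = "paf") -> pd.DataFrame:
    """All eight CTT criteria for every item of the model.

    Flag columns hold True/False, or None where a criterion is not
    computable / not applicable for the item (e.g. the extreme-group
    t-test for reverse-keyed complaint items, alpha-if-deleted in 2-item
    dimensions); None flags never count toward deletion.

    Floor/ceiling proportions use the raw responses; every total-score
    criterion uses reverse-keyed items flipped toward satisfaction.
    """
    items = m.all_indicators
    dk = keyed_dataset(d, m)
    totals = total_scores(dk)
    alpha_tab = alpha_if_deleted(dk, m, margin=alpha_margin)
    step = stepwise_flags(dk, m)
    efa = efa_flags(dk, m, method=efa_method)

    rows = []
    for it in items:
        p_fl, p_ce, f_fl, f_ce = floor_ceiling(d, it)
        dim = m.first_order_of_item(it)
        if dim in ttest_na_latents:
            t_stat, t_p, t_flag = np.nan, np.nan, None
        else:
            t_stat, t_p, t_flag, _note = extreme_group_ttest(dk, it, totals)
        r_dim, r_tot, dflag, tflag = item_correlations(dk, it, m)
        rows.append({
            "item": it,
            "floor_prop": p_fl, "floor_flag": f_fl,
            "ceiling_prop": p_ce, "ceiling_flag": f_ce,
            "ttest_t": t_stat, "ttest_p": t_p, "ttest_flag": t_flag,
            "item_dimension_r": r_dim, "item_dimension_flag": dflag,
            "item_total_r": r_tot, "item_total_flag": tflag,
            "alpha_without": alpha_tab.loc[it, "alpha_without"],
            "alpha_flag": alpha_tab.loc[it, "alpha_flag"],
            "stepwise_flag": bool(step[it]),
            "max_loading": efa.loc[it, "max_loading"],
            "efa_flag": efa.loc[it, "efa_flag"],
        })
    return pd.DataFrame(rows).set_index("item")
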