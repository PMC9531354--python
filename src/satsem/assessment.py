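"""Measurement- and structural-model assessment for PLS path models.

Measurement side: Cronbach's alpha, composite reliability
CR = (sum lambda)^2 / [(sum lambda)^2 + sum(1 - lambda^2)], average variance
extracted AVE = mean(lambda^2), cross-loadings, and the Fornell-Larcker
criterion (sqrt(AVE) on the diagonal must dominate the latent correlations).

Structural side: R^2 and adjusted R^2, effect sizes
f^2 = (R^2_full - R^2_reduced) / (1 - R^2_full), inner VIFs, effect
decomposition, and blindfolding predictive relevance Q^2 (construct
cross-validated redundancy).

Every statistic is computable either from a fitted model or directly from
printed summaries (outer loadings and a latent correlation matrix), so
published results can be replayed without the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import (PLSSEMResults, effects_decomposition,
                  structural_from_correlations)
from .screening import cronbach_alpha

__all__ = [
    "composite_reliability",
    "ave",
    "fornell_larcker",
    "cross_loadings",
    "r_squared_adjusted",
    "f_squared",
    "f_squared_table",
    "inner_vif",
    "q_squared_blindfold",
    "MeasurementReport",
    "StructuralReport",
    "measurement_report",
    "structural_report",
    "replay_structural_summary",
]


# ---------------------------------------------------------------------------
# Reliability / convergent validity
# ---------------------------------------------------------------------------

def composite_reliability(loadings) -> float:
    """CR = (sum lambda)^2 / [(sum lambda)^2 + sum(1 - lambda^2)]."""
    lam = np.asarray(list(loadings), dtype=float)
    if lam.size < 2:
        raise ValueError("composite reliability needs >= 2 loadings")
    if np.any(np.abs(lam) > 1):
        raise ValueError("loading magnitude exceeds 1")
    s2 = lam.sum() ** 2
    return float(s2 / (s2 + np.sum(1.0 - lam**2)))


def ave(loadings):
    """Average variance extracted and its square root."""
    lam = np.asarray(list(loadings), dtype=float)
    if lam.size < 1:
        raise ValueError("AVE needs >= 1 loading")
    a = float(np.mean(lam**2))
    return a, float(np.sqrt(a))


# ---------------------------------------------------------------------------
# Discriminant validity
# ---------------------------------------------------------------------------

def fornell_larcker(loadings_by_construct: dict, R: pd.DataFrame):
    """Fornell-Larcker matrix: sqrt(AVE) on the diagonal, latent
    correlations off it; a violation is any off-diagonal >= the
    corresponding diagonal.  Returns (matrix, violations)."""
    names = [c for c in R.columns if c in loadings_by_construct]
    M = R.loc[names, names].copy().astype(float)
    for c in names:
        M.loc[c, c] = ave(loadings_by_construct[c])[1]
    violations = []
    for i, a_ in enumerate(names):
        for b_ in names[i + 1:]:
            r = abs(float(R.loc[a_, b_]))
            if r >= min(M.loc[a_, a_], M.loc[b_, b_]):
                violations.append(
                    f"|corr({a_},{b_})| = {r:.3f} >= sqrt(AVE) of "
                    f"{a_ if M.loc[a_, a_] <= M.loc[b_, b_] else b_}")
    return M, violations


def cross_loadings(fit: PLSSEMResults):
    """Item-by-construct loading matrix with violations: an item whose
    loading on a foreign construct meets or exceeds its own-construct
    loading."""
    L = fit.outer_loadings
    m = fit.model.model
    violations = []
    for it in L.index:
        own = m.first_order_of_item(it)
        own_l = abs(L.loc[it, own])
        for c in L.columns:
            if c == own:
                continue
            if abs(L.loc[it, c]) >= own_l:
                violations.append(
                    f"{it}: loading on {c} ({L.loc[it, c]:.3f}) >= own "
                    f"loading on {own} ({L.loc[it, own]:.3f})")
    return L, violations


# ---------------------------------------------------------------------------
# Structural assessment
# ---------------------------------------------------------------------------

def r_squared_adjusted(r2: float, n: int, k: int) -> float:
    """R^2_adj = 1 - (1 - R^2)(n - 1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - k - 1))


def f_squared(r2_full: float, r2_reduced: float) -> float:
    """f^2 = (R^2_full - R^2_reduced) / (1 - R^2_full)."""
    if r2_full >= 1.0:
        raise ValueError("R^2_full must be < 1")
    if r2_reduced > r2_full + 1e-12:
        import warnings
        warnings.warn("reduced R^2 exceeds full R^2", stacklevel=2)
    return float((r2_full - r2_reduced) / (1.0 - r2_full))


def f_squared_table(R: pd.DataFrame, paths) -> pd.DataFrame:
    """Effect size of each predictor of each endogenous construct, by
    refitting the reduced structural regression from the latent
    correlation matrix."""
    paths = [(p.source, p.target) if hasattr(p, "source") else tuple(p)
             for p in paths]
    _beta, r2 = structural_from_correlations(R, paths=paths)
    rows = []
    for t in sorted({t for _s, t in paths}):
        preds = [s for s, tt in paths if tt == t]
        if r2[t] >= 1.0 - 1e-9:
            # saturated construct (e.g. a second-order construct fully
            # determined by its facets): effect sizes are undefined
            for drop in preds:
                rows.append({"source": drop, "target": t,
                             "f_squared": np.nan})
            continue
        for drop in preds:
            reduced_paths = [(s, t) for s in preds if s != drop]
            if reduced_paths:
                _b, r2_red = structural_from_correlations(
                    R, paths=reduced_paths)
                r2r = r2_red[t]
            else:
                r2r = 0.0
            rows.append({"source": drop, "target": t,
                         "f_squared": f_squared(r2[t], r2r)})
    return pd.DataFrame(rows).set_index(["source", "target"])


def inner_vif(R: pd.DataFrame, paths) -> pd.DataFrame:
    """Collinearity among each endogenous construct's predictors:
    VIF_j = 1 / (1 - R^2 of predictor j on the other predictors)."""
    paths = [(p.source, p.target) if hasattr(p, "source") else tuple(p)
             for p in paths]
    rows = []
    for t in sorted({t for _s, t in paths}):
        preds = [s for s, tt in paths if tt == t]
        for j in preds:
            others = [s for s in preds if s != j]
            if not others:
                vif = 1.0
                flagged = False
            else:
                _b, r2 = structural_from_correlations(
                    R, paths=[(o, j) for o in others])
                r2j = r2[j]
                if r2j >= 1.0 - 1e-12:
                    vif, flagged = np.inf, True
                else:
                    vif, flagged = 1.0 / (1.0 - r2j), False
            rows.append({"predictor": j, "target": t, "vif": vif,
                         "flagged": flagged})
    return pd.DataFrame(rows).set_index(["target", "predictor"])


def q_squared_blindfold(fit: PLSSEMResults, omission_distance: int = 7) -> dict:
    """Construct cross-validated redundancy Q^2 per endogenous construct.

    Every D-th data point of the construct's indicator block is omitted in
    turn (D = omission distance, adjusted upward by one if it divides n);
    omitted points are predicted from the structural model (predicted
    construct score from its predecessors, carried to the indicator by its
    loading), and Q^2 = 1 - SSE/SSO over all omission rounds.  The
    procedure is deterministic given D.
    """
    if omission_distance < 2:
        raise ValueError("omission distance must be >= 2")
    n = len(fit.latent_scores)
    D = omission_distance
    if n % D == 0:
        D += 1
    paths = fit.structural_paths
    beta = fit.path_coefficients
    scores = fit.latent_scores
    m = fit.model.model

    out = {}
    for t in sorted({t for _s, t in paths}):
        preds = [s for s, tt in paths if tt == t]
        yhat = np.zeros(n)
        for s in preds:
            yhat += beta[(s, t)] * scores[s].to_numpy()
        lv = m.latent(t)
        if lv.order == "second":
            # indicators are the facet scores
            block = scores[list(m.hoc_components[t])].to_numpy()
            lam = np.array([
                np.corrcoef(scores[t], scores[f])[0, 1]
                for f in m.hoc_components[t]])
        else:
            its = list(lv.indicators)
            block = fit.item_data[its].to_numpy()
            lam = fit.outer_loadings.loc[its, t].to_numpy(dtype=float)
        J = block.shape[1]
        sse = sso = 0.0
        for r in range(D):
            flat = np.arange(n * J)
            omit = flat[flat % D == r]
            i_idx, j_idx = omit // J, omit % J
            x = block[i_idx, j_idx]
            pred = lam[j_idx] * yhat[i_idx]
            sse += float(np.sum((x - pred) ** 2))
            sso += float(np.sum(x**2))
        if sso == 0:
            raise ValueError(f"degenerate construct {t}")
        out[t] = 1.0 - sse / sso
    return out


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class MeasurementReport:
    reliability: pd.DataFrame        # construct: alpha, CR, flags
    convergent: pd.DataFrame         # item: own loading, construct AVE, flags
    fornell_larcker_matrix: pd.DataFrame
    fl_violations: list
    cross_loadings: pd.DataFrame
    cl_violations: list

    def summary(self) -> str:
        lines = ["Measurement model assessment", "=" * 52,
                 self.reliability.round(3).to_string(), "",
                 "Fornell-Larcker (diagonal = sqrt AVE):",
                 self.fornell_larcker_matrix.round(3).to_string()]
        lines.append("")
        lines.append(f"Fornell-Larcker violations: "
                     f"{len(self.fl_violations)}")
        lines += [f"  {v}" for v in self.fl_violations]
        lines.append(f"Cross-loading violations: {len(self.cl_violations)}")
        return "\n".join(lines)


@dataclass
class StructuralReport:
    r2: pd.DataFrame                  # endogenous: R2, R2_adj, Q2
    f2: pd.DataFrame
    vif: pd.DataFrame
    effects: pd.DataFrame

    def summary(self) -> str:
        return "\n".join([
            "Structural model assessment", "=" * 52,
            self.r2.round(3).to_string(), "",
            "Effect sizes (f^2):", self.f2.round(3).to_string(), "",
            "Inner VIF:", self.vif.round(3).to_string(),
        ])


def measurement_report(fit: PLSSEMResults,
                       loading_threshold: float = 0.7,
                       ave_threshold: float = 0.5,
                       reliability_threshold: float = 0.7) -> MeasurementReport:
    """Full measurement-model evaluation of a fitted PLS model."""
    m = fit.model.model
    firsts = [lv for lv in m.latents if lv.order == "first"]
    load_by_construct = {}
    rows = []
    for lv in firsts:
        its = list(lv.indicators)
        lam = [float(fit.outer_loadings.loc[i, lv.name]) for i in its]
        load_by_construct[lv.name] = lam
        alpha = cronbach_alpha(fit.item_data[its]) if len(its) >= 2 else np.nan
        cr = composite_reliability(lam) if len(lam) >= 2 else 1.0
        a_, _sqrt = ave(lam)
        rows.append({"construct": lv.name, "alpha": alpha, "cr": cr,
                     "ave": a_,
                     "alpha_ok": (alpha >= reliability_threshold)
                     if np.isfinite(alpha) else None,
                     "cr_ok": cr >= reliability_threshold,
                     "ave_ok": a_ >= ave_threshold})
    # second-order construct: facet scores as indicators
    for lv in m.latents:
        if lv.order != "second":
            continue
        comps = m.hoc_components[lv.name]
        lam = [float(np.corrcoef(fit.latent_scores[lv.name],
                                 fit.latent_scores[f])[0, 1]) for f in comps]
        load_by_construct[lv.name] = lam
        rows.append({"construct": lv.name, "alpha": np.nan,
                     "cr": composite_reliability(lam), "ave": ave(lam)[0],
                     "alpha_ok": None,
                     "cr_ok": composite_reliability(lam) >= reliability_threshold,
                     "ave_ok": ave(lam)[0] >= ave_threshold})
    reliability = pd.DataFrame(rows).set_index("construct")

    conv_rows = []
    for lv in firsts:
        for i in lv.indicators:
            lam = float(fit.outer_loadings.loc[i, lv.name])
            conv_rows.append({"item": i, "construct": lv.name,
                              "loading": lam,
                              "loading_ok": lam >= loading_threshold})
    convergent = pd.DataFrame(conv_rows).set_index("item")

    fl, fl_v = fornell_larcker(load_by_construct, fit.latent_correlations)
    cl, cl_v = cross_loadings(fit)
    return MeasurementReport(reliability=reliability, convergent=convergent,
                             fornell_larcker_matrix=fl, fl_violations=fl_v,
                             cross_loadings=cl, cl_violations=cl_v)


def structural_report(fit: PLSSEMResults, n: int = None,
                      omission_distance: int = 7,
                      vif_threshold: float = 5.0) -> StructuralReport:
    """Full structural-model evaluation of a fitted PLS model."""
    if n is None:
        n = len(fit.latent_scores)
    paths = fit.structural_paths
    R = fit.latent_correlations
    _beta, r2 = structural_from_correlations(R, paths=paths)
    q2 = q_squared_blindfold(fit, omission_distance)
    rows = []
    for t, v in sorted(r2.items()):
        k = len([s for s, tt in paths if tt == t])
        rows.append({"construct": t, "r2": v,
                     "r2_adj": r_squared_adjusted(v, n, k),
                     "q2": q2.get(t, np.nan)})
    r2_df = pd.DataFrame(rows).set_index("construct")
    f2 = f_squared_table(R, paths)
    vif = inner_vif(R, paths)
    vif["ok"] = vif["vif"] < vif_threshold
    eff = effects_decomposition(fit.path_coefficients)
    return StructuralReport(r2=r2_df, f2=f2, vif=vif, effects=eff)


def replay_structural_summary(R: pd.DataFrame, paths, n: int) -> dict:
    """Recompute the structural assessment suite from a printed latent
    correlation matrix: coefficients, R^2, adjusted R^2, f^2, VIF and the
    effect decomposition, exactly as they are recoverable from summary
    tables without the raw data."""
    paths = [(p.source, p.target) if hasattr(p, "source") else tuple(p)
             for p in paths]
    beta, r2 = structural_from_correlations(R, paths=paths)
    r2_adj = {t: r_squared_adjusted(v, n, len([s for s, tt in paths if tt == t]))
              for t, v in r2.items()}
    return {
        "coefficients": beta,
        "r2": r2,
        "r2_adj": r2_adj,
        "f2": f_squared_table(R, paths),
        "vif": inner_vif(R, paths),
        "effects": effects_decomposition(beta),
    }
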