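"""Partial least squares structural equation modelling with second-order
constructs, bootstrap inference, multigroup comparison and effect
decomposition.

The estimator is the classic Lohmoller/Wold algorithm: mode-A outer
estimation (weights proportional to the correlations of the indicators with
the inner proxy), path-weighting inner scheme, iterated to convergence of
the outer weights.  The structural stage is then ordinary least squares of
each endogenous composite on its predecessors, which is why path
coefficients are recoverable from the latent correlation matrix alone
(:func:`structural_from_correlations`).

A second-order construct (here: perceived quality over five facets) is
estimated by the embedded two-stage approach by default: stage one
estimates the facet scores from a model in which the facets replace the
higher-order construct; stage two uses those scores as the higher-order
construct's indicators.  The repeated-indicators approach is available as
an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_spec import ModelDefinition, StructuralPath
from .synthetic import SurveyDataset

__all__ = [
    "PLSSEM",
    "PLSSEMResults",
    "PlsFit",
    "BootstrapResult",
    "pls_estimate",
    "structural_from_correlations",
    "effects_decomposition",
    "bootstrap",
    "mga_compare",
    "min_sample_inverse_sqrt",
]


# ---------------------------------------------------------------------------
# Sample-size rule
# ---------------------------------------------------------------------------

def min_sample_inverse_sqrt(beta_min: float, attrition: float = 0.0,
                            n_groups: int = 1) -> int:
    """Inverse-square-root minimum sample size for PLS path models.

    The base requirement is n > (2.486 / |beta|_min)^2, i.e. the smallest
    integer strictly greater than the square; it is then inflated for an
    anticipated attrition proportion and multiplied by the number of
    analysis groups.
    """
    if beta_min <= 0:
        raise ValueError("beta_min must be positive")
    if not (0.0 <= attrition < 1.0):
        raise ValueError("attrition must lie in [0, 1)")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    base = math.floor((2.486 / beta_min) ** 2) + 1
    return math.ceil(base / (1.0 - attrition)) * n_groups


# ---------------------------------------------------------------------------
# Core iterative algorithm
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        raise ValueError(f"zero-variance column(s) at positions {bad.tolist()}")
    return (X - mu) / sd


def _pls_core(X: np.ndarray, blocks: dict, paths: list,
              tol: float = 1e-7, max_iter: int = 300):
    """Iterate mode-A outer / path-weighting inner estimation.

    X : standardized n x p data; blocks maps construct -> column indices;
    paths is a list of (source, target) construct names.  Returns
    (weights dict, scores dict, iterations, converged).
    """
    n = X.shape[0]
    names = list(blocks)
    preds = {c: [s for s, t in paths if t == c] for c in names}
    succs = {c: [t for s, t in paths if s == c] for c in names}

    def block_scores(w):
        out = {}
        for c in names:
            y = X[:, blocks[c]] @ w[c]
            sd = y.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate composite for {c}")
            out[c] = y / sd
        return out

    w = {c: np.ones(len(blocks[c])) for c in names}
    scores = block_scores(w)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        # inner proxies, path weighting scheme
        Z = {}
        for c in names:
            z = np.zeros(n)
            p = preds[c]
            if p:
                # regression of the composite on its predecessors
                Yp = np.column_stack([scores[j] for j in p])
                coef, *_ = np.linalg.lstsq(Yp, scores[c], rcond=None)
                z = z + Yp @ coef
            for j in succs[c]:
                r = float(np.corrcoef(scores[c], scores[j])[0, 1])
                z = z + r * scores[j]
            if not p and not succs[c]:
                z = scores[c].copy()  # isolated construct keeps its composite
            sd = z.std(ddof=1)
            Z[c] = z / sd if sd > 0 else scores[c]
        # mode-A outer update
        new_w = {}
        for c in names:
            wv = X[:, blocks[c]].T @ Z[c] / (n - 1)
            y = X[:, blocks[c]] @ wv
            sd = y.std(ddof=1)
            new_w[c] = wv / sd if sd > 0 else wv
        delta = max(np.max(np.abs(new_w[c] - w[c])) for c in names)
        w = new_w
        scores = block_scores(w)
        if delta < tol:
            converged = True
            break
    return w, scores, iterations, converged


def structural_from_correlations(R: pd.DataFrame, m=None, paths=None):
    """Solve the structural stage from a latent correlation matrix.

    For each endogenous construct, the path coefficients are the solution
    of the normal equations on its predictors' correlation submatrix, and
    R^2 = beta' r.  Returns (path_coefficients dict keyed (source, target),
    r2 dict keyed by endogenous construct).
    """
    if paths is None:
        paths = [(p.source, p.target) for p in m.paths]
    R = pd.DataFrame(R)
    beta, r2 = {}, {}
    targets = {t for _s, t in paths}
    for t in targets:
        pr = [s for s, tt in paths if tt == t]
        Rpp = R.loc[pr, pr].to_numpy(dtype=float)
        rpt = R.loc[pr, t].to_numpy(dtype=float)
        try:
            b = np.linalg.solve(Rpp, rpt)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"singular predictor block for {t}") from e
        for s, bb in zip(pr, b):
            beta[(s, t)] = float(bb)
        r2[t] = float(b @ rpt)
    return beta, r2


def effects_decomposition(beta: dict, paths=None) -> pd.DataFrame:
    """Direct, indirect and total effects for every ordered construct pair
    connected by at least one directed chain.

    `beta` maps (source, target) -> coefficient over an acyclic path set;
    indirect effects sum the coefficient products over all multi-step
    chains (computed through powers of the nilpotent coefficient matrix).
    """
    if hasattr(beta, "path_coefficients"):
        beta = beta.path_coefficients
    names = sorted({s for s, _ in beta} | {t for _, t in beta})
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    B = np.zeros((k, k))
    for (s, t), v in beta.items():
        B[idx[t], idx[s]] = v
    # DAG check: B must be nilpotent
    total = np.zeros_like(B)
    P = B.copy()
    for _ in range(k):
        total += P
        P = P @ B
    if np.abs(P).max() > 1e-12:
        raise ValueError("cycle detected in structural paths")
    indirect = total - B
    rows = []
    for s in names:
        for t in names:
            if s == t or abs(total[idx[t], idx[s]]) < 1e-15:
                continue
            rows.append({
                "source": s, "target": t,
                "direct": B[idx[t], idx[s]],
                "indirect": indirect[idx[t], idx[s]],
                "total": total[idx[t], idx[s]],
            })
    return pd.DataFrame(rows).set_index(["source", "target"])


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class PLSSEM:
    """PLS path model for an ordinal satisfaction survey.

    Parameters
    ----------
    data : SurveyDataset or DataFrame
        Respondent-by-item responses; NaN = missing.
    model : ModelDefinition
    hoc_method : {"two_stage", "repeated_indicators"}
        How a second-order construct is estimated.
    missing : {"mean", "listwise"}
        Mean replacement before standardization (default) or row removal.
    tol, max_iter : outer-weight convergence controls.
    """

    def __init__(self, data, model: ModelDefinition,
                 hoc_method: str = "two_stage", missing: str = "mean",
                 tol: float = 1e-7, max_iter: int = 300):
        if isinstance(data, SurveyDataset):
            df = data.responses
        else:
            df = pd.DataFrame(data)
        self.model = model
        items = [i for i in model.all_indicators if i in df.columns]
        missing_items = [i for i in model.all_indicators if i not in df.columns]
        if missing_items:
            raise ValueError(f"data lacks model indicators: {missing_items}")
        df = df[items]
        if missing == "listwise":
            df = df.dropna()
        elif missing == "mean":
            df = df.fillna(df.mean())
        else:
            raise ValueError("missing must be 'mean' or 'listwise'")
        self.items = items
        self.endog_names = model.latent_names
        self.data = df
        self.hoc_method = hoc_method
        self.tol = tol
        self.max_iter = max_iter

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: ModelDefinition,
                       **kwargs) -> "PLSSEM":
        return cls(df, model, **kwargs)

    # -- structural graphs for the stages ---------------------------------

    def _second_order(self):
        socs = [lv.name for lv in self.model.latents if lv.order == "second"]
        return socs[0] if socs else None

    def _stage1_graph(self):
        """Facets replace the second-order construct in the path set."""
        m = self.model
        soc = self._second_order()
        comps = m.hoc_components[soc]
        paths = []
        for p in m.paths:
            if p.source == soc:
                paths += [(c, p.target) for c in comps]
            elif p.target == soc:
                paths += [(p.source, c) for c in comps]
            else:
                paths.append((p.source, p.target))
        constructs = [lv.name for lv in m.latents if lv.order == "first"]
        return constructs, paths

    def _expanded_graph(self):
        """Structural graph with the second-order construct expanded: its
        predecessors feed the facets, the facets feed the construct.  The
        original predecessor-to-construct paths are not estimated directly
        (their effect is the facet-mediated total, reported separately)."""
        m = self.model
        soc = self._second_order()
        if soc is None:
            return [(p.source, p.target) for p in m.paths]
        comps = m.hoc_components[soc]
        paths = []
        for p in m.paths:
            if p.target == soc:
                paths += [(p.source, c) for c in comps]
            else:
                paths.append((p.source, p.target))
        paths += [(c, soc) for c in comps]
        return paths

    # -- estimation --------------------------------------------------------

    def fit(self, _index=None, _dominant=None) -> "PLSSEMResults":
        """Estimate outer weights/loadings, composite scores, and the
        structural coefficients.  `_index` (row positions) and `_dominant`
        (construct -> item forced to a positive loading) support bootstrap
        resampling and sign alignment."""
        df = self.data if _index is None else self.data.iloc[_index]
        X = _standardize(df.to_numpy(dtype=float))
        col = {it: j for j, it in enumerate(self.items)}
        m = self.model
        soc = self._second_order()

        if soc is None:
            constructs = [lv.name for lv in m.latents if lv.order == "first"]
            blocks = {c: [col[i] for i in m.latent(c).indicators]
                      for c in constructs}
            paths = [(p.source, p.target) for p in m.paths]
            w, scores, iters, conv = _pls_core(
                X, blocks, paths, self.tol, self.max_iter)
            score_df = pd.DataFrame(scores)
            weight_map = {}
            for c in constructs:
                for k, it in enumerate(m.latent(c).indicators):
                    weight_map[it] = (c, float(w[c][k]))
            iterations, converged = iters, conv
            structural_paths = paths
        elif self.hoc_method == "two_stage":
            comps = m.hoc_components[soc]
            # stage 1: facets in place of the second-order construct
            constructs1, paths1 = self._stage1_graph()
            blocks1 = {c: [col[i] for i in m.latent(c).indicators]
                       for c in constructs1}
            w1, s1, it1, conv1 = _pls_core(
                X, blocks1, paths1, self.tol, self.max_iter)
            # stage 2: facet scores serve as the HOC's indicators
            top = [lv.name for lv in m.latents
                   if lv.order == "first" and lv.name not in comps] + [soc]
            stage2_cols = []
            names2 = []
            for c in top:
                if c == soc:
                    for f in comps:
                        stage2_cols.append(s1[f])
                        names2.append(f"__score_{f}")
                else:
                    for i in m.latent(c).indicators:
                        stage2_cols.append(X[:, col[i]])
                        names2.append(i)
            X2 = _standardize(np.column_stack(stage2_cols))
            col2 = {nm: j for j, nm in enumerate(names2)}
            blocks2 = {}
            for c in top:
                if c == soc:
                    blocks2[c] = [col2[f"__score_{f}"] for f in comps]
                else:
                    blocks2[c] = [col2[i] for i in m.latent(c).indicators]
            paths2 = [(p.source, p.target) for p in m.paths]
            w2, s2, it2, conv2 = _pls_core(
                X2, blocks2, paths2, self.tol, self.max_iter)
            score_df = pd.DataFrame({**{c: s2[c] for c in top},
                                     **{f: s1[f] for f in comps}})
            weight_map = {}
            for c in constructs1:
                for k, i in enumerate(m.latent(c).indicators):
                    weight_map[i] = (c, float(w1[c][k]))
            for k, f in enumerate(comps):
                weight_map[f"score[{f}]"] = (soc, float(w2[soc][k]))
            iterations = it1 + it2
            converged = conv1 and conv2
            structural_paths = self._expanded_graph()
        elif self.hoc_method == "repeated_indicators":
            comps = m.hoc_components[soc]
            constructs = [lv.name for lv in m.latents if lv.order == "first"]
            blocks = {c: [col[i] for i in m.latent(c).indicators]
                      for c in constructs}
            blocks[soc] = [col[i] for i in m.indicators_of(soc)]
            paths = self._expanded_graph()
            w, scores, iterations, converged = _pls_core(
                X, blocks, paths, self.tol, self.max_iter)
            score_df = pd.DataFrame(scores)
            weight_map = {}
            for c, idxs in blocks.items():
                its = m.indicators_of(c) if c == soc else m.latent(c).indicators
                for k, i in enumerate(its):
                    key = i if c != soc else f"{i}@{soc}"
                    weight_map[key] = (c, float(w[c][k]))
            structural_paths = paths
        else:
            raise ValueError(f"unknown hoc_method {self.hoc_method!r}")

        # sign alignment: dominant indicator of every construct positive
        load = self._loadings(X, score_df)
        dominant = _dominant or {}
        for c in score_df.columns:
            own = self._own_items(c)
            own = [i for i in own if i in load.index]
            if not own:
                continue
            dom = dominant.get(c) or max(own, key=lambda i: abs(load.loc[i, c]))
            if load.loc[dom, c] < 0:
                score_df[c] = -score_df[c]
        load = self._loadings(X, score_df)

        R = score_df.corr()
        beta, r2 = structural_from_correlations(R, paths=structural_paths)

        # facet-mediated totals for the second-order construct's original
        # predecessors (reported without a direct regression coefficient)
        hoc_derived = {}
        if soc is not None:
            eff = effects_decomposition(beta)
            for p in m.paths:
                if p.target == soc and (p.source, soc) in eff.index:
                    hoc_derived[(p.source, soc)] = float(
                        eff.loc[(p.source, soc), "total"])

        return PLSSEMResults(
            model=self, item_data=pd.DataFrame(X, columns=self.items),
            latent_scores=score_df, outer_loadings=load,
            outer_weights=weight_map, latent_correlations=R,
            path_coefficients=beta, r_squared=r2,
            structural_paths=structural_paths,
            hoc_derived=hoc_derived,
            iterations_used=iterations, converged=converged,
        )

    def _own_items(self, construct):
        m = self.model
        lv = m.latent(construct)
        return list(m.indicators_of(construct) if lv.order == "second"
                    else lv.indicators)

    def _loadings(self, X, score_df) -> pd.DataFrame:
        """Item-by-construct correlation matrix (cross-loadings; the entry
        for an item's own construct is its outer loading)."""
        n = X.shape[0]
        S = score_df.to_numpy(dtype=float)
        S = (S - S.mean(0)) / S.std(0, ddof=1)
        L = X.T @ S / (n - 1)
        return pd.DataFrame(L, index=self.items, columns=score_df.columns)


@dataclass
class PLSSEMResults:
    """Fitted PLS path model.

    Composite scores are standardized (mean 0, unit variance); outer
    loadings are the correlations of each standardized item with each
    composite; `path_coefficients` maps (source, target) to the
    structural coefficient.
    """

    model: PLSSEM
    item_data: pd.DataFrame
    latent_scores: pd.DataFrame
    outer_loadings: pd.DataFrame
    outer_weights: dict
    latent_correlations: pd.DataFrame
    path_coefficients: dict
    r_squared: dict
    structural_paths: list
    iterations_used: int
    converged: bool
    hoc_derived: dict = field(default_factory=dict)
    _bootstrap: "BootstrapResult" = field(default=None, repr=False)

    @property
    def path_coefficients_frame(self) -> pd.DataFrame:
        rows = [{"source": s, "target": t, "coefficient": v,
                 "derived": False}
                for (s, t), v in self.path_coefficients.items()]
        rows += [{"source": s, "target": t, "coefficient": v,
                  "derived": True}
                 for (s, t), v in self.hoc_derived.items()]
        return pd.DataFrame(rows).set_index(["source", "target"])

    def own_loading(self, item: str) -> float:
        c = self.model.model.first_order_of_item(item)
        return float(self.outer_loadings.loc[item, c])

    def effects(self) -> pd.DataFrame:
        return effects_decomposition(self.path_coefficients)

    def bootstrap(self, n_resamples: int = 5000, seed: int = 0) -> "BootstrapResult":
        self._bootstrap = bootstrap(self.model, n_resamples=n_resamples,
                                    seed=seed, fit=self)
        return self._bootstrap

    def hypothesis_signs(self) -> pd.DataFrame:
        """Sign consistency of the estimates with the hypothesized paths."""
        rows = []
        for p in self.model.model.paths:
            est = self.path_coefficients.get((p.source, p.target))
            if est is None:
                continue
            rows.append({
                "source": p.source, "target": p.target,
                "hypothesized_sign": p.hypothesized_sign,
                "coefficient": est,
                "consistent": bool(np.sign(est) == p.hypothesized_sign),
            })
        return pd.DataFrame(rows).set_index(["source", "target"])

    def summary(self) -> str:
        lines = ["PLS path model results",
                 "=" * 54,
                 f"n respondents: {len(self.latent_scores)}    "
                 f"iterations: {self.iterations_used}    "
                 f"converged: {self.converged}",
                 "",
                 "Structural coefficients:"]
        for (s, t), v in self.path_coefficients.items():
            lines.append(f"  {s:>16s} -> {t:<16s} {v:+.3f}")
        lines.append("")
        lines.append("R-squared:")
        for t, v in sorted(self.r_squared.items()):
            lines.append(f"  {t:<16s} {v:.3f}")
        return "\n".join(lines)

    def plot_paths(self, ax=None):
        """Simple layered diagram of the structural graph with coefficients."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        order = {}
        beta = self.path_coefficients
        names = sorted({s for s, _ in beta} | {t for _, t in beta})
        for i, nm in enumerate(names):
            order[nm] = (i % 3, -(i // 3))
        for (s, t), v in beta.items():
            x0, y0 = order[s]
            x1, y1 = order[t]
            ax.annotate("", xy=(x1, y1), xytext=(x0, y0),
                        arrowprops=dict(arrowstyle="->", alpha=0.6))
            ax.text((x0 + x1) / 2, (y0 + y1) / 2, f"{v:.2f}", fontsize=7)
        for nm, (x, y) in order.items():
            ax.text(x, y, nm, ha="center", va="center",
                    bbox=dict(boxstyle="round", fc="w"))
        ax.set_axis_off()
        return ax


PlsFit = PLSSEMResults


def pls_estimate(d, m: ModelDefinition, **kwargs) -> PLSSEMResults:
    """Functional entry point: fit the PLS path model on a survey."""
    return PLSSEM(d, m, **kwargs).fit()


# ---------------------------------------------------------------------------
# Bootstrap inference
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap for the structural coefficients."""

    estimates: pd.DataFrame   # per path: coefficient, se, t, p, ci_low, ci_high
    n_resamples: int
    seed: int
    n_redrawn: int = 0
    draws: pd.DataFrame = None  # resample-by-path coefficient draws

    def summary_frame(self) -> pd.DataFrame:
        return self.estimates


def bootstrap(model: PLSSEM, n_resamples: int = 5000, seed: int = 0,
              fit: PLSSEMResults = None, ci_level: float = 0.95) -> BootstrapResult:
    """Respondent-level resampling with replacement.

    Each resample is re-estimated with construct orientations aligned to
    the original fit's dominant indicators; resamples yielding a singular
    fit are redrawn (capped at 10% of `n_resamples`).  SE is the resample
    standard deviation, t = estimate / SE, two-sided p from the standard
    normal, and the CI is percentile.
    """
    from scipy.stats import norm as _norm

    if fit is None:
        fit = model.fit()
    dominant = {}
    for c in fit.latent_scores.columns:
        own = [i for i in model._own_items(c) if i in fit.outer_loadings.index]
        if own:
            dominant[c] = max(own, key=lambda i: abs(fit.outer_loadings.loc[i, c]))
    n = len(model.data)
    rng = np.random.default_rng(seed)
    paths = list(fit.path_coefficients)
    draws = np.full((n_resamples, len(paths)), np.nan)
    redrawn = 0
    cap = max(1, n_resamples // 10)
    b = 0
    while b < n_resamples:
        idx = rng.integers(0, n, size=n)
        try:
            res = model.fit(_index=idx, _dominant=dominant)
        except (ValueError, np.linalg.LinAlgError):
            redrawn += 1
            if redrawn > cap:
                raise RuntimeError(
                    "too many singular bootstrap resamples (>10%)")
            continue
        draws[b] = [res.path_coefficients.get(p, np.nan) for p in paths]
        b += 1

    alpha = 1.0 - ci_level
    rows = []
    for j, p in enumerate(paths):
        est = fit.path_coefficients[p]
        se = float(np.nanstd(draws[:, j], ddof=1))
        t = est / se if se > 0 else np.inf
        pval = 2 * (1 - _norm.cdf(abs(t))) if np.isfinite(t) else 0.0
        lo, hi = np.nanpercentile(draws[:, j],
                                  [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rows.append({"source": p[0], "target": p[1], "coefficient": est,
                     "se": se, "t": abs(t), "p": pval,
                     "ci_low": float(lo), "ci_high": float(hi)})
    est_df = pd.DataFrame(rows).set_index(["source", "target"])
    draw_df = pd.DataFrame(draws, columns=pd.MultiIndex.from_tuples(paths))
    return BootstrapResult(estimates=est_df, n_resamples=n_resamples,
                           seed=seed, n_redrawn=redrawn, draws=draw_df)


# ---------------------------------------------------------------------------
# Multigroup analysis
# ---------------------------------------------------------------------------

def mga_compare(d: SurveyDataset, m: ModelDefinition,
                n_resamples: int = 500, seed: int = 0,
                groups=None, **fit_kwargs) -> pd.DataFrame:
    """Distribution-based PLS multigroup comparison.

    Fits and bootstraps the model separately per group; the one-sided
    probability that group 1's coefficient exceeds group 2's is computed
    over all bootstrap pairs, and the reported two-sided p is
    2*min(q, 1-q).  Identical groups therefore give p ~ 1.
    """
    labels = d.group
    if groups is None:
        groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    g1, g2 = groups
    for g in groups:
        if not (labels == g).any():
            raise ValueError(f"group {g!r} missing from the data")
        ng = int((labels == g).sum())
        req = min_sample_inverse_sqrt(0.11)
        if ng < req:
            import warnings
            warnings.warn(
                f"group {g!r} has n={ng}, below the inverse-square-root "
                f"requirement {req}", stacklevel=2)

    results = {}
    for k, g in enumerate(groups):
        sub = d.subset(np.where((labels == g).to_numpy())[0])
        model = PLSSEM(sub, m, **fit_kwargs)
        fit = model.fit()
        bs = bootstrap(model, n_resamples=n_resamples,
                       seed=seed + 1000 * k, fit=fit)
        results[g] = (fit, bs)

    fit1, bs1 = results[g1]
    fit2, bs2 = results[g2]
    draws1 = bs1.draws
    draws2 = bs2.draws
    rows = []
    for p in fit1.path_coefficients:
        if p not in fit2.path_coefficients:
            continue
        a = draws1[p].to_numpy()
        b = draws2[p].to_numpy()
        # P(beta_1 > beta_2) over all bootstrap pairs
        q = float(np.mean(a[:, None] > b[None, :]))
        rows.append({
            "source": p[0], "target": p[1],
            f"coef_{g1}": fit1.path_coefficients[p],
            f"coef_{g2}": fit2.path_coefficients[p],
            "difference": fit1.path_coefficients[p] - fit2.path_coefficients[p],
            "p_one_sided": q,
            "p_value": 2 * min(q, 1 - q),
        })
    return pd.DataFrame(rows).set_index(["source", "target"])
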