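"""Synthetic ordinal survey generation under the hypothesized latent structure.

The study data behind the URRBMI satisfaction instrument are not public, so
this module emulates them: a standardized linear structural system on the
hypothesized DAG (every latent score has unit marginal variance), perceived
quality realized as a second-order construct whose five facets are loaded
children, ordinal item responses drawn from a graded response model per
item, ceiling effects on selected items, completely-at-random missingness,
and an urban/rural two-group structure for multigroup analysis.

Defaults reproduce the published study conditions: 1,909 respondents
(899 urban / 1,020 rural), a 574/1,335 construction/evaluation split,
28–29 items on a ten-category scale, and the published structural
coefficients as the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import GrmItemParams, category_probabilities
from .model_spec import ModelDefinition, default_initial_model

__all__ = [
    "GeneratorConfig",
    "SurveyDataset",
    "default_grm_params",
    "implied_latent_correlations",
    "generate_latent_scores",
    "generate_ordinal_responses",
    "simulate_survey",
    "split_sample",
]

# Published point estimates of the structural coefficients, used as the
# generating values for the standardized system.
DEFAULT_STRUCTURAL = {
    ("PE", "PQ"): 0.568,
    ("PE", "PV"): 0.204,
    ("PE", "PS"): 0.070,
    ("PQ", "PV"): 0.676,
    ("PQ", "PS"): 0.421,
    ("PV", "PS"): 0.467,
    ("PS", "PC"): -0.243,
    ("PS", "PT"): 0.634,
}

# Facet-on-quality loadings: the facets are generated as lambda*PQ + noise,
# so lambda equals the implied facet-quality correlation; values follow the
# reported facet-quality correlations of the validation survey.
DEFAULT_FACET_LOADINGS = {
    "PQ_overall": 0.692,
    "PQ_information": 0.705,
    "PQ_service": 0.815,
    "PQ_policy": 0.937,
    "PQ_institution": 0.908,
}

# Items given downward-shifted thresholds so the screening stage sees
# realistic ceiling-effect positives.
DEFAULT_CEILING_ITEMS = ("PQ1", "PQ14", "PE2", "PT1", "PT2")

DEFAULT_GROUP_PROPORTIONS = {"urban": 899 / 1909, "rural": 1020 / 1909}


def default_grm_params(m: ModelDefinition = None,
                       a: float = 2.5,
                       ceiling_items=DEFAULT_CEILING_ITEMS,
                       ceiling_top: float = 0.6) -> dict:
    """Per-item GRM parameters: discrimination 2.5 and thresholds evenly
    spaced over (-2.4, 2.4); ceiling items get thresholds compressed
    downward (top threshold at `ceiling_top`, all within the (-4, 4)
    screening range) so >20% of respondents land in the top category."""
    if m is None:
        m = default_initial_model()
    lo, hi = m.scale
    k = hi - lo + 1
    base = np.linspace(-2.4, 2.4, k - 1)
    # ceiling items: compressed, downward-shifted thresholds; the lowest
    # stays well inside the (-4, 4) screening range even after the outward
    # stretch that shared-trait calibration applies to weakly loading facets
    ceil_b = np.linspace(-2.2, ceiling_top, k - 1)
    out = {}
    for it in m.all_indicators:
        b = ceil_b if it in ceiling_items else base
        out[it] = GrmItemParams(a=a, b=b.copy())
    return out


@dataclass
class GeneratorConfig:
    """Conditions under which a synthetic survey is generated.

    All coefficients refer to the standardized system: every latent score
    has unit marginal variance, so disturbance variances are derived, not
    chosen, and must come out nonnegative.
    """

    n_respondents: int = 1909
    structural_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL))
    facet_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_FACET_LOADINGS))
    grm_params: dict = None
    group_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS))
    group_effect: dict = field(default_factory=dict)  # group -> {path: delta}
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SurveyDataset:
    """Respondent-by-item ordinal responses with group labels.

    responses : DataFrame of floats; NaN encodes missing (never an
        in-range category).
    group : per-respondent labels aligned with `responses`.
    true_latent_scores : generating latent scores, retained for recovery
        tests; None for real data.
    scale : ordinal bounds (min_category, max_category).
    """

    responses: pd.DataFrame
    group: pd.Series = None
    true_latent_scores: pd.DataFrame = None
    scale: tuple = (1, 10)

    def __post_init__(self):
        vals = self.responses.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        lo, hi = self.scale
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise ValueError("observed responses outside the model scale bounds")
        if self.group is None:
            self.group = pd.Series(["all"] * len(self.responses),
                                   index=self.responses.index, name="group")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.responses.isna()

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    @property
    def items(self) -> list:
        return list(self.responses.columns)

    def subset(self, idx) -> "SurveyDataset":
        tls = None if self.true_latent_scores is None \
            else self.true_latent_scores.iloc[idx].reset_index(drop=True)
        return SurveyDataset(
            responses=self.responses.iloc[idx].reset_index(drop=True),
            group=self.group.iloc[idx].reset_index(drop=True),
            true_latent_scores=tls,
            scale=self.scale,
        )


# ---------------------------------------------------------------------------
# Latent scores
# ---------------------------------------------------------------------------

def _effective_coefficients(cfg: GeneratorConfig, group: str) -> dict:
    beta = dict(cfg.structural_coefficients)
    for path, delta in cfg.group_effect.get(group, {}).items():
        beta[tuple(path)] = beta.get(tuple(path), 0.0) + delta
    return beta


def _implied_corr(beta: dict, facet_lambda: dict, m: ModelDefinition) -> pd.DataFrame:
    """Model-implied latent correlation matrix by forward recursion on the
    standardized DAG (the closed-form path-tracing result)."""
    order = m.topological_order()
    top = [n for n in order if n not in facet_lambda]
    names = top + list(facet_lambda)
    C = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    done = []
    for n in top:
        parents = [p for p in m.predecessors(n) if p in top]
        if parents:
            bvec = np.array([beta.get((p, n), 0.0) for p in parents])
            for j in done:
                C.loc[n, j] = C.loc[j, n] = float(
                    bvec @ C.loc[parents, j].to_numpy())
            var_lin = float(bvec @ C.loc[parents, parents].to_numpy() @ bvec)
            if var_lin > 1.0 + 1e-12:
                raise ValueError(
                    f"infeasible coefficients: implied disturbance variance "
                    f"of {n} is {1 - var_lin:.4f} < 0")
        done.append(n)
    # facets are loaded children of PQ: corr(f, j) = lambda_f * corr(PQ, j),
    # corr(f, f') = lambda_f * lambda_f'
    for f, lam in facet_lambda.items():
        for j in names:
            if j == f:
                continue
            if j in facet_lambda:
                val = lam * facet_lambda[j]
            else:
                val = lam * C.loc["PQ", j]
            C.loc[f, j] = C.loc[j, f] = val
    np.fill_diagonal(C.values, 1.0)
    return C


def implied_latent_correlations(cfg: GeneratorConfig,
                                m: ModelDefinition = None) -> pd.DataFrame:
    """Closed-form latent correlation matrix implied by the generator
    (single-group; group offsets ignored)."""
    if m is None:
        m = default_initial_model()
    return _implied_corr(dict(cfg.structural_coefficients),
                         dict(cfg.facet_coefficients), m)


def generate_latent_scores(cfg: GeneratorConfig,
                           m: ModelDefinition = None,
                           rng: np.random.Generator = None) -> pd.DataFrame:
    """Draw respondent-by-latent scores from the standardized structural
    system: exogenous latents ~ N(0,1); each endogenous latent is the
    coefficient-weighted sum of its parents plus a Gaussian disturbance
    scaled for unit marginal variance; facets of a second-order construct
    are generated as loaded children of it.

    Raises ValueError ("infeasible coefficients") if any implied
    disturbance variance is negative.
    """
    if m is None:
        m = default_initial_model()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_respondents

    groups = sorted(cfg.group_proportions)
    probs = np.array([cfg.group_proportions[g] for g in groups], dtype=float)
    probs /= probs.sum()
    labels = rng.choice(groups, size=n, p=probs)

    facet_lambda = dict(cfg.facet_coefficients)
    order = m.topological_order()
    top = [x for x in order if x not in facet_lambda]

    scores = pd.DataFrame(index=range(n),
                          columns=top + list(facet_lambda), dtype=float)
    for g in groups:
        sel = labels == g
        ng = int(sel.sum())
        if ng == 0:
            continue
        beta = _effective_coefficients(cfg, g)
        C = _implied_corr(beta, {}, m)  # validates feasibility for this group
        block = {}
        for name in top:
            parents = [p for p in m.predecessors(name) if p in top]
            if not parents:
                block[name] = rng.standard_normal(ng)
                continue
            bvec = np.array([beta.get((p, name), 0.0) for p in parents])
            lin = np.column_stack([block[p] for p in parents]) @ bvec
            var_lin = float(bvec @ C.loc[parents, parents].to_numpy() @ bvec)
            sd = np.sqrt(max(1.0 - var_lin, 0.0))
            block[name] = lin + sd * rng.standard_normal(ng)
        for f, lam in facet_lambda.items():
            if abs(lam) > 1:
                raise ValueError(
                    f"infeasible coefficients: facet loading of {f} "
                    f"exceeds 1 in magnitude")
            block[f] = lam * block["PQ"] + np.sqrt(1 - lam**2) \
                * rng.standard_normal(ng)
        for name, vals in block.items():
            scores.loc[sel, name] = vals

    scores.attrs["group"] = pd.Series(labels, name="group")
    return scores


# ---------------------------------------------------------------------------
# Ordinal responses
# ---------------------------------------------------------------------------

def generate_ordinal_responses(scores: pd.DataFrame,
                               cfg: GeneratorConfig,
                               m: ModelDefinition = None,
                               rng: np.random.Generator = None) -> SurveyDataset:
    """Sample each item's category from its GRM probabilities at
    theta = the score of the item's first-order latent, then mask
    `missing_rate` of the entries completely at random."""
    if m is None:
        m = default_initial_model()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    grm_params = cfg.grm_params or default_grm_params(m)
    lo, _hi = m.scale
    n = len(scores)

    resp = pd.DataFrame(index=scores.index, columns=m.all_indicators,
                        dtype=float)
    for it in m.all_indicators:
        p = grm_params[it]
        theta = scores[m.first_order_of_item(it)].to_numpy(dtype=float)
        probs = category_probabilities(p, theta)          # (n, K)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        cat = (u[:, None] > cum).sum(axis=1)              # 0..K-1
        resp[it] = lo + cat

    if cfg.missing_rate > 0:
        mask = rng.random(resp.shape) < cfg.missing_rate
        resp = resp.mask(mask)

    group = scores.attrs.get("group")
    if group is not None:
        group = group.reset_index(drop=True)
    return SurveyDataset(responses=resp, group=group,
                         true_latent_scores=scores.reset_index(drop=True),
                         scale=m.scale)


def simulate_survey(cfg: GeneratorConfig = None,
                    m: ModelDefinition = None) -> SurveyDataset:
    """One-call generator: latent scores, then ordinal responses."""
    if cfg is None:
        cfg = GeneratorConfig()
    if m is None:
        m = default_initial_model()
    rng = np.random.default_rng(cfg.seed)
    scores = generate_latent_scores(cfg, m, rng)
    return generate_ordinal_responses(scores, cfg, m, rng)


# ---------------------------------------------------------------------------
# Sample splitting
# ---------------------------------------------------------------------------

def split_sample(d: SurveyDataset, fraction: float = None, seed: int = 0,
                 n_construction: int = None):
    """Disjoint random partition into (construction, evaluation) sets.

    Either `fraction` (construction share, rounded to the nearest integer
    count) or an explicit `n_construction` (e.g. 574 to reproduce the
    574/1,335 study split) must be given.
    """
    n = d.n_respondents
    if n_construction is None:
        if fraction is None or not (0.0 < fraction < 1.0):
            raise ValueError("fraction must lie strictly between 0 and 1")
        n_construction = int(np.rint(n * fraction))
    if not (0 < n_construction < n):
        raise ValueError("construction set size out of range")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    first = np.sort(perm[:n_construction])
    second = np.sort(perm[n_construction:])
    return d.subset(first), d.subset(second)
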