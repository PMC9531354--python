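"""Samejima's graded response model: calibration, information, screening flags.

Each first-order construct is treated as unidimensional: responses to its
items are governed by a latent trait theta ~ N(0, 1) through the cumulative
logistic model

    P(X_i >= k | theta) = 1 / (1 + exp(-a_i (theta - b_{i,k-1}))),

with discrimination a_i > 0 and strictly increasing thresholds
b_{i,1} < ... < b_{i,K-1}.  The logistic metric is used without the 1.7
scaling constant.

Calibration is marginal maximum likelihood by EM over a fixed quadrature
grid (equally spaced nodes weighted by the standard-normal density).
Item information follows Samejima's formula; the per-item average
information Ibar is the standard-normal-weighted mean of the item
information function, used for the information-based screening criterion
Ibar >= 16 / (number of items in the draft instrument).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "GrmItemParams",
    "InformationCurve",
    "GradedResponseModel",
    "GrmResults",
    "fit_grm",
    "category_probabilities",
    "item_information",
    "information_threshold",
    "grm_flags",
]


@dataclass
class GrmItemParams:
    """Item parameters of the graded response model.

    a : discrimination (> 0 in fitted output)
    b : ordered thresholds b_1..b_{K-1} on the theta scale
    se_a, se_b : standard errors (None until estimated)
    """

    a: float
    b: np.ndarray
    se_a: float = None
    se_b: np.ndarray = None

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        if self.b.ndim != 1 or len(self.b) < 1:
            raise ValueError("thresholds must be a non-empty 1-d array")
        if np.any(np.diff(self.b) <= 0):
            raise ValueError("threshold order: b must be strictly increasing")

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass
class InformationCurve:
    """Item information evaluated on a theta grid, with its
    standard-normal-weighted mean Ibar."""

    grid: np.ndarray
    iif: np.ndarray
    mean_info: float


# ---------------------------------------------------------------------------
# Probabilities and information
# ---------------------------------------------------------------------------

def _cum_probs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P*(k) = P(X >= k+1 | theta) for k = 0..K-1 stacked with the
    boundary rows P*_0 = 1 and P*_K = 0.  Shape (K+1, len(theta))."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    ps = expit(a * (theta[None, :] - np.asarray(b, dtype=float)[:, None]))
    ones = np.ones((1, theta.size))
    zeros = np.zeros((1, theta.size))
    return np.vstack([ones, ps, zeros])


def category_probabilities(p: GrmItemParams, theta) -> np.ndarray:
    """P(X = k | theta) for k = 1..K; shape (len(theta), K)."""
    star = _cum_probs(p.a, p.b, theta)
    return (star[:-1] - star[1:]).T


def item_information(p: GrmItemParams, grid, eps: float = 1e-12) -> InformationCurve:
    """Samejima item information

        I(theta) = a^2 sum_k [P*_k(1-P*_k) - P*_{k+1}(1-P*_{k+1})]^2
                              / (P*_k - P*_{k+1})

    with P*_0 = 1, P*_K = 0; categories with probability below `eps` at a
    grid point contribute nothing there.  `mean_info` is the integral of
    I(theta) against the standard-normal density (trapezoidal on the grid,
    weights renormalized).
    """
    grid = np.asarray(grid, dtype=float)
    star = _cum_probs(p.a, p.b, grid)
    q = star * (1.0 - star)
    num = (q[:-1] - q[1:]) ** 2
    den = star[:-1] - star[1:]
    terms = np.where(den > eps, num / np.where(den > eps, den, 1.0), 0.0)
    iif = p.a**2 * terms.sum(axis=0)
    w = norm.pdf(grid)
    if grid.size < 2:
        mean_info = float(iif[0])
    else:
        mean_info = float(np.trapezoid(iif * w, grid) / np.trapezoid(w, grid))
    return InformationCurve(grid=grid, iif=iif, mean_info=mean_info)


def information_threshold(k_items: int, total_floor: float = 16.0) -> float:
    """Per-item average-information floor: a test is considered poor below
    total information 16, so each of K items must contribute at least
    16 / K on average (16/29 ~ 0.55 for the 29-item draft)."""
    return total_floor / k_items


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def _default_grid(n_nodes: int = 21, lo: float = -6.0, hi: float = 6.0):
    grid = np.linspace(lo, hi, n_nodes)
    w = norm.pdf(grid)
    return grid, w / w.sum()


def _pack(a, b):
    # a > 0 via log; b increasing via first threshold + log-gaps
    return np.concatenate([[np.log(a), b[0]], np.log(np.diff(b))]) if len(b) > 1 \
        else np.array([np.log(a), b[0]])


def _unpack(x):
    a = float(np.exp(x[0]))
    if len(x) > 2:
        b = np.concatenate([[x[1]], x[1] + np.cumsum(np.exp(x[2:]))])
    else:
        b = np.array([x[1]])
    return a, b


class GradedResponseModel:
    """Marginal-maximum-likelihood GRM for one block of ordinal items.

    Parameters
    ----------
    data : DataFrame
        Respondent-by-item integer responses (NaN = missing), categories
        on any integer scale; internally recoded to 1..K per item, with
        unobserved categories collapsed (mapping recorded).
    n_nodes, grid_range : quadrature controls (equally spaced nodes,
        standard-normal weights).
    """

    def __init__(self, data: pd.DataFrame, n_nodes: int = 21,
                 grid_range=(-6.0, 6.0)):
        self.items = list(data.columns)
        self.n_nodes = n_nodes
        self.grid, self.weights = _default_grid(n_nodes, *grid_range)
        self._recode(data)

    def _recode(self, data):
        self.codes = {}          # item -> sorted observed raw categories
        self._resp = {}          # item -> int array, -1 = missing
        self.collapsed = {}      # item -> mapping raw category -> 1..K
        for it in self.items:
            col = data[it].to_numpy(dtype=float)
            obs = np.unique(col[~np.isnan(col)]).astype(int)
            if len(obs) < 2:
                raise ValueError(
                    f"item {it!r}: all responses in one category"
                )
            mapping = {raw: k + 1 for k, raw in enumerate(obs)}
            self.codes[it] = obs
            self.collapsed[it] = mapping
            coded = np.full(len(col), -1, dtype=int)
            m = ~np.isnan(col)
            coded[m] = np.array([mapping[int(v)] for v in col[m]])
            self._resp[it] = coded

    # -- likelihood machinery ---------------------------------------------

    def _item_logprob(self, params: GrmItemParams) -> np.ndarray:
        """log P(X=k | theta_q), shape (K, Q)."""
        star = _cum_probs(params.a, params.b, self.grid)
        pk = np.clip(star[:-1] - star[1:], 1e-300, None)
        return np.log(pk)

    def _posteriors(self, params: dict):
        """Posterior over quadrature nodes per respondent and the marginal
        log-likelihood."""
        n = len(next(iter(self._resp.values())))
        logjoint = np.tile(np.log(self.weights), (n, 1))
        for it in self.items:
            lp = self._item_logprob(params[it])          # (K, Q)
            coded = self._resp[it]
            m = coded > 0
            logjoint[m] += lp[coded[m] - 1, :]
        mx = logjoint.max(axis=1, keepdims=True)
        joint = np.exp(logjoint - mx)
        marg = joint.sum(axis=1)
        loglik = float((np.log(marg) + mx.ravel()).sum())
        return joint / marg[:, None], loglik

    def _mstep_item(self, it, post) -> GrmItemParams:
        coded = self._resp[it]
        m = coded > 0
        K = len(self.codes[it])
        # expected counts r[k, q]
        r = np.zeros((K, self.n_nodes))
        for k in range(K):
            sel = m & (coded == k + 1)
            if sel.any():
                r[k] += post[sel].sum(axis=0)

        def neg(x):
            a, b = _unpack(x)
            star = _cum_probs(a, b, self.grid)
            pk = np.clip(star[:-1] - star[1:], 1e-300, None)
            return -(r * np.log(pk)).sum()

        x0 = _pack(self._params[it].a, self._params[it].b)
        res = minimize(neg, x0, method="L-BFGS-B")
        a, b = _unpack(res.x)
        return GrmItemParams(a=a, b=b)

    def _start_values(self):
        params = {}
        for it in self.items:
            K = len(self.codes[it])
            coded = self._resp[it]
            obs = coded[coded > 0]
            # cumulative proportions -> normal-quantile starts
            props = np.array([(obs >= k + 2).mean() for k in range(K - 1)])
            props = np.clip(props, 0.01, 0.99)
            b = norm.ppf(1 - props)  # b_k ~ -Phi^-1(P(X >= k+1))
            b = np.maximum.accumulate(b) + 1e-4 * np.arange(K - 1)
            params[it] = GrmItemParams(a=1.0, b=b)
        return params

    def fit(self, max_iter: int = 500, tol: float = 1e-4) -> "GrmResults":
        """EM iteration until max absolute parameter change < `tol`."""
        self._params = self._start_values()
        history = []
        converged = False
        for _ in range(max_iter):
            post, loglik = self._posteriors(self._params)
            history.append(loglik)
            new = {it: self._mstep_item(it, post) for it in self.items}
            delta = max(
                max(abs(new[it].a - self._params[it].a),
                    np.max(np.abs(new[it].b - self._params[it].b)))
                for it in self.items
            )
            self._params = new
            if delta < tol:
                converged = True
                break
        _, loglik = self._posteriors(self._params)
        history.append(loglik)
        self._attach_ses(self._params)
        return GrmResults(
            model=self, params=self._params, loglik=loglik,
            loglik_history=history, converged=converged,
        )

    def _attach_ses(self, params):
        """Per-item standard errors from the outer product of per-respondent
        scores of the marginal log-likelihood (BHHH block approximation),
        with numerical differentiation in the packed parameterization."""
        post, _ = self._posteriors(params)
        n = post.shape[0]
        for it in self.items:
            x_hat = _pack(params[it].a, params[it].b)
            h = 1e-5

            def per_resp_loglik(x):
                a, b = _unpack(x)
                lp = self._item_logprob(GrmItemParams(a=a, b=b))
                coded = self._resp[it]
                m = coded > 0
                out = np.zeros(n)
                # E-step posterior fixed: expected per-respondent loglik
                out[m] = (post[m] * lp[coded[m] - 1, :]).sum(axis=1)
                return out

            base = per_resp_loglik(x_hat)
            grads = np.zeros((n, len(x_hat)))
            for j in range(len(x_hat)):
                xp = x_hat.copy()
                xp[j] += h
                grads[:, j] = (per_resp_loglik(xp) - base) / h
            info = grads.T @ grads
            try:
                cov_packed = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                continue
            # delta method back to (a, b)
            J = np.zeros((len(x_hat), len(x_hat)))
            for j in range(len(x_hat)):
                xp = x_hat.copy()
                xp[j] += h
                ap, bp = _unpack(xp)
                a0, b0 = _unpack(x_hat)
                J[0, j] = (ap - a0) / h
                J[1:, j] = (bp - b0) / h
            cov = J @ cov_packed @ J.T
            ses = np.sqrt(np.clip(np.diag(cov), 0, None))
            params[it].se_a = float(ses[0])
            params[it].se_b = ses[1:]


@dataclass
class GrmResults:
    """Fitted GRM for one construct."""

    model: GradedResponseModel
    params: dict
    loglik: float
    loglik_history: list
    converged: bool
    _curves: dict = field(default_factory=dict, repr=False)

    def information(self, item: str, grid=None) -> InformationCurve:
        if grid is None:
            grid = self.model.grid
        return item_information(self.params[item], grid)

    def test_information(self, grid=None) -> np.ndarray:
        """Test information = sum of item informations on the grid."""
        if grid is None:
            grid = self.model.grid
        return np.sum([self.information(it, grid).iif for it in self.params], axis=0)

    def mean_information(self) -> dict:
        return {it: self.information(it).mean_info for it in self.params}

    def summary_frame(self) -> pd.DataFrame:
        """Item, a, se_a, b_k, se_b_k, Ibar table."""
        rows = []
        for it, p in self.params.items():
            row = {"item": it, "a": p.a, "se_a": p.se_a}
            for k, bk in enumerate(p.b, start=1):
                row[f"b{k}"] = bk
            if p.se_b is not None:
                for k, s in enumerate(p.se_b, start=1):
                    row[f"se_b{k}"] = s
            row["mean_info"] = self.information(it).mean_info
            rows.append(row)
        return pd.DataFrame(rows).set_index("item")

    def plot_information(self, ax=None):
        """Item information curves plus the test information function."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for it in self.params:
            c = self.information(it)
            ax.plot(c.grid, c.iif, label=it, lw=1)
        ax.plot(self.model.grid, self.test_information(), "k--", label="TIF", lw=2)
        ax.set_xlabel(r"$\theta$")
        ax.set_ylabel("information")
        ax.legend(fontsize=7, ncol=2)
        return ax


def fit_grm(data: pd.DataFrame, items=None, **kwargs) -> dict:
    """Calibrate the GRM on one construct's items; returns item -> params.

    Thin functional wrapper around :class:`GradedResponseModel`.
    """
    if items is not None:
        data = data[list(items)]
    res = GradedResponseModel(data, **kwargs).fit()
    return res.params


# ---------------------------------------------------------------------------
# Screening flags
# ---------------------------------------------------------------------------

def grm_flags(params: dict, curves: dict, k_items: int,
              a_floor: float = 0.3, b_range=(-4.0, 4.0)) -> pd.DataFrame:
    """IRT deletion flags per item.

    a_flag:    a < 0.3 (poor discrimination)
    b_flag:    any threshold outside (-4, 4)
    info_flag: Ibar < 16 / k_items (k_items = draft instrument size)
    """
    thr = information_threshold(k_items)
    rows = []
    for it, p in params.items():
        ibar = curves[it].mean_info
        rows.append({
            "item": it,
            "a": p.a,
            "a_flag": p.a < a_floor,
            "b_min": float(p.b.min()),
            "b_max": float(p.b.max()),
            "b_flag": bool((p.b <= b_range[0]).any() or (p.b >= b_range[1]).any()),
            "mean_info": ibar,
            "info_flag": ibar < thr,
        })
    return pd.DataFrame(rows).set_index("item")
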