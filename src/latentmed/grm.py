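"""Graded Response Model (GRM) fitting and latent-trait scoring.

The GRM links ordered polytomous items :math:`Y_j \\in \\{1, \\dots, K_j\\}`
to a single latent trait :math:`\\theta` through logistic cumulative response
curves

.. math::

    P(Y_j \\ge k \\mid \\theta) = \\frac{1}{1 + e^{-a_j(\\theta - b_{j,k-1})}},
    \\qquad k = 2, \\dots, K_j,

with item discrimination :math:`a_j > 0` and strictly increasing thresholds
:math:`b_{j1} < \\dots < b_{j,K_j-1}`.  The trait prior is standard normal,
which identifies the scale.  Estimation is marginal maximum likelihood by an
EM algorithm: the E-step computes posterior weights of each participant over
a fixed Gauss-Hermite quadrature grid, the M-step refits each item's logistic
parameters against the expected category-by-node counts.  Missing item
responses simply drop out of a participant's likelihood contribution.

Participant trait scores are expected a posteriori (EAP) values — posterior
means of :math:`\\theta` under the N(0,1) prior given the observed responses —
and are standardized to sample mean 0, SD 1 before use as exposures
downstream.  Model fit is assessed with two-way margins: observed versus
model-expected bivariate category frequencies for every item pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "GRMItem",
    "GRMModel",
    "TraitScores",
    "category_probabilities",
    "fit_grm",
    "eap_scores",
    "two_way_margins",
    "gauss_hermite_normal",
]


def gauss_hermite_normal(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights rescaled for integration against N(0,1)."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


@dataclass(frozen=True)
class GRMItem:
    """One graded item: discrimination ``a`` and ordered thresholds ``b``."""

    discrimination: float
    thresholds: tuple[float, ...]
    name: str = ""

    def __post_init__(self):
        if not self.discrimination > 0:
            raise ValueError(
                f"item {self.name!r}: discrimination must be > 0, "
                f"got {self.discrimination}"
            )
        b = np.asarray(self.thresholds, dtype=float)
        if b.size < 1:
            raise ValueError(f"item {self.name!r}: needs >= 2 categories")
        if not np.all(np.diff(b) > 0):
            raise ValueError(
                f"item {self.name!r}: thresholds must be strictly increasing, "
                f"got {self.thresholds}"
            )
        object.__setattr__(self, "thresholds", tuple(float(v) for v in b))

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


def category_probabilities(theta, item: GRMItem) -> np.ndarray:
    """Category probabilities P(Y = k | theta), k = 0..K-1.

    Cumulative curves P*(k) = expit(a (theta - b_k)) are differenced, with
    P*(below first) = 1 and P*(beyond last) = 0.  Returns shape
    ``(len(theta), K)`` (or ``(K,)`` for scalar ``theta``); rows sum to 1.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(item.thresholds)
    cum = expit(item.discrimination * (th[:, None] - b[None, :]))
    ones = np.ones((th.size, 1))
    zeros = np.zeros((th.size, 1))
    star = np.hstack([ones, cum, zeros])
    probs = star[:, :-1] - star[:, 1:]
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return probs[0]
    return probs


@dataclass
class TraitScores:
    """EAP trait scores with posterior SDs and the standardized version."""

    eap: pd.Series
    posterior_sd: pd.Series
    standardized: pd.Series


@dataclass
class GRMModel:
    """A fitted (or constructed) graded response model for one trait."""

    items: list[GRMItem]
    log_likelihood: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    n_quadrature: int = 61
    #: per item, the original category labels in ascending order
    category_labels: dict[str, list] = field(default_factory=dict)

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    def to_json(self) -> str:
        payload = {
            "items": [
                {
                    "name": it.name,
                    "discrimination": it.discrimination,
                    "thresholds": list(it.thresholds),
                }
                for it in self.items
            ],
            "log_likelihood": None
            if np.isnan(self.log_likelihood)
            else self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "n_quadrature": self.n_quadrature,
            "category_labels": self.category_labels,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GRMModel":
        d = json.loads(text)
        items = [
            GRMItem(e["discrimination"], tuple(e["thresholds"]), e["name"])
            for e in d["items"]
        ]
        return cls(
            items=items,
            log_likelihood=np.nan
            if d["log_likelihood"] is None
            else d["log_likelihood"],
            n_iterations=d["n_iterations"],
            converged=d["converged"],
            n_quadrature=d["n_quadrature"],
            category_labels={k: list(v) for k, v in d["category_labels"].items()},
        )


# ---------------------------------------------------------------------------
# response-matrix plumbing


def _encode_responses(responses) -> tuple[np.ndarray, list[str], list[list]]:
    """Map a response table to 0-based integer codes (missing -> -1).

    Accepts a DataFrame (columns = items) or a 2-D array.  Each item's
    observed unique values, sorted ascending, become categories 0..K-1.
    """
    if isinstance(responses, pd.DataFrame):
        names = [str(c) for c in responses.columns]
        raw = responses.to_numpy(dtype=float)
    else:
        raw = np.asarray(responses, dtype=float)
        if raw.ndim != 2:
            raise ValueError("responses must be 2-D (participants x items)")
        names = [f"item{j}" for j in range(raw.shape[1])]

    n, J = raw.shape
    codes = np.full((n, J), -1, dtype=int)
    labels: list[list] = []
    for j in range(J):
        col = raw[:, j]
        obs = np.unique(col[~np.isnan(col)])
        if obs.size < 2:
            raise ValueError(
                f"item {names[j]!r} shows {obs.size} observed category(ies); "
                "collapse it with a neighbouring category or drop the item"
            )
        labels.append([float(v) for v in obs])
        mask = ~np.isnan(col)
        codes[mask, j] = np.searchsorted(obs, col[mask])
    return codes, names, labels


def _item_prob_table(item: GRMItem, nodes: np.ndarray) -> np.ndarray:
    """P(Y = k | theta_q), shape (K, Q), floored away from exact zero."""
    p = category_probabilities(nodes, item).T
    return np.clip(p, 1e-300, None)


def _marginal_loglik(codes, items, nodes, log_wq) -> tuple[float, np.ndarray]:
    """Marginal log-likelihood and posterior node weights (n x Q)."""
    n, J = codes.shape
    Q = nodes.size
    logjoint = np.tile(log_wq, (n, 1))
    for j, item in enumerate(items):
        logp = np.log(_item_prob_table(item, nodes))  # (K, Q)
        mask = codes[:, j] >= 0
        logjoint[mask] += logp[codes[mask, j], :]
    ll_i = logsumexp(logjoint, axis=1)
    with np.errstate(under="ignore"):
        post = np.exp(logjoint - ll_i[:, None])
    return float(ll_i.sum()), post


def _pack_item(a: float, b: np.ndarray) -> np.ndarray:
    """(a, b) -> unconstrained vector (log a, b1, log diffs)."""
    b = np.asarray(b, dtype=float)
    z = np.empty(1 + b.size)
    z[0] = np.log(a)
    z[1] = b[0]
    if b.size > 1:
        z[2:] = np.log(np.diff(b))
    return z


def _unpack_item(z: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(z[0]))
    b = np.empty(z.size - 1)
    b[0] = z[1]
    if b.size > 1:
        b[1:] = b[0] + np.cumsum(np.exp(z[2:]))
    return a, b


def _mstep_item(counts: np.ndarray, nodes: np.ndarray, item: GRMItem) -> GRMItem:
    """Maximize the expected complete-data log-likelihood for one item.

    ``counts[k, q]`` is the expected number of responses in category k at
    quadrature node q (from the E-step posterior weights).
    """

    def neg_ell(z):
        a, b = _unpack_item(z)
        probe = GRMItem(a, tuple(b), item.name)
        logp = np.log(_item_prob_table(probe, nodes))
        return -float(np.sum(counts * logp))

    z0 = _pack_item(item.discrimination, np.asarray(item.thresholds))
    res = minimize(neg_ell, z0, method="L-BFGS-B")
    a, b = _unpack_item(res.x if res.fun <= neg_ell(z0) else z0)
    return GRMItem(a, tuple(b), item.name)


def _start_items(codes, names, labels, nodes) -> list[GRMItem]:
    """Crude but safe starts: a = 1, thresholds at normal quantiles of the
    observed cumulative frequencies."""
    from scipy.stats import norm

    items = []
    for j, name in enumerate(names):
        K = len(labels[j])
        col = codes[:, j]
        obs = col[col >= 0]
        freq = np.bincount(obs, minlength=K) / obs.size
        cum_above = 1.0 - np.cumsum(freq)[:-1]
        cum_above = np.clip(cum_above, 1e-4, 1 - 1e-4)
        b = -norm.ppf(cum_above)
        b = np.maximum.accumulate(b + 1e-9 * np.arange(K - 1))
        items.append(GRMItem(1.0, tuple(b), name))
    return items


def fit_grm(
    responses,
    n_quadrature: int = 61,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> GRMModel:
    """Fit a unidimensional GRM by EM over a Gauss-Hermite grid.

    Parameters
    ----------
    responses
        DataFrame or 2-D array of ordinal responses; NaN marks a missing
        item response (that item is dropped from the participant's
        likelihood contribution).
    n_quadrature
        Number of Gauss-Hermite nodes for integrating over theta ~ N(0,1).
    max_iter, tol
        EM stops when the marginal log-likelihood improves by less than
        ``tol`` or after ``max_iter`` cycles (then flagged non-converged).
    """
    codes, names, labels = _encode_responses(responses)
    if codes.shape[1] < 2:
        raise ValueError("need at least 2 items to identify a GRM")
    nodes, wq = gauss_hermite_normal(n_quadrature)
    log_wq = np.log(wq)

    items = _start_items(codes, names, labels, nodes)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, post = _marginal_loglik(codes, items, nodes, log_wq)
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
        new_items = []
        for j, item in enumerate(items):
            K = len(labels[j])
            mask = codes[:, j] >= 0
            # expected category-by-node counts
            counts = np.zeros((K, len(nodes)))
            cj = codes[mask, j]
            np.add.at(counts, cj, post[mask])
            new_items.append(_mstep_item(counts, nodes, item))
        items = new_items

    ll, _ = _marginal_loglik(codes, items, nodes, log_wq)
    if not converged:
        warnings.warn(
            f"GRM EM did not converge in {max_iter} iterations "
            f"(last improvement {ll - ll_prev:.3g})",
            RuntimeWarning,
        )
    return GRMModel(
        items=items,
        log_likelihood=ll,
        n_iterations=it,
        converged=converged,
        n_quadrature=n_quadrature,
        category_labels={name: labels[j] for j, name in enumerate(names)},
    )


def eap_scores(model: GRMModel, responses) -> TraitScores:
    """Expected a posteriori trait scores with posterior SDs.

    Participants with every item missing receive a missing score.  The
    ``standardized`` series has sample mean 0 and SD 1 over scored
    participants.
    """
    codes, names, labels = _encode_responses_against(model, responses)
    nodes, wq = gauss_hermite_normal(model.n_quadrature)
    _, post = _marginal_loglik(codes, model.items, nodes, np.log(wq))
    eap = post @ nodes
    second = post @ nodes**2
    psd = np.sqrt(np.maximum(second - eap**2, 0.0))

    all_missing = np.all(codes < 0, axis=1)
    eap[all_missing] = np.nan
    psd[all_missing] = np.nan

    index = (
        responses.index
        if isinstance(responses, pd.DataFrame)
        else pd.RangeIndex(len(eap))
    )
    eap_s = pd.Series(eap, index=index, name="eap")
    scored = eap_s.dropna()
    z = (eap_s - scored.mean()) / scored.std(ddof=1)
    return TraitScores(
        eap=eap_s,
        posterior_sd=pd.Series(psd, index=index, name="posterior_sd"),
        standardized=z.rename("standardized"),
    )


def _encode_responses_against(model: GRMModel, responses):
    """Encode responses using the fitted model's stored category labels, so
    scoring data never silently re-maps categories."""
    if isinstance(responses, pd.DataFrame):
        names = [str(c) for c in responses.columns]
        raw = responses.to_numpy(dtype=float)
    else:
        raw = np.asarray(responses, dtype=float)
        names = [it.name for it in model.items]
    if names != model.item_names:
        raise ValueError(
            f"response columns {names} do not match model items "
            f"{model.item_names}"
        )
    n, J = raw.shape
    codes = np.full((n, J), -1, dtype=int)
    labels = []
    for j, name in enumerate(names):
        lab = np.asarray(model.category_labels.get(name, []), dtype=float)
        if lab.size == 0:
            lab = np.unique(raw[:, j][~np.isnan(raw[:, j])])
        labels.append(list(lab))
        col = raw[:, j]
        mask = ~np.isnan(col)
        pos = np.searchsorted(lab, col[mask])
        pos = np.clip(pos, 0, lab.size - 1)
        if not np.allclose(lab[pos], col[mask]):
            raise ValueError(f"item {name!r}: unseen category in scoring data")
        codes[mask, j] = pos
    return codes, names, labels


def two_way_margins(
    model: GRMModel, responses, flag_threshold: float = 4.0
) -> pd.DataFrame:
    """Observed vs model-expected bivariate margins for every item pair.

    For items (j, l) the model-expected probability of the category pair
    (k, m) integrates the product of the two items' category curves over the
    N(0,1) trait prior; expected counts use the number of participants with
    both items observed.  The chi-square-type residual (O - E)^2 / E is
    reported per cell and flagged when above ``flag_threshold`` (classical
    rule of thumb).
    """
    codes, names, labels = _encode_responses_against(model, responses)
    nodes, wq = gauss_hermite_normal(model.n_quadrature)
    tables = [_item_prob_table(it, nodes) for it in model.items]

    rows = []
    J = len(model.items)
    for j in range(J):
        for l in range(j + 1, J):
            both = (codes[:, j] >= 0) & (codes[:, l] >= 0)
            n_pair = int(both.sum())
            if n_pair == 0:
                continue
            Kj, Kl = len(labels[j]), len(labels[l])
            obs = np.zeros((Kj, Kl))
            np.add.at(obs, (codes[both, j], codes[both, l]), 1.0)
            # E[p_jk p_lm] over theta ~ N(0,1)
            exp_p = np.einsum("kq,mq,q->km", tables[j], tables[l], wq)
            exp_c = n_pair * exp_p
            resid = (obs - exp_c) ** 2 / exp_c
            for k in range(Kj):
                for m in range(Kl):
                    rows.append(
                        {
                            "item_a": names[j],
                            "item_b": names[l],
                            "category_a": labels[j][k],
                            "category_b": labels[l][m],
                            "observed": obs[k, m],
                            "expected": exp_c[k, m],
                            "residual": resid[k, m],
                            "flagged": bool(resid[k, m] > flag_threshold),
                        }
                    )
    return pd.DataFrame(rows)
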