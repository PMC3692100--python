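"""Two-state gain/loss Markov models with among-character rate variation.

The dynamics of each binary character along the tree follow a continuous-time
Markov chain with gain rate g (0 -> 1) and loss rate l (1 -> 0).  Three model
tiers describe how rates vary among characters:

``single``
    one (g, l) pair shared by all characters;
``gamma_invariant``
    an overall rate multiplier drawn from a discretized gamma distribution
    (K mean-of-quantile-bin categories, Yang-style) plus an invariant
    (rate-0) category of proportion p_inv — the default, since different
    genes evolve at very different rates;
``mixture``
    gain and loss multipliers drawn *independently* from two discretized
    gamma distributions, giving a K_gain x K_loss category grid.

All tiers are normalized so that the mixture-average number of events per
unit branch length at stationarity equals 1, which puts branch lengths in
units of expected events per character and removes the rate/branch-length
confounding.  Likelihoods are computed by Felsenstein pruning with per-node
scaling, optionally conditioned on the character being observable at all
(an all-absent character never enters a real dataset, so the per-site
likelihood is divided by 1 - P(all-zero column)).  Free parameters are fit
by maximum likelihood with fixed multi-starts.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from .tree_inference import Phylogeny

__all__ = [
    "GainLossParams",
    "RateMixture",
    "LikelihoodResult",
    "ModelError",
    "transition_probability",
    "stationary_frequencies",
    "build_rate_mixture",
    "site_likelihood",
    "corrected_log_likelihood",
    "fit_model",
    "posterior_rate_per_site",
]

MODEL_TIERS = ("single", "gamma_invariant", "mixture")


class ModelError(ValueError):
    """Raised for invalid model parameters or likelihood failures."""


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the best result seen so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def transition_probability(g: float, l: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the gain/loss chain over time t.

    Closed form: with r = g + l, pi1 = g / r,
    P01(t) = pi1 (1 - e^{-rt}) and P10(t) = pi0 (1 - e^{-rt}).
    """
    if t < 0:
        raise ModelError("negative branch length")
    if g < 0 or l < 0:
        raise ModelError("rates must be non-negative")
    r = g + l
    if r == 0:
        raise ModelError("gain and loss rates cannot both be zero")
    pi1 = g / r
    pi0 = l / r
    decay = math.exp(-r * t)
    return np.array([[pi0 + pi1 * decay, pi1 * (1.0 - decay)],
                     [pi0 * (1.0 - decay), pi1 + pi0 * decay]])


def stationary_frequencies(g: float, l: float):
    """Stationary distribution (pi0, pi1) = (l, g) / (g + l)."""
    r = g + l
    if r <= 0:
        raise ModelError("g + l must be positive")
    return (l / r, g / r)


@dataclass
class GainLossParams:
    """Parameters of one model tier (rates before normalization).

    Only the gain/loss *ratio* is identifiable once the mixture is
    normalized to one expected event per unit branch length, so fitted
    parameter sets conventionally carry l = 1.
    """

    g: float = 1.0
    l: float = 1.0
    model_tier: str = "gamma_invariant"
    alpha: float = 1.0
    p_inv: float = 0.0
    K: int = 4
    alpha_gain: float = 1.0
    alpha_loss: float = 1.0
    K_gain: int = 3
    K_loss: int = 3

    def __post_init__(self):
        if self.model_tier not in MODEL_TIERS:
            raise ModelError(f"unknown model tier {self.model_tier!r}")
        if self.g <= 0 or self.l <= 0:
            raise ModelError("rates must be strictly positive")
        if not (0.0 <= self.p_inv < 1.0):
            raise ModelError("p_inv must lie in [0, 1)")
        if min(self.K, self.K_gain, self.K_loss) < 1:
            raise ModelError("category counts must be >= 1")
        if min(self.alpha, self.alpha_gain, self.alpha_loss) <= 0:
            raise ModelError("gamma shapes must be positive")

    @property
    def ratio(self) -> float:
        return self.g / self.l

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GainLossParams":
        return cls(**json.loads(text))


@dataclass
class RateMixture:
    """Discretized rate categories: (gain_i, loss_i, weight_i) triples.

    ``pis[i]`` holds the root prior of category i; for the invariant
    (rate-0) category, where the stationary distribution is undefined, the
    base-rate stationary frequencies are used.
    """

    gains: np.ndarray
    losses: np.ndarray
    weights: np.ndarray
    pis: np.ndarray

    def __post_init__(self):
        self.gains = np.atleast_1d(np.asarray(self.gains, dtype=float))
        self.losses = np.atleast_1d(np.asarray(self.losses, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.pis = np.atleast_2d(np.asarray(self.pis, dtype=float))
        k = self.gains.size
        if not (self.losses.size == k == self.weights.size == self.pis.shape[0]):
            raise ModelError("mixture component arrays disagree in length")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ModelError("mixture weights must sum to 1")
        if np.any(self.gains < 0) or np.any(self.losses < 0):
            raise ModelError("rates must be >= 0")

    @property
    def n_categories(self) -> int:
        return self.gains.size

    def categories(self):
        return list(zip(self.gains, self.losses, self.weights))

    def mean_total_rate(self) -> float:
        """Mixture-average events per unit branch length at stationarity."""
        flux = np.zeros_like(self.gains)
        tot = self.gains + self.losses
        nz = tot > 0
        flux[nz] = 2.0 * self.gains[nz] * self.losses[nz] / tot[nz]
        return float(self.weights @ flux)


def _gamma_category_multipliers(alpha: float, K: int) -> np.ndarray:
    """Mean-of-quantile-bin discretization of Gamma(alpha, mean 1) into K
    equal-weight categories (the category mean equals the conditional mean
    of the bin, so the discretized mean is exactly 1)."""
    if K == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, K + 1), a=alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    return K * np.diff(upper)


def build_rate_mixture(params: GainLossParams) -> RateMixture:
    """Discretize a parameter set into weighted (gain, loss) categories,
    normalized to a mixture-mean total rate of 1."""
    g, l = params.g, params.l
    base_pi = stationary_frequencies(g, l)
    if params.model_tier == "single":
        gains, losses, weights = np.array([g]), np.array([l]), np.array([1.0])
    elif params.model_tier == "gamma_invariant":
        mult = _gamma_category_multipliers(params.alpha, params.K)
        gains = np.append(mult * g, 0.0)
        losses = np.append(mult * l, 0.0)
        weights = np.append(np.full(params.K, (1.0 - params.p_inv) / params.K),
                            params.p_inv)
        if params.p_inv == 0.0:
            gains, losses, weights = gains[:-1], losses[:-1], weights[:-1]
    else:  # mixture: independent gain and loss multipliers on a grid
        mg = _gamma_category_multipliers(params.alpha_gain, params.K_gain)
        ml = _gamma_category_multipliers(params.alpha_loss, params.K_loss)
        gains = np.repeat(mg, params.K_loss) * g
        losses = np.tile(ml, params.K_gain) * l
        weights = np.full(params.K_gain * params.K_loss,
                          1.0 / (params.K_gain * params.K_loss))

    weights = weights / weights.sum()
    pis = np.empty((gains.size, 2))
    for i in range(gains.size):
        tot = gains[i] + losses[i]
        pis[i] = (losses[i] / tot, gains[i] / tot) if tot > 0 else base_pi

    mix = RateMixture(gains=gains, losses=losses, weights=weights, pis=pis)
    mean = mix.mean_total_rate()
    if mean <= 0:
        raise ModelError("mixture has zero mean rate")
    return RateMixture(gains=gains / mean, losses=losses / mean,
                       weights=weights, pis=pis)


# ------------------------------------------------------------ likelihoods

def _leaf_partials(tree: Phylogeny, matrix: np.ndarray, taxa) -> np.ndarray:
    """One-hot tip partials, shape (n_nodes, n_sites, 2), in tree node ids."""
    row_of = {t: i for i, t in enumerate(taxa)}
    missing = [lb for lb in tree.leaf_labels if lb not in row_of]
    if missing:
        raise ModelError(f"pattern lacks taxa present in the tree: {missing[:3]}")
    if len(taxa) != tree.n_leaves:
        raise ModelError("pattern taxa do not match the tree's leaf set")
    n_sites = matrix.shape[1]
    L = np.zeros((tree.n_nodes, n_sites, 2))
    for node in tree.leaves:
        states = matrix[row_of[tree.labels[node]]]
        L[node, np.arange(n_sites), states] = 1.0
    return L


def _branch_transition_matrices(tree: Phylogeny, g: float, l: float) -> np.ndarray:
    P = np.empty((tree.n_nodes, 2, 2))
    for v in range(tree.n_nodes):
        if v == tree.root:
            P[v] = np.eye(2)
        elif g + l == 0:
            P[v] = np.eye(2)
        else:
            P[v] = transition_probability(g, l, float(tree.lengths[v]))
    return P


def _category_up_pass(tree: Phylogeny, leaf_partials: np.ndarray,
                      g: float, l: float, pi):
    """Pruning up-pass for one category.

    Returns (U, logscale, P) where U[v] are per-node partials rescaled per
    site (max entry 1 at internal nodes) and logscale accumulates the
    per-site log of the factors divided out on the path to the root.
    """
    n_sites = leaf_partials.shape[1]
    P = _branch_transition_matrices(tree, g, l)
    U = leaf_partials.copy()
    logscale = np.zeros(n_sites)
    for v in tree.postorder:
        if tree.is_leaf[v]:
            continue
        acc = np.ones((n_sites, 2))
        for c in tree.children[v]:
            acc *= U[c] @ P[c].T
        mx = acc.max(axis=1)
        dead = mx <= 0
        if np.any(dead):  # impossible column under this category
            mx = np.where(dead, 1.0, mx)
        acc = acc / mx[:, None]
        logscale += np.where(dead, -np.inf, np.log(mx))
        U[v] = acc
    root_like = U[tree.root] @ np.asarray(pi)
    return U, logscale, P, root_like


def _per_category_site_loglik(tree, leaf_partials, mix):
    """(K, n_sites) matrix of per-category log site likelihoods."""
    n_sites = leaf_partials.shape[1]
    out = np.empty((mix.n_categories, n_sites))
    for k in range(mix.n_categories):
        _, logscale, _, root_like = _category_up_pass(
            tree, leaf_partials, mix.gains[k], mix.losses[k], mix.pis[k])
        with np.errstate(divide="ignore"):
            out[k] = np.log(root_like) + logscale
    return out


def site_likelihood(tree: Phylogeny, column, mix: RateMixture, taxa=None) -> float:
    """Mixture likelihood of a single 0/1 column (for small examples).

    ``column`` is ordered like ``taxa`` (default: the tree's leaf-label
    order).  Each category contributes its pruning likelihood with root
    prior equal to that category's stationary frequencies.
    """
    taxa = list(taxa) if taxa is not None else list(tree.leaf_labels)
    col = np.asarray(column, dtype=np.intp).reshape(-1, 1)
    if col.shape[0] != len(taxa):
        raise ModelError("column length does not match taxa")
    if not np.isin(col, (0, 1)).all():
        raise ModelError("column entries must be 0 or 1")
    lp = _leaf_partials(tree, col, taxa)
    logl = _per_category_site_loglik(tree, lp, mix)
    return float(np.exp(logsumexp(logl[:, 0], b=mix.weights)))


@dataclass
class LikelihoodResult:
    """Total and per-site log-likelihoods plus posterior category weights."""

    log_likelihood: float
    per_site_log_likelihood: np.ndarray
    posterior_category_weights: np.ndarray  # (n_sites, K), rows sum to 1
    correction: str = "none"
    log_p_unobservable: float = -np.inf     # log P(all-zero column)


def log_p_all_zero(tree: Phylogeny, mix: RateMixture) -> float:
    """log probability that a character is absent from every taxon."""
    zero_col = np.zeros(tree.n_leaves, dtype=np.intp).reshape(-1, 1)
    lp = _leaf_partials(tree, zero_col, list(tree.leaf_labels))
    logl = _per_category_site_loglik(tree, lp, mix)
    return float(logsumexp(logl[:, 0], b=mix.weights))


def corrected_log_likelihood(tree: Phylogeny, pattern, mix: RateMixture,
                             correction: str = "no_absent") -> LikelihoodResult:
    """Mixture log-likelihood of a pattern, optionally conditioned on
    observability.

    With ``correction="no_absent"`` every per-site likelihood is divided by
    1 - P(all-zero column) on the same tree and mixture: an all-absent
    character can never be observed, so the sampling distribution of real
    columns is the model truncated to observable patterns.
    """
    if correction not in ("none", "no_absent"):
        raise ModelError(f"unknown correction {correction!r}")
    lp = _leaf_partials(tree, np.asarray(pattern.matrix, dtype=np.intp),
                        list(pattern.taxa))
    cat_logl = _per_category_site_loglik(tree, lp, mix)  # (K, S)
    logw = np.log(mix.weights)[:, None]
    site_logl = logsumexp(cat_logl + logw, axis=0)
    post = np.exp(cat_logl + logw - site_logl[None, :]).T  # (S, K)

    log_p0 = -np.inf
    if correction == "no_absent":
        log_p0 = log_p_all_zero(tree, mix)
        p0 = math.exp(log_p0)
        if p0 >= 1.0 - 1e-12:
            raise ModelError("P(all-zero) is numerically 1; correction impossible")
        site_logl = site_logl - math.log1p(-p0)

    return LikelihoodResult(log_likelihood=float(site_logl.sum()),
                            per_site_log_likelihood=site_logl,
                            posterior_category_weights=post,
                            correction=correction,
                            log_p_unobservable=log_p0)


# ------------------------------------------------------------------- fits

def _params_from_vector(x, tier, K, K_gain, K_loss):
    ratio = math.exp(min(max(x[0], -12.0), 12.0))
    kw = dict(g=ratio, l=1.0, model_tier=tier, K=K, K_gain=K_gain, K_loss=K_loss)
    if tier == "gamma_invariant":
        kw["alpha"] = math.exp(min(max(x[1], -5.0), 7.0))
        kw["p_inv"] = 1.0 / (1.0 + math.exp(-min(max(x[2], -30.0), 6.0)))
    elif tier == "mixture":
        kw["alpha_gain"] = math.exp(min(max(x[1], -5.0), 7.0))
        kw["alpha_loss"] = math.exp(min(max(x[2], -5.0), 7.0))
    return GainLossParams(**kw)


_MULTISTARTS = {
    # fixed, deterministic start points in transformed coordinates
    "single": [np.array([math.log(r)]) for r in (0.3, 1.0, 3.0)],
    "gamma_invariant": [np.array([math.log(r), 0.0, -2.2]) for r in (0.3, 1.0, 3.0)],
    "mixture": [np.array([math.log(r), 0.0, 0.0]) for r in (0.3, 1.0, 3.0)],
}


def fit_model(tree: Phylogeny, pattern, tier: str = "gamma_invariant",
              correction: str = "no_absent", K: int = 4,
              K_gain: int = 3, K_loss: int = 3,
              fit_branch_scale: bool = False, tol: float = 1e-6):
    """Maximum-likelihood fit of a model tier to a pattern on a fixed tree.

    Optimizes the corrected log-likelihood over the gain/loss ratio and, per
    tier, the gamma shape(s) and invariant proportion, using Nelder–Mead
    from three fixed starts (log/logit transforms keep the search
    unconstrained).  Branch lengths are taken from the tree and not
    re-optimized; ``fit_branch_scale`` optionally adds one global scaling
    factor.  Deterministic: no randomness enters the search.

    Returns ``(params, result)`` where ``result`` also reflects the scaled
    tree if a branch scale was fitted (the factor is recorded in
    ``params_extra['branch_scale']`` attached to the result).
    """
    if tier not in MODEL_TIERS:
        raise ModelError(f"unknown model tier {tier!r}")

    lp_matrix = np.asarray(pattern.matrix, dtype=np.intp)

    def objective(x):
        try:
            params = _params_from_vector(x, tier, K, K_gain, K_loss)
            mix = build_rate_mixture(params)
            t = tree if not fit_branch_scale else tree.scaled(math.exp(
                min(max(x[-1], -6.0), 6.0)))
            res = corrected_log_likelihood(t, pattern, mix, correction)
            if not np.isfinite(res.log_likelihood):
                return 1e12
            return -res.log_likelihood
        except (ModelError, OverflowError):
            return 1e12

    starts = [s.copy() for s in _MULTISTARTS[tier]]
    if fit_branch_scale:
        starts = [np.append(s, 0.0) for s in starts]

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"fatol": tol, "xatol": 1e-5,
                                         "maxiter": 2000})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FitError("optimizer failed from every start", best=best)
    if not any_converged:
        raise FitError("optimizer did not converge after all restarts", best=best)

    params = _params_from_vector(best.x, tier, K, K_gain, K_loss)
    mix = build_rate_mixture(params)
    fitted_tree = tree
    branch_scale = 1.0
    if fit_branch_scale:
        branch_scale = math.exp(min(max(best.x[-1], -6.0), 6.0))
        fitted_tree = tree.scaled(branch_scale)
    result = corrected_log_likelihood(fitted_tree, pattern, mix, correction)
    result.params_extra = {"branch_scale": branch_scale}
    return params, result


def posterior_rate_per_site(result: LikelihoodResult, mix: RateMixture) -> np.ndarray:
    """Posterior-mean (gain_rate, loss_rate) per site, shape (n_sites, 2)."""
    W = result.posterior_category_weights
    if W.shape[1] != mix.n_categories:
        raise ModelError("posterior weights do not match mixture size")
    return np.column_stack([W @ mix.gains, W @ mix.losses])
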