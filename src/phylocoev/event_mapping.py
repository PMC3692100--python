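"""Posterior expected gain and loss events per branch per character.

Stochastic mapping for the two-state chain in closed form.  For a branch of
length t with endpoint states (a, b), the expected number of i -> j jumps is

    E[N_ij | a, b] = q_ij * Integral_0^t P_ai(s) P_jb(t - s) ds / P_ab(t),

and because the chain has just two eigenvalues (0 and -(g + l)) the integral
is elementary — no uniformization or trajectory sampling is needed.  Branch
endpoint posteriors come from the standard inside-outside (up/down) vectors
per rate category; categories are mixed by their per-site posterior weight.
Events are attributed to branches of the rooted tree, read root -> tip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gainloss_model import (ModelError, RateMixture, LikelihoodResult,
                             _leaf_partials, _category_up_pass)
from .tree_inference import Phylogeny

__all__ = [
    "EventExpectations",
    "branch_conditional_expectations",
    "map_events",
]


@dataclass
class EventExpectations:
    """Site-by-branch matrices of posterior expected gain/loss counts.

    ``r_gain``/``r_loss`` hold the martingale residuals
    E[N_gain] - g * E[dwell time in 0] (and the loss analogue): the excess
    of mapped events over what the site's own rates predict from its
    inferred state occupancy.  They have conditional mean zero under the
    independence model whatever the data say, which makes them the
    smear-free signal used for coevolution scoring.
    """

    site_ids: list
    branch_names: list
    e_gain: np.ndarray  # (n_sites, n_branches)
    e_loss: np.ndarray
    r_gain: np.ndarray | None = None
    r_loss: np.ndarray | None = None

    def __post_init__(self):
        self.e_gain = np.asarray(self.e_gain, dtype=float)
        self.e_loss = np.asarray(self.e_loss, dtype=float)
        shape = (len(self.site_ids), len(self.branch_names))
        if self.e_gain.shape != shape or self.e_loss.shape != shape:
            raise ModelError("expectation matrices do not match ids")
        if (not np.all(np.isfinite(self.e_gain))
                or not np.all(np.isfinite(self.e_loss))
                or np.any(self.e_gain < -1e-12) or np.any(self.e_loss < -1e-12)):
            raise ModelError("expectations must be finite and >= 0")
        np.clip(self.e_gain, 0.0, None, out=self.e_gain)
        np.clip(self.e_loss, 0.0, None, out=self.e_loss)
        for r in (self.r_gain, self.r_loss):
            if r is not None and (r.shape != shape or not np.all(np.isfinite(r))):
                raise ModelError("residual matrices do not match ids")

    def totals(self) -> np.ndarray:
        """Total expected events (gains + losses) per site."""
        return self.e_gain.sum(axis=1) + self.e_loss.sum(axis=1)

    def site_index(self, site_id) -> int:
        return self.site_ids.index(site_id)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: site, branch, exp_gain, exp_loss."""
        s = np.repeat(self.site_ids, len(self.branch_names))
        b = np.tile(self.branch_names, len(self.site_ids))
        return pd.DataFrame({"site": s, "branch": b,
                             "exp_gain": self.e_gain.ravel(),
                             "exp_loss": self.e_loss.ravel()})


def _conditional_integrals(g: float, l: float, t: float):
    """Closed-form endpoint-conditional expectations on one branch.

    Returns four 2x2 arrays over endpoint pairs (a, b): expected gains,
    expected losses, expected dwell time in state 0 and in state 1.  All
    come from the same elementary integral Integral_0^t P_ai(s) P_jb(t-s) ds
    with (i, j) = (0, 1), (1, 0), (0, 0), (1, 1).  Entries with
    P_ab(t) == 0 are set to 0 (gains/losses) or split evenly (dwell)."""
    r = g + l
    if r == 0 or t == 0:
        half = np.full((2, 2), t / 2.0)
        return np.zeros((2, 2)), np.zeros((2, 2)), half, half
    pi = np.array([l / r, g / r])
    one_minus_e = -np.expm1(-r * t)
    decay = np.exp(-r * t)
    eye = np.eye(2)
    P = pi[None, :] + decay * (eye - pi[None, :])

    def integral(i, j):
        # Integral_0^t P_ai(s) P_jb(t-s) ds, all (a, b) at once
        A = eye[:, i] - pi[i]          # indexed by a
        B = eye[j, :] - pi              # indexed by b
        return (pi[i] * pi[None, :] * t
                + (pi[i] * B[None, :] + pi[None, :] * A[:, None]) * one_minus_e / r
                + A[:, None] * B[None, :] * t * decay)

    ok = P > 0
    safe = np.where(ok, P, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Eg = np.where(ok, g * integral(0, 1) / safe, 0.0)
        El = np.where(ok, l * integral(1, 0) / safe, 0.0)
        T0 = np.where(ok, integral(0, 0) / safe, t / 2.0)
        T1 = np.where(ok, integral(1, 1) / safe, t / 2.0)
    return (np.clip(Eg, 0.0, None), np.clip(El, 0.0, None),
            np.clip(T0, 0.0, t), np.clip(T1, 0.0, t))


def _expected_event_matrices(g: float, l: float, t: float):
    Eg, El, _, _ = _conditional_integrals(g, l, t)
    return Eg, El


def branch_conditional_expectations(g: float, l: float, t: float,
                                    state_start: int, state_end: int):
    """Expected (gains, losses) on one branch conditional on its endpoints."""
    if t < 0:
        raise ModelError("negative branch length")
    if state_start not in (0, 1) or state_end not in (0, 1):
        raise ModelError("endpoint states must be 0 or 1")
    if t == 0 or g + l == 0:
        if state_start != state_end:
            raise ModelError("impossible endpoint pair on a zero-rate branch")
        return (0.0, 0.0)
    from .gainloss_model import transition_probability
    if transition_probability(g, l, t)[state_start, state_end] <= 0:
        raise ModelError("endpoint pair has zero probability")
    Eg, El = _expected_event_matrices(g, l, t)
    return (float(Eg[state_start, state_end]), float(El[state_start, state_end]))


def map_events(tree: Phylogeny, pattern, mix: RateMixture,
               fit: LikelihoodResult | None = None) -> EventExpectations:
    """Posterior expected gains and losses per (site, branch).

    For every rate category the up/down vectors give the joint posterior of
    the two endpoint states of each branch; multiplying by the analytic
    conditional expectations and mixing categories by their per-site
    posterior weight yields the expectations.  If ``fit`` is supplied its
    posterior category weights are reused, otherwise they are recomputed
    (the two are identical on the same tree/pattern/mixture).
    """
    matrix = np.asarray(pattern.matrix, dtype=np.intp)
    lp = _leaf_partials(tree, matrix, list(pattern.taxa))
    n_sites = matrix.shape[1]
    K = mix.n_categories
    if fit is not None and fit.posterior_category_weights.shape != (n_sites, K):
        raise ModelError("fit result does not match pattern/mixture")

    branches = list(tree.branch_nodes)
    b_index = {v: i for i, v in enumerate(branches)}
    shape = (n_sites, len(branches))
    e_gain = np.zeros(shape)
    e_loss = np.zeros(shape)
    r_gain = np.zeros(shape)
    r_loss = np.zeros(shape)
    cat_site_logl = np.empty((K, n_sites))

    per_cat_contrib = []
    for k in range(K):
        g, l = float(mix.gains[k]), float(mix.losses[k])
        U, logscale, P, root_like = _category_up_pass(tree, lp, g, l, mix.pis[k])
        with np.errstate(divide="ignore"):
            cat_site_logl[k] = np.log(root_like) + logscale
        cg, cl, crg, crl = (np.zeros(shape) for _ in range(4))
        if g + l > 0:
            _accumulate_category(tree, U, P, mix.pis[k], g, l, b_index,
                                 cg, cl, crg, crl)
        per_cat_contrib.append((cg, cl, crg, crl))

    if fit is not None:
        post = fit.posterior_category_weights
    else:
        logw = np.log(mix.weights)[:, None]
        site_logl = logsumexp(cat_site_logl + logw, axis=0)
        post = np.exp(cat_site_logl + logw - site_logl[None, :]).T

    for k, (cg, cl, crg, crl) in enumerate(per_cat_contrib):
        w = post[:, k][:, None]
        e_gain += w * cg
        e_loss += w * cl
        r_gain += w * crg
        r_loss += w * crl

    return EventExpectations(site_ids=list(pattern.characters),
                             branch_names=list(tree.branch_names),
                             e_gain=e_gain, e_loss=e_loss,
                             r_gain=r_gain, r_loss=r_loss)


def _accumulate_category(tree, U, P, pi, g, l, b_index, cg, cl, crg, crl):
    """Down-pass for one category: joint endpoint posteriors times analytic
    conditional expectations, written into cg/cl (site x branch) with the
    martingale residuals (events minus rate x dwell time) in crg/crl."""
    n_sites = U.shape[1]
    D = np.zeros_like(U)
    D[tree.root] = np.asarray(pi)[None, :]

    for u in tree.preorder:
        if tree.is_leaf[u]:
            continue
        kids = tree.children[u]
        msgs = [U[c] @ P[c].T for c in kids]  # (n_sites, 2) each, indexed by s_u
        # sibling products via prefix/suffix
        pref = [np.ones((n_sites, 2))]
        for m in msgs[:-1]:
            pref.append(pref[-1] * m)
        suff = np.ones((n_sites, 2))
        for c, m in zip(reversed(range(len(kids))), reversed(msgs)):
            v = kids[c]
            dup = D[u] * pref[c] * suff       # (n_sites, 2), outside of v
            suff = suff * m
            # joint posterior over (s_u, s_v)
            jp = dup[:, :, None] * P[v][None, :, :] * U[v][:, None, :]
            norm = jp.sum(axis=(1, 2))
            ok = norm > 0
            jp[ok] /= norm[ok, None, None]
            jp[~ok] = 0.0
            Eg, El, T0, T1 = _conditional_integrals(g, l, float(tree.lengths[v]))
            bi = b_index[v]
            cg[:, bi] = np.einsum("sab,ab->s", jp, Eg)
            cl[:, bi] = np.einsum("sab,ab->s", jp, El)
            crg[:, bi] = cg[:, bi] - g * np.einsum("sab,ab->s", jp, T0)
            crl[:, bi] = cl[:, bi] - l * np.einsum("sab,ab->s", jp, T1)
            # downward vector for v
            dn = np.einsum("sa,ab->sb", dup, P[v])
            tot = dn.sum(axis=1)
            good = tot > 0
            dn[good] /= tot[good, None]
            D[v] = dn
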