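"""Simulation benchmark: coevolving/independent characters and detectors.

Characters evolve independently down the tree under the fitted two-state
mixture.  Coevolving pairs evolve as a single 4-state chain over
{00, 01, 10, 11} built from the two marginal gain/loss generators: every
rate entering a concordant state (00 or 11) is multiplied by a dependency
factor d >= 1 and every rate leaving a concordant state divided by d, so the
pair lingers in matched states and its gains and losses co-occur.  d = 1
reduces exactly to independence (the Kronecker sum of the marginals).

Detectors are callables returning a scored pair list; their rankings are
compared by average precision (area under the precision-recall curve)
against the simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .gainloss_model import ModelError, RateMixture, fit_model, build_rate_mixture
from .phyletic_io import PhyleticPattern
from .tree_inference import Phylogeny

__all__ = [
    "BenchmarkSet",
    "random_phylogeny",
    "simulate_independent_sites",
    "simulate_coevolving_pair",
    "joint_pair_generator",
    "make_benchmark",
    "observed_correlation_detector",
    "event_correlation_detector",
    "average_precision",
    "run_benchmark",
]


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_phylogeny(n_leaves: int, seed, total_length: float = 6.0) -> Phylogeny:
    """Random pure-birth (Yule) tree rescaled to a given total branch length.

    A birth process (every lineage splits at rate 1) is the standard neutral
    model for species trees; it yields reasonably balanced ultrametric
    topologies without the two dominant basal branches of a coalescent
    genealogy.  Branch lengths are rescaled so the sum over all branches is
    ``total_length`` — i.e. the expected number of events per character over
    the whole tree under a unit-rate model.
    """
    if n_leaves < 2:
        raise ModelError("need at least 2 leaves")
    rng = _as_rng(seed)
    # open lineages: (parent node id, start height); node 0 is the root
    heights = {0: 0.0}
    parent = {}
    children_of: dict[int, list[int]] = {0: []}
    open_lineages = [(0, 0.0), (0, 0.0)]
    nxt = 1
    t = 0.0
    while len(open_lineages) < n_leaves:
        k = len(open_lineages)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        par_node, start = open_lineages.pop(i)
        heights[nxt] = t
        parent[nxt] = par_node
        children_of.setdefault(par_node, [])
        children_of[par_node].append(nxt)
        children_of[nxt] = []
        open_lineages.append((nxt, t))
        open_lineages.append((nxt, t))
        nxt += 1
    T = t + rng.exponential(1.0 / n_leaves)
    width = max(2, len(str(n_leaves)))
    leaf_nodes = []
    for par_node, start in open_lineages:
        heights[nxt] = T
        parent[nxt] = par_node
        children_of[par_node].append(nxt)
        leaf_nodes.append(nxt)
        nxt += 1
    par = np.full(nxt, -1, dtype=np.int64)
    lens = np.zeros(nxt)
    labs: list[str | None] = [None] * nxt
    for node, p in parent.items():
        par[node] = p
        lens[node] = heights[node] - heights[p]
    for i, node in enumerate(leaf_nodes):
        labs[node] = f"T{i + 1:0{width}d}"
    tree = Phylogeny(par, lens, labs)
    return tree.scaled(total_length / tree.total_length())


def default_benchmark_mixture() -> RateMixture:
    """Single-rate mixture with gain/loss ratio 0.5 (deletion-biased gene
    content: acquired genes are lost about twice as fast as new ones are
    gained, stationary presence 1/3), normalized to unit flux."""
    from .gainloss_model import GainLossParams, build_rate_mixture
    return build_rate_mixture(GainLossParams(g=0.5, l=1.0, model_tier="single"))


def _simulate_branch(g: float, l: float, t: float, start: np.ndarray, rng):
    """Evolve many sites over one branch, recording actual event counts.

    Vectorized jump-chain simulation: repeatedly draw exponential waiting
    times at the current state's exit rate and flip until the branch is
    exhausted.  Returns (end_states, n_gains, n_losses).
    """
    state = np.asarray(start, dtype=np.int8).copy()
    n = state.size
    ngain = np.zeros(n, dtype=np.int64)
    nloss = np.zeros(n, dtype=np.int64)
    if t == 0 or (g == 0 and l == 0) or n == 0:
        return state, ngain, nloss
    rates = np.array([g, l])
    elapsed = np.zeros(n)
    idx = np.arange(n)
    while idx.size:
        r = rates[state[idx]]
        wait = np.full(idx.size, np.inf)
        pos = r > 0
        wait[pos] = rng.exponential(1.0, int(pos.sum())) / r[pos]
        elapsed[idx] += wait
        flip = elapsed[idx] <= t
        idx = idx[flip]
        gained = state[idx] == 0
        ngain[idx[gained]] += 1
        nloss[idx[~gained]] += 1
        state[idx] ^= 1
    return state, ngain, nloss


def _simulate_sites(tree: Phylogeny, mix: RateMixture, n_sites: int, rng,
                    record_events: bool = False):
    cats = rng.choice(mix.n_categories, size=n_sites, p=mix.weights)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    states[tree.root] = (rng.random(n_sites) < mix.pis[cats, 1]).astype(np.int8)
    n_b = len(tree.branch_nodes)
    eg = np.zeros((n_sites, n_b)) if record_events else None
    el = np.zeros((n_sites, n_b)) if record_events else None
    for bi, v in enumerate(tree.branch_nodes):
        p = int(tree.parent[v])
        for k in np.unique(cats):
            sel = np.flatnonzero(cats == k)
            end, ng, nl = _simulate_branch(float(mix.gains[k]), float(mix.losses[k]),
                                           float(tree.lengths[v]), states[p, sel], rng)
            states[v, sel] = end
            if record_events:
                eg[sel, bi] = ng
                el[sel, bi] = nl
    matrix = np.vstack([states[leaf] for leaf in tree.leaves]).astype(np.uint8)
    return matrix, cats, eg, el


def simulate_independent_sites(tree: Phylogeny, mix: RateMixture, n_sites: int,
                               seed, return_events: bool = False):
    """Simulate independent characters under the mixture model.

    Each site draws a rate category, a root state from that category's
    stationary frequencies, and then evolves down the tree branch by
    branch.  With ``return_events`` the realized per-branch gain/loss counts
    are returned too (they ground the stochastic-mapping oracle tests).
    """
    if n_sites < 1:
        raise ModelError("n_sites must be >= 1")
    rng = _as_rng(seed)
    matrix, cats, eg, el = _simulate_sites(tree, mix, n_sites, rng,
                                           record_events=return_events)
    width = max(4, len(str(n_sites)))
    pattern = PhyleticPattern(taxa=list(tree.leaf_labels),
                              characters=[f"C{i + 1:0{width}d}" for i in range(n_sites)],
                              matrix=matrix)
    if return_events:
        return pattern, {"categories": cats, "e_gain": eg, "e_loss": el,
                         "branch_names": list(tree.branch_names)}
    return pattern


# ------------------------------------------------------- coevolving pairs

_JOINT_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))  # index = 2*s1 + s2
_CONCORDANT = (0, 3)


def joint_pair_generator(g1, l1, g2, l2, d: float) -> np.ndarray:
    """4-state generator of a coevolving character pair.

    Starts from the Kronecker sum of the two marginal 2-state generators
    (exact independence) and biases it toward concordance: off-diagonal
    rates into {00, 11} are multiplied by d, rates out of {00, 11} divided
    by d.  Rows sum to zero.
    """
    if d < 1:
        raise ModelError("dependency factor d must be >= 1")
    Q = np.zeros((4, 4))
    for x, (s1, s2) in enumerate(_JOINT_STATES):
        # character 1 flips
        y = 2 * (1 - s1) + s2
        Q[x, y] = g1 if s1 == 0 else l1
        # character 2 flips
        y = 2 * s1 + (1 - s2)
        Q[x, y] = g2 if s2 == 0 else l2
    for x in range(4):
        for y in range(4):
            if x == y or Q[x, y] == 0:
                continue
            if y in _CONCORDANT:
                Q[x, y] *= d
            if x in _CONCORDANT:
                Q[x, y] /= d
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _joint_stationary(Q: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    if np.allclose(Q, 0.0):
        return fallback
    A = np.vstack([Q.T, np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _stationary_flux(Q: np.ndarray, pi: np.ndarray) -> float:
    off = Q - np.diag(np.diag(Q))
    return float(pi @ off.sum(axis=1))


def simulate_coevolving_pair(tree: Phylogeny, mix: RateMixture, d: float, seed):
    """Simulate one coevolving character pair; returns two 0/1 columns
    (taxon order = tree leaf order) and the rate category used.

    The pair shares one rate category drawn from the mixture.  The biased
    generator is rescaled so its stationary event flux equals that of two
    independent characters of the same category — without this, lingering
    in concordant states would make coevolving pairs systematically slower
    than independent ones, confounding coevolution with rate.  The joint
    chain starts at its stationary distribution; per-branch transitions are
    taken from the matrix exponential of the generator.
    """
    rng = _as_rng(seed)
    k = int(rng.choice(mix.n_categories, p=mix.weights))
    g, l = float(mix.gains[k]), float(mix.losses[k])
    Q = joint_pair_generator(g, l, g, l, d)
    pi4 = _joint_stationary(Q, np.kron(mix.pis[k], mix.pis[k]))
    flux = _stationary_flux(Q, pi4)
    if flux > 0:
        target = 2.0 * (2.0 * g * l / (g + l))  # two independent characters
        Q = Q * (target / flux)
    states = np.empty(tree.n_nodes, dtype=np.int8)
    states[tree.root] = rng.choice(4, p=pi4)
    P_cache: dict[float, np.ndarray] = {}
    for v in tree.branch_nodes:
        t = float(tree.lengths[v])
        if t not in P_cache:
            P = expm(Q * t)
            P = np.clip(P, 0.0, None)
            P_cache[t] = P / P.sum(axis=1, keepdims=True)
        row = P_cache[t][states[int(tree.parent[v])]]
        states[v] = rng.choice(4, p=row)
    leaf_states = states[np.array(tree.leaves)]
    col1 = (leaf_states >> 1).astype(np.uint8)
    col2 = (leaf_states & 1).astype(np.uint8)
    return col1, col2, k


@dataclass
class BenchmarkSet:
    """Simulated pattern with known coevolving ground truth."""

    pattern: PhyleticPattern
    tree: Phylogeny
    truth: set            # of (id1, id2) tuples, id1 < id2
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = set(self.pattern.characters)
        seen = set()
        for a, b in self.truth:
            if a not in ids or b not in ids:
                raise ModelError("truth pair references unknown character")
            if a in seen or b in seen:
                raise ModelError("coevolving pairs must be disjoint")
            seen.update((a, b))


def make_benchmark(tree: Phylogeny, mix: RateMixture, n_pairs_coev: int,
                   n_indep: int, d: float = 16.0, seed=0) -> BenchmarkSet:
    """Assemble a benchmark pattern: coevolving pairs + independent sites,
    column order shuffled, with the true pairs recorded by character id."""
    if n_pairs_coev < 0 or n_indep < 0:
        raise ModelError("counts must be >= 0")
    n_total = 2 * n_pairs_coev + n_indep
    if n_total == 0:
        raise ModelError("benchmark needs at least one character")
    rng = _as_rng(seed)
    cols = []
    sources = []  # pair index or -1 for independent
    for p in range(n_pairs_coev):
        c1, c2, _ = simulate_coevolving_pair(tree, mix, d, rng)
        cols.extend([c1, c2])
        sources.extend([p, p])
    if n_indep:
        m, _, _, _ = _simulate_sites(tree, mix, n_indep, rng)
        cols.extend(m.T)
        sources.extend([-1] * n_indep)
    matrix = np.column_stack(cols)
    perm = rng.permutation(n_total)
    matrix = matrix[:, perm]
    sources = [sources[i] for i in perm]
    width = max(4, len(str(n_total)))
    ids = [f"G{i + 1:0{width}d}" for i in range(n_total)]
    truth = set()
    for p in range(n_pairs_coev):
        members = [ids[i] for i, s in enumerate(sources) if s == p]
        truth.add(tuple(sorted(members)))
    pattern = PhyleticPattern(taxa=list(tree.leaf_labels), characters=ids,
                              matrix=matrix)
    return BenchmarkSet(pattern=pattern, tree=tree, truth=truth,
                        params={"n_pairs_coev": n_pairs_coev, "n_indep": n_indep,
                                "d": d, "seed": seed})


# -------------------------------------------------------------- detectors

def observed_correlation_detector(pattern: PhyleticPattern) -> pd.DataFrame:
    """Phylogeny-blind baseline: Pearson correlation of extant 0/1 columns.

    Constant columns carry no signal and are excluded.  Returns a pair
    table (id1, id2, score) in fixed column order.
    """
    X = np.asarray(pattern.matrix, dtype=float)
    keep = np.flatnonzero(X.std(axis=0) > 0)
    if keep.size < 2:
        raise ModelError("need at least 2 non-constant columns")
    Z = X[:, keep]
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    R = (Z.T @ Z) / Z.shape[0]
    ids = [pattern.characters[i] for i in keep]
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame({"id1": [ids[i] for i in iu],
                         "id2": [ids[j] for j in ju],
                         "score": R[iu, ju]})


def event_correlation_detector(pattern: PhyleticPattern, tree: Phylogeny,
                               tier: str = "gamma_invariant",
                               correction: str = "no_absent",
                               statistic: str = "residual",
                               **fit_kwargs) -> pd.DataFrame:
    """Phylogeny-aware detector: fit the gain/loss mixture, map posterior
    expected events onto branches and correlate the per-branch event
    vectors (martingale residuals by default) of each character pair.

    Characters whose extant column is constant carry no coevolution signal
    (an all-absent character could never be observed at all) and are
    excluded, which also keeps the pair set comparable with the
    observed-correlation baseline.
    """
    import warnings
    from .coevolution import score_pairs  # deferred: avoids import cycle
    from .event_mapping import map_events
    params, fit = fit_model(tree, pattern, tier=tier, correction=correction,
                            **fit_kwargs)
    mix = build_rate_mixture(params)
    em = map_events(tree, pattern, mix, fit=fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        scores, _ = score_pairs(em, statistic=statistic)
    X = np.asarray(pattern.matrix, dtype=float)
    informative = {pattern.characters[i]
                   for i in np.flatnonzero(X.std(axis=0) > 0)}
    return scores[scores["id1"].isin(informative)
                  & scores["id2"].isin(informative)].reset_index(drop=True)


def average_precision(scores: pd.DataFrame, truth: set) -> float:
    """Average precision of a scored pair list against the truth set.

    Pairs are ranked by descending score; ties keep the (id1, id2) order
    (stable sort), which is reported behavior since AP is tie-sensitive.
    AP = mean over true pairs of the precision at that pair's rank.
    """
    truth_norm = {tuple(sorted(p)) for p in truth}
    df = scores.sort_values(["id1", "id2"], kind="stable")
    df = df.sort_values("score", ascending=False, kind="stable")
    labels = np.array([tuple(sorted((a, b))) in truth_norm
                       for a, b in zip(df["id1"], df["id2"])])
    if labels.sum() == 0:
        raise ModelError("no true pair among the scored pairs")
    ranks = np.arange(1, labels.size + 1)
    precision_at = np.cumsum(labels) / ranks
    return float(precision_at[labels].mean())


def run_benchmark(bench: BenchmarkSet, detectors: dict) -> pd.DataFrame:
    """Score every detector on the same benchmark; one AUPR per detector.

    ``detectors`` maps a name to a callable taking the BenchmarkSet and
    returning a scored pair table (id1, id2, score).
    """
    rows = []
    for name, fn in detectors.items():
        scores = fn(bench)
        rows.append({"detector": name,
                     "aupr": average_precision(scores, bench.truth),
                     "n_pairs_scored": len(scores)})
    return pd.DataFrame(rows, columns=["detector", "aupr", "n_pairs_scored"])
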