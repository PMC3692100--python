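"""Independent oracles used by the test suite.

Deliberately naive implementations — exhaustive enumeration, grid search and
Monte-Carlo trajectory sampling — kept free of the package's pruning /
optimization / closed-form code paths so they can certify them.
"""

import itertools

import numpy as np


def enumerate_site_likelihood(tree, column, mix):
    """Mixture likelihood of one 0/1 column by brute-force summation over
    every assignment of states to interior nodes (trees <= ~8 leaves)."""
    column = np.asarray(column, dtype=int)
    leaf_state = {}
    for i, node in enumerate(tree.leaves):
        leaf_state[node] = int(column[i])
    interior = [v for v in range(tree.n_nodes) if not tree.is_leaf[v]]
    total = 0.0
    for k in range(mix.n_categories):
        g, l, w = mix.gains[k], mix.losses[k], mix.weights[k]
        pi = mix.pis[k]
        r = g + l

        def p(a, b, t):
            if r == 0:
                return 1.0 if a == b else 0.0
            decay = np.exp(-r * t)
            P = np.array([[pi[0] + pi[1] * decay, pi[1] * (1 - decay)],
                          [pi[0] * (1 - decay), pi[1] + pi[0] * decay]])
            return P[a, b]

        cat_sum = 0.0
        for assign in itertools.product((0, 1), repeat=len(interior)):
            state = dict(zip(interior, assign))
            state.update(leaf_state)
            prob = pi[state[tree.root]]
            for v in range(tree.n_nodes):
                if v != tree.root:
                    prob *= p(state[int(tree.parent[v])], state[v],
                              float(tree.lengths[v]))
            cat_sum += prob
        total += w * cat_sum
    return total


def sample_branch_histories(g, l, t, start, n, rng):
    """Jump-chain simulation of n independent trajectories over one branch.

    Returns (end_states, n_gains, n_losses) as integer arrays; the basis of
    the Monte-Carlo stochastic-mapping oracle.
    """
    state = np.full(n, start, dtype=np.int8)
    ngain = np.zeros(n, dtype=np.int64)
    nloss = np.zeros(n, dtype=np.int64)
    elapsed = np.zeros(n)
    idx = np.arange(n)
    rates = np.array([g, l], dtype=float)
    while idx.size:
        r = rates[state[idx]]
        wait = np.full(idx.size, np.inf)
        pos = r > 0
        wait[pos] = rng.exponential(1.0, int(pos.sum())) / r[pos]
        elapsed[idx] += wait
        keep = elapsed[idx] <= t
        idx = idx[keep]
        gained = state[idx] == 0
        ngain[idx[gained]] += 1
        nloss[idx[~gained]] += 1
        state[idx] ^= 1
    return state, ngain, nloss


def mc_conditional_expectations(g, l, t, a, b, n, rng):
    """Monte-Carlo estimate of E[gains], E[losses] conditional on endpoints
    (a, b), with standard errors.  Rejection-free: simulates from ``a`` and
    buckets by realized end state."""
    end, ngain, nloss = sample_branch_histories(g, l, t, a, n, rng)
    sel = end == b
    m = int(sel.sum())
    if m == 0:
        raise RuntimeError("no trajectory reached the requested end state")
    eg, el = ngain[sel], nloss[sel]
    return (eg.mean(), el.mean(),
            eg.std(ddof=1) / np.sqrt(m) if m > 1 else np.inf,
            el.std(ddof=1) / np.sqrt(m) if m > 1 else np.inf, m)


def grid_ml_distance(x, y, freqs, cap=10.0, step=1e-4):
    """Dense 1-D grid maximization of the two-sequence log-likelihood."""
    x = np.asarray(x, int)
    y = np.asarray(y, int)
    pi0, pi1 = freqs
    counts = np.bincount(2 * x + y, minlength=4).astype(float)
    ts = np.arange(step, cap + step, step)
    s = 1.0 / (2.0 * pi0 * pi1)
    e = np.exp(-s * ts)
    tiny = 1e-300
    ll = (counts[0] * np.log(np.maximum(pi0 * (pi0 + pi1 * e), tiny))
          + counts[1] * np.log(np.maximum(pi0 * pi1 * (1 - e), tiny))
          + counts[2] * np.log(np.maximum(pi1 * pi0 * (1 - e), tiny))
          + counts[3] * np.log(np.maximum(pi1 * (pi1 + pi0 * e), tiny)))
    return float(ts[np.argmax(ll)])


def random_binary_phylogeny(n_leaves, rng, min_len=0.05, max_len=1.0):
    """Random binary topology with uniform branch lengths (additive ground
    truth for NJ recovery tests).  Built by sequential random attachment."""
    import phylocoev as pc
    # start from a 2-leaf tree rooted at the top, grow by splitting branches
    parent = [-1, 0, 0]
    lengths = [0.0, u(rng, min_len, max_len), u(rng, min_len, max_len)]
    labels = [None, "L1", "L2"]
    leaf_ids = [1, 2]
    for i in range(3, n_leaves + 1):
        target = int(rng.integers(1, len(parent)))  # any non-root node
        # split target's branch, attach the new leaf at the junction
        junction = len(parent)
        parent.append(parent[target])
        lengths.append(lengths[target] * 0.5)
        labels.append(None)
        parent[target] = junction
        lengths[target] *= 0.5
        new_leaf = len(parent)
        parent.append(junction)
        lengths.append(u(rng, min_len, max_len))
        labels.append(f"L{i}")
        leaf_ids.append(new_leaf)
    return pc.Phylogeny(parent, lengths, labels)


def u(rng, lo, hi):
    return float(lo + (hi - lo) * rng.random())
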