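"""Coevolution scoring, simulation-based significance and the network.

Two characters coevolve when their gains and losses co-occur on the same
branches of the tree.  Each character is summarized by the concatenation of
its per-branch expected gain and expected loss vectors; the coevolution
score of a pair is the Pearson correlation of those vectors.  Significance
is parametric-bootstrap: independent characters are simulated under the
fitted model, mapped on the same tree, and their pairwise correlations form
the null distribution.  Because the null law of a correlation depends
strongly on how many events a character has, null pairs are stratified by
quantile bins of per-site total expected events and each real pair is
compared only against nulls from its own (event-abundance-matched) stratum.
Empirical p-values use the add-one rank rule, so they are valid and never
zero; Benjamini-Hochberg converts them to q-values, and edges with
q <= alpha enter the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .event_mapping import EventExpectations, map_events
from .gainloss_model import ModelError, RateMixture
from .tree_inference import Phylogeny

__all__ = [
    "PairResult",
    "NullScoreBank",
    "CoevolutionNetwork",
    "event_vector",
    "coevolution_score",
    "score_pairs",
    "simulate_null_scores",
    "pair_pvalue",
    "bh_adjust",
    "analyze_pairs",
    "build_network",
    "network_summaries",
    "pair_state_categories",
    "annotated_newick",
]

STRATUM_FLOOR = 100


@dataclass
class PairResult:
    """One character pair: score, empirical p-value, BH q-value."""

    id1: str
    id2: str
    score: float
    pvalue: float
    qvalue: float


def event_vector(em: EventExpectations, site) -> np.ndarray:
    """Per-branch expected gains then expected losses, fixed branch order."""
    i = em.site_index(site)
    return np.concatenate([em.e_gain[i], em.e_loss[i]])


def event_matrix(em: EventExpectations, statistic: str = "residual") -> np.ndarray:
    """Site-by-(2 branches) matrix used for pair scoring.

    ``"residual"`` (default) uses the martingale residuals
    (events minus rate x dwell), whose conditional mean is zero under
    independence for any data; ``"expectation"`` uses the raw posterior
    expected counts.
    """
    if statistic == "expectation" or em.r_gain is None:
        return np.hstack([em.e_gain, em.e_loss])
    if statistic != "residual":
        raise ModelError(f"unknown scoring statistic {statistic!r}")
    return np.hstack([em.r_gain, em.r_loss])


def coevolution_score(v1, v2) -> float:
    """Pearson correlation of two event vectors, in [-1, 1]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.size != v2.size:
        raise ModelError("event vectors differ in length")
    if v1.std() == 0 or v2.std() == 0:
        raise ModelError("score undefined for a constant event vector")
    # commutative formulation so score(i, j) == score(j, i) bit-for-bit
    z1 = v1 - v1.mean()
    z2 = v2 - v2.mean()
    r = float((z1 * z2).sum() / np.sqrt((z1 * z1).sum() * (z2 * z2).sum()))
    return max(-1.0, min(1.0, r))


def _correlation_upper(M: np.ndarray):
    """All-pairs Pearson correlations of matrix rows; returns (iu, ju, r)
    over non-constant rows plus the indices of excluded constant rows."""
    sd = M.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    excluded = np.flatnonzero(sd == 0)
    Z = M[keep]
    Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
    R = (Z @ Z.T) / Z.shape[1]
    iu, ju = np.triu_indices(keep.size, k=1)
    return keep, iu, ju, np.clip(R[iu, ju], -1.0, 1.0), excluded


def score_pairs(em: EventExpectations, statistic: str = "residual"):
    """Coevolution scores for all character pairs.

    Characters with a constant event vector (typically all-zero: no mapped
    events) cannot be scored and are excluded with a warning.  Returns
    ``(table, excluded_ids)`` with table columns id1, id2, score ordered by
    character position (id1 before id2).
    """
    M = event_matrix(em, statistic=statistic)
    keep, iu, ju, r, excluded = _correlation_upper(M)
    excluded_ids = [em.site_ids[i] for i in excluded]
    if excluded_ids:
        warnings.warn(f"{len(excluded_ids)} characters with constant event "
                      "vectors excluded from scoring", UserWarning, stacklevel=2)
    ids = [em.site_ids[i] for i in keep]
    table = pd.DataFrame({"id1": [ids[i] for i in iu],
                          "id2": [ids[j] for j in ju],
                          "score": r})
    return table, excluded_ids


# ------------------------------------------------------------- null bank

@dataclass
class NullScoreBank:
    """Null correlation samples stratified by event-abundance bins.

    ``edges`` are the quantile cut points (computed from the *real* data's
    per-site total expected events); a pair's stratum is the sorted pair of
    its two sites' bin indices.  Under-filled strata are pooled at lookup
    with their nearest neighbours (Manhattan distance on bin indices) until
    the sample floor is met.
    """

    edges: np.ndarray
    strata: dict
    n_sims: int
    seed: int
    floor: int = STRATUM_FLOOR
    _pooled_cache: dict = field(default_factory=dict, repr=False)

    def assign_bins(self, totals) -> np.ndarray:
        return np.searchsorted(self.edges, np.asarray(totals), side="right")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def stratum_of(self, total1: float, total2: float) -> tuple:
        b1, b2 = self.assign_bins([total1, total2])
        return (min(b1, b2), max(b1, b2))

    def pooled(self, stratum: tuple) -> np.ndarray:
        """Sorted null scores for a stratum, pooled to >= floor samples."""
        if stratum in self._pooled_cache:
            return self._pooled_cache[stratum]
        keys = sorted(self.strata,
                      key=lambda k: (abs(k[0] - stratum[0]) + abs(k[1] - stratum[1]), k))
        parts = []
        n = 0
        for k in keys:
            parts.append(self.strata[k])
            n += len(self.strata[k])
            if n >= self.floor:
                break
        if n < self.floor:
            raise ModelError("null bank too small for the stratum floor; "
                             "increase n_sims")
        pooled = np.sort(np.concatenate(parts))
        self._pooled_cache[stratum] = pooled
        return pooled


def simulate_null_scores(tree: Phylogeny, mix: RateMixture, real_em: EventExpectations,
                         n_sims: int = 1000, seed: int = 0, n_bins: int = 5,
                         floor: int = STRATUM_FLOOR,
                         statistic: str = "residual") -> NullScoreBank:
    """Parametric-bootstrap null: simulate independent characters under the
    fitted model, map their events on the same tree, correlate all disjoint
    null pairs and bin them by event abundance.

    Bin edges are interior quantiles of the real data's per-site total
    expected events, so every real pair falls in a covered stratum.  The
    null uses the same scoring ``statistic`` as the real pairs.
    """
    from .benchmark import simulate_independent_sites  # deferred import
    if n_sims * (n_sims - 1) // 2 < floor:
        raise ModelError("n_sims too small for the stratum floor; increase n_sims")
    real_totals = real_em.totals()
    edges = np.quantile(real_totals, np.linspace(0, 1, n_bins + 1)[1:-1])

    null_pattern = simulate_independent_sites(tree, mix, n_sims, seed)
    null_em = map_events(tree, null_pattern, mix)
    M = event_matrix(null_em, statistic=statistic)
    totals = null_em.totals()

    keep, iu, ju, r, _ = _correlation_upper(M)
    bins = np.searchsorted(edges, totals[keep], side="right")
    b1 = np.minimum(bins[iu], bins[ju])
    b2 = np.maximum(bins[iu], bins[ju])
    strata: dict[tuple, np.ndarray] = {}
    order = np.lexsort((b2, b1))
    b1s, b2s, rs = b1[order], b2[order], r[order]
    boundaries = np.flatnonzero(np.diff(b1s) | np.diff(b2s)) + 1
    for chunk_b1, chunk_b2, chunk_r in zip(np.split(b1s, boundaries),
                                           np.split(b2s, boundaries),
                                           np.split(rs, boundaries)):
        strata[(int(chunk_b1[0]), int(chunk_b2[0]))] = np.sort(chunk_r)
    return NullScoreBank(edges=edges, strata=strata, n_sims=n_sims,
                         seed=int(seed), floor=floor)


def pair_pvalue(score: float, bank: NullScoreBank, stratum: tuple) -> float:
    """Add-one empirical p-value: (1 + #{null >= score}) / (N + 1)."""
    pooled = bank.pooled(stratum)
    n_ge = pooled.size - np.searchsorted(pooled, score, side="left")
    return float((1 + n_ge) / (pooled.size + 1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ModelError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_pairs(em: EventExpectations, bank: NullScoreBank,
                  statistic: str = "residual") -> pd.DataFrame:
    """Score all real pairs, attach stratified empirical p-values and BH
    q-values.  Returns columns id1, id2, score, pvalue, qvalue.  The
    ``statistic`` must match the one used to build the null bank."""
    table, _ = score_pairs(em, statistic=statistic)
    totals = dict(zip(em.site_ids, em.totals()))
    bins = {sid: int(bank.assign_bins([totals[sid]])[0]) for sid in totals}
    strata = [(min(bins[a], bins[b]), max(bins[a], bins[b]))
              for a, b in zip(table["id1"], table["id2"])]
    pvals = np.empty(len(table))
    scores = table["score"].to_numpy()
    strat_arr = np.array(strata)
    for st in sorted(set(strata)):
        sel = np.flatnonzero((strat_arr[:, 0] == st[0]) & (strat_arr[:, 1] == st[1]))
        pooled = bank.pooled(st)
        n_ge = pooled.size - np.searchsorted(pooled, scores[sel], side="left")
        pvals[sel] = (1 + n_ge) / (pooled.size + 1)
    table = table.copy()
    table["pvalue"] = pvals
    table["qvalue"] = bh_adjust(pvals)
    return table


# ---------------------------------------------------------------- network

@dataclass
class CoevolutionNetwork:
    """Significant pairs as an undirected graph with annotated nodes."""

    graph: nx.Graph
    alpha: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(pairs: pd.DataFrame, alpha: float = 0.01,
                  annotations=None, nodes=None) -> CoevolutionNetwork:
    """Keep pairs with q-value <= alpha as network edges.

    ``nodes`` optionally lists all tested characters so isolated characters
    still appear; annotations (an AnnotationTable or dict) become node
    attributes.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ModelError("alpha must lie in [0, 1]")
    ann = getattr(annotations, "entries", annotations) or {}
    g = nx.Graph()
    node_list = list(nodes) if nodes is not None else sorted(
        set(pairs["id1"]) | set(pairs["id2"]))
    for n in node_list:
        g.add_node(n, annotation=ann.get(n, ""))
    sig = pairs[pairs["qvalue"] <= alpha]
    for row in sig.itertuples(index=False):
        g.add_edge(row.id1, row.id2, score=float(row.score),
                   pvalue=float(row.pvalue), qvalue=float(row.qvalue))
    return CoevolutionNetwork(graph=g, alpha=float(alpha))


_SIGNIFICANCE_BINS = np.array([0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 5e-2, 1.0])


def network_summaries(net: CoevolutionNetwork) -> dict:
    """Degree distribution, edge-significance histogram and components.

    Returns a dict of DataFrames: ``degrees`` (node, degree),
    ``significance_hist`` (p-value bin, edge count) and ``components``
    (node, component id; components numbered by their smallest node id).
    """
    g = net.graph
    degrees = pd.DataFrame(sorted(g.degree()), columns=["node", "degree"])
    pvals = np.array([d["pvalue"] for _, _, d in g.edges(data=True)])
    counts, _ = np.histogram(pvals, bins=_SIGNIFICANCE_BINS) if pvals.size else (
        np.zeros(len(_SIGNIFICANCE_BINS) - 1, dtype=int), None)
    hist = pd.DataFrame({"bin_low": _SIGNIFICANCE_BINS[:-1],
                         "bin_high": _SIGNIFICANCE_BINS[1:],
                         "n_edges": counts})
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    rows = [{"node": n, "component": ci}
            for ci, comp in enumerate(comps) for n in sorted(comp)]
    components = pd.DataFrame(rows, columns=["node", "component"])
    return {"degrees": degrees, "significance_hist": hist,
            "components": components}


def pair_state_categories(pattern, id1: str, id2: str) -> pd.Series:
    """Per-taxon joint state of two characters: '11', '00', '10' or '01'
    (presence in both / neither / first only / second only)."""
    c1 = pattern.column(id1)
    c2 = pattern.column(id2)
    labels = [f"{a}{b}" for a, b in zip(c1, c2)]
    return pd.Series(labels, index=list(pattern.taxa), name=f"{id1}|{id2}")


def annotated_newick(tree: Phylogeny, categories: pd.Series) -> str:
    """Newick with the pair category appended to each leaf label, for tree
    viewers that color tips by name."""
    mapping = {taxon: f"{taxon}|{cat}" for taxon, cat in categories.items()}
    return tree.relabeled(mapping).to_newick()
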