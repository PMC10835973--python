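"""Stage-wise gene regulatory networks from binarized expression.

Expression within one stage is discretized at the per-gene median (0
below or at the median, 1 above), a Bayesian-network DAG is learned by
greedy hill climbing over add/delete/reverse moves maximizing the BIC
score for discrete variables, and edges are then filtered by Pearson and
Spearman correlation of the z-scored normalized expression, with a
three-level confidence class:

* thin   - exactly one coefficient significant (p <= 0.05)
* medium - both significant, both |coefficients| below 0.89
* thick  - both significant, both |coefficients| >= 0.89

Robustness is quantified by graph density and six centralities, with
and without pseudogene nodes, on the original network (ON) and its
degree-of-differentiation (DD) and degree-of-pleiotropy (DP) induced
subnetworks.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_MAX = 0.05
STRONG_R = 0.89


# ------------------------------------------------------------- binarize

def binarize(values: pd.DataFrame) -> pd.DataFrame:
    """Median-binarize each gene over the given samples.

    Values strictly above the per-gene median map to 1, the rest to 0;
    a constant gene therefore becomes all zeros.
    """
    med = values.median(axis=1)
    return values.gt(med, axis=0).astype(np.int8)


# ----------------------------------------------------- BIC hill climbing

def _local_bic(child: np.ndarray, parents: np.ndarray | None,
               n_samples: int) -> float:
    """BIC contribution of one binary node given its parent columns.

    log-likelihood from the contingency counts minus (ln N / 2) * number
    of free parameters (2^|parents| * (2 - 1) for binary variables).
    """
    if parents is None or parents.shape[1] == 0:
        config = np.zeros(n_samples, dtype=np.int64)
        q = 1
    else:
        config = parents @ (1 << np.arange(parents.shape[1], dtype=np.int64))
        q = 2 ** parents.shape[1]
    joint = config * 2 + child
    counts = np.bincount(joint, minlength=2 * q).reshape(q, 2).astype(float)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / row_tot), 0.0).sum()
    return ll - 0.5 * np.log(n_samples) * q


class _ScoreCache:
    def __init__(self, data: np.ndarray):
        self.data = data
        self.n = data.shape[0]
        self.cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, node: int, parents: tuple[int, ...]) -> float:
        key = (node, parents)
        if key not in self.cache:
            cols = self.data[:, list(parents)] if parents else None
            self.cache[key] = _local_bic(self.data[:, node], cols, self.n)
        return self.cache[key]


def bic_score(data: pd.DataFrame, dag: nx.DiGraph) -> float:
    """Total BIC of a DAG on binary data (columns are variables)."""
    arr = data.to_numpy(dtype=np.int64)
    idx = {g: i for i, g in enumerate(data.columns)}
    cache = _ScoreCache(arr)
    total = 0.0
    for node in data.columns:
        parents = tuple(sorted(idx[p] for p in dag.predecessors(node))
                        ) if dag.has_node(node) else ()
        total += cache.local(idx[node], parents)
    return total


def learn_structure(binary: pd.DataFrame, seed: int = 0,
                    max_iter: int = 1000, n_restarts: int = 6,
                    split_blocks: int | None = None) -> nx.DiGraph:
    """Random-restart greedy BIC hill climbing (add/delete/reverse moves).

    ``binary`` has samples as rows and genes as columns (transpose of
    the expression layout).  Constant columns carry no information and
    are removed with a warning.  The first climb starts from the empty
    graph; each further restart starts from a seeded random DAG, and the
    local optimum with the best total BIC wins (greedy search alone can
    stall one repair-move short of the optimum).  Deterministic given
    the seed: candidate moves are scanned in lexicographic (source,
    target) order and exact ties go to the earliest candidate.
    ``split_blocks`` optionally learns on overlapping variable blocks of
    that size and unions the edges (cycle-closing edges skipped in
    deterministic order); the default is a single search over all
    variables.
    """
    if binary.shape[0] < 8:
        raise ValueError("need at least 8 samples to learn a structure")
    if binary.shape[1] < 2:
        raise ValueError("need at least 2 genes")
    constant = [c for c in binary.columns if binary[c].nunique() <= 1]
    if constant:
        warnings.warn(f"removing {len(constant)} constant gene(s) before "
                      "structure learning", stacklevel=2)
        binary = binary.drop(columns=constant)
    genes = list(binary.columns)

    if split_blocks is not None and split_blocks < len(genes):
        return _learn_blocks(binary, seed, max_iter, split_blocks)

    arr = binary.to_numpy(dtype=np.int64)
    n_vars = len(genes)
    cache = _ScoreCache(arr)
    rng = np.random.default_rng(seed)

    best_edges: set[tuple[int, int]] | None = None
    best_score = -np.inf
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            init: list[tuple[int, int]] = []
        else:
            order = rng.permutation(n_vars)
            init = [(int(order[i]), int(order[j]))
                    for i in range(n_vars) for j in range(i + 1, n_vars)
                    if rng.random() < 0.25]
        edges = _climb(cache, n_vars, init, max_iter)
        score = sum(cache.local(v, tuple(sorted(
            {u for u, w in edges if w == v}))) for v in range(n_vars))
        if score > best_score + 1e-9:
            best_score, best_edges = score, edges

    out = nx.DiGraph()
    out.add_nodes_from(genes)
    out.add_edges_from((genes[u], genes[v]) for u, v in sorted(best_edges))
    return out


def _climb(cache: _ScoreCache, n_vars: int,
           init_edges: list[tuple[int, int]],
           max_iter: int) -> set[tuple[int, int]]:
    """One greedy climb from a given (acyclic) starting edge set."""
    parents: dict[int, set[int]] = {i: set() for i in range(n_vars)}
    dag = nx.DiGraph()
    dag.add_nodes_from(range(n_vars))
    for u, v in init_edges:
        if u != v and not (dag.has_node(u) and nx.has_path(dag, v, u)):
            dag.add_edge(u, v)
            parents[v].add(u)

    def delta_add(u: int, v: int) -> float:
        cur = cache.local(v, tuple(sorted(parents[v])))
        new = cache.local(v, tuple(sorted(parents[v] | {u})))
        return new - cur

    def delta_del(u: int, v: int) -> float:
        cur = cache.local(v, tuple(sorted(parents[v])))
        new = cache.local(v, tuple(sorted(parents[v] - {u})))
        return new - cur

    for _ in range(max_iter):
        best: tuple[float, int, tuple] = (1e-10, 2, ())
        for u, v in itertools.permutations(range(n_vars), 2):
            if v in parents and u in parents[v]:
                d = delta_del(u, v)
                if d > best[0]:
                    best = (d, 1, ("del", u, v))
                # reverse = delete u->v, add v->u (if acyclic)
                dag.remove_edge(u, v)
                creates = nx.has_path(dag, u, v)
                dag.add_edge(u, v)
                if not creates:
                    d2 = d + delta_add(v, u)
                    if d2 > best[0]:
                        best = (d2, 1, ("rev", u, v))
            else:
                if nx.has_path(dag, v, u):
                    continue  # adding u->v would close a cycle
                d = delta_add(u, v)
                if d > best[0]:
                    best = (d, 1, ("add", u, v))
        if not best[2]:
            break
        op, u, v = best[2]
        if op == "add":
            parents[v].add(u)
            dag.add_edge(u, v)
        elif op == "del":
            parents[v].discard(u)
            dag.remove_edge(u, v)
        else:  # reverse
            parents[v].discard(u)
            dag.remove_edge(u, v)
            parents[u].add(v)
            dag.add_edge(v, u)

    return set(dag.edges)


def _learn_blocks(binary: pd.DataFrame, seed: int, max_iter: int,
                  block: int) -> nx.DiGraph:
    """Block-splitting variant: learn per overlapping block, union edges."""
    genes = list(binary.columns)
    step = max(block // 2, 1)
    union = nx.DiGraph()
    union.add_nodes_from(genes)
    edges: set[tuple[str, str]] = set()
    for start in range(0, len(genes), step):
        sub = genes[start:start + block]
        if len(sub) < 2:
            break
        sub_dag = learn_structure(binary[sub], seed=seed, max_iter=max_iter)
        edges.update(sub_dag.edges)
        if start + block >= len(genes):
            break
    for u, v in sorted(edges):
        if not (union.has_node(u) and union.has_node(v)
                and nx.has_path(union, v, u)):
            union.add_edge(u, v)
    return union


# ------------------------------------------------------- edge filtering

def confidence_class(r: float, p_r: float, rho: float, p_rho: float,
                     p_max: float = P_MAX,
                     strong: float = STRONG_R) -> str | None:
    """Three-level edge confidence from the dual correlation test.

    None (drop) when neither coefficient is significant; thin when
    exactly one is; medium when both are but either |coefficient| is
    below the strong cut-off; thick when both are significant and both
    |coefficients| reach it.
    """
    sig_r, sig_rho = p_r <= p_max, p_rho <= p_max
    if not (sig_r or sig_rho):
        return None
    if sig_r and sig_rho:
        return "thick" if (abs(r) >= strong and abs(rho) >= strong) else "medium"
    return "thin"


def filter_edges(dag: nx.DiGraph, zscores: pd.DataFrame,
                 curated_pairs: set[tuple[str, str]] | None = None,
                 p_max: float = P_MAX, strong: float = STRONG_R,
                 biotypes: dict[str, str] | None = None) -> nx.DiGraph:
    """Correlation-filter DAG edges and assign confidence classes.

    ``zscores`` holds z-scored normalized expression (genes x samples).
    Edges where neither Pearson nor Spearman reaches p <= ``p_max`` are
    dropped; retained edges carry both coefficients, their p-values, the
    confidence class and the evidence flag (curated when the pair is in
    the curated interaction table, in either orientation).
    """
    curated = curated_pairs or set()
    grn = nx.DiGraph()
    for node in dag.nodes:
        grn.add_node(node, biotype=(biotypes or {}).get(node, "coding"))
    for u, v in sorted(dag.edges):
        if u == v:
            continue  # self-loops removed before analysis
        x = zscores.loc[u].to_numpy(dtype=float)
        y = zscores.loc[v].to_numpy(dtype=float)
        r, p_r = stats.pearsonr(x, y)
        rho, p_rho = stats.spearmanr(x, y)
        confidence = confidence_class(r, p_r, rho, p_rho, p_max, strong)
        if confidence is None:
            continue
        evidence = ("curated" if (u, v) in curated or (v, u) in curated
                    else "inferred")
        grn.add_edge(u, v, pearson_r=float(r), pearson_p=float(p_r),
                     spearman_rho=float(rho), spearman_p=float(p_rho),
                     confidence=confidence, evidence=evidence)
    return grn


# ----------------------------------------------------------- subnetworks

def subnetworks(grn: nx.DiGraph, lea_genes: set[str],
                pleiotropy_genes: set[str]) -> tuple[nx.DiGraph, nx.DiGraph]:
    """DD and DP node-induced subgraphs.

    Both keep every DaP and miRNA node; DD adds the leading-edge overlap
    genes, DP adds the expression-independent overlap genes.
    """
    core = {n for n, d in grn.nodes(data=True)
            if d.get("biotype") in ("pseudogene", "miRNA")}
    dd = grn.subgraph(core | (lea_genes & set(grn.nodes))).copy()
    dp = grn.subgraph(core | (pleiotropy_genes & set(grn.nodes))).copy()
    return dd, dp


# -------------------------------------------------------------- topology

@dataclass
class TopologyReport:
    """Density plus six per-node centralities for one network variant.

    Degree centrality is computed on the directed graph (in+out);
    betweenness, closeness, eigenvector and subgraph centralities on the
    undirected simple projection, matching common network-analyzer
    conventions.
    """

    variant: str
    n_nodes: int
    n_edges: int
    density: float
    degree: dict[str, float] = field(default_factory=dict)
    betweenness: dict[str, float] = field(default_factory=dict)
    closeness: dict[str, float] = field(default_factory=dict)
    eigenvector: dict[str, float] = field(default_factory=dict)
    subgraph: dict[str, float] = field(default_factory=dict)
    degree_centrality: dict[str, float] = field(default_factory=dict)


def topology(grn: nx.DiGraph, drop_pseudogenes: bool = False,
             variant: str = "ON") -> TopologyReport:
    """Density and centralities, optionally after pseudogene knock-out."""
    g = grn.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    if drop_pseudogenes:
        drop = [n for n, d in g.nodes(data=True)
                if d.get("biotype") == "pseudogene"]
        g.remove_nodes_from(drop)
    n, m = g.number_of_nodes(), g.number_of_edges()
    density = m / (n * (n - 1)) if n > 1 else 0.0
    label = f"{variant}_{'without' if drop_pseudogenes else 'with'}_pseudogenes"
    if n == 0:
        return TopologyReport(label, 0, 0, 0.0)
    und = g.to_undirected()
    try:
        eig = nx.eigenvector_centrality_numpy(und) if m else dict.fromkeys(g, 0.0)
    except (nx.NetworkXException, TypeError):
        eig = dict.fromkeys(g, float("nan"))
    return TopologyReport(
        variant=label, n_nodes=n, n_edges=m, density=density,
        degree={v: d for v, d in g.degree()},
        betweenness=nx.betweenness_centrality(und),
        closeness=nx.closeness_centrality(und),
        eigenvector=eig,
        subgraph=nx.subgraph_centrality(und) if n else {},
        degree_centrality=nx.degree_centrality(g),
    )


def edge_table(grn: nx.DiGraph) -> pd.DataFrame:
    """Flat edge list with correlation stats, class and evidence."""
    rows = [{"source": u, "target": v, **d}
            for u, v, d in grn.edges(data=True)]
    cols = ["source", "target", "pearson_r", "pearson_p", "spearman_rho",
            "spearman_p", "confidence", "evidence"]
    return pd.DataFrame(rows, columns=cols)
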