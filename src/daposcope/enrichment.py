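"""Minimal gene-set enrichment analysis with leading-edge overlap.

Expression-dependent arm: genes are ranked by signal-to-noise between
two phenotype groups, the weighted Kolmogorov-Smirnov running sum gives
the enrichment score (ES) and its leading edge, and significance comes
from gene-set permutation (random same-size sets), with NES normalized
by the mean same-sign null |ES| and FDR q computed by the same-sign
pooled-null procedure.  Expression-independent arm: hypergeometric
over-representation with Benjamini-Hochberg adjustment.

Retention uses inclusive thresholds FDR q <= 0.25, |ES| >= 0.50 and
|NES| >= 1.5, followed by a top-k (default 30) cut on |NES|; the
filter-then-top-k order is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, GeneSetCollection

Q_MAX = 0.25
ES_MIN = 0.50
NES_MIN = 1.5
TOP_K = 30


# --------------------------------------------------------------- ranking

def rank_genes(em: ExpressionMatrix, group_a: list[str],
               group_b: list[str]) -> pd.Series:
    """Signal-to-noise ranking of genes for group_a versus group_b.

    score = (mu_a - mu_b) / (sigma_a' + sigma_b') with each standard
    deviation floored at 0.2 * |mean| (and a small absolute floor to
    avoid zero denominators on constant genes).  Returned sorted
    descending; ties break lexicographically on the gene id so the
    ranking is stable across runs.
    """
    a = em.values[group_a].to_numpy(dtype=float)
    b = em.values[group_b].to_numpy(dtype=float)
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), 0.2 * np.abs(mu_a))
    sd_b = np.maximum(b.std(axis=1, ddof=1), 0.2 * np.abs(mu_b))
    denom = np.maximum(sd_a + sd_b, 1e-12)
    scores = pd.Series((mu_a - mu_b) / denom, index=em.genes, name="score")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order]


# ------------------------------------------------------ enrichment score

def enrichment_score(ranked: pd.Series, gene_set: list[str],
                     weight: float = 1.0) -> tuple[float, list[str]]:
    """Weighted KS running-sum ES and the leading-edge members.

    Hits advance the sum by |score|^weight (normalized over hits),
    misses retreat by 1/(N - N_hits).  ES is the extremum of the running
    sum; the leading edge is the members at or before the positive peak
    (at or after the negative peak for ES < 0).  A set covering the
    whole universe has no misses and gets ES = 0 by convention.
    """
    genes = ranked.index
    member = genes.isin(set(gene_set))
    n_hits = int(member.sum())
    n_total = len(genes)
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hits == n_total:
        return 0.0, []

    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight
    hit_w = np.where(member, weights, 0.0)
    total_hit = hit_w.sum()
    if total_hit <= 0:  # all-zero scores: fall back to unweighted steps
        hit_w = member.astype(float)
        total_hit = hit_w.sum()
    running = np.cumsum(hit_w / total_hit
                        - (~member).astype(float) / (n_total - n_hits))
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        leading = [g for g, m in zip(genes[:peak + 1], member[:peak + 1]) if m]
    else:
        leading = [g for g, m in zip(genes[peak:], member[peak:]) if m]
    return es, leading


# --------------------------------------------------- permutation nulls

def _null_es(ranked: pd.Series, set_size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    n = len(ranked)
    out = np.empty(n_perm)
    genes = list(ranked.index)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        out[i], _ = enrichment_score(ranked, [genes[j] for j in idx])
    return out


def nes_fdr(ranked: pd.Series, collection: GeneSetCollection,
            n_perm: int = 1000, seed: int = 0,
            mode: str = "gene_set",
            em: ExpressionMatrix | None = None,
            group_a: list[str] | None = None,
            group_b: list[str] | None = None) -> pd.DataFrame:
    """ES, NES, empirical p and pooled-null FDR q for every set.

    ``mode='gene_set'`` permutes gene labels (random same-size sets);
    ``mode='phenotype'`` permutes sample labels and re-ranks, for the
    configuration used with whole-matrix microarray cohorts.
    """
    rng = np.random.default_rng(seed)
    names = collection.names()
    observed = {}
    leading = {}
    nulls: dict[str, np.ndarray] = {}

    if mode == "gene_set":
        by_size: dict[int, np.ndarray] = {}
        for name in names:
            members = [g for g in collection[name] if g in ranked.index]
            es, le = enrichment_score(ranked, members)
            observed[name], leading[name] = es, le
            size = len(members)
            if size not in by_size:
                by_size[size] = _null_es(ranked, size, n_perm, rng)
            nulls[name] = by_size[size]
    elif mode == "phenotype":
        if em is None or group_a is None or group_b is None:
            raise ValueError("phenotype mode needs em, group_a and group_b")
        for name in names:
            members = [g for g in collection[name] if g in ranked.index]
            observed[name], leading[name] = enrichment_score(ranked, members)
        pooled = list(group_a) + list(group_b)
        perm_es = {name: np.empty(n_perm) for name in names}
        for i in range(n_perm):
            perm = [pooled[j] for j in rng.permutation(len(pooled))]
            pa, pb = perm[:len(group_a)], perm[len(group_a):]
            perm_ranked = rank_genes(em, pa, pb)
            for name in names:
                members = [g for g in collection[name]
                           if g in perm_ranked.index]
                perm_es[name][i], _ = enrichment_score(perm_ranked, members)
        nulls = perm_es
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")

    rows = []
    pooled_nes: list[np.ndarray] = []
    for name in names:
        es, null = observed[name], nulls[name]
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        norm = pos_mean if es >= 0 else neg_mean
        nes = es / norm if norm and np.isfinite(norm) else 0.0
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        p = (float(np.mean(np.abs(same_sign) >= abs(es)))
             if len(same_sign) else 1.0)
        null_nes = np.concatenate([
            null[null > 0] / pos_mean if np.isfinite(pos_mean) else [],
            null[null < 0] / neg_mean if np.isfinite(neg_mean) else [],
        ]) if len(null) else np.array([])
        pooled_nes.append(null_nes)
        rows.append({"name": name, "es": es, "nes": nes, "pvalue": p,
                     "leading_edge": leading[name],
                     "tissue_class": collection.tissue_class.get(name, "other")})

    result = pd.DataFrame(rows)
    all_null_nes = (np.concatenate(pooled_nes) if pooled_nes
                    else np.array([]))
    # same-sign pooled-null FDR: both the null and the observed fractions
    # are conditioned on the sign of NES*
    obs_nes = result["nes"].to_numpy()
    null_pos = all_null_nes[all_null_nes >= 0]
    null_neg = all_null_nes[all_null_nes < 0]
    obs_pos = obs_nes[obs_nes >= 0]
    obs_neg = obs_nes[obs_nes < 0]
    qvals = np.ones(len(result))
    for i, nes in enumerate(obs_nes):
        if nes >= 0:
            null_frac = np.mean(null_pos >= nes) if len(null_pos) else 1.0
            obs_frac = np.mean(obs_pos >= nes) if len(obs_pos) else 0.0
        else:
            null_frac = np.mean(null_neg <= nes) if len(null_neg) else 1.0
            obs_frac = np.mean(obs_neg <= nes) if len(obs_neg) else 0.0
        qvals[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    result["fdr_q"] = qvals
    return result


# -------------------------------------------------------------- filtering

def filter_enrichments(results: pd.DataFrame, q_max: float = Q_MAX,
                       es_min: float = ES_MIN, nes_min: float = NES_MIN,
                       top_k: int | None = TOP_K,
                       top_k_first: bool = False) -> pd.DataFrame:
    """Retain sets passing the inclusive q/|ES|/|NES| cut-offs, then top-k.

    ``top_k_first`` applies the |NES| top-k cut before the thresholds
    instead (the alternative reading of the tool's workflow).
    """
    def threshold(df: pd.DataFrame) -> pd.DataFrame:
        keep = ((df["fdr_q"] <= q_max) & (df["es"].abs() >= es_min)
                & (df["nes"].abs() >= nes_min))
        return df[keep]

    def head(df: pd.DataFrame) -> pd.DataFrame:
        if top_k is None or len(df) <= top_k:
            return df
        return df.reindex(
            df["nes"].abs().sort_values(ascending=False, kind="stable")
            .index[:top_k])

    out = threshold(head(results)) if top_k_first else head(threshold(results))
    return out.reset_index(drop=True)


# ------------------------------------------------- leading-edge overlap

@dataclass
class OverlapSummary:
    """Within-module overlap: G genes shared by >=2 terms, P terms hit."""

    module: str
    n_genes: int  # G: distinct genes appearing in >= 2 retained terms
    n_terms: int  # P: retained terms containing >= 1 such gene
    incidence: pd.DataFrame | None = None

    @property
    def ratio(self) -> float:
        return self.n_genes / self.n_terms if self.n_terms else 0.0


def leading_edge_overlap(results: pd.DataFrame,
                         module: str = "module") -> OverlapSummary:
    """Summarize gene sharing across the leading edges of one module."""
    edges = {row["name"]: set(row["leading_edge"])
             for _, row in results.iterrows()}
    genes = sorted(set().union(*edges.values())) if edges else []
    incidence = pd.DataFrame(
        {name: [g in members for g in genes]
         for name, members in edges.items()},
        index=genes, dtype=bool,
    )
    shared = incidence.index[incidence.sum(axis=1) >= 2]
    terms_hit = [name for name in incidence.columns
                 if incidence.loc[shared, name].any()]
    return OverlapSummary(module, len(shared), len(terms_hit), incidence)


def node_overlap(sets: dict[str, set[str]], module: str) -> OverlapSummary:
    """Overlap summary over arbitrary term->gene memberships (ORA nodes)."""
    frame = pd.DataFrame({"name": list(sets),
                          "leading_edge": [sorted(v) for v in sets.values()]})
    return leading_edge_overlap(frame, module)


# ------------------------------------------------------------------- ORA

def ora(gene_list: list[str], collection: GeneSetCollection,
        universe: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set."""
    query = set(gene_list) & set(universe)
    if not query:
        raise ValueError("empty gene list (or no overlap with the universe)")
    n_universe = len(set(universe))
    rows = []
    for name in collection.names():
        members = set(collection[name]) & set(universe)
        hits = sorted(query & members)
        k, n, kk = len(members), len(query), len(hits)
        p = stats.hypergeom.sf(kk - 1, n_universe, k, n) if members else 1.0
        rows.append({"name": name, "n_set": k, "n_hits": kk,
                     "pvalue": float(p), "hits": hits,
                     "tissue_class": collection.tissue_class.get(name, "other")})
    out = pd.DataFrame(rows)
    out["fdr_q"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
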