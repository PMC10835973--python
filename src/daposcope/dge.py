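"""Per-stage differential-expression calling against normal tissue.

Normalization follows the median-of-ratios convention (per-sample size
factor = median over genes of the ratio to that gene's geometric-mean
reference); the test engine is a two-sided rank-sum test per gene with
Benjamini-Hochberg adjustment, and a gene is called de-regulated only
when it passes the dual cut-off: adjusted p <= alpha AND |log2FC| >= the
fold-change threshold (defaults 0.05 and 1.5).  The engine is pluggable
so a count-model backend can be swapped in without touching the
thresholds, which are the part of the procedure that matters downstream.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import NORMAL, ExpressionMatrix

#: dual cut-off defaults used throughout the pipeline
LFC_THRESHOLD = 1.5
ALPHA = 0.05


def size_factors(values: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Genes with a zero count in any sample have an undefined geometric
    mean on the log scale and are excluded from factor estimation.
    """
    if (values.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        logs = np.log(values.to_numpy(dtype=float))
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ValueError("no gene with all-positive counts; cannot "
                         "estimate size factors")
    ref = logs[finite].mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs[finite] - ref, axis=0))
    return pd.Series(factors, index=values.columns, name="size_factor")


def normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its median-of-ratios size factor."""
    if em.normalized:
        return em
    if not (em.values.to_numpy() > 0).any():
        raise ValueError("all-zero count matrix")
    sf = size_factors(em.values)
    return ExpressionMatrix(em.values / sf, em.stages, normalized=True)


def _ranksum_engine(tumour: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p-value per gene (rows)."""
    res = stats.mannwhitneyu(tumour, normal, axis=1, alternative="two-sided",
                             method="asymptotic")
    return np.asarray(res.pvalue)


def call_de(em: ExpressionMatrix, stage: str,
            lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA,
            normal_label: str = NORMAL,
            engine: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
            ) -> pd.DataFrame:
    """Call de-regulated genes in one stage versus normal samples.

    Returns a frame with columns ``gene, stage, log2fc, pvalue, padj,
    direction`` where direction is ``up``/``down``/``none`` under the
    dual cut-off.  log2FC uses a +1 pseudocount on normalized means.
    """
    labels = set(em.stages)
    if stage not in labels or normal_label not in labels:
        raise KeyError(f"unknown stage label {stage!r} (have {sorted(labels)})")
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    norm = normalize(em)
    t_cols = norm.samples_of(stage)
    n_cols = norm.samples_of(normal_label)
    if len(t_cols) < 3 or len(n_cols) < 3:
        raise ValueError("need at least 3 samples per group")

    tum = norm.values[t_cols].to_numpy(dtype=float)
    ref = norm.values[n_cols].to_numpy(dtype=float)
    log2fc = np.log2(tum.mean(axis=1) + 1.0) - np.log2(ref.mean(axis=1) + 1.0)
    engine = engine or _ranksum_engine
    pvals = np.nan_to_num(engine(tum, ref), nan=1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]

    significant = padj <= alpha
    direction = np.where(significant & (log2fc >= lfc_threshold), "up",
                         np.where(significant & (log2fc <= -lfc_threshold),
                                  "down", "none"))
    return pd.DataFrame({
        "gene": norm.genes, "stage": stage, "log2fc": log2fc,
        "pvalue": pvals, "padj": padj, "direction": direction,
    }).reset_index(drop=True)


def call_de_all_stages(em: ExpressionMatrix,
                       stages: list[str] | None = None,
                       **kwargs) -> pd.DataFrame:
    """Concatenate :func:`call_de` over every tumour stage present."""
    stages = stages or [s for s in em.stage_labels() if s != NORMAL]
    return pd.concat([call_de(em, s, **kwargs) for s in stages],
                     ignore_index=True)
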