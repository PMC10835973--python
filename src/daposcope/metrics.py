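"""The study's three bespoke summary statistics.

* Enriched degree of differentiation: mean over enrichment modules of
  G/P, where G counts genes overlapping >= 2 retained terms and P counts
  the terms containing such genes.  Modules with no retained term drop
  out of the average.
* Degree of pleiotropy: the same ratio averaged over the
  expression-independent enrichment modules.
* Cellular-reprogramming (SD/SL) ratio: retained stomach/duodenum adult
  signatures divided by retained small/large-intestine embryonic
  signatures; a higher ratio proxies faster reprogramming towards
  non-oesophageal adult fates.

Averages are kept at full precision; printed values in the field round
or truncate at 3 decimals, so comparisons should allow +/-0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .enrichment import OverlapSummary


@dataclass
class RatioReport:
    """Per-module G/P ratios plus their full-precision mean."""

    per_module: dict[str, float]
    n_modules: int
    average: float


DifferentiationReport = RatioReport
PleiotropyReport = RatioReport


def _average_ratio(summaries: list[OverlapSummary]) -> RatioReport:
    contributing = [s for s in summaries if s.n_terms > 0]
    if not contributing:
        raise ValueError("no module with retained terms")
    per_module = {s.module: s.ratio for s in contributing}
    avg = sum(per_module.values()) / len(per_module)
    return RatioReport(per_module, len(per_module), avg)


def degree_of_differentiation(summaries: list[OverlapSummary]) -> RatioReport:
    """Average G/P over leading-edge-analysis modules with data."""
    return _average_ratio(summaries)


def degree_of_pleiotropy(summaries: list[OverlapSummary]) -> RatioReport:
    """Average G/P over expression-independent enrichment modules."""
    return _average_ratio(summaries)


def reprogramming_ratio(results: pd.DataFrame) -> float:
    """SD/SL signature-count ratio over retained enrichments.

    Returns 0 when no SD signature is retained, +inf when SD signatures
    exist but no SL signature does.
    """
    classes = results["tissue_class"]
    n_sd = int((classes == "SD").sum())
    n_sl = int((classes == "SL").sum())
    if n_sd == 0:
        return 0.0
    if n_sl == 0:
        return math.inf
    return n_sd / n_sl


def gi_fraction(results: pd.DataFrame, k: int = 30,
                gi_classes: tuple[str, ...] = ("SD", "SL")) -> float:
    """Fraction of the top-k retained signatures labelled non-oesophageal GI."""
    if results.empty:
        return 0.0
    top = results.reindex(
        results["nes"].abs().sort_values(ascending=False, kind="stable")
        .index[:k]) if "nes" in results else results.head(k)
    return float(top["tissue_class"].isin(gi_classes).mean())
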