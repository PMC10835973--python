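"""Bundled worked-example datasets.

These small tables encode the published pan-stage survey of
differentiation-associated pseudogenes (DaPs) in oesophageal carcinoma:
the 45-gene stage-membership table and the per-module overlap counts
(genes, terms) behind the degree-of-differentiation and
degree-of-pleiotropy statistics.  They serve as desk-scale worked
examples and as regression fixtures for the set-algebra and metric
operations.
"""

from __future__ import annotations

import pandas as pd

from .core import STAGES
from .enrichment import OverlapSummary

# gene, direction (+1 up / -1 down), flags for SI, SII, SIII, SIV
_DAP_TABLE = [
    ("AOC4P", -1, 1, 1, 1, 1),
    ("AOX2P", +1, 0, 0, 1, 0),
    ("ARSDP1", -1, 0, 1, 0, 0),
    ("ATP5F1BP1", -1, 1, 0, 0, 0),
    ("ATP5PFP1", -1, 1, 1, 1, 1),
    ("BCORP1", -1, 1, 0, 0, 0),
    ("CCT8L1P", -1, 1, 1, 1, 1),
    ("CCT8P1", -1, 1, 1, 1, 1),
    ("CETN4P", -1, 1, 0, 0, 0),
    ("CHIAP2", -1, 1, 1, 1, 1),
    ("CMAHP", -1, 1, 0, 0, 0),
    ("DGAT2L7P", +1, 0, 0, 1, 0),
    ("DNAJB3", +1, 0, 1, 0, 0),
    ("DUX4L9", +1, 0, 1, 0, 0),
    ("DUXAP10", +1, 1, 1, 1, 1),
    ("DUXAP9", +1, 1, 1, 1, 1),
    ("ESRRAP1", -1, 1, 0, 0, 0),
    ("FAR2P1", +1, 1, 1, 1, 1),
    ("FCGR1CP", -1, 1, 1, 1, 1),
    ("FER1L4", -1, 0, 1, 0, 0),
    ("FSCN1P1", +1, 0, 1, 0, 0),
    ("GGNBP1", +1, 0, 0, 1, 0),
    ("GTF2IRD2P1", +1, 0, 1, 0, 0),
    ("GYG2P1", -1, 0, 1, 0, 0),
    ("H2BP1", -1, 1, 1, 1, 1),
    ("HSPD1P11", -1, 0, 1, 0, 0),
    ("IGHV3-71", -1, 0, 1, 0, 0),
    ("KRT17P1", +1, 0, 1, 0, 0),
    ("KRT17P2", +1, 0, 1, 0, 0),
    ("MAGEA5P", +1, 0, 1, 0, 0),
    ("MT1JP", -1, 1, 1, 1, 1),
    ("MYLKP1", -1, 0, 0, 1, 0),
    ("NANOGP1", +1, 0, 0, 1, 0),
    ("OR7E12P", -1, 1, 1, 1, 1),
    ("PLAC9P1", -1, 0, 0, 1, 0),
    ("RPL36P16", -1, 0, 0, 0, 1),
    ("RPS24P1", -1, 0, 0, 1, 0),
    ("SHC1P1", -1, 0, 1, 0, 0),
    ("SIGLEC17P", -1, 1, 0, 0, 0),
    ("TPRXL", +1, 0, 1, 0, 0),
    ("TRPC2", -1, 1, 0, 0, 0),
    ("TSSC2", -1, 1, 1, 1, 1),
    ("UOX", -1, 0, 0, 0, 1),
    ("VNN3P", +1, 1, 1, 1, 1),
    ("YWHAEP7", +1, 0, 0, 1, 0),
]


def dap_stage_table() -> pd.DataFrame:
    """Signed stage-membership matrix of the 45 surveyed DaPs."""
    rows = {g: [d * si, d * sii, d * siii, d * siv]
            for g, d, si, sii, siii, siv in _DAP_TABLE}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(STAGES)).sort_index()


# per-stage (module -> (G genes, P terms)) counts behind the published
# enriched-degree-of-differentiation averages
_DIFFERENTIATION_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "SI": {"CS-LEA": (12, 11), "GO_BP-LEA": (7, 4)},
    "SII": {"CS-LEA": (24, 10), "GO_BP-LEA": (37, 9), "KEGG-LEA": (8, 5)},
    "SIII": {"CS-LEA": (6, 4), "IS-LEA": (17, 16)},
    "SIV": {"CS-LEA": (1, 3), "GO_BP-LEA": (10, 4)},
}

# per-stage (module -> (G genes, P nodes)) counts behind the published
# degree-of-pleiotropy averages (expression-independent enrichment)
_PLEIOTROPY_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "SI": {"GO_BP": (16, 9), "GO_CC": (5, 7), "GO_MF": (7, 4),
           "KEGG": (13, 10), "Hallmark": (4, 4), "WikiPathways": (12, 17)},
    "SII": {"GO_BP": (80, 24), "GO_CC": (37, 21), "GO_MF": (41, 18),
            "KEGG": (11, 10), "Hallmark": (6, 5), "WikiPathways": (19, 10)},
    "SIII": {"GO_BP": (29, 17), "GO_CC": (8, 11), "GO_MF": (8, 4),
             "WikiPathways": (7, 10)},
    "SIV": {"GO_BP": (32, 17), "GO_CC": (17, 15), "GO_MF": (9, 5),
            "KEGG": (9, 7), "Hallmark": (7, 6), "WikiPathways": (17, 29)},
}


def _summaries(counts: dict[str, dict[str, tuple[int, int]]],
               stage: str) -> list[OverlapSummary]:
    if stage not in counts:
        raise KeyError(f"unknown stage {stage!r}")
    return [OverlapSummary(module, g, p)
            for module, (g, p) in counts[stage].items()]


def differentiation_overlap_counts(stage: str) -> list[OverlapSummary]:
    """Worked-example overlap summaries for the differentiation metric."""
    return _summaries(_DIFFERENTIATION_COUNTS, stage)


def pleiotropy_overlap_counts(stage: str) -> list[OverlapSummary]:
    """Worked-example overlap summaries for the pleiotropy metric."""
    return _summaries(_PLEIOTROPY_COUNTS, stage)
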