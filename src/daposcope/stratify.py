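"""Combinatorial DaP-based patient stratification.

Tumour samples of a stage are labelled by a Boolean rule on their
median-binarized DaP expression: a sample is ``UDaP_Combo`` when the
median of its up-regulated-DaP binary states is >= 0.5 AND the median
of its down-regulated-DaP binary states equals 0 (most up-DaPs in the
high state, most down-DaPs in the low state); otherwise
``UDaP_No_Combo``.  Medians of binary vectors use the standard midpoint
convention, so an even down-DaP count split 50/50 gives median 0.5 and
fails the strict "= 0" test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

COMBO = "UDaP_Combo"
NO_COMBO = "UDaP_No_Combo"


def stratify_samples(binary: pd.DataFrame, up_daps: list[str],
                     down_daps: list[str]) -> pd.DataFrame:
    """Label every sample (column of ``binary``) by the combinatorial rule.

    Both constitutive and stage-specific DaPs belong in the two gene
    lists.  Returns columns ``sample, median_up, median_down, label``.
    """
    if not up_daps or not down_daps:
        raise ValueError("both DaP lists must be non-empty")
    missing = (set(up_daps) | set(down_daps)) - set(binary.index)
    if missing:
        raise KeyError(f"DaPs absent from the binary matrix: {sorted(missing)}")
    med_up = binary.loc[list(up_daps)].median(axis=0)
    med_down = binary.loc[list(down_daps)].median(axis=0)
    label = np.where((med_up >= 0.5) & (med_down == 0), COMBO, NO_COMBO)
    return pd.DataFrame({
        "sample": binary.columns, "median_up": med_up.to_numpy(),
        "median_down": med_down.to_numpy(), "label": label,
    }).reset_index(drop=True)


def cohort_split(table: pd.DataFrame, strata: pd.DataFrame,
                 sample_column: str = "Tumor_Sample_Barcode",
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split any per-sample table (e.g. a MAF) by the stratification labels."""
    labels = strata.set_index("sample")["label"]
    assigned = table[sample_column].map(labels)
    combo = table[assigned == COMBO].reset_index(drop=True)
    no_combo = table[assigned == NO_COMBO].reset_index(drop=True)
    for name, part in ((COMBO, combo), (NO_COMBO, no_combo)):
        if part.empty:
            warnings.warn(f"stratum {name} is empty", stacklevel=2)
    return combo, no_combo
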