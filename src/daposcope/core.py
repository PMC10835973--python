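"""Shared containers for the pan-stage pseudogene analysis pipeline.

The pipeline operates on a tumour cohort sampled across an ordered stage
landscape (normal tissue followed by tumour stages SI..SIV).  Expression
data travel as a genes x samples count matrix plus a per-sample stage
label; gene-set collections carry an optional per-set tissue-class label
used by the cellular-reprogramming metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical tumour stage labels, in landscape order
STAGES: tuple[str, ...] = ("SI", "SII", "SIII", "SIV")

#: label of the non-tumour reference group
NORMAL: str = "normal"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample stage labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are sample identifiers.  Raw counts are
        non-negative integers; after normalization values are real.
    stages : pandas.Series
        Maps each sample identifier (index) to its stage label.
    normalized : bool
        Whether size-factor normalization has been applied.
    """

    values: pd.DataFrame
    stages: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.stages.index]
        if missing:
            raise ValueError(f"samples without stage labels: {missing[:5]}")
        self.stages = self.stages.loc[list(self.values.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def stage_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.stages:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_of(self, stage: str) -> list[str]:
        """Sample identifiers belonging to one stage group."""
        hits = [s for s, g in self.stages.items() if g == stage]
        if not hits:
            raise KeyError(f"unknown stage label: {stage!r}")
        return hits

    def subset(self, stages: list[str]) -> "ExpressionMatrix":
        """Restrict to samples whose stage label is in ``stages``."""
        cols = [s for s in self.samples if self.stages[s] in stages]
        return ExpressionMatrix(self.values[cols], self.stages.loc[cols],
                                normalized=self.normalized)


@dataclass
class GeneSetCollection:
    """Named gene sets plus per-set tissue-class metadata.

    ``tissue_class`` maps a set name to one of the study's signature
    classes (``SD`` stomach/duodenum adult, ``SL`` small/large-intestine
    embryonic, ``lung``, ``oesophageal``, ``immune`` or ``other``); the
    class is input metadata, never inferred from the set name.
    """

    sets: dict[str, list[str]]
    tissue_class: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
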