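"""Stage-wise expression-pattern set algebra and gene classification.

The substrate is a signed stage-membership matrix: one row per gene, one
column per tumour stage, entries +1 (up-regulated), -1 (down-regulated)
or 0 (not de-regulated).  A gene is *constitutive* when it is
de-regulated in every stage with a uniform direction; *stage-specific*
when it is de-regulated in exactly one stage; everything else
(multi-stage, or all-stage with mixed direction) is *multi-stage*.
These three sets partition the de-regulated universe.

Classification splits the de-regulated genes into the study's
categories: differentiation-associated pseudogenes (DaPs),
pseudogene-interacting genes (PiGs: de-regulated curated interactors of
a DaP), differentiation-associated coding genes (DaCGs) and miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DirectionalSet:
    """A gene set split by regulation direction."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.genes)


def membership_from_de(de_table: pd.DataFrame,
                       stages: list[str] | None = None) -> pd.DataFrame:
    """Build the signed membership matrix from a DE result table.

    ``de_table`` needs columns ``gene, stage, direction``; genes with
    direction ``none`` in every stage are dropped.
    """
    stages = stages or sorted(de_table["stage"].unique())
    sign = de_table["direction"].map({"up": 1, "down": -1, "none": 0})
    wide = (de_table.assign(sign=sign)
            .pivot_table(index="gene", columns="stage", values="sign",
                         fill_value=0, aggfunc="sum"))
    wide = wide.reindex(columns=stages, fill_value=0).astype(int)
    return wide[(wide != 0).any(axis=1)].sort_index()


def constitutive_set(membership: pd.DataFrame) -> DirectionalSet:
    """Genes de-regulated in all stages, split by uniform direction.

    Mixed-direction all-stage genes are excluded here (they land in the
    multi-stage bucket): the per-direction intersection semantics match
    computing the stage intersection separately for up- and
    down-regulated gene sets.
    """
    if membership.shape[1] < 2:
        raise ValueError("need at least two stages")
    vals = membership.to_numpy()
    up = membership.index[(vals == 1).all(axis=1)]
    down = membership.index[(vals == -1).all(axis=1)]
    return DirectionalSet(set(up), set(down))


def stage_specific_set(membership: pd.DataFrame, stage: str) -> DirectionalSet:
    """Genes de-regulated in ``stage`` and in no other stage.

    This is the evaluated form of the piecewise stage-difference
    formula: removing from GS_i its pairwise intersections with every
    other stage leaves exactly the genes flagged only in stage i.
    """
    if stage not in membership.columns:
        raise KeyError(f"unknown stage {stage!r}")
    others = membership.drop(columns=stage)
    only_here = (membership[stage] != 0) & (others == 0).all(axis=1)
    here = membership.loc[only_here, stage]
    return DirectionalSet(set(here.index[here == 1]),
                          set(here.index[here == -1]))


def multi_stage_set(membership: pd.DataFrame) -> set[str]:
    """De-regulated genes that are neither constitutive nor stage-specific."""
    flagged = (membership != 0).sum(axis=1)
    multi = set(membership.index[flagged > 1])
    return multi - constitutive_set(membership).genes


def partition(membership: pd.DataFrame) -> dict[str, set[str]]:
    """The full, pairwise-disjoint partition of the de-regulated universe."""
    parts: dict[str, set[str]] = {"constitutive": constitutive_set(membership).genes}
    for stage in membership.columns:
        parts[f"specific_{stage}"] = stage_specific_set(membership, stage).genes
    parts["multi_stage"] = multi_stage_set(membership)
    return parts


@dataclass
class GeneClasses:
    """Disjoint DaP / PiG / DaCG / miRNA partition of the de-regulated genes."""

    daps: set[str]
    pigs: set[str]
    dacgs: set[str]
    mirnas: set[str]
    unannotated: set[str] = field(default_factory=set)

    def of(self, category: str) -> set[str]:
        return getattr(self, category)


def classify_genes(membership: pd.DataFrame,
                   annotation: pd.DataFrame) -> GeneClasses:
    """Partition de-regulated genes into DaP / PiG / miRNA / DaCG.

    ``annotation`` is indexed by gene with columns ``biotype``
    (pseudogene/coding/TF/miRNA), ``differentiation_flag`` (bool) and
    ``interactors`` (list of gene ids curated as DaP partners).  Genes
    absent from the annotation are logged and bucketed as coding
    differentiation-associated (the conservative default).  Precedence:
    DaP > PiG > miRNA > DaCG, which keeps the categories disjoint.
    """
    de_genes = list(membership.index)
    unannotated = {g for g in de_genes if g not in annotation.index}
    if unannotated:
        logger.warning("%d de-regulated genes missing from annotation; "
                       "classified as coding", len(unannotated))

    def biotype(g: str) -> str:
        return annotation.at[g, "biotype"] if g in annotation.index else "coding"

    def diff_flag(g: str) -> bool:
        return (bool(annotation.at[g, "differentiation_flag"])
                if g in annotation.index else True)

    daps = {g for g in de_genes
            if biotype(g) == "pseudogene" and diff_flag(g)}
    interactors_of_daps: set[str] = set()
    for dap in daps & set(annotation.index):
        interactors_of_daps.update(annotation.at[dap, "interactors"])
    # curated links are symmetric: a gene listing a DaP as interactor counts
    for g in set(de_genes) & set(annotation.index):
        if set(annotation.at[g, "interactors"]) & daps:
            interactors_of_daps.add(g)

    pigs = {g for g in de_genes if g not in daps and g in interactors_of_daps}
    mirnas = {g for g in de_genes
              if g not in daps | pigs and biotype(g) == "miRNA"}
    dacgs = {g for g in de_genes
             if g not in daps | pigs | mirnas and diff_flag(g)
             and biotype(g) in ("coding", "TF")}
    return GeneClasses(daps, pigs, dacgs, mirnas, unannotated)


def multi_stage_mirnas(membership: pd.DataFrame, mirnas: set[str]) -> set[str]:
    """miRNAs de-regulated in more than one stage but not in all."""
    flagged = (membership != 0).sum(axis=1)
    n_stages = membership.shape[1]
    hits = membership.index[(flagged > 1) & (flagged < n_stages)]
    return set(hits) & mirnas


def complementarity(pairs: list[tuple[str, str]],
                    membership: pd.DataFrame) -> float:
    """Fraction of (PiG, DaP) pairs with identical stage pattern+direction."""
    if not pairs:
        raise ValueError("no pairs given")
    matched = 0
    for pig, dap in pairs:
        if pig not in membership.index or dap not in membership.index:
            continue
        if (membership.loc[pig] == membership.loc[dap]).all():
            matched += 1
    return matched / len(pairs)
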