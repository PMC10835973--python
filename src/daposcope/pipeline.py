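"""Configuration-driven end-to-end orchestration on a synthetic study.

Chains simulate -> normalize/DE -> partition/classify -> GSEA ->
overlap metrics -> GRN -> stratify -> mutation analytics -> motif prep,
writing every intermediate as plain text plus a machine-readable JSON
run report (versions, seeds, input hashes, per-stage summaries).  Any
stage failure aborts with the failing stage named.

The bundled default scenario is deliberately desk-scale: it keeps the
whole chain to about a minute on one CPU while every planted truth
(stage-specific effects, gene-set overlap design, dependence chain,
hypermutation cluster) remains recoverable.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import platform
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import dge, enrichment, genesets, grn, io, metrics, motifprep, mutations, stratify
from .core import NORMAL, GeneSetCollection
from .synthetic import (PlantedEffect, SyntheticScenario, generate_counts,
                        generate_gene_sets, generate_maf, generate_reference,
                        generate_sequences)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one run; defaults are the study's."""

    outdir: str = "daposcope_run"
    seed: int = 0
    stage: str = "SII"
    lfc_threshold: float = dge.LFC_THRESHOLD
    alpha: float = dge.ALPHA
    q_max: float = enrichment.Q_MAX
    es_min: float = enrichment.ES_MIN
    nes_min: float = enrichment.NES_MIN
    top_k: int = enrichment.TOP_K
    n_perm: int = 200
    kataegis_min_mut: int = mutations.KATAEGIS_MIN_MUT
    kataegis_max_mean_imd: float = mutations.KATAEGIS_MAX_MEAN_IMD
    run_nmf: bool = False
    scenario: SyntheticScenario | None = None


def bundled_scenario(seed: int = 0) -> SyntheticScenario:
    """The default synthetic study with planted, recoverable truths.

    24 genes are planted strongly up-regulated in SII and shared by all
    10 gene sets (true overlap summary G=24, P=10, so the planted
    degree of differentiation is 2.4); a 4-gene dependence chain feeds
    the GRN; one 8-mutation cluster at 100 bp spacing feeds the
    kataegis caller; 30% of background mutations carry the tCw C>G
    APOBEC context.
    """
    n_genes = 240
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    planted_de = {g: PlantedEffect(("SII",), "up", 3.0) for g in genes[:24]}
    planted_de.update({g: PlantedEffect(("SII",), "down", 3.0)
                       for g in genes[24:32]})
    chain = [(genes[200 + i], genes[201 + i]) for i in range(3)]
    return SyntheticScenario(
        seed=seed, n_genes=n_genes, n_samples_per_group=10,
        groups=(NORMAL, "SI", "SII"),
        planted_de=planted_de, planted_dag=chain,
        planted_kataegis=[("chr1", 10_000, 8, 100)],
        apobec_fractions={"tCw_CtoG": 0.3},
        background_mutations_per_sample=40, n_maf_samples=10,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; returns (and writes) the run report."""
    out = io.ensure_dir(config.outdir)
    scenario = config.scenario or bundled_scenario(config.seed)
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "scenario_seed": scenario.seed,
        "stages": {},
        "inputs": {},
    }

    # ---- simulate ------------------------------------------------------
    @_stage("simulate")
    def simulate():
        em = generate_counts(scenario)
        # 2 x 500 kb keeps background mutations sparse (mean spacing
        # ~12 kb per sample) so the planted cluster is the only
        # kataegis-dense run
        reference = generate_reference(scenario, n_contigs=2,
                                       contig_length=500_000)
        maf = generate_maf(scenario, reference)
        planted_up = [g for g, e in scenario.planted_de.items()
                      if e.direction == "up"]
        sets = generate_gene_sets(
            scenario, shared_genes=planted_up or None,
            tissue_classes={f"SET_{i:02d}": cls for i, cls in
                            zip(range(1, 11),
                                ["SD"] * 3 + ["SL"] * 2 +
                                ["lung", "immune", "other",
                                 "oesophageal", "SD"])})
        seqs, tss = generate_sequences(scenario)
        io.write_counts(em, f"{out}/counts.tsv", f"{out}/labels.tsv")
        io.write_maf(maf, f"{out}/mutations.maf")
        io.write_gmt(sets, f"{out}/gene_sets.gmt")
        io.write_fasta(seqs, f"{out}/sequences.fasta")
        io.write_tss_table(tss, f"{out}/tss.tsv")
        io.write_fasta(reference, f"{out}/reference.fasta")
        return em, reference, maf, sets, seqs, tss

    em, reference, maf, sets, seqs, tss = simulate()
    for name in ("counts.tsv", "labels.tsv", "mutations.maf",
                 "gene_sets.gmt", "sequences.fasta", "tss.tsv"):
        report["inputs"][name] = _sha256(f"{out}/{name}")

    # ---- differential expression --------------------------------------
    @_stage("dge")
    def run_dge():
        norm = dge.normalize(em)
        de = dge.call_de_all_stages(em, lfc_threshold=config.lfc_threshold,
                                    alpha=config.alpha)
        de.to_csv(f"{out}/de_table.tsv", sep="\t", index=False)
        return norm, de

    norm, de = run_dge()
    report["stages"]["dge"] = {
        "n_tested": int(de["gene"].nunique()),
        "n_deregulated": int((de["direction"] != "none").sum()),
    }

    # ---- partition -----------------------------------------------------
    @_stage("partition")
    def run_partition():
        membership = genesets.membership_from_de(de)
        parts = genesets.partition(membership)
        pd.Series({k: len(v) for k, v in parts.items()}).rename("n_genes") \
            .to_csv(f"{out}/partition_sizes.tsv", sep="\t")
        return membership, parts

    membership, parts = run_partition()
    report["stages"]["partition"] = {k: len(v) for k, v in parts.items()}

    # ---- GSEA ----------------------------------------------------------
    @_stage("gsea")
    def run_gsea():
        ranked = enrichment.rank_genes(
            norm, norm.samples_of(config.stage), norm.samples_of(NORMAL))
        results = enrichment.nes_fdr(ranked, sets, n_perm=config.n_perm,
                                     seed=config.seed)
        retained = enrichment.filter_enrichments(
            results, q_max=config.q_max, es_min=config.es_min,
            nes_min=config.nes_min, top_k=config.top_k)
        summary = enrichment.leading_edge_overlap(retained, module="CS-LEA")
        keep = retained.drop(columns="leading_edge").assign(
            leading_edge=[",".join(le) for le in retained["leading_edge"]])
        keep.to_csv(f"{out}/enrichment.tsv", sep="\t", index=False)
        return ranked, results, retained, summary

    ranked, results, retained, summary = run_gsea()
    dod = metrics.degree_of_differentiation([summary])
    sd_sl = metrics.reprogramming_ratio(retained)
    report["stages"]["gsea"] = {
        "n_retained": int(len(retained)),
        "overlap_genes": summary.n_genes,
        "overlap_terms": summary.n_terms,
        "degree_of_differentiation": dod.average,
        "sd_sl_ratio": sd_sl if math.isfinite(sd_sl) else "inf",
    }

    # ---- GRN -----------------------------------------------------------
    @_stage("grn")
    def run_grn():
        stage_em = norm.subset([config.stage])
        dag_genes = sorted({g for e in scenario.planted_dag for g in e})
        grn_genes = sorted(set(dag_genes)
                           | set(list(scenario.planted_de)[:16]))
        binary = grn.binarize(stage_em.values.loc[grn_genes])
        dag = grn.learn_structure(binary.T, seed=config.seed)
        z = stage_em.values.loc[grn_genes].apply(
            lambda r: (r - r.mean()) / (r.std(ddof=0) or 1.0), axis=1)
        biotypes = {g: ("pseudogene" if g in list(scenario.planted_de)[:8]
                        else "coding") for g in grn_genes}
        net = grn.filter_edges(dag, z, biotypes=biotypes)
        grn.edge_table(net).to_csv(f"{out}/grn_edges.tsv", sep="\t",
                                   index=False)
        topo = grn.topology(net)
        topo_no_pg = grn.topology(net, drop_pseudogenes=True)
        return binary, net, topo, topo_no_pg

    binary, net, topo, topo_no_pg = run_grn()
    report["stages"]["grn"] = {
        "n_nodes": topo.n_nodes, "n_edges": topo.n_edges,
        "density": topo.density,
        "density_without_pseudogenes": topo_no_pg.density,
    }

    # ---- stratify ------------------------------------------------------
    @_stage("stratify")
    def run_stratify():
        stage_em = norm.subset([config.stage])
        up = [g for g, e in scenario.planted_de.items()
              if e.direction == "up" and config.stage in e.stages]
        down = [g for g, e in scenario.planted_de.items()
                if e.direction == "down" and config.stage in e.stages]
        b = grn.binarize(stage_em.values)
        strata = stratify.stratify_samples(b, up, down)
        strata.to_csv(f"{out}/strata.tsv", sep="\t", index=False)
        return strata

    strata = run_stratify()
    report["stages"]["stratify"] = (
        strata["label"].value_counts().to_dict())

    # ---- mutations -----------------------------------------------------
    @_stage("mutations")
    def run_mutations():
        annotated = mutations.annotate_context(maf, reference)
        classes = mutations.substitution_classes(annotated)
        motifs = mutations.apobec_motifs(annotated)
        calls = mutations.kataegis(
            annotated, min_mut=config.kataegis_min_mut,
            max_mean_imd=config.kataegis_max_mean_imd)
        math_by_sample = mutations.math_scores(annotated)
        classes.to_csv(f"{out}/substitution_classes.tsv", sep="\t",
                       index=False)
        motifs.to_csv(f"{out}/apobec_motifs.tsv", sep="\t", index=False)
        pd.DataFrame([{**vars(c)} for c in calls]).to_csv(
            f"{out}/kataegis.tsv", sep="\t", index=False)
        math_by_sample.to_csv(f"{out}/math_scores.tsv", sep="\t")
        result = {"n_kataegis": len(calls),
                  "median_math": float(math_by_sample.median()),
                  "mean_tCw_CtoG": float(motifs["tCw_CtoG"].mean())}
        if config.run_nmf:
            ctx = mutations.context_matrix(annotated)
            nmf = mutations.signature_nmf(ctx, seed=config.seed)
            nmf.signatures.to_csv(f"{out}/signatures.tsv", sep="\t")
            result["chosen_k"] = nmf.chosen_k
        return calls, result

    calls, mut_summary = run_mutations()
    report["stages"]["mutations"] = mut_summary

    # ---- motif prep ----------------------------------------------------
    @_stage("motifprep")
    def run_motifprep():
        windows = []
        for _, row in tss.iterrows():
            windows.append(motifprep.tss_window(
                row["gene"], seqs[row["seqid"]], int(row["tss"])))
        slid = motifprep.sliding_windows("GENE_SHORT", seqs["GENE_SHORT"])
        motifprep.export_fasta(windows, f"{out}/tss_windows.fasta")
        motifprep.export_fasta(slid, f"{out}/sliding_windows.fasta")
        return windows, slid

    windows, slid = run_motifprep()
    report["stages"]["motifprep"] = {
        "n_tss_windows": len(windows), "n_sliding_windows": len(slid)}

    with open(f"{out}/run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def load_config(path: str) -> RunConfig:
    """Read a YAML run configuration (flat keys matching RunConfig)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f: raw[f] for f in raw if f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**known)
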