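"""Readers and writers for the plain-text formats the pipeline consumes.

Counts, annotations, DE tables, MAFs and TSS tables are tab-separated;
gene sets use the standard GMT layout (name TAB description TAB genes...);
sequences use FASTA via Biopython.  All genomic coordinates in TSS tables
are 0-based half-open; MAF positions are 1-based per the format.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ExpressionMatrix, GeneSetCollection

MAF_COLUMNS = [
    "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Type", "Tumor_Sample_Barcode",
    "t_ref_count", "t_alt_count",
]


# ---------------------------------------------------------------- counts

def write_counts(em: ExpressionMatrix, counts_path: str, labels_path: str) -> None:
    em.values.to_csv(counts_path, sep="\t", index_label="gene")
    em.stages.rename("stage").to_csv(labels_path, sep="\t", index_label="sample")


def read_counts(counts_path: str, labels_path: str) -> ExpressionMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)["stage"]
    return ExpressionMatrix(values, labels)


# ------------------------------------------------------------ annotation

def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    out = annotation.copy()
    out["interactors"] = [
        ",".join(v) if isinstance(v, (list, tuple)) else (v or "")
        for v in out.get("interactors", [""] * len(out))
    ]
    out.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    ann["differentiation_flag"] = ann["differentiation_flag"].astype(bool)
    ann["interactors"] = [
        [g for g in str(v).split(",") if g] for v in ann["interactors"]
    ]
    return ann


# ------------------------------------------------------------------- GMT

def write_gmt(collection: GeneSetCollection, path: str) -> None:
    """One set per line; the description column carries ``class=<label>``."""
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = f"class={collection.tissue_class.get(name, 'other')}"
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    classes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, genes = parts[0], parts[1], parts[2:]
            sets[name] = [g for g in genes if g]
            if desc.startswith("class="):
                classes[name] = desc.split("=", 1)[1]
    return GeneSetCollection(sets, classes)


# ------------------------------------------------------------------- MAF

def write_maf(table: pd.DataFrame, path: str) -> None:
    table.loc[:, MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_maf(path: str) -> pd.DataFrame:
    """Read the MAF column subset and derive the VAF from read counts."""
    maf = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MAF_COLUMNS if c not in maf.columns]
    if missing:
        raise ValueError(f"MAF is missing required columns: {missing}")
    depth = maf["t_ref_count"] + maf["t_alt_count"]
    maf["vaf"] = (maf["t_alt_count"] / depth).where(depth > 0)
    return maf


# ----------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ------------------------------------------------------------- TSS table

def write_tss_table(tss: pd.DataFrame, path: str) -> None:
    """Columns: gene, seqid, tss (0-based position on the sequence)."""
    tss.to_csv(path, sep="\t", index=False)


def read_tss_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
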