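"""Seeded generators for every input the pipeline consumes.

Each generator plants a recoverable ground truth: negative-binomial
counts with stage-restricted de-regulation and an optional dependence
DAG, MAF records with planted hypermutation clusters and APOBEC-context
quotas, gene-set collections with a known overlap design, and sequences
whose TSS positions exercise every windowing branch.  A single
:class:`SyntheticScenario` holds all knobs; identical seeds give
byte-identical outputs (one ``numpy.random.default_rng`` stream per
generator call, fixed iteration order).

The count model is the bulk RNA-seq convention: per-gene baseline means
drawn log-normally, gamma-Poisson (negative binomial) sampling with a
common dispersion, planted effects expressed as log2 fold-changes so
they are directly comparable to the DE caller's threshold.  Variant
allele fractions follow a Beta(2, 8) cohort model (median ~0.2, the
dispersion typical of impure tumours).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import NORMAL, STAGES, ExpressionMatrix, GeneSetCollection

#: recognised APOBEC motif-class keys for planted context quotas
APOBEC_CLASSES = ("tCw_CtoT", "tCw_CtoG", "cCw_CtoT", "cCw_CtoG")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PlantedEffect:
    """A gene de-regulated in specific stages with a signed log2 effect."""

    stages: tuple[str, ...]
    direction: str  # "up" or "down"
    log2_effect: float = 2.0


@dataclass
class SyntheticScenario:
    """All knobs for one synthetic study, with planted ground truth."""

    seed: int = 0
    n_genes: int = 200
    n_samples_per_group: int = 10
    groups: tuple[str, ...] = (NORMAL, *STAGES)
    planted_de: dict[str, PlantedEffect] = field(default_factory=dict)
    planted_dag: list[tuple[str, str]] = field(default_factory=list)
    planted_kataegis: list[tuple[str, int, int, int]] = field(default_factory=list)
    planted_signatures: np.ndarray | None = None
    apobec_fractions: dict[str, float] = field(default_factory=dict)
    nb_dispersion: float = 0.15
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    dag_fold: float = 8.0
    vaf_alpha: float = 2.0
    vaf_beta: float = 8.0
    read_depth: int = 100
    background_mutations_per_sample: int = 50
    n_maf_samples: int = 6

    def gene_universe(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_samples_per_group < 3:
            raise ValueError("need at least 3 samples per group")
        universe = set(self.gene_universe())
        for g, eff in self.planted_de.items():
            if g not in universe:
                raise ValueError(f"planted DE gene {g!r} outside gene universe")
            if eff.direction not in ("up", "down"):
                raise ValueError(f"bad direction {eff.direction!r} for {g!r}")
            unknown = set(eff.stages) - set(self.groups)
            if unknown:
                raise ValueError(f"planted stages {unknown} not in groups")
        dag_nodes = {g for e in self.planted_dag for g in e}
        if dag_nodes - universe:
            raise ValueError("planted DAG gene outside gene universe")
        dag = nx.DiGraph(self.planted_dag)
        if self.planted_dag and not nx.is_directed_acyclic_graph(dag):
            raise ValueError("planted_dag contains a cycle")
        total = sum(self.apobec_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError("apobec_fractions sum above 1")
        for cls in self.apobec_fractions:
            if cls not in APOBEC_CLASSES:
                raise ValueError(f"unknown APOBEC motif class {cls!r}")


# ---------------------------------------------------------------- counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Gamma-Poisson sample with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_counts(scenario: SyntheticScenario) -> ExpressionMatrix:
    """Negative-binomial counts with planted effects and DAG dependence.

    Genes in ``planted_de`` have their mean multiplied by ``2**effect``
    (up) or ``2**-effect`` (down) in the listed stages only.  Genes in
    ``planted_dag`` get a latent binary activity state per sample by
    ancestral sampling over the DAG (root: fair coin; child: active with
    probability 0.9 when the majority of parents are active, 0.1
    otherwise); active states multiply the mean by ``dag_fold`` so that
    parent/child pairs stay dependent after median binarization.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    genes = scenario.gene_universe()
    baselines = np.exp(rng.normal(scenario.baseline_log_mean,
                                  scenario.baseline_log_sd,
                                  size=scenario.n_genes))
    base = pd.Series(baselines, index=genes)

    samples: list[str] = []
    stages: list[str] = []
    for grp in scenario.groups:
        for i in range(1, scenario.n_samples_per_group + 1):
            samples.append(f"{grp}_{i:02d}")
            stages.append(grp)
    n_samp = len(samples)

    mean = np.tile(base.to_numpy()[:, None], (1, n_samp)).astype(float)
    gidx = {g: i for i, g in enumerate(genes)}
    for g, eff in scenario.planted_de.items():
        sign = 1.0 if eff.direction == "up" else -1.0
        factor = 2.0 ** (sign * eff.log2_effect)
        cols = [j for j, st in enumerate(stages) if st in eff.stages]
        mean[gidx[g], cols] *= factor

    # latent DAG states, topological order for ancestral sampling
    dag = nx.DiGraph(scenario.planted_dag)
    states: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(dag):
        parents = list(dag.predecessors(node))
        if not parents:
            states[node] = rng.random(n_samp) < 0.5
        else:
            up = np.mean([states[p] for p in parents], axis=0) >= 0.5
            prob = np.where(up, 0.9, 0.1)
            states[node] = rng.random(n_samp) < prob
    for node, state in states.items():
        mean[gidx[node], state] *= scenario.dag_fold

    counts = _nb_draw(rng, mean, scenario.nb_dispersion)
    values = pd.DataFrame(counts, index=genes, columns=samples)
    labels = pd.Series(stages, index=samples, name="stage")
    return ExpressionMatrix(values, labels)


# ------------------------------------------------------------- reference

def generate_reference(scenario: SyntheticScenario, n_contigs: int = 2,
                       contig_length: int = 100_000) -> dict[str, str]:
    """Toy reference genome: uniform-base contigs, seeded."""
    rng = np.random.default_rng(scenario.seed + 1)
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(bases[rng.integers(0, 4, contig_length)])
        for i in range(n_contigs)
    }


# ------------------------------------------------------------------- MAF

def _motif_sites(seq: str, cls: str) -> np.ndarray:
    """1-based positions of the mutable C of a motif class on the ref strand."""
    five = "T" if cls.startswith("tCw") else "C"
    hits = [
        i + 1
        for i in range(1, len(seq) - 1)
        if seq[i] == "C" and seq[i - 1] == five and seq[i + 1] in "AT"
    ]
    return np.asarray(hits, dtype=np.int64)


def _transition(base: str) -> str:
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]


def generate_maf(scenario: SyntheticScenario,
                 reference: dict[str, str]) -> pd.DataFrame:
    """MAF records with planted clusters and APOBEC-context quotas.

    Per tumour sample, ``background_mutations_per_sample`` substitutions
    are placed: the ``apobec_fractions`` quota of them at reference-strand
    motif sites with the class's substitution, the rest uniform over the
    genome.  Planted hypermutation clusters (``chrom, start, n_mut,
    spacing``) are laid down as consecutive equally spaced substitutions
    and assigned to samples round-robin.  VAFs are Beta(alpha, beta)
    draws converted to read counts at ``read_depth``.
    """
    scenario.validate()
    for chrom, start, n_mut, spacing in scenario.planted_kataegis:
        if chrom not in reference:
            raise ValueError(f"planted cluster chrom {chrom!r} not in reference")
        end = start + (n_mut - 1) * spacing
        if start < 2 or end > len(reference[chrom]) - 1:
            raise ValueError("planted cluster outside reference bounds")

    rng = np.random.default_rng(scenario.seed + 2)
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    site_cache = {
        cls: {c: _motif_sites(reference[c], cls) for c in chroms}
        for cls in scenario.apobec_fractions
    }
    samples = [f"T{i:02d}" for i in range(1, scenario.n_maf_samples + 1)]

    rows: list[dict] = []

    def add_record(sample: str, chrom: str, pos: int, ref: str, alt: str) -> None:
        vaf = rng.beta(scenario.vaf_alpha, scenario.vaf_beta)
        alt_reads = int(round(vaf * scenario.read_depth))
        alt_reads = min(max(alt_reads, 1), scenario.read_depth - 1)
        rows.append({
            "Hugo_Symbol": "Unknown", "Chromosome": chrom,
            "Start_Position": pos, "Reference_Allele": ref,
            "Tumor_Seq_Allele2": alt, "Variant_Type": "SNP",
            "Tumor_Sample_Barcode": sample,
            "t_ref_count": scenario.read_depth - alt_reads,
            "t_alt_count": alt_reads,
        })

    for sample in samples:
        n_bg = scenario.background_mutations_per_sample
        quotas = {cls: int(round(f * n_bg))
                  for cls, f in scenario.apobec_fractions.items()}
        n_uniform = n_bg - sum(quotas.values())
        for cls, n_cls in quotas.items():
            alt = "T" if cls.endswith("CtoT") else "G"
            for _ in range(n_cls):
                chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
                sites = site_cache[cls][chrom]
                pos = int(sites[rng.integers(0, len(sites))])
                add_record(sample, chrom, pos, "C", alt)
        for _ in range(max(n_uniform, 0)):
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            pos = int(rng.integers(2, len(reference[chrom])))
            ref = reference[chrom][pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            add_record(sample, chrom, pos, ref, str(alt))

    for k, (chrom, start, n_mut, spacing) in enumerate(scenario.planted_kataegis):
        sample = samples[k % len(samples)]
        for j in range(n_mut):
            pos = start + j * spacing
            ref = reference[chrom][pos - 1]
            add_record(sample, chrom, pos, ref, _transition(ref))

    maf = pd.DataFrame(rows, columns=[
        "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
        "Tumor_Seq_Allele2", "Variant_Type", "Tumor_Sample_Barcode",
        "t_ref_count", "t_alt_count",
    ])
    depth = maf["t_ref_count"] + maf["t_alt_count"]
    maf["vaf"] = (maf["t_alt_count"] / depth).where(depth > 0)
    return maf


# ------------------------------------------------------------- gene sets

def generate_gene_sets(scenario: SyntheticScenario, n_sets: int = 10,
                       n_shared: int = 24, shared_in: int | None = None,
                       n_unique: int = 10,
                       shared_genes: list[str] | None = None,
                       tissue_classes: dict[str, str] | None = None,
                       ) -> GeneSetCollection:
    """Gene sets with a planted overlap design.

    ``n_shared`` genes are members of ``shared_in`` sets (all sets by
    default); each set additionally gets ``n_unique`` private genes, so
    the true overlap summary is (G=n_shared, P=shared_in) when
    ``shared_in >= 2`` and (0, 0) otherwise, known by construction.
    ``shared_genes`` pins the shared block to specific genes (e.g. the
    planted de-regulated ones) instead of a random draw.
    """
    rng = np.random.default_rng(scenario.seed + 3)
    universe = scenario.gene_universe()
    shared_in = n_sets if shared_in is None else shared_in
    if shared_in > n_sets:
        raise ValueError("shared_in exceeds the number of sets")
    if shared_genes is not None:
        unknown = set(shared_genes) - set(universe)
        if unknown:
            raise ValueError(f"shared genes outside universe: {sorted(unknown)}")
        n_shared = len(shared_genes)
    need = n_shared + n_sets * n_unique
    if need > len(universe):
        raise ValueError("gene universe too small for the requested design")
    if shared_genes is None:
        picked = rng.choice(len(universe), size=need, replace=False)
        pool = [universe[i] for i in picked]
        shared, rest = pool[:n_shared], pool[n_shared:]
    else:
        shared = list(shared_genes)
        remaining = [g for g in universe if g not in set(shared)]
        picked = rng.choice(len(remaining), size=n_sets * n_unique,
                            replace=False)
        rest = [remaining[i] for i in picked]

    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        name = f"SET_{i + 1:02d}"
        members = list(rest[i * n_unique:(i + 1) * n_unique])
        if i < shared_in:
            members = list(shared) + members
        sets[name] = members
    return GeneSetCollection(sets, dict(tissue_classes or {}))


# ------------------------------------------------------------- sequences

def generate_sequences(scenario: SyntheticScenario, flank: int = 2000,
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Gene sequences plus a TSS table covering every windowing branch.

    Four anchored cases: TSS interior (both flanks fit), TSS at the
    sequence start, TSS at the sequence end, and a sequence shorter than
    the full window.
    """
    rng = np.random.default_rng(scenario.seed + 4)
    bases = np.array(list("ACGT"))

    def seq(n: int) -> str:
        return "".join(bases[rng.integers(0, 4, n)])

    window = 2 * flank + 1
    specs = [
        ("GENE_INTERIOR", 5 * window, 2 * window),
        ("GENE_START", 3 * window, 0),
        ("GENE_END", 3 * window, 3 * window - 1),
        ("GENE_SHORT", window // 3, window // 6),
    ]
    sequences = {name: seq(length) for name, length, _ in specs}
    tss = pd.DataFrame(
        [(name, name, pos) for name, _, pos in specs],
        columns=["gene", "seqid", "tss"],
    )
    return sequences, tss
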