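"""MAF-based mutational-landscape analytics.

Single-base substitutions are strand-normalized to the pyrimidine
convention (purine-reference records become their reverse complement,
context included) before classification into the six classes C>A, C>G,
C>T, T>A, T>C, T>G.  On top of that sit the APOBEC deamination motif
fractions (tCw for A3A/A3B, cCw for A3G, with w = A or T), rainfall
inter-mutation distances with kataegis calling (>= 6 consecutive
substitutions with mean spacing <= 1 kb, the rainfall-tool convention),
the MATH tumour-heterogeneity score (100 x scaled MAD of the VAFs over
their median) and NMF mutational-signature extraction over the 96
trinucleotide contexts with cophenetic-correlation model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = {"C>T", "T>C"}
KATAEGIS_MIN_MUT = 6
KATAEGIS_MAX_MEAN_IMD = 1000.0
MAD_SCALE = 1.4826  # consistency factor making the MAD match sigma for normals

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: the 96 pyrimidine-context channels, in lexicographic order
CONTEXTS_96 = [
    f"{five}[{ref}>{alt}]{three}"
    for ref, alts in (("C", "AGT"), ("T", "ACG"))
    for alt in alts
    for five in "ACGT"
    for three in "ACGT"
]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ----------------------------------------------------- context handling

def annotate_context(maf: pd.DataFrame,
                     reference: dict[str, str]) -> pd.DataFrame:
    """Attach the 5'-X[ref]Y-3' reference-strand trinucleotide context.

    Positions are 1-based; records at contig edges (no flank available)
    are dropped with a warning, as are records whose reference allele
    disagrees with the sequence.
    """
    out = maf.copy()
    contexts, keep = [], []
    for chrom, pos, ref in zip(out["Chromosome"], out["Start_Position"],
                               out["Reference_Allele"]):
        seq = reference.get(str(chrom))
        if seq is None or pos < 2 or pos > len(seq) - 1:
            keep.append(False)
            contexts.append("")
            continue
        tri = seq[pos - 2:pos + 1]
        keep.append(tri[1] == ref)
        contexts.append(tri)
    dropped = len(keep) - sum(keep)
    if dropped:
        warnings.warn(f"dropped {dropped} record(s) at contig edges or with "
                      "mismatching reference allele", stacklevel=2)
    out["context"] = contexts
    return out[np.asarray(keep)].reset_index(drop=True)


def normalize_pyrimidine(maf: pd.DataFrame) -> pd.DataFrame:
    """Map purine-reference SNVs onto the pyrimidine strand.

    G>A with context TGA becomes C>T with context TCA, etc.  Records
    already on the pyrimidine strand are untouched, so the map is
    idempotent.  Non-SNV records are excluded.
    """
    snv = maf[
        maf["Reference_Allele"].isin(list("ACGT"))
        & maf["Tumor_Seq_Allele2"].isin(list("ACGT"))
        & (maf["Reference_Allele"] != maf["Tumor_Seq_Allele2"])
    ].copy()
    purine = snv["Reference_Allele"].isin(["A", "G"])
    snv.loc[purine, "Reference_Allele"] = [
        b.translate(_COMPLEMENT) for b in snv.loc[purine, "Reference_Allele"]]
    snv.loc[purine, "Tumor_Seq_Allele2"] = [
        b.translate(_COMPLEMENT) for b in snv.loc[purine, "Tumor_Seq_Allele2"]]
    if "context" in snv.columns:
        snv.loc[purine, "context"] = [
            _revcomp(c) if c else c for c in snv.loc[purine, "context"]]
    snv["sub_class"] = snv["Reference_Allele"] + ">" + snv["Tumor_Seq_Allele2"]
    return snv.reset_index(drop=True)


# --------------------------------------------------- substitution classes

def substitution_classes(maf: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractions of the six substitution classes plus Ti/Tv.

    Fractions sum to 1 per sample; the Ti/Tv ratio is +inf when a sample
    has transitions but no transversions.
    """
    snv = normalize_pyrimidine(maf)
    rows = []
    for sample, grp in snv.groupby("Tumor_Sample_Barcode", sort=True):
        counts = grp["sub_class"].value_counts()
        total = counts.sum()
        frac = {cls: counts.get(cls, 0) / total for cls in SUB_CLASSES}
        ti = sum(counts.get(c, 0) for c in TRANSITIONS & set(SUB_CLASSES))
        tv = total - ti
        rows.append({"sample": sample, **frac, "n_snv": int(total),
                     "ti": int(ti), "tv": int(tv),
                     "ti_tv": ti / tv if tv else (np.inf if ti else np.nan)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------- APOBEC motifs

def apobec_motifs(maf: pd.DataFrame) -> pd.DataFrame:
    """Per-sample tCw / cCw motif fractions split by alteration type.

    Applied after pyrimidine normalization; w is A or T.  Fractions are
    relative to all SNVs of the sample, reported for the two
    APOBEC-relevant alterations C>T (transition) and C>G (transversion).
    """
    snv = normalize_pyrimidine(maf)
    if "context" not in snv.columns or (snv["context"] == "").any():
        raise ValueError("records need trinucleotide contexts; run "
                         "annotate_context first")
    ctx = snv["context"].str.upper()
    five, three = ctx.str[0], ctx.str[2]
    w = three.isin(["A", "T"])
    tcw = (five == "T") & w
    ccw = (five == "C") & w
    rows = []
    for sample, idx in snv.groupby("Tumor_Sample_Barcode", sort=True).groups.items():
        sub = snv.loc[idx, "sub_class"]
        n = len(idx)
        rows.append({
            "sample": sample, "n_snv": n,
            "tCw_CtoT": float(((sub == "C>T") & tcw.loc[idx]).sum() / n),
            "tCw_CtoG": float(((sub == "C>G") & tcw.loc[idx]).sum() / n),
            "cCw_CtoT": float(((sub == "C>T") & ccw.loc[idx]).sum() / n),
            "cCw_CtoG": float(((sub == "C>G") & ccw.loc[idx]).sum() / n),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------ rainfall/kataegis

@dataclass
class KataegisCall:
    """A maximal hypermutation run satisfying both thresholds."""

    sample: str
    chrom: str
    start: int
    end: int
    n_mutations: int
    mean_imd: float
    classes: dict[str, int] = field(default_factory=dict)


def _scan_positions(positions: np.ndarray, min_mut: int,
                    max_mean_imd: float) -> list[tuple[int, int]]:
    """Maximal non-overlapping index runs with mean spacing below cut-off."""
    runs: list[tuple[int, int]] = []
    i, m = 0, len(positions)
    while i <= m - min_mut:
        best_j = -1
        for j in range(i + min_mut - 1, m):
            mean_imd = (positions[j] - positions[i]) / (j - i)
            if mean_imd <= max_mean_imd:
                best_j = j
        if best_j >= 0:
            runs.append((i, best_j))
            i = best_j + 1
        else:
            i += 1
    return runs


def kataegis(maf: pd.DataFrame, min_mut: int = KATAEGIS_MIN_MUT,
             max_mean_imd: float = KATAEGIS_MAX_MEAN_IMD,
             ) -> list[KataegisCall]:
    """Call kataegis events per sample and chromosome."""
    snv = normalize_pyrimidine(maf)
    calls: list[KataegisCall] = []
    for (sample, chrom), grp in snv.groupby(
            ["Tumor_Sample_Barcode", "Chromosome"], sort=True):
        grp = grp.sort_values("Start_Position")
        pos = grp["Start_Position"].to_numpy(dtype=np.int64)
        for i, j in _scan_positions(pos, min_mut, max_mean_imd):
            classes = (grp["sub_class"].iloc[i:j + 1]
                       .value_counts().to_dict())
            calls.append(KataegisCall(
                sample=str(sample), chrom=str(chrom),
                start=int(pos[i]), end=int(pos[j]), n_mutations=j - i + 1,
                mean_imd=float((pos[j] - pos[i]) / (j - i)),
                classes=classes))
    return calls


def rainfall(maf: pd.DataFrame, sample: str) -> pd.DataFrame:
    """Ordered inter-mutation distances for one sample (rainfall series)."""
    snv = normalize_pyrimidine(maf)
    snv = snv[snv["Tumor_Sample_Barcode"] == sample]
    if snv.empty:
        raise KeyError(f"no SNVs for sample {sample!r}")
    frames = []
    for chrom, grp in snv.groupby("Chromosome", sort=True):
        grp = grp.sort_values("Start_Position").reset_index(drop=True)
        imd = grp["Start_Position"].diff()
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": grp["Start_Position"], "imd": imd,
            "sub_class": grp["sub_class"]}))
    return pd.concat(frames, ignore_index=True)


def expression_split_kataegis(maf: pd.DataFrame, expression: pd.Series,
                              **kwargs) -> dict[str, object]:
    """Kataegis per above/below-median expression cohorts of one gene.

    Samples with expression strictly above the median are the positive
    cohort, the rest negative; the two cohorts partition the samples.
    """
    med = expression.median()
    positive = set(expression.index[expression > med])
    negative = set(expression.index) - positive
    pos_maf = maf[maf["Tumor_Sample_Barcode"].isin(positive)]
    neg_maf = maf[maf["Tumor_Sample_Barcode"].isin(negative)]
    return {
        "positive_samples": sorted(positive),
        "negative_samples": sorted(negative),
        "positive": kataegis(pos_maf, **kwargs) if len(pos_maf) else [],
        "negative": kataegis(neg_maf, **kwargs) if len(neg_maf) else [],
    }


# ------------------------------------------------------------- MATH score

def math_score(vafs: np.ndarray | pd.Series) -> float:
    """Mutant-Allele Tumour Heterogeneity score of one sample's VAFs.

    100 x (1.4826 x median(|vaf - median|)) / median(vaf).  Scale
    invariant; higher values indicate more clonal heterogeneity.
    """
    v = np.asarray(vafs, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    med = np.median(v)
    if med == 0:
        return float("nan")
    mad = MAD_SCALE * np.median(np.abs(v - med))
    return float(100.0 * mad / med)


def math_scores(maf: pd.DataFrame) -> pd.Series:
    """Per-sample MATH scores from the MAF ``vaf`` column."""
    return (maf.groupby("Tumor_Sample_Barcode")["vaf"]
            .apply(math_score).rename("math"))


# --------------------------------------------------------- NMF signatures

def context_matrix(maf: pd.DataFrame) -> pd.DataFrame:
    """96-context x sample count matrix from annotated, normalized records."""
    snv = normalize_pyrimidine(maf)
    channel = (snv["context"].str[0] + "[" + snv["sub_class"] + "]"
               + snv["context"].str[2])
    table = (pd.crosstab(channel, snv["Tumor_Sample_Barcode"])
             .reindex(CONTEXTS_96, fill_value=0))
    return table


@dataclass
class SignatureResult:
    """NMF decomposition per rank with cophenetic model selection."""

    cophenetic: dict[int, float]
    chosen_k: int
    signatures: pd.DataFrame  # contexts x chosen_k, column-normalized
    exposures: pd.DataFrame  # chosen_k x samples
    reconstruction_error: dict[int, float]


def _consensus_cophenetic(assignments: list[np.ndarray]) -> float:
    n = len(assignments[0])
    if n < 3:
        return 1.0
    consensus = np.zeros((n, n))
    for a in assignments:
        consensus += (a[:, None] == a[None, :])
    consensus /= len(assignments)
    dist = 1.0 - consensus
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        return 1.0
    z = linkage(condensed, method="average")
    c, _ = cophenet(z, condensed)
    return float(c) if np.isfinite(c) else 1.0


def _select_rank(ks: list[int], coph: dict[int, float],
                 tol: float = 1e-3) -> int:
    """Rank at which the cophenetic curve begins to fall.

    The consensus is perfectly stable (coefficient ~1) for every rank
    up to the true one and degrades beyond it, so the chosen rank is
    the last one before the first material drop (> ``tol``).  A curve
    that never drops yields the largest rank attaining its maximum.
    """
    if len(ks) == 1:
        return ks[0]
    drops = [coph[ks[i]] - coph[ks[i + 1]] for i in range(len(ks) - 1)]
    for i, d in enumerate(drops):
        if d > tol:
            return ks[i]
    best = max(coph[k] for k in ks)
    return max(k for k in ks if coph[k] >= best - tol)


def signature_nmf(counts: pd.DataFrame, k_range: tuple[int, ...] = (1, 2, 3, 4),
                  n_restarts: int = 20, seed: int = 0,
                  reference: pd.DataFrame | None = None) -> SignatureResult:
    """Extract mutational signatures by seeded multi-restart NMF.

    For each rank the consensus over restarts (samples clustered by
    dominant signature) yields a cophenetic correlation; the chosen rank
    precedes the first significant drop of that curve (see
    :func:`_select_rank`).  Signatures of
    the chosen rank come from the restart with the lowest Frobenius
    reconstruction error; columns are normalized to probability vectors.
    ``reference`` (contexts x catalogue signatures) triggers cosine
    best-matching, reported in ``signatures.attrs['matches']``.
    """
    x = counts.to_numpy(dtype=float)
    ks = sorted(k_range)
    coph: dict[int, float] = {}
    best_models: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    rng = np.random.default_rng(seed)
    for k in ks:
        assignments, best = [], None
        for _ in range(n_restarts):
            model = NMF(n_components=k, init="random", solver="mu",
                        beta_loss="frobenius", max_iter=600,
                        random_state=int(rng.integers(0, 2**31 - 1)))
            w = model.fit_transform(x)
            h = model.components_
            err = model.reconstruction_err_
            assignments.append(np.argmax(h, axis=0))
            if best is None or err < best[0]:
                best = (err, w, h)
        coph[k] = _consensus_cophenetic(assignments)
        best_models[k] = best
    chosen = _select_rank(ks, coph)
    err, w, h = best_models[chosen]
    col_sums = w.sum(axis=0, keepdims=True)
    col_sums[col_sums == 0] = 1.0
    sig_names = [f"S{i + 1}" for i in range(chosen)]
    signatures = pd.DataFrame(w / col_sums, index=counts.index,
                              columns=sig_names)
    exposures = pd.DataFrame(h * col_sums.T, index=sig_names,
                             columns=counts.columns)
    if reference is not None:
        signatures.attrs["matches"] = match_signatures(signatures, reference)
    return SignatureResult(
        cophenetic=coph, chosen_k=chosen, signatures=signatures,
        exposures=exposures,
        reconstruction_error={k: v[0] for k, v in best_models.items()})


def match_signatures(signatures: pd.DataFrame,
                     reference: pd.DataFrame) -> dict[str, tuple[str, float]]:
    """Best cosine match of each extracted signature in a catalogue."""
    ref = reference.reindex(signatures.index).fillna(0.0)
    matches = {}
    for name in signatures.columns:
        s = signatures[name].to_numpy()
        best_name, best_cos = None, -1.0
        for rname in ref.columns:
            r = ref[rname].to_numpy()
            denom = np.linalg.norm(s) * np.linalg.norm(r)
            cos = float(s @ r / denom) if denom else 0.0
            if cos > best_cos:
                best_name, best_cos = rname, cos
        matches[name] = (best_name, best_cos)
    return matches
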