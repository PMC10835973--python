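"""Substitution classes, APOBEC motifs, kataegis, MATH and NMF signatures."""

import numpy as np
import pandas as pd
import pytest

from daposcope import mutations as mut


def maf_rows(rows):
    """Build a MAF-like frame from (sample, chrom, pos, ref, alt, ctx)."""
    df = pd.DataFrame(rows, columns=["Tumor_Sample_Barcode", "Chromosome",
                                     "Start_Position", "Reference_Allele",
                                     "Tumor_Seq_Allele2", "context"])
    df["t_ref_count"] = 80
    df["t_alt_count"] = 20
    df["vaf"] = 0.2
    return df


class TestStrandNormalization:
    def test_purine_record_reverse_complemented(self):
        maf = maf_rows([("s", "1", 100, "G", "A", "TGA")])
        out = mut.normalize_pyrimidine(maf)
        assert out["sub_class"].iloc[0] == "C>T"
        assert out["context"].iloc[0] == "TCA"

    def test_idempotent(self):
        maf = maf_rows([("s", "1", 100, "G", "A", "TGA"),
                        ("s", "1", 200, "C", "G", "TCA")])
        once = mut.normalize_pyrimidine(maf)
        twice = mut.normalize_pyrimidine(once.drop(columns="sub_class"))
        pd.testing.assert_series_equal(once["sub_class"], twice["sub_class"])
        pd.testing.assert_series_equal(once["context"], twice["context"])

    def test_non_snv_records_excluded(self):
        maf = maf_rows([("s", "1", 100, "C", "C", "TCA"),
                        ("s", "1", 200, "-", "T", ""),
                        ("s", "1", 300, "C", "T", "ACT")])
        assert len(mut.normalize_pyrimidine(maf)) == 1


class TestSubstitutionClasses:
    def test_fractions_sum_to_one(self, rng):
        rows = []
        bases = "ACGT"
        for i in range(300):
            ref = bases[rng.integers(4)]
            alt = [b for b in bases if b != ref][rng.integers(3)]
            rows.append((f"s{i % 3}", "1", 100 + i, ref, alt, ""))
        out = mut.substitution_classes(maf_rows(rows))
        sums = out[list(mut.SUB_CLASSES)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_uniform_classes_near_sixth(self, rng):
        rows = []
        classes = [("C", "A"), ("C", "G"), ("C", "T"),
                   ("T", "A"), ("T", "C"), ("T", "G")]
        for i in range(6000):
            ref, alt = classes[int(rng.integers(6))]
            rows.append(("s", "1", i + 1, ref, alt, ""))
        out = mut.substitution_classes(maf_rows(rows))
        for cls in mut.SUB_CLASSES:
            assert out[cls].iloc[0] == pytest.approx(1 / 6, abs=0.02)

    def test_transitions_only_gives_zero_tv(self):
        rows = [("s", "1", 100, "C", "T", ""), ("s", "1", 200, "T", "C", "")]
        out = mut.substitution_classes(maf_rows(rows))
        assert out["tv"].iloc[0] == 0
        assert np.isinf(out["ti_tv"].iloc[0])


class TestApobecMotifs:
    def test_favoured_motifs_counted(self):
        rows = [("s", "1", 100, "C", "G", "TCA"),   # tCw C>G
                ("s", "1", 200, "C", "T", "CCT"),   # cCw C>T
                ("s", "1", 300, "C", "T", "GCT")]   # gCw: neither
        out = mut.apobec_motifs(maf_rows(rows))
        assert out["tCw_CtoG"].iloc[0] == pytest.approx(1 / 3)
        assert out["cCw_CtoT"].iloc[0] == pytest.approx(1 / 3)
        assert out["tCw_CtoT"].iloc[0] == 0.0
        assert out["cCw_CtoG"].iloc[0] == 0.0

    def test_purine_records_normalized_before_test(self):
        # G>C at context TGA is C>G at TCA on the pyrimidine strand
        out = mut.apobec_motifs(maf_rows([("s", "1", 100, "G", "C", "TGA")]))
        assert out["tCw_CtoG"].iloc[0] == 1.0

    def test_missing_context_rejected(self):
        with pytest.raises(ValueError, match="context"):
            mut.apobec_motifs(maf_rows([("s", "1", 100, "C", "T", "")]))


class TestKataegis:
    def cluster(self, n, spacing, start=1000, sample="s", chrom="1"):
        return [(sample, chrom, start + i * spacing, "C", "T", "TCA")
                for i in range(n)]

    def test_six_mutations_one_call(self):
        calls = mut.kataegis(maf_rows(self.cluster(6, 100)))
        assert len(calls) == 1
        assert calls[0].n_mutations == 6
        assert calls[0].mean_imd == pytest.approx(100.0)

    def test_five_mutations_no_call(self):
        assert mut.kataegis(maf_rows(self.cluster(5, 100))) == []

    def test_wide_spacing_no_call(self):
        assert mut.kataegis(maf_rows(self.cluster(10, 2000))) == []

    def test_calls_disjoint_and_within_thresholds(self, rng):
        rows = (self.cluster(8, 50, start=1_000)
                + self.cluster(6, 200, start=50_000)
                + [("s", "1", int(p), "C", "T", "TCA")
                   for p in rng.integers(100_000, 5_000_000, size=100)])
        calls = mut.kataegis(maf_rows(rows))
        intervals = sorted((c.start, c.end) for c in calls)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 < s2
        for c in calls:
            assert c.n_mutations >= 6 and c.mean_imd <= 1000.0

    def test_sparse_random_mutations_never_called(self):
        """Poisson spacing argument: ~30 mutations over 10 Mb essentially
        never produce 6 within a 5 kb span; simulate 100 seeds."""
        false_calls = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pos = np.sort(rng.integers(1, 10_000_000, size=30))
            rows = [("s", "1", int(p), "C", "T", "TCA") for p in pos]
            false_calls += len(mut.kataegis(maf_rows(rows)))
        assert false_calls == 0

    def test_expression_split_planted_cohort(self):
        rows = self.cluster(8, 100, sample="pos1") + [
            ("neg1", "1", 10_000_000, "C", "T", "TCA")]
        expr = pd.Series({"pos1": 10.0, "neg1": 1.0, "neg2": 2.0})
        out = mut.expression_split_kataegis(maf_rows(rows), expr)
        assert len(out["positive"]) == 1
        assert out["negative"] == []
        joined = set(out["positive_samples"]) | set(out["negative_samples"])
        assert joined == set(expr.index)
        assert not set(out["positive_samples"]) & set(out["negative_samples"])


class TestMathScore:
    def test_equal_vafs_zero(self):
        assert mut.math_score([0.3] * 5) == 0.0

    def test_hand_computed_example(self):
        # median 0.3, MAD 0.1 -> 100 * 1.4826 * 0.1 / 0.3
        got = mut.math_score([0.1, 0.2, 0.3, 0.4, 0.5])
        assert got == pytest.approx(100 * 1.4826 * 0.1 / 0.3, abs=1e-9)
        assert got == pytest.approx(49.42, abs=0.001)

    def test_scale_and_order_invariance(self, rng):
        v = rng.beta(2, 8, size=51)
        base = mut.math_score(v)
        assert mut.math_score(v * 0.37) == pytest.approx(base, abs=1e-9)
        assert mut.math_score(v[::-1]) == pytest.approx(base, abs=1e-9)

    def test_empty_gives_nan(self):
        assert np.isnan(mut.math_score([]))


class TestRainfall:
    def test_imd_series_manual(self):
        rows = [("s", "1", p, "C", "T", "TCA") for p in (100, 250, 1000)]
        out = mut.rainfall(maf_rows(rows), "s")
        assert out["imd"].tolist()[1:] == [150, 750]
        assert np.isnan(out["imd"].iloc[0])

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            mut.rainfall(maf_rows([("s", "1", 1, "C", "T", "TCA")]), "zz")


def planted_signature_matrix(rng, n_samples=30, total=400):
    """Two sharply distinct 96-channel signatures mixed per sample."""
    sig = np.zeros((96, 2))
    sig[:20, 0] = rng.random(20) + 0.5
    sig[60:90, 1] = rng.random(30) + 0.5
    sig /= sig.sum(axis=0)
    weights = np.zeros((2, n_samples))
    half = n_samples // 2
    weights[0, :half] = rng.uniform(0.8, 1.0, half)
    weights[1, :half] = 1 - weights[0, :half]
    weights[1, half:] = rng.uniform(0.8, 1.0, n_samples - half)
    weights[0, half:] = 1 - weights[1, half:]
    expected = sig @ weights * total
    counts = rng.poisson(expected)
    return sig, pd.DataFrame(counts, index=mut.CONTEXTS_96,
                             columns=[f"s{i}" for i in range(n_samples)])


class TestSignatureNmf:
    def test_rank_one_cophenetic_unity(self, rng):
        sig = rng.random(96)
        counts = pd.DataFrame(np.outer(sig, rng.uniform(50, 150, 10)),
                              index=mut.CONTEXTS_96,
                              columns=[f"s{i}" for i in range(10)])
        res = mut.signature_nmf(counts, k_range=(1,), n_restarts=5, seed=0)
        assert res.cophenetic[1] == 1.0
        assert res.chosen_k == 1

    def test_reconstruction_error_non_increasing(self, rng):
        _, counts = planted_signature_matrix(rng)
        res = mut.signature_nmf(counts, k_range=(1, 2, 3), n_restarts=5,
                                seed=0)
        errs = [res.reconstruction_error[k] for k in (1, 2, 3)]
        assert errs[0] >= errs[1] >= errs[2] - 1e-6

    def test_planted_two_signatures_recovered(self, rng):
        sig, counts = planted_signature_matrix(rng)
        res = mut.signature_nmf(counts, k_range=(1, 2, 3, 4), n_restarts=10,
                                seed=1)
        assert res.chosen_k == 2
        ref = pd.DataFrame(sig, index=mut.CONTEXTS_96,
                           columns=["true1", "true2"])
        matches = mut.match_signatures(res.signatures, ref)
        cosines = sorted(c for _, c in matches.values())
        assert cosines[0] >= 0.95
        assert {m for m, _ in matches.values()} == {"true1", "true2"}

    def test_context_matrix_counts(self):
        rows = [("s1", "1", 100, "C", "T", "ACA"),
                ("s1", "1", 200, "C", "T", "ACA"),
                ("s2", "1", 300, "G", "A", "TGT")]  # revcomp -> ACA C>T
        ctx = mut.context_matrix(maf_rows(rows))
        assert ctx.loc["A[C>T]A", "s1"] == 2
        assert ctx.loc["A[C>T]A", "s2"] == 1
        assert ctx.to_numpy().sum() == 3


class TestAnnotateContext:
    def test_context_extracted_and_edges_dropped(self):
        ref = {"1": "ATCGA"}
        maf = maf_rows([("s", "1", 3, "C", "T", ""),
                        ("s", "1", 1, "A", "T", ""),  # contig edge
                        ("s", "1", 4, "G", "A", "")]).drop(columns="context")
        with pytest.warns(UserWarning, match="dropped"):
            out = mut.annotate_context(maf, ref)
        assert out["context"].tolist() == ["TCG", "CGA"]

    def test_reference_mismatch_dropped(self):
        ref = {"1": "ATCGA"}
        maf = maf_rows([("s", "1", 3, "G", "T", "")]).drop(columns="context")
        with pytest.warns(UserWarning):
            assert mut.annotate_context(maf, ref).empty
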