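import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import xiscape as x
from xiscape import snp6_ase
from xiscape.thresholds import Thresholds

from conftest import make_calls


def records_df(rows):
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "genotype",
                                     "channel_a", "channel_b"])
    df["seg_major_cn"] = np.nan
    df["seg_minor_cn"] = np.nan
    return df


class TestLoadSnpTable:
    def test_sorts_by_coordinate(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("snp_id\tchrom\tpos\tgenotype\tchannel_a\tchannel_b\n"
                     "s3\tchr2\t300\tAB\t1\t2\n"
                     "s1\tchr2\t100\tAA\t3\t4\n"
                     "s2\tchr2\t200\tAB\t5\t6\n")
        df = snp6_ase.load_snp_table(p)
        assert list(df.snp_id) == ["s1", "s2", "s3"]

    def test_shuffled_file_same_output(self, tmp_path):
        header = "snp_id\tchrom\tpos\tgenotype\tchannel_a\tchannel_b\n"
        rows = [f"s{i}\tchrX\t{i * 10}\tAB\t{i}\t{i * 2}\n"
                for i in range(1, 8)]
        (tmp_path / "a.tsv").write_text(header + "".join(rows))
        (tmp_path / "b.tsv").write_text(header + "".join(rows[::-1]))
        pd.testing.assert_frame_equal(
            snp6_ase.load_snp_table(tmp_path / "a.tsv"),
            snp6_ase.load_snp_table(tmp_path / "b.tsv"))

    def test_bad_intensity_names_row(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("snp_id\tchrom\tpos\tgenotype\tchannel_a\tchannel_b\n"
                     "s1\tchr2\t100\tAB\t1\t2\n"
                     "s2\tchr2\t200\tAB\tx\t2\n")
        with pytest.raises(ValueError, match=r"channel_a.*\[2\]"):
            snp6_ase.load_snp_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("snp_id\tchrom\tpos\tgenotype\tchannel_a\n"
                     "s1\tchr2\t100\tAB\t1\n")
        with pytest.raises(ValueError, match="channel_b"):
            snp6_ase.load_snp_table(p)


class TestScoreExpression:
    def test_uniform_all_expressed(self):
        df = records_df([(f"s{i}", "chrX", i + 1, "AB", 10, 10)
                         for i in range(6)])
        assert snp6_ase.score_expression(df).all()

    def test_bimodal_flags_high_mode(self):
        rows = [(f"lo{i}", "chrX", i + 1, "AB", 5, 5) for i in range(10)]
        rows += [(f"hi{i}", "chrX", 100 + i, "AB", 50, 50)
                 for i in range(10)]
        df = records_df(rows)
        expressed = snp6_ase.score_expression(df)
        # oracle: direct quantile of the totals
        totals = df.channel_a + df.channel_b
        cutoff = np.quantile(totals, 0.5)
        np.testing.assert_array_equal(expressed.values,
                                      (totals >= cutoff).values)
        assert expressed[df.snp_id.str.startswith("hi")].all()
        assert not expressed[df.snp_id.str.startswith("lo")].any()

    def test_single_record_expressed(self):
        df = records_df([("s1", "chrX", 1, "AB", 3, 4)])
        assert snp6_ase.score_expression(df).all()

    def test_all_zero_warns_unexpressed(self):
        df = records_df([("s1", "chrX", 1, "AB", 0, 0)])
        with pytest.warns(UserWarning):
            assert not snp6_ase.score_expression(df).any()


class TestMaskNoninformative:
    def test_het_inside_loh_not_informative(self):
        df = records_df([("s1", "chrX", 500, "AB", 1, 1)])
        assert not snp6_ase.mask_noninformative(
            df, [("chrX", 100, 1000)]).any()

    def test_het_outside_informative_hom_not(self):
        df = records_df([("s1", "chrX", 500, "AB", 1, 1),
                         ("s2", "chrX", 600, "AA", 1, 1)])
        inf = snp6_ase.mask_noninformative(df, [("chrX", 1000, 2000)])
        assert list(inf) == [True, False]

    def test_lost_minor_copy_not_informative(self):
        df = records_df([("s1", "chrX", 500, "AB", 1, 1)])
        df["seg_minor_cn"] = 0
        assert not snp6_ase.mask_noninformative(df).any()


class TestClassifySnp:
    @pytest.mark.parametrize("a,b,expect_class,expect_frac", [
        (100, 100, "biallelic", 0.5),
        (100, 0, "monoallelic", 0.0),
        (85, 15, "monoallelic", 0.15),   # 0.15 < 0.20 cutoff
        (80, 20, "biallelic", 0.20),     # boundary: >= passes
    ])
    def test_allelic_rule(self, a, b, expect_class, expect_frac):
        df = records_df([("s1", "chrX", 1, "AB", a, b)])
        calls = snp6_ase.classify_snp_allelic(
            df, expressed=pd.Series([True]), informative=pd.Series([True]))
        assert calls.allelic_class[0] == expect_class
        assert calls.minor_channel_fraction[0] == pytest.approx(expect_frac)

    def test_uncallable_snp_gets_na(self):
        df = records_df([("s1", "chrX", 1, "AA", 100, 0)])
        calls = snp6_ase.classify_snp_allelic(
            df, expressed=pd.Series([True]), informative=pd.Series([False]))
        assert calls.allelic_class[0] == "NA"

    def test_zero_total_with_expressed_flag_errors(self):
        df = records_df([("s1", "chrX", 1, "AB", 0, 0)])
        with pytest.raises(ValueError, match="zero total"):
            snp6_ase.classify_snp_allelic(
                df, expressed=pd.Series([True]),
                informative=pd.Series([True]))

    @given(cut1=st.floats(0.01, 0.49), cut2=st.floats(0.01, 0.49),
           a=st.integers(0, 1000), b=st.integers(1, 1000))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_raising_cutoff_never_promotes_to_biallelic(self, cut1, cut2,
                                                        a, b):
        lo, hi = sorted((cut1, cut2))
        df = records_df([("s1", "chrX", 1, "AB", a, b)])
        kw = dict(expressed=pd.Series([True]), informative=pd.Series([True]))
        c_lo = snp6_ase.classify_snp_allelic(
            df, Thresholds(snp_minor_fraction=lo), **kw).allelic_class[0]
        c_hi = snp6_ase.classify_snp_allelic(
            df, Thresholds(snp_minor_fraction=hi), **kw).allelic_class[0]
        if c_lo == "monoallelic":
            assert c_hi == "monoallelic"


def brute_force_windows(calls, size, step, members="informative"):
    """Independent recount: python loops over explicit window slices."""
    rows = []
    for chrom in calls.chrom.unique():
        sub = calls[calls.chrom == chrom].sort_values("pos")
        if members == "informative":
            sub = sub[sub.informative]
        recs = list(sub.itertuples())
        if not recs:
            continue
        if len(recs) < size:
            windows = [recs]
        else:
            windows = [recs[s:s + size]
                       for s in range(0, len(recs) - size + 1, step)]
        for w in windows:
            n_bi = sum(r.allelic_class == "biallelic" for r in w)
            n_mono = sum(r.allelic_class == "monoallelic" for r in w)
            rows.append((chrom, n_bi + n_mono, n_bi, n_mono))
    return rows


class TestWindowProfile:
    def test_all_monoallelic_single_window(self):
        calls = make_calls([(f"s{i}", "chrX", i + 1, True, True,
                             "monoallelic") for i in range(50)])
        prof = snp6_ase.window_profile(calls)
        assert len(prof) == 1
        row = prof.iloc[0]
        assert (row.n_expressed_informative, row.n_biallelic,
                row.n_monoallelic) == (50, 0, 50)
        assert not row.truncated

    def test_short_chromosome_truncated_window(self):
        calls = make_calls([(f"s{i}", "chrX", i + 1, True, True,
                             "monoallelic") for i in range(49)])
        prof = snp6_ase.window_profile(calls)
        assert len(prof) == 1
        assert prof.iloc[0].truncated and prof.iloc[0].n_snps == 49

    def test_empty_input_empty_output(self):
        assert snp6_ase.window_profile(make_calls([])).empty

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(42)
        n = 1000
        cls = rng.choice(["biallelic", "monoallelic", "NA"], size=n)
        informative = rng.random(n) < 0.8
        cls = np.where(informative & (cls != "NA"), cls, "NA")
        calls = make_calls([
            (f"s{i}", "chr" + str(rng.integers(1, 4)), i + 1,
             bool(cls[i] != "NA"), bool(informative[i]), cls[i])
            for i in range(n)])
        for step in (1, 7):
            th = Thresholds(window_step=step)
            prof = snp6_ase.window_profile(calls, th)
            got = [(r.chrom, r.n_expressed_informative, r.n_biallelic,
                    r.n_monoallelic) for r in prof.itertuples()]
            assert got == brute_force_windows(calls, 50, step)


class TestGeneCall:
    GENES = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chrX"],
                          "start": [1], "end": [1000]})

    def _calls(self, classes):
        return make_calls([(f"s{i}", "chrX", 10 * (i + 1), c != "NA",
                            c != "NA", c) for i, c in enumerate(classes)])

    def test_one_third_biallelic_is_monoallelic(self):
        calls = self._calls(["biallelic", "monoallelic", "monoallelic"])
        out = snp6_ase.gene_call(calls, self.GENES)
        assert out.allelic_class[0] == "monoallelic"

    def test_two_thirds_boundary_is_biallelic(self):
        calls = self._calls(["biallelic", "biallelic", "monoallelic"])
        out = snp6_ase.gene_call(calls, self.GENES)
        assert out.allelic_class[0] == "biallelic"

    def test_no_callable_snps_uninformative(self):
        calls = self._calls(["NA", "NA"])
        out = snp6_ase.gene_call(calls, self.GENES)
        assert out.allelic_class[0] == "uninformative"

    def test_snp_in_two_overlapping_genes_counted_in_both(self, caplog):
        genes = pd.DataFrame({"gene_id": ["g1", "g2"],
                              "chrom": ["chrX", "chrX"],
                              "start": [1, 500], "end": [1000, 1500]})
        calls = make_calls([("s1", "chrX", 700, True, True, "biallelic")])
        out = snp6_ase.gene_call(calls, genes)
        assert (out.n_expressed_informative == 1).all()


class TestClonality:
    def _phase(self, calls, alleles):
        return pd.DataFrame({"snp_id": calls.snp_id, "hap1_allele": alleles})

    def test_single_haplotype_clonal(self):
        calls = make_calls([(f"s{i}", "chrX", i + 1, True, True,
                             "monoallelic") for i in range(10)])
        calls["major_channel"] = "A"
        rep = snp6_ase.clonality_check(calls, self._phase(calls, ["A"] * 10))
        assert rep["clonal"] and rep["majority_fraction"] == 1.0

    def test_even_split_not_clonal(self):
        calls = make_calls([(f"s{i}", "chrX", i + 1, True, True,
                             "monoallelic") for i in range(10)])
        calls["major_channel"] = "A"
        rep = snp6_ase.clonality_check(
            calls, self._phase(calls, ["A"] * 5 + ["B"] * 5))
        assert not rep["clonal"]
        assert rep["majority_fraction"] == 0.5

    def test_no_phased_snps_indeterminate(self):
        calls = make_calls([("s1", "chrX", 1, True, True, "biallelic")])
        rep = snp6_ase.clonality_check(calls, self._phase(calls, ["A"]))
        assert rep["status"] == "indeterminate"

    def test_synthetic_clone_is_clonal(self, exact_config):
        ann = x.simulate_annotation(exact_config)
        truth = x.simulate_clone(exact_config, x.SampleSpec("n", "maternal"),
                                 ann)
        arr = x.simulate_snp6_intensities(truth, exact_config)
        calls = snp6_ase.classify_snp_allelic(arr)
        rep = snp6_ase.clonality_check(calls, truth.snps)
        assert rep["clonal"] and rep["majority_fraction"] == 1.0


class TestNoiseFreeRecovery:
    def test_exact_agreement_with_ground_truth(self, exact_config):
        """Noise-free clone: every expressed subject gene monoallelic,
        every PAR/autosomal/escapee-above-threshold gene as per truth."""
        ann = x.simulate_annotation(exact_config)
        genes, _ = ann
        truth = x.simulate_clone(exact_config, x.SampleSpec("n", "maternal"),
                                 ann)
        arr = x.simulate_snp6_intensities(truth, exact_config)
        _, _, gcalls = snp6_ase.call_sample(arr, genes)
        merged = gcalls.merge(truth.genes[["gene_id", "xci_status",
                                           "xi_fraction"]], on="gene_id")
        subj = merged[merged.xci_status == "subject"]
        assert (subj.allelic_class == "monoallelic").all()
        bi = merged[merged.xci_status.isin(["PAR", "autosomal"])]
        assert (bi.allelic_class == "biallelic").all()
        esc = merged[merged.xci_status == "constitutive_escapee"]
        expect = np.where(esc.xi_fraction >= 0.20, "biallelic",
                          "monoallelic")
        assert (esc.allelic_class.values == expect).all()

    def test_record_order_does_not_change_calls(self, exact_config):
        ann = x.simulate_annotation(exact_config)
        genes, _ = ann
        truth = x.simulate_clone(exact_config, x.SampleSpec("n", "maternal"),
                                 ann)
        arr = x.simulate_snp6_intensities(truth, exact_config)
        shuffled = arr.sample(frac=1.0, random_state=1).reset_index(drop=True)
        _, _, g1 = snp6_ase.call_sample(arr, genes)
        _, _, g2 = snp6_ase.call_sample(shuffled, genes)
        m = g1.merge(g2, on="gene_id", suffixes=("_a", "_b"))
        assert (m.allelic_class_a == m.allelic_class_b).all()
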