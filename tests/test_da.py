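import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from chromatac.core import GenomicInterval, PeakCountTable
from chromatac.da import (Transcript, annotate_feature, apply_tiers,
                          fit_variance_prior, moderate_variances,
                          normalize_counts, normalize_to_reference,
                          rank_results, run_da, tier_summary)
from chromatac.da import test_all_peaks as da_test_all_peaks
from chromatac.da import test_peak as da_test_peak
from chromatac.errors import ParameterError, UndefinedValueError
from chromatac.simulate import CountSimParams, simulate_peak_counts


def make_table(counts, conditions=("WT", "iH1.0")):
    counts = np.asarray(counts)
    n = counts.shape[1] // 2
    samples = [f"{conditions[0]}_{i}" for i in range(n)] + \
              [f"{conditions[1]}_{i}" for i in range(n)]
    cond = {s: s.rsplit("_", 1)[0] for s in samples}
    peaks = [GenomicInterval("chr1", i * 1000, i * 1000 + 500, f"p{i}")
             for i in range(counts.shape[0])]
    return PeakCountTable(peaks, counts, samples, cond)


class TestNormalization:
    def test_identical_samples_have_unit_factors(self):
        t = make_table(np.tile([[10], [20], [30]], (1, 4)))
        _, factors = normalize_counts(t)
        np.testing.assert_allclose(factors, 1.0)

    def test_doubled_library_has_double_factor(self):
        base = np.array([[10, 20], [30, 60], [50, 100], [70, 140]])
        t = make_table(base)
        normalized, factors = normalize_counts(t)
        assert factors[1] / factors[0] == pytest.approx(2.0)
        np.testing.assert_allclose(normalized[:, 0], normalized[:, 1])

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(80, size=(50, 4))
        counts[counts == 0] = 1
        t = make_table(counts)
        _, factors = normalize_counts(t)
        # from-scratch: geometric-mean reference, per-sample median ratio
        logs = np.log(counts.astype(float))
        ref = np.exp(logs.mean(axis=1))
        expected = np.median(counts / ref[:, None], axis=0)
        np.testing.assert_allclose(factors, expected, atol=1e-9)

    def test_fallback_to_total_count_scaling(self, caplog):
        # every peak has a zero somewhere -> no all-positive reference peak
        counts = np.array([[0, 5, 5, 5], [5, 0, 5, 5],
                           [5, 5, 0, 5], [5, 5, 5, 0]])
        with caplog.at_level("WARNING"):
            _, factors = normalize_counts(make_table(counts))
        assert "total-count" in caplog.text
        np.testing.assert_allclose(factors, 1.0)


class TestTestPeak:
    def test_identical_replicates_give_null_result(self):
        row = np.array([10.0, 12.0, 11.0, 10.0, 12.0, 11.0])
        l2fc, p = da_test_peak(row, np.array([3, 4, 5]), np.array([0, 1, 2]))
        assert l2fc == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swapping_labels_negates_fold_change(self):
        rng = np.random.default_rng(1)
        row = rng.poisson(50, 6).astype(float)
        a, b = np.array([0, 1, 2]), np.array([3, 4, 5])
        l1, p1 = da_test_peak(row, b, a)
        l2, p2 = da_test_peak(row, a, b)
        assert l1 == pytest.approx(-l2)
        assert p1 == pytest.approx(p2)

    def test_welch_p_matches_textbook_formula(self):
        row = np.array([12.0, 18.0, 15.0, 40.0, 52.0, 47.0])
        tx, wt = np.array([3, 4, 5]), np.array([0, 1, 2])
        _, p = da_test_peak(row, tx, wt)
        # textbook Welch on the log2(x + 0.5) replicate values
        from scipy import stats
        x = np.log2(row[tx] + 0.5)
        y = np.log2(row[wt] + 0.5)
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(expected, abs=1e-9)

    def test_all_zero_peak_is_null(self):
        l2fc, p = da_test_peak(np.zeros(6), np.array([3, 4, 5]),
                            np.array([0, 1, 2]))
        assert (l2fc, p) == (0.0, 1.0)


class TestModeration:
    def test_prior_pools_homogeneous_variances(self):
        rng = np.random.default_rng(2)
        s_sq = rng.chisquare(4, 2000) / 4 * 0.2  # true variance 0.2, df 4
        prior = fit_variance_prior(s_sq, 4)
        assert prior.s0_sq == pytest.approx(0.2, rel=0.1)
        assert prior.d0 > 20  # near-homogeneous -> strong pooling
        post = moderate_variances(s_sq, prior)
        assert post.std() < s_sq.std() / 2

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_moderated_p_matches_limma(self, tmp_path):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(20, 20 / (20 + 500.0), size=(200, 6))
        table = make_table(counts)
        normalized, _ = normalize_counts(table)
        lmat = np.log2(normalized + 0.5)
        assert lmat.var(axis=1).min() > 0  # fixture precondition
        res = da_test_all_peaks(table, method="moderated")

        mat_path = tmp_path / "logmat.tsv"
        pd.DataFrame(lmat).to_csv(mat_path, sep="\t", index=False)
        out_path = tmp_path / "limma.tsv"
        rscript = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{mat_path}"))
        design <- model.matrix(~ c(0,0,0,1,1,1))
        fit <- eBayes(lmFit(m, design))
        write.table(data.frame(p=fit$p.value[,2], d0=fit$df.prior,
                               s02=fit$s2.prior),
                    "{out_path}", sep="\t", row.names=FALSE)
        """
        r_file = tmp_path / "oracle.R"
        r_file.write_text(rscript)
        subprocess.run(["Rscript", str(r_file)], check=True,
                       capture_output=True)
        oracle = pd.read_csv(out_path, sep="\t")
        np.testing.assert_allclose(res["p_value"], oracle["p"], rtol=1e-5)


class TestMethodComparison:
    """The facts motivating the moderated default (see docs/methods.md)."""

    def test_moderated_beats_welch_on_planted_effects(self):
        planted = tuple((i, 8.0, "closed") for i in range(100))
        table, _ = simulate_peak_counts(CountSimParams(
            n_peaks=4000, planted=planted, seed=6))
        hits = {}
        for method in ("moderated", "welch"):
            res = da_test_all_peaks(table, method=method)
            stringent = ((res["p_value"] < 1e-3)
                         & (res["log2_fc"].abs() > 2)).to_numpy()
            hits[method] = int(stringent[:100].sum())
        assert hits["moderated"] >= 99
        assert hits["welch"] < hits["moderated"]

    def test_welch_is_more_conservative_under_null(self):
        table, _ = simulate_peak_counts(CountSimParams(
            n_peaks=10_000, seed=7))
        welch = da_test_all_peaks(table, method="welch")
        moderated = da_test_all_peaks(table, method="moderated")
        assert (welch["p_value"] < 0.01).mean() < \
            (moderated["p_value"] < 0.01).mean()


class TestTiers:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["log2_fc", "p_value"])

    def test_example_calls(self):
        df = self.frame([
            (math.log2(3), 0.005),    # relaxed, open
            (-math.log2(5), 5e-4),    # stringent, closed
            (math.log2(10), 0.05),    # none (p too large)
        ])
        out = apply_tiers(df)
        assert list(out["tier"]) == ["relaxed", "stringent", "none"]
        assert list(out["direction"]) == ["open", "closed", "none"]

    def test_stringent_implies_relaxed(self):
        rng = np.random.default_rng(4)
        df = self.frame(list(zip(rng.normal(0, 3, 500),
                                 10 ** rng.uniform(-6, 0, 500))))
        out = apply_tiers(df)
        assert set(out.loc[out["tier"] == "stringent"].index) <= \
            set(out.loc[out["tier"] != "none"].index)

    def test_boundary_is_strict(self):
        df = self.frame([(1.0, 0.005), (1.0001, 0.01)])
        out = apply_tiers(df)
        assert list(out["tier"]) == ["none", "none"]


class TestRanking:
    def test_primary_key_is_p_value(self):
        df = pd.DataFrame({"log2_fc": [1.5, 3.0], "p_value": [1e-5, 1e-3]})
        out = rank_results(df)
        assert list(out["rank"]) == [1, 2]

    def test_effect_size_breaks_p_ties(self):
        df = pd.DataFrame({"log2_fc": [3.0, 8.0], "p_value": [1e-4, 1e-4]})
        out = rank_results(df)
        assert list(out["rank"]) == [2, 1]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(5)
        n = 200
        df = pd.DataFrame({
            "log2_fc": rng.normal(0, 2, n),
            "p_value": 10 ** rng.integers(-6, 0, n).astype(float),
        })
        peaks = [GenomicInterval("chr1", i * 100, i * 100 + 50)
                 for i in rng.permutation(n)]
        out = rank_results(df, peaks)
        keys = [(df["p_value"][i], -abs(df["log2_fc"][i]),
                 peaks[i].chrom, peaks[i].start) for i in range(n)]
        expected_order = sorted(range(n), key=lambda i: keys[i])
        expected_rank = np.empty(n, dtype=int)
        expected_rank[expected_order] = np.arange(1, n + 1)
        np.testing.assert_array_equal(out["rank"], expected_rank)


class TestFeatureAnnotation:
    TX_PLUS = Transcript("chr1", 10_000, 20_000, "gene1", "+",
                         12_500, 18_000,
                         ((10_000, 13_000), (15_000, 16_000),
                          (17_500, 20_000)))
    TX_MINUS = Transcript("chr2", 10_000, 20_000, "gene2", "-",
                          12_500, 18_000,
                          ((10_000, 13_000), (17_500, 20_000)))

    def peak_at(self, chrom, mid):
        return GenomicInterval(chrom, mid - 100, mid + 100)

    @pytest.mark.parametrize("chrom,mid,expected", [
        ("chr1", 9_500, "promoter"),    # 500 bp upstream of + TSS
        ("chr1", 12_250, "5'UTR"),      # exonic, before CDS start
        ("chr1", 19_000, "3'UTR"),      # exonic, after CDS end
        ("chr1", 15_500, "exon"),       # internal CDS exon
        ("chr1", 14_000, "intron"),
        ("chr1", 500_000, "distal"),
        ("chr2", 20_500, "promoter"),   # upstream of - strand TSS (= end)
        ("chr2", 12_000, "3'UTR"),      # before cds_start on - strand
    ])
    def test_categories(self, chrom, mid, expected):
        model = [self.TX_PLUS, self.TX_MINUS]
        assert annotate_feature(self.peak_at(chrom, mid), model) == expected

    def test_promoter_takes_precedence_over_exon(self):
        assert annotate_feature(self.peak_at("chr1", 11_000),
                                [self.TX_PLUS]) == "promoter"


class TestReferenceNormalization:
    def test_known_ratios(self):
        assert normalize_to_reference(10.0, 10.0) == 1.0
        assert normalize_to_reference(5.0, 10.0) == 0.5

    def test_scale_invariance(self):
        assert normalize_to_reference(5.0 * 7, 10.0 * 7) == \
            pytest.approx(normalize_to_reference(5.0, 10.0))

    def test_zero_reference_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            normalize_to_reference(5.0, 0.0)


class TestRunDa:
    def test_planted_effects_called_with_direction(self):
        planted = tuple((i, 8.0, "closed") for i in range(10)) + \
            tuple((i, 8.0, "open") for i in range(10, 15))
        table, _ = simulate_peak_counts(CountSimParams(
            n_peaks=2000, planted=planted, seed=2))
        res = run_da(table)
        stringent = res[res["tier"] == "stringent"]
        assert (stringent["direction"][:10] == "closed").all()
        summary = tier_summary(res)
        closed = summary.query(
            "tier == 'stringent' and direction == 'closed'")["n_peaks"].item()
        assert closed >= 9

    def test_requires_two_replicates(self):
        t = make_table(np.array([[5, 6], [7, 8]]))
        with pytest.raises(ParameterError):
            da_test_all_peaks(t)
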