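import numpy as np
import pytest
from scipy import stats

from chromatac.errors import ParameterError
from chromatac.simulate import (CountSimParams, FragmentSimParams,
                                StateSimSpec, apply_gc_bias,
                                simulate_abundance_table,
                                simulate_fragment_lengths,
                                simulate_peak_counts, simulate_state_dataset)
from chromatac.stoich import h1_per_nucleosome, percent_of_total_h1


class TestFragmentLengths:
    def test_degenerate_mixture_collapses_to_core_length(self):
        p = FragmentSimParams(period_bp=190, core_bp=147, n_orders=1,
                              peak_sd_bp=0.0, periodic_fraction=1.0,
                              n_fragments=5000, seed=0)
        lengths = simulate_fragment_lengths(p)
        assert np.all(lengths == 147.0)

    def test_pure_background_matches_truncated_exponential(self):
        scale = 60.0
        p = FragmentSimParams(periodic_fraction=0.0,
                              background_scale_bp=scale,
                              n_fragments=50_000, seed=42)
        lengths = simulate_fragment_lengths(p)
        # background model: exponential truncated below at 1 bp
        cdf = lambda x: np.where(x < 1, 0.0, 1.0 - np.exp(-(x - 1) / scale))
        stat = stats.kstest(lengths, cdf)
        assert stat.pvalue > 0.01

    def test_expected_periodic_fraction(self):
        p = FragmentSimParams(periodic_fraction=0.6, n_fragments=100_000,
                              seed=3)
        lengths = simulate_fragment_lengths(p)
        # ladder fragments are >= ~100 bp; background mostly below
        assert 0.55 < np.mean(lengths > 120) < 0.70

    def test_seeded_reproducibility_is_bit_exact(self):
        p = FragmentSimParams(n_fragments=10_000, seed=7)
        a = simulate_fragment_lengths(p)
        b = simulate_fragment_lengths(p)
        np.testing.assert_array_equal(a, b)

    def test_all_lengths_at_least_one(self):
        p = FragmentSimParams(periodic_fraction=0.5, background_scale_bp=2.0,
                              n_fragments=20_000, seed=0)
        assert simulate_fragment_lengths(p).min() >= 1.0

    @pytest.mark.parametrize("bad", [
        dict(period_bp=100, core_bp=147),
        dict(periodic_fraction=1.5),
        dict(n_orders=0),
        dict(order_decay=1.0),
        dict(background_scale_bp=0.0),
    ])
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ParameterError):
            simulate_fragment_lengths(FragmentSimParams(**bad))


class TestGcBias:
    def test_zero_slope_is_identity(self):
        f = {"a": 0.3, "b": 0.7}
        out = apply_gc_bias(f, {"a": 0.4, "b": 0.6}, 0.0)
        assert out == pytest.approx(f)

    def test_two_state_closed_form_ratio(self):
        out = apply_gc_bias({"lo": 0.5, "hi": 0.5},
                            {"lo": 0.4, "hi": 0.6}, 2.0)
        assert out["hi"] / out["lo"] == pytest.approx(np.exp(0.4))
        assert sum(out.values()) == pytest.approx(1.0)

    def test_negative_slope_inverts_ordering(self):
        gc = {"lo": 0.3, "mid": 0.5, "hi": 0.7}
        f = {k: 1 / 3 for k in gc}
        up = apply_gc_bias(f, gc, 1.5)
        dn = apply_gc_bias(f, gc, -1.5)
        assert up["hi"] > up["mid"] > up["lo"]
        assert dn["hi"] < dn["mid"] < dn["lo"]

    def test_empty_mapping_is_error(self):
        with pytest.raises(ParameterError):
            apply_gc_bias({}, {}, 1.0)


def small_specs(shares=(0.5, 0.5), gcs=(0.4, 0.6), pf=0.0):
    p = FragmentSimParams(periodic_fraction=pf)
    return [StateSimSpec(f"s{i}", p, p, gc_fraction=g, genome_share=sh)
            for i, (sh, g) in enumerate(zip(shares, gcs))]


class TestStateDataset:
    def test_single_state_gc_and_labels(self):
        ds = simulate_state_dataset(small_specs((1.0,), (0.5,)),
                                    chrom_length=20_000, seed=0,
                                    n_fragments_per_condition=2000)
        seq = ds.genome["chrSim"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52
        assert [s.label for s in ds.states] == ["s0"]
        for frags in ds.fragments.values():
            assert all(0 <= f.interval.start < f.interval.end <= 20_000
                       for f in frags)

    def test_equal_shares_give_equal_fragment_split(self):
        ds = simulate_state_dataset(small_specs(), chrom_length=100_000,
                                    seed=1, n_fragments_per_condition=100_000)
        frags = ds.fragments["WT"]
        boundary = ds.states[0].end
        frac0 = np.mean([f.interval.midpoint < boundary for f in frags])
        assert frac0 == pytest.approx(0.5, abs=0.01)

    def test_gc_bias_orders_representation_log_ratios(self):
        specs = small_specs((1/3, 1/3, 1/3), (0.35, 0.45, 0.55))
        ds = simulate_state_dataset(specs, chrom_length=60_000, seed=2,
                                    n_fragments_per_condition=60_000,
                                    gc_bias_slope={"iH1.0": 2.0})
        counts = {c: np.zeros(3) for c in ds.fragments}
        bounds = [s.end for s in ds.states]
        for cond, frags in ds.fragments.items():
            for f in frags:
                counts[cond][np.searchsorted(bounds, f.interval.midpoint,
                                             side="right")] += 1
        ratios = np.log(counts["iH1.0"] / counts["WT"])
        assert ratios[0] < ratios[1] < ratios[2]

    def test_bad_shares_raise(self):
        with pytest.raises(ParameterError, match="sum"):
            simulate_state_dataset(small_specs((0.5, 0.4)),
                                   chrom_length=50_000, seed=0)

    def test_determinism(self):
        a = simulate_state_dataset(small_specs(), 50_000, seed=5,
                                   n_fragments_per_condition=500)
        b = simulate_state_dataset(small_specs(), 50_000, seed=5,
                                   n_fragments_per_condition=500)
        assert a.genome == b.genome
        assert a.fragments == b.fragments


class TestPeakCounts:
    def test_zero_dispersion_is_poisson(self):
        table, _ = simulate_peak_counts(CountSimParams(
            n_peaks=10_000, dispersion=0.0, mean_depth=50.0, seed=0))
        counts = table.counts.astype(float)
        assert counts.mean() == pytest.approx(50.0, rel=0.02)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_planted_truth_and_direction(self):
        planted = ((0, 8.0, "closed"), (1, 8.0, "open"))
        table, truth = simulate_peak_counts(CountSimParams(
            n_peaks=100, mean_depth=400.0, dispersion=0.01,
            planted=planted, seed=1))
        wt = table.counts[:, table.sample_indices("WT")].mean(axis=1)
        tx = table.counts[:, table.sample_indices("iH1.0")].mean(axis=1)
        assert tx[0] < wt[0] / 4
        assert tx[1] > wt[1] * 4
        assert list(truth["peak_index"]) == [0, 1]

    def test_reproducibility(self):
        params = CountSimParams(n_peaks=50, seed=9)
        a, _ = simulate_peak_counts(params)
        b, _ = simulate_peak_counts(params)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestAbundanceTable:
    def test_noiseless_single_subtype_round_trip(self):
        t = simulate_abundance_table({"H1.0": 1.0}, 0.125, 0.0, 0)
        assert percent_of_total_h1(t, "H1.0") == pytest.approx(100.0)
        assert h1_per_nucleosome(t, "H1.0") == pytest.approx(0.125)

    def test_noiseless_mixture_recovers_18_percent(self):
        t = simulate_abundance_table(
            {"H1.0": 0.18, "H1.2": 0.41, "H1.4": 0.41}, 0.125, 0.0, 0)
        assert percent_of_total_h1(t, "H1.0") == pytest.approx(18.0)

    def test_noisy_recovery_is_unbiased(self):
        fracs = {"H1.0": 0.18, "H1.2": 0.41, "H1.4": 0.41}
        recovered = [
            percent_of_total_h1(
                simulate_abundance_table(fracs, 0.125, 0.05, seed), "H1.0")
            for seed in range(100)]
        assert np.mean(recovered) == pytest.approx(18.0, abs=1.0)

    def test_fraction_sum_validation(self):
        with pytest.raises(ParameterError):
            simulate_abundance_table({"H1.0": 0.5}, 0.1, 0.0, 0)
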