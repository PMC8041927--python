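"""Windowed peak calling: counting, filtering, scoring, testing, merging."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from m6acall import (
    GeneModel,
    InputError,
    PeakCallParams,
    SimulationConfig,
    adjust_fdr,
    call_peaks,
    count_windows,
    enrichment_score,
    filter_low_windows,
    fisher_window_test,
    metagene_distribution,
    normalize_by_gene_median,
    simulate_fragments,
    simulate_gene_models,
    unique_peaks,
    window_grid,
)
from m6acall.peaks import call_and_merge, count_in_windows


def single_exon_model(gene_id="g", length=1000, cds=None):
    cds_start, cds_end = cds if cds else (None, None)
    return GeneModel(gene_id, f"t_{gene_id}", "chr1", "+",
                     np.array([0]), np.array([length]), cds_start, cds_end)


class TestWindowGrid:
    @pytest.mark.parametrize(
        "length,expected_n,last",
        [
            (300, 21, (200, 300)),     # floor((300-100)/10)+1 windows
            (305, 22, (205, 305)),     # extra right-anchored terminal window
            (100, 1, (0, 100)),
            (60, 1, (0, 60)),          # shorter than a window: full transcript
        ],
    )
    def test_grid_shape(self, length, expected_n, last):
        g = window_grid(length)
        assert len(g) == expected_n
        assert tuple(g[-1]) == last
        assert np.all(g[:, 1] - g[:, 0] <= 100)

    def test_windows_cover_transcript(self):
        g = window_grid(437)
        assert g[0, 0] == 0 and g[-1, 1] == 437


class TestCounting:
    def test_overlap_rule_150nt_fragment(self):
        m = single_exon_model(length=300)
        frag = np.array([[0, 150]])
        rec = count_windows(m, frag, np.empty((0, 2), dtype=np.int64))
        counted = rec[rec["ip_count"] > 0]["start"].to_numpy()
        assert counted.max() == 140 and counted.min() == 0
        assert len(counted) == 15

    def test_no_fragments_all_zero(self):
        m = single_exon_model(length=300)
        empty = np.empty((0, 2), dtype=np.int64)
        rec = count_windows(m, empty, empty)
        assert (rec["ip_count"] == 0).all() and (rec["input_count"] == 0).all()

    def test_counts_match_naive_overlap(self):
        rng = np.random.default_rng(0)
        iv = np.column_stack([rng.integers(0, 900, 200), np.zeros(200, int)])
        iv[:, 1] = iv[:, 0] + rng.integers(1, 200, 200)
        grid = window_grid(1000)
        fast = count_in_windows(iv, grid)
        naive = [
            int(np.sum((iv[:, 0] < we) & (iv[:, 1] > ws))) for ws, we in grid
        ]
        np.testing.assert_array_equal(fast, naive)


class TestLowWindowFilter:
    def _records(self, rows):
        df = pd.DataFrame(rows, columns=["ip_count", "input_count"])
        df["gene_id"] = "g"
        df["start"] = np.arange(len(df)) * 10
        df["end"] = df["start"] + 100
        return df

    def test_failing_only_one_library_is_retained(self):
        # top IP 100, top input 40: window (4, 3) is low in IP but not input
        rec = self._records([(100, 40), (4, 3)])
        out = filter_low_windows(rec)
        assert out["retained"].tolist() == [True, True]

    def test_low_in_both_is_excluded(self):
        rec = self._records([(100, 40), (4, 1)])
        out = filter_low_windows(rec)
        assert out["retained"].tolist() == [True, False]

    def test_all_zero_gene_fully_excluded(self):
        rec = self._records([(0, 0), (0, 0)])
        assert not filter_low_windows(rec)["retained"].any()

    def test_removing_filter_only_adds_windows(self):
        rng = np.random.default_rng(3)
        rec = self._records(list(zip(rng.integers(0, 100, 50), rng.integers(0, 100, 50))))
        filtered = filter_low_windows(rec, min_frac=0.05)
        unfiltered = filter_low_windows(rec, min_frac=0.0)
        kept = filtered[filtered["retained"]]
        assert unfiltered["retained"].all()
        # retained windows keep identical counts with or without the filter
        merged = kept.merge(unfiltered, on="start", suffixes=("_f", "_u"))
        assert (merged["ip_count_f"] == merged["ip_count_u"]).all()
        assert set(kept["start"]) <= set(unfiltered[unfiltered["retained"]]["start"])


class TestNormalization:
    def _records(self, ip, inp):
        df = pd.DataFrame({"ip_count": ip, "input_count": inp})
        df["gene_id"] = "g"
        df["retained"] = True
        return df

    def test_equal_counts_normalize_to_one(self):
        out = normalize_by_gene_median(self._records([7, 7, 7], [3, 3, 3]))
        assert (out["norm_ip"] == 1.0).all() and (out["norm_input"] == 1.0).all()

    def test_median_of_arithmetic_sequence(self):
        out = normalize_by_gene_median(self._records([2, 4, 6], [2, 4, 6]))
        np.testing.assert_allclose(out["norm_ip"], [0.5, 1.0, 1.5])

    def test_even_count_median_is_middle_pair_mean(self):
        out = normalize_by_gene_median(self._records([1, 2, 4, 8], [1, 1, 1, 1]))
        assert out["ip_median"].iloc[0] == 3.0

    def test_zero_median_pseudocount_keeps_finite(self):
        out = normalize_by_gene_median(self._records([0, 0, 5], [0, 0, 0]))
        assert np.isfinite(out["norm_ip"]).all()
        # hand evaluation of the +1 rule: (a+1)/(median+1)
        np.testing.assert_allclose(out["norm_ip"], [1.0, 1.0, 6.0])


class TestEnrichmentScore:
    def test_printed_formula(self):
        assert enrichment_score(20, 5, 4, 5) == 5.0

    def test_window_at_gene_median_is_null(self):
        assert enrichment_score(7, 7, 3, 3) == 1.0

    def test_pseudocount_hand_value(self):
        # zero input count: all four terms get +1 -> (11*6)/(6*1)
        assert enrichment_score(10, 5, 0, 5) == pytest.approx(11.0)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            enrichment_score(-1, 5, 1, 5)

    def test_strictly_increasing_in_ip_count(self):
        es = enrichment_score(np.arange(1, 50), 5, 4, 5)
        assert np.all(np.diff(es) > 0)


class TestFisher:
    def test_proportional_table_p_one(self):
        assert fisher_window_test(5, 50, 10, 100) == pytest.approx(1.0)

    def test_empty_margins_p_one(self):
        assert fisher_window_test(0, 0, 0, 0) == 1.0

    def test_matches_exhaustive_enumeration(self):
        """Integer-arithmetic enumeration over all tables with fixed margins."""
        def oracle(a, A, c, C):
            N, K = A + C, a + c
            lo, hi = max(0, K - C), min(A, K)
            weights = [math.comb(A, k) * math.comb(C, K - k) for k in range(lo, hi + 1)]
            w_obs = weights[a - lo]
            num = sum(w for w in weights if w * 10**7 <= w_obs * (10**7 + 1))
            return num / sum(weights)

        rng = np.random.default_rng(17)
        for _ in range(300):
            A = int(rng.integers(1, 80))
            C = int(rng.integers(1, 80))
            a = int(rng.integers(0, A + 1))
            c = int(rng.integers(0, C + 1))
            assert fisher_window_test(a, A, c, C) == pytest.approx(
                oracle(a, A, c, C), abs=1e-10)

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            A, C = int(rng.integers(1, 60)), int(rng.integers(1, 60))
            a, c = int(rng.integers(0, A + 1)), int(rng.integers(0, C + 1))
            ours = fisher_window_test(a, A, c, C)
            theirs = fisher_exact([[a, A - a], [c, C - c]])[1]
            assert ours == pytest.approx(theirs, abs=1e-10)


class TestFdr:
    def test_textbook_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.2]), [0.2])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty_input(self):
        assert adjust_fdr([]).size == 0

    def test_order_preserving_and_dominating(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = adjust_fdr(p)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestMerge:
    def _records(self, windows, fdr=0.001, log2es=3.0):
        rows = []
        for s, e in windows:
            rows.append({"gene_id": "g", "start": s, "end": e, "retained": True,
                         "fdr": fdr, "log2_es": log2es, "es": 2.0 ** log2es,
                         "ip_median": 5.0, "input_median": 5.0})
        return pd.DataFrame(rows)

    def _call(self, windows):
        model = single_exon_model(length=400)
        frags = {"g": np.array([[0, 150]])}
        return call_and_merge(self._records(windows), frags, frags, {"g": model})

    def test_overlapping_windows_merge(self):
        peaks = self._call([(0, 100), (10, 110)])
        assert len(peaks) == 1
        assert (peaks["start"].iloc[0], peaks["end"].iloc[0]) == (0, 110)
        assert peaks["n_windows"].iloc[0] == 2

    def test_disjoint_windows_stay_separate(self):
        peaks = self._call([(0, 100), (200, 300)])
        assert len(peaks) == 2

    def test_min_fdr_aggregation(self):
        rec = self._records([(0, 100), (10, 110)])
        rec.loc[1, "fdr"] = 1e-6
        model = single_exon_model(length=400)
        frags = {"g": np.array([[0, 150]])}
        peaks = call_and_merge(rec, frags, frags, {"g": model})
        assert peaks["min_fdr"].iloc[0] == 1e-6


def test_planted_peak_recovered_end_to_end():
    """A planted 8-fold window at depth 50 yields exactly one overlapping peak."""
    cfg = SimulationConfig(seed=4, n_genes=1, peaks_per_gene=1,
                           shared_down=0, shared_up=0)
    models, truth = simulate_gene_models(cfg)
    ip_df, input_df = simulate_fragments(models, truth, cfg)
    res = call_peaks({models[0].gene_id: models[0]}, ip_df, input_df)
    (s, e, _), = truth.peaks[models[0].gene_id]
    assert len(res.peaks) == 1
    peak = res.peaks.iloc[0]
    assert peak["start"] < e and peak["end"] > s
    assert math.log2(peak["es"]) >= 1


class TestUniquePeaks:
    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "start", "end"])

    def test_identical_sets_all_shared(self):
        p = self._peaks([("g", 0, 100), ("h", 50, 150)])
        ua, ub, shared = unique_peaks(p, p.copy())
        assert len(ua) == 0 and len(ub) == 0 and len(shared) == 4

    def test_disjoint_gene_sets_all_unique(self):
        pa = self._peaks([("g", 0, 100)])
        pb = self._peaks([("h", 0, 100)])
        ua, ub, shared = unique_peaks(pa, pb)
        assert len(ua) == 1 and len(ub) == 1 and len(shared) == 0

    def test_ten_nt_overlap_is_shared(self):
        ua, ub, shared = unique_peaks(
            self._peaks([("g", 0, 110)]), self._peaks([("g", 100, 200)])
        )
        assert len(ua) == 0 and len(ub) == 0 and len(shared) == 2

    def test_touching_intervals_are_unique(self):
        ua, ub, _ = unique_peaks(
            self._peaks([("g", 0, 100)]), self._peaks([("g", 100, 200)])
        )
        assert len(ua) == 1 and len(ub) == 1

    def test_annotation_mismatch_raises(self):
        models = {"g": single_exon_model("g")}
        with pytest.raises(InputError, match="absent"):
            unique_peaks(self._peaks([("zz", 0, 100)]), self._peaks([]), models)


class TestMetagene:
    def test_midpoints_at_cds_start_land_in_first_cds_bin(self):
        m = single_exon_model(length=1000, cds=(100, 700))
        peaks = pd.DataFrame({"gene_id": ["g"] * 3, "start": [100] * 3, "end": [100] * 3})
        density, skipped = metagene_distribution(peaks, {"g": m})
        assert skipped == 0
        assert density[30] == 1.0 and density.sum() == 1.0

    def test_noncoding_peaks_skipped_and_counted(self):
        m = single_exon_model(length=1000)  # no CDS
        peaks = pd.DataFrame({"gene_id": ["g"], "start": [0], "end": [100]})
        with pytest.warns(UserWarning):
            density, skipped = metagene_distribution(peaks, {"g": m})
        assert skipped == 1 and density.sum() == 0

    def test_empty_peaks_warn_and_zero(self):
        with pytest.warns(UserWarning):
            density, _ = metagene_distribution(
                pd.DataFrame(columns=["gene_id", "start", "end"]), {})
        assert density.sum() == 0

    def test_uniform_midpoints_give_flat_cds_block(self):
        """Uniformly placed CDS midpoints spread evenly over the CDS bins."""
        rng = np.random.default_rng(12)
        m = single_exon_model(length=10000, cds=(1000, 7000))
        mids = rng.integers(1000, 7000, size=10_000)
        peaks = pd.DataFrame({"gene_id": "g", "start": mids, "end": mids})
        density, _ = metagene_distribution(peaks, {"g": m})
        cds = density[30:70]
        assert np.all(density[:30] == 0) and np.all(density[70:] == 0)
        expected = np.full(40, 1 / 40)
        chi2 = np.sum((cds - expected) ** 2 / expected) * len(mids)
        # chi-square sanity: 39 dof, 99.9th percentile ~ 72
        assert chi2 < 72


def test_midpoint_rule_counts_and_recovery():
    """Midpoint counting assigns each fragment to ~10 windows and still
    recovers every planted peak at default depths."""
    iv = np.array([[0, 150]])
    grid = window_grid(300)
    mid_counts = count_in_windows(iv, grid, rule="midpoint")
    # midpoint 75 lies in windows starting 0..70
    assert mid_counts.sum() == 8
    assert np.all(mid_counts <= count_in_windows(iv, grid))

    cfg = SimulationConfig(seed=9, n_genes=8, shared_down=0, shared_up=0)
    models, truth = simulate_gene_models(cfg)
    ip_df, input_df = simulate_fragments(models, truth, cfg)
    md = {m.gene_id: m for m in models}
    res = call_peaks(md, ip_df, input_df, PeakCallParams(count_rule="midpoint"))
    for gene, plist in truth.peaks.items():
        sub = res.peaks[res.peaks["gene_id"] == gene]
        for s, e, _ in plist:
            assert ((sub["start"] < e) & (sub["end"] > s)).any()


def test_unstranded_flag_keeps_antisense_fragments(small_sim):
    config, models, truth, ip_df, input_df = small_sim
    flipped = ip_df.copy()
    flipped["strand"] = np.where(flipped["strand"] == "+", "-", "+")
    md = {m.gene_id: m for m in models[:3]}
    stranded = call_peaks(md, flipped, input_df, PeakCallParams())
    unstranded = call_peaks(md, flipped, input_df, PeakCallParams(stranded=False))
    assert stranded.windows["ip_count"].sum() == 0
    assert unstranded.windows["ip_count"].sum() > 0
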