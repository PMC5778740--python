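"""Fisher combination, window construction, Storey q, merging, overlap."""
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdmr.datatypes import DMRegion
from methdmr.windows import (
    SlidingWindowDMR,
    fishers_method,
    make_windows,
    merge_significant_windows,
    region_overlap,
    regions_to_frame,
    score_windows,
    storey_qvalues,
)


def _probe_frame(positions, chrom="chr1", p=None, delta=None):
    n = len(positions)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:05d}" for i in range(n)],
            "chrom": chrom,
            "pos": positions,
            "p": p if p is not None else np.full(n, 0.5),
            "delta_beta": delta if delta is not None else np.zeros(n),
        }
    )


class TestFishersMethod:
    def test_single_half(self):
        stat, df, p = fishers_method([0.5])
        assert stat == pytest.approx(-2 * np.log(0.5), abs=1e-12)  # 1.3863
        assert df == 2
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_two_halves_closed_form(self):
        stat, df, p = fishers_method([0.5, 0.5])
        assert stat == pytest.approx(2.7726, abs=1e-4)
        # chi2(4) survival at x: (1 + x/2) * exp(-x/2)
        assert p == pytest.approx((1 + stat / 2) * np.exp(-stat / 2), rel=1e-12)
        assert p == pytest.approx(0.5966, abs=1e-4)

    def test_ten_strong(self):
        _, _, p = fishers_method([0.01] * 10)
        assert p < 1e-10

    def test_matches_scipy_combine_pvalues(self):
        rng = np.random.default_rng(50)
        for k in (1, 3, 8):
            p = rng.uniform(1e-6, 1, size=k)
            stat, _, comb = fishers_method(p)
            ref_stat, ref_p = stats.combine_pvalues(p, method="fisher")
            assert stat == pytest.approx(ref_stat, rel=1e-12)
            assert comb == pytest.approx(ref_p, rel=1e-10)

    def test_brute_force_log_sum(self):
        p = np.array([0.2, 0.03, 0.77, 0.5])
        stat, df, comb = fishers_method(p)
        brute = -2 * sum(np.log(x) for x in p)
        assert stat == pytest.approx(brute, abs=1e-12)
        assert comb == pytest.approx(stats.chi2.sf(brute, 8), rel=1e-12)

    def test_zero_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="methdmr.windows"):
            _, _, p = fishers_method([0.0, 0.5])
        assert any("clipping" in r.message for r in caplog.records)
        assert 0 < p < 1e-100 or p >= 0

    def test_invalid_raises(self):
        with pytest.raises(ValueError):
            fishers_method([])
        with pytest.raises(ValueError):
            fishers_method([0.5, 1.1])


class TestMakeWindows:
    def test_worked_example(self):
        probes = _probe_frame([100, 500, 1200])
        win = make_windows(probes, width=1000)
        assert len(win) == 3
        # anchor at 100 spans [100, 1099]: holds probes at 100 and 500
        assert list(win["k"]) == [2, 2, 1]
        assert list(win["start"]) == [100, 500, 1200]
        assert list(win["end"]) == [1099, 1499, 2199]

    def test_duplicate_positions_share_anchor(self):
        probes = _probe_frame([100, 100, 900])
        win = make_windows(probes, width=1000)
        assert len(win) == 2
        assert list(win["k"]) == [3, 1]

    def test_unsorted_raises(self):
        probes = _probe_frame([500, 100])
        with pytest.raises(ValueError):
            make_windows(probes)

    def test_chromosomes_do_not_leak(self):
        probes = pd.concat(
            [_probe_frame([100, 500], chrom="chr1"), _probe_frame([600], chrom="chr2")],
            ignore_index=True,
        )
        win = make_windows(probes, width=1000)
        assert list(win["k"]) == [2, 1, 1]

    def test_empty(self):
        assert len(make_windows(_probe_frame([]))) == 0


class TestScoreWindows:
    def test_matches_direct_fisher(self):
        rng = np.random.default_rng(51)
        pos = np.sort(rng.choice(np.arange(1, 20000), size=60, replace=False))
        p = rng.uniform(1e-5, 1, size=60)
        probes = _probe_frame(pos, p=p)
        win = score_windows(make_windows(probes), p)
        for row in win.itertuples(index=False):
            stat, df, pp = fishers_method(p[row.i0 : row.i1])
            assert row.fisher_stat == pytest.approx(stat, rel=1e-10)
            assert row.p == pytest.approx(pp, rel=1e-8)

    def test_missing_p_skips_window(self, caplog):
        probes = _probe_frame([100, 2000])
        p = np.array([np.nan, 0.3])
        with caplog.at_level("WARNING", logger="methdmr.windows"):
            win = score_windows(make_windows(probes), p)
        assert np.isnan(win.loc[0, "p"])
        assert win.loc[1, "p"] == pytest.approx(0.3)
        assert any("skipping" in r.message for r in caplog.records)


class TestStoreyQvalues:
    def test_pi0_one_equals_bh(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(52)
        p = rng.random(80)
        q = storey_qvalues(p)  # n<100 -> pi0=1 (BH)
        ref = sm.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)

    def test_scales_bh_by_pi0(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(53)
        p = rng.random(500)
        q = storey_qvalues(p, pi0=0.6)
        ref = np.clip(0.6 * sm.multipletests(p, method="fdr_bh")[1], 0, 1)
        np.testing.assert_allclose(q, ref, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(54)
        p = rng.random(300)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_null_rejections_rare(self):
        rng = np.random.default_rng(55)
        p = rng.random(20000)
        q = storey_qvalues(p)
        assert (q < 0.05).mean() <= 0.005

    def test_small_n_warns(self, caplog):
        with caplog.at_level("WARNING", logger="methdmr.windows"):
            storey_qvalues(np.linspace(0.01, 0.99, 50))
        assert any("pi0" in r.message for r in caplog.records)

    def test_invalid_raises(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])


class TestMergeRegions:
    def _scored(self, pos, p, delta):
        probes = _probe_frame(pos, p=p, delta=delta)
        win = score_windows(make_windows(probes), p)
        win["q"] = storey_qvalues(win["p"].to_numpy())
        return win, probes

    def test_adjacent_windows_merge_and_dedup(self):
        pos = [100, 400, 800, 5000]
        p = np.array([1e-8, 1e-8, 1e-8, 0.9])
        delta = np.array([0.1, 0.1, 0.1, 0.0])
        win, probes = self._scored(pos, p, delta)
        regions = merge_significant_windows(win, probes, q_threshold=0.05)
        assert len(regions) == 1
        r = regions[0]
        assert r.probe_ids == ["p00000", "p00001", "p00002"]  # no duplicates
        assert (r.start, r.end) == (100, 800)  # CpG span, not window padding
        assert r.direction == "hypermethylated"
        assert r.source_window_count == 3

    def test_majority_direction(self):
        pos = [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]
        p = np.full(10, 1e-9)
        delta = np.array([-0.1] * 7 + [0.1] * 3)
        win, probes = self._scored(pos, p, delta)
        regions = merge_significant_windows(win, probes, q_threshold=0.05)
        assert len(regions) == 1
        assert regions[0].direction == "hypomethylated"

    def test_tie_is_ambiguous(self):
        pos = [100, 200]
        probes = _probe_frame(pos, p=[1e-9, 1e-9], delta=[0.1, -0.1])
        win = score_windows(make_windows(probes), probes["p"].to_numpy())
        win["q"] = 0.001
        regions = merge_significant_windows(win, probes)
        assert regions[0].direction == "ambiguous"

    def test_no_significant_windows(self):
        win, probes = self._scored([100, 5000], np.array([0.5, 0.6]), np.zeros(2))
        assert merge_significant_windows(win, probes) == []

    def test_region_p_is_fisher_over_probe_union(self):
        pos = [100, 400]
        p = np.array([1e-7, 1e-7])
        win, probes = self._scored(pos, p, np.array([0.1, 0.1]))
        regions = merge_significant_windows(win, probes, q_threshold=0.05)
        assert regions[0].p == pytest.approx(fishers_method(p)[2], rel=1e-10)


class TestRegionOverlap:
    def test_identity(self):
        r = [DMRegion("chr1", 100, 199, ["a"], 0.01, 0.01, "hypermethylated", 1)]
        ov = region_overlap(r, r)
        assert len(ov) == 1
        assert ov.loc[0, "overlap_bp"] == 100

    def test_disjoint(self):
        a = [DMRegion("chr1", 100, 199, ["a"], 0.01, 0.01, "hypermethylated", 1)]
        b = [DMRegion("chr1", 200, 299, ["b"], 0.01, 0.01, "hypermethylated", 1)]
        assert len(region_overlap(a, b)) == 0

    def test_partial_overlap_bp(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [199]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [299]})
        ov = region_overlap(a, b)
        assert ov.loc[0, "overlap_bp"] == 50

    def test_empty_result_has_columns(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [10]})
        b = pd.DataFrame({"chrom": ["chr2"], "start": [1], "end": [10]})
        ov = region_overlap(a, b)
        assert list(ov.columns) == ["index_a", "index_b", "overlap_bp"]

    @pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools not available")
    def test_matches_bedtools(self, tmp_path):
        rng = np.random.default_rng(56)

        def rand_iv(n):
            start = rng.integers(1, 100_000, size=n)
            return pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], size=n),
                    "start": start,
                    "end": start + rng.integers(50, 3000, size=n),
                }
            )

        a, b = rand_iv(40), rand_iv(40)
        ours = region_overlap(a, b)
        fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
        for df, f in ((a, fa), (b, fb)):
            bed = df.copy().sort_values(["chrom", "start"])
            bed["start0"] = bed["start"] - 1  # BED is 0-based half-open
            bed[["chrom", "start0", "end"]].to_csv(f, sep="\t", header=False, index=False)
        out = subprocess.run(
            ["bedtools", "intersect", "-a", str(fa), "-b", str(fb), "-wo"],
            capture_output=True, text=True, check=True,
        ).stdout
        bt_pairs = set()
        for line in out.strip().splitlines():
            fld = line.split("\t")
            bt_pairs.add((fld[0], int(fld[1]) + 1, int(fld[2]), int(fld[6])))
        our_pairs = {
            (a.loc[r.index_a, "chrom"], int(a.loc[r.index_a, "start"]),
             int(a.loc[r.index_a, "end"]), int(r.overlap_bp))
            for r in ours.itertuples(index=False)
        }
        assert our_pairs == bt_pairs


class TestSlidingWindowDMR:
    def test_estimator_end_to_end(self):
        rng = np.random.default_rng(57)
        pos = np.sort(rng.choice(np.arange(1, 200_000, 200), size=300, replace=False))
        p = rng.random(300)
        p[100:110] = 1e-10
        delta = np.zeros(300)
        delta[100:110] = 0.1
        probes = _probe_frame(pos, p=p, delta=delta)
        model = SlidingWindowDMR().fit(probes)
        assert len(model.windows_) == 300
        assert len(model.regions_) >= 1
        hit = model.regions_[0]
        frame = regions_to_frame(model.regions_)
        assert frame.loc[0, "n_probes"] == hit.n_probes
        # most of the spiked block belongs to one reported region
        spiked = set(probes["probe_id"].iloc[100:110])
        best = max(len(spiked & set(r.probe_ids)) for r in model.regions_)
        assert best >= 8
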