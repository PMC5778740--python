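"""Clustering, smoothing, bump detection and the permutation FWER."""
import numpy as np
import pandas as pd
import pytest

from methdmr.bumphunter import (
    BumpHunter,
    _cluster_ids,
    _smooth_all,
    bootstrap_fwer,
    cluster_probes,
    find_bumps,
    probe_effects,
    smooth_cluster,
)
from methdmr.simulate import choose_spike_regions, generate_manifest, simulate_dataset


def _probes(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:05d}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
        }
    )


class TestClusterProbes:
    def test_worked_example(self):
        # gaps 500, 900 join; 1500 splits; chromosome change splits
        probes = pd.concat(
            [_probes([100, 600, 1500, 3000]), _probes([100], chrom="chr2")],
            ignore_index=True,
        )
        probes["probe_id"] = [f"p{i:05d}" for i in range(5)]
        clusters = cluster_probes(probes, maxgap=1000)
        members = [c.probe_ids for c in clusters]
        assert members == [["p00000", "p00001", "p00002"], ["p00003"], ["p00004"]]
        assert [c.chrom for c in clusters] == ["chr1", "chr1", "chr2"]

    def test_gap_exactly_maxgap_joins(self):
        ids = _cluster_ids(np.array(["chr1", "chr1"]), np.array([100, 1100]), 1000)
        assert list(ids) == [0, 0]

    def test_empty(self):
        assert cluster_probes(_probes([])) == []


class TestSmoothing:
    def test_even_k_raises(self):
        with pytest.raises(ValueError):
            smooth_cluster(np.ones(10), k=4)

    def test_short_cluster_unsmoothed(self):
        x = np.array([3.0, -1.0])
        np.testing.assert_array_equal(smooth_cluster(x), x)

    def test_matches_naive_running_median(self):
        rng = np.random.default_rng(60)
        x = rng.normal(size=37)
        k = 5
        got = smooth_cluster(x, k=k)
        half = k // 2
        expect = np.array(
            [np.median(x[max(0, i - half) : min(x.size, i + half + 1)]) for i in range(x.size)]
        )
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_smooth_all_matches_per_cluster(self):
        rng = np.random.default_rng(61)
        sizes = [1, 2, 7, 3, 12, 5]
        coefs = rng.normal(size=sum(sizes))
        cids = np.repeat(np.arange(len(sizes)), sizes)
        got = _smooth_all(coefs, cids, k=5)
        pieces = []
        start = 0
        for s in sizes:
            pieces.append(smooth_cluster(coefs[start : start + s], k=5))
            start += s
        np.testing.assert_allclose(got, np.concatenate(pieces), atol=1e-12)


class TestProbeEffects:
    def test_matches_ols(self):
        rng = np.random.default_rng(62)
        n = 40
        status = np.array(["case"] * 20 + ["control"] * 20)
        age = rng.uniform(10, 60, size=n)
        sex = rng.choice(["F", "M"], size=n)
        y = rng.normal(0.5, 0.05, size=(6, n))
        y[0] += 0.08 * (status == "case")
        got = probe_effects(y, status, age=age, sex=sex)
        X = np.column_stack(
            [np.ones(n), (status == "case").astype(float), age, (sex == "F").astype(float)]
        )
        for i in range(y.shape[0]):
            beta = np.linalg.lstsq(X, y[i], rcond=None)[0]
            assert got[i] == pytest.approx(beta[1], abs=1e-10)
        assert got[0] > 0.05

    def test_constant_status_raises(self):
        status = np.array(["case"] * 10)  # indicator collinear with the intercept
        with pytest.raises(ValueError):
            probe_effects(np.random.default_rng(0).normal(size=(2, 10)), status)

    def test_collinear_covariate_dropped_with_warning(self, caplog):
        status = np.array(["case"] * 5 + ["control"] * 5)
        age = (status == "case").astype(float)  # age duplicates status
        with caplog.at_level("WARNING", logger="methdmr.bumphunter"):
            out = probe_effects(np.random.default_rng(0).normal(size=(2, 10)), status, age=age)
        assert any("collinear" in r.message for r in caplog.records)
        assert np.isfinite(out).all()

    def test_missing_mean_imputed(self):
        status = np.array(["case"] * 10 + ["control"] * 10)
        y = np.full((1, 20), 0.5)
        y[0, :10] = 0.6
        y[0, 3] = np.nan
        got = probe_effects(y, status)
        assert np.isfinite(got[0])


class TestFindBumps:
    def test_runs_split_by_sign_and_cluster(self):
        probes = _probes([100, 200, 300, 400, 5000, 5100])
        sm = np.array([0.2, 0.2, -0.2, -0.2, 0.2, 0.2])
        cids = np.array([0, 0, 0, 0, 1, 1])
        bumps = find_bumps(sm, probes, cutoff=0.1, cluster_ids=cids)
        assert len(bumps) == 3
        assert [b.direction for b in bumps] == [
            "hypermethylated", "hypomethylated", "hypermethylated",
        ]
        assert (bumps[0].start, bumps[0].end) == (100, 200)
        assert bumps[0].area == pytest.approx(0.4)
        assert bumps[0].max_abs_coef == pytest.approx(0.2)

    def test_subthreshold_ignored(self):
        probes = _probes([100, 200])
        assert find_bumps(np.array([0.05, -0.05]), probes, cutoff=0.1) == []

    def test_nonpositive_cutoff_raises(self):
        with pytest.raises(ValueError):
            find_bumps(np.ones(3), _probes([1, 2, 3]), cutoff=0.0)


class TestBootstrapFWER:
    def _toy(self, seed=63):
        rng = np.random.default_rng(seed)
        n = 40
        samples = pd.DataFrame(
            {
                "status": ["case"] * 20 + ["control"] * 20,
                "sex": list(rng.choice(["F", "M"], size=n)),
                "cohort": ["adult"] * n,
            }
        )
        values = rng.normal(0.5, 0.03, size=(30, n))
        return values, samples

    def test_deterministic_for_fixed_seed(self):
        values, samples = self._toy()
        probes = _probes(list(range(100, 3100, 100)))
        cids = np.zeros(30, dtype=int)
        from methdmr.bumphunter import CandidateBump

        cand = [CandidateBump(chrom="chr1", start=100, end=500, area=0.5)]
        a = bootstrap_fwer(values, samples, [cand[0]], 0.02, cids, B=50, seed=7)
        values2, samples2 = self._toy()
        cand2 = [CandidateBump(chrom="chr1", start=100, end=500, area=0.5)]
        b = bootstrap_fwer(values2, samples2, [cand2[0]], 0.02, cids, B=50, seed=7)
        assert a[0].fwer == b[0].fwer
        assert a[0].p_boot == b[0].p_boot

    def test_huge_area_gets_fwer_zero(self):
        values, samples = self._toy()
        cids = np.zeros(30, dtype=int)
        from methdmr.bumphunter import CandidateBump

        c = CandidateBump(chrom="chr1", start=1, end=2, area=1e9)
        out = bootstrap_fwer(values, samples, [c], 0.02, cids, B=30, seed=1)
        assert out[0].fwer == 0.0

    def test_invalid_b_raises(self):
        values, samples = self._toy()
        with pytest.raises(ValueError):
            bootstrap_fwer(values, samples, [], 0.02, np.zeros(30, dtype=int), B=0)


class TestBumpHunterEstimator:
    def test_recovers_spiked_cluster(self):
        man = generate_manifest(3000, seed=64)
        spikes = choose_spike_regions(man, 2, delta_beta=0.15, n_probes=12, seed=64)
        ds, truth = simulate_dataset(man, spikes=spikes, seed=64)
        model = BumpHunter(cutoff_quantile=0.98, B=50, seed=64).fit(ds)
        sig = model.table_[model.table_["fwer"] <= 0.2]
        found = 0
        for sp in truth:
            hit = (
                (sig["chrom"] == sp.chrom)
                & (sig["start"] <= sp.end)
                & (sig["end"] >= sp.start)
            )
            found += int(hit.any())
        assert found == len(truth)
        # directions follow the spiked signs
        for sp in truth:
            hit = sig[
                (sig["chrom"] == sp.chrom)
                & (sig["start"] <= sp.end)
                & (sig["end"] >= sp.start)
            ]
            want = "hypermethylated" if sp.delta_beta > 0 else "hypomethylated"
            assert want in set(hit["direction"])

    def test_null_yields_no_confident_bumps(self):
        man = generate_manifest(2000, seed=65)
        ds, _ = simulate_dataset(man, seed=65)
        model = BumpHunter(cutoff_quantile=0.99, B=50, seed=65).fit(ds)
        sig = model.table_[model.table_["fwer"] <= 0.05]
        assert len(sig) == 0
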