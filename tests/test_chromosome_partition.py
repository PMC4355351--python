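from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from txatlas import chromosome_partition as cp
from txatlas.models import RegionTable

REGIONS = RegionTable([("R1", 0, 1000), ("C", 1000, 2000), ("R3", 2000, 3000)])


class TestWindowedDensity:
    def test_counts_and_units(self):
        track = cp.windowed_density([500_000, 1_500_000, 1_500_001],
                                    chrom_length=3_000_000,
                                    window=1_000_000, step=1_000_000)
        assert track.n_windows == 3
        assert list(track.values) == [1.0, 2.0, 0.0]

    def test_half_open_boundary(self):
        track = cp.windowed_density([1_000_000], chrom_length=2_000_000,
                                    window=1_000_000, step=1_000_000)
        assert list(track.values) == [0.0, 1.0]

    def test_sliding_overlap(self):
        track = cp.windowed_density([5_000_000], chrom_length=20_000_000,
                                    window=10_000_000, step=1_000_000)
        assert track.n_windows == 11
        assert (track.values[:6] > 0).all() and (track.values[6:] == 0).all()

    def test_window_longer_than_chromosome_warns(self, caplog):
        with caplog.at_level("WARNING"):
            track = cp.windowed_density([100], 1_000, window=10_000, step=500)
        assert track.n_windows == 1
        assert "using one window" in caplog.text

    def test_mass_conservation_when_tiling(self):
        rng = np.random.default_rng(0)
        mids = rng.integers(0, 10_000_000, 500)
        track = cp.windowed_density(mids, 10_000_000,
                                    window=1_000_000, step=1_000_000)
        assert track.values.sum() * 1.0 == pytest.approx(len(mids))


class TestZscore:
    def test_two_values(self):
        track = cp.windowed_density([], 2_000_000, 1_000_000, 1_000_000)
        track.values = np.array([0.0, 10.0])
        cp.zscore(track)
        assert track.zscores == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_series(self):
        track = cp.windowed_density([], 3_000_000, 1_000_000, 1_000_000)
        track.values = np.full(3, 4.0)
        assert (cp.zscore(track).zscores == 0).all()

    def test_needs_two_windows(self):
        track = cp.windowed_density([], 1_000_000, 1_000_000, 1_000_000)
        with pytest.raises(ValueError):
            cp.zscore(track)


class TestRegions:
    def test_half_open_except_last(self):
        assert cp.assign_region(0, REGIONS) == "R1"
        assert cp.assign_region(1000, REGIONS) == "C"
        assert cp.assign_region(1999.9, REGIONS) == "C"
        assert cp.assign_region(3000, REGIONS) == "R3"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cp.assign_region(-1, REGIONS)
        with pytest.raises(ValueError):
            cp.assign_region(3001, REGIONS)

    def test_region_density(self):
        df = cp.region_density([100, 200, 1500], REGIONS)
        assert list(df["n"]) == [2, 1, 0]
        assert df["density_per_mb"].iloc[0] == pytest.approx(2 / 0.001)

    def test_distance_to_centromere(self):
        d = cp.distance_to_centromere([0, 1500, 3000], REGIONS)
        assert list(d) == [1500.0, 0.0, 1500.0]
        with pytest.raises(ValueError, match="no region named"):
            cp.distance_to_centromere([0], REGIONS, centromere_region="X")


class TestSegmentation:
    def test_clean_two_step(self):
        x = np.concatenate([np.full(20, 2.0), np.full(20, 8.0), np.full(20, 1.0)])
        rng = np.random.default_rng(3)
        seg = cp.binary_segmentation(x + rng.normal(0, 0.3, 60),
                                     step_bp=1_000_000)
        assert seg.changepoints == [19, 39]
        assert seg.changepoint_bp == [20_000_000, 40_000_000]
        assert len(seg.segment_means) == 3
        assert seg.segment_means[1] == pytest.approx(8.0, abs=0.5)

    def test_constant_series_no_changepoints(self):
        seg = cp.binary_segmentation(np.full(30, 5.0))
        assert seg.changepoints == []
        assert seg.segment_means == [5.0]

    def test_pure_noise_rarely_splits(self):
        rng = np.random.default_rng(0)
        n_cp = sum(
            len(cp.binary_segmentation(rng.normal(0, 1, 60)).changepoints)
            for _ in range(20)
        )
        assert n_cp <= 4  # BIC penalty keeps false positives rare

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cp.binary_segmentation([1.0, 2.0])
        with pytest.raises(ValueError, match="BIC"):
            cp.binary_segmentation(np.arange(10.0), penalty="AIC")

    def test_best_single_split_exact(self):
        x = np.array([0.0] * 10 + [5.0] * 10)
        k, gain = cp.best_single_split(x)
        assert k == 9 and gain == pytest.approx(10 * 10 * 2.5**2 / 5)


class TestRegionStats:
    def test_welch_and_skip(self, caplog):
        rng = np.random.default_rng(0)
        ids = [f"g{i}" for i in range(40)]
        pos = pd.Series([100] * 20 + [1500] * 19 + [2500], index=ids)
        feat = pd.DataFrame(
            {"x": np.concatenate([rng.normal(0, 1, 20),
                                  rng.normal(5, 1, 19), [0.0]])},
            index=ids,
        )
        with caplog.at_level("INFO"):
            summ, tests = cp.region_feature_stats(feat, pos, REGIONS)
        assert len(summ) == 3
        t = tests[(tests["region_a"] == "R1") & (tests["region_b"] == "C")]
        assert t["p"].iloc[0] < 1e-6
        # R3 has one gene: every pair involving it is skipped
        assert not ((tests["region_a"] == "R3") | (tests["region_b"] == "R3")).any()


class TestGradientsAndFit:
    def test_spearman_monotone(self):
        rho, p = cp.spearman_gradient([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_spearman_constant_error(self):
        with pytest.raises(ValueError, match="constant vector"):
            cp.spearman_gradient([1, 1, 1, 1], [1, 2, 3, 4])

    def test_chi2_identical_distributions(self):
        rng = np.random.default_rng(0)
        mids = rng.integers(0, 50_000_000, 400)
        chi2, df = cp.distribution_fit_chi2(mids, mids, 50_000_000,
                                            window=10_000_000, step=10_000_000)
        assert chi2 == pytest.approx(0.0)
        assert df == 4

    def test_chi2_shifted_distribution_large(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 10_000_000, 300)
        b = rng.integers(40_000_000, 50_000_000, 300)
        chi2, _ = cp.distribution_fit_chi2(a, np.concatenate([a, b]),
                                           50_000_000, 10_000_000, 10_000_000)
        assert chi2 > 100


def test_synthetic_density_gradient(ts_dataset):
    cfg = ts_dataset.config
    truth = ts_dataset.truth["loci"]
    mids = [g.midpoint for g in ts_dataset.genes if truth[g.gene_id]["expressed"]]
    dens = cp.region_density(mids, cfg.regions).set_index("region")["density_per_mb"]
    assert dens["R1"] > dens["R2a"] > dens["C"]
    assert dens["C"] < dens["R2b"] < dens["R3"]
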