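"""Synthetic-data generator: point process, photometry, rendering, output."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import small_sim_config
from stedclust import (
    PixelImage,
    SimConfig,
    render_image,
    render_signal,
    sample_positions,
    write_dataset,
)
from stedclust.errors import ValidationError
from stedclust.simulate import sample_crowding_counts


class TestSamplePositions:
    def test_csr_count_is_poisson_with_analytic_mean(self):
        # 25.6 µm field at 4/µm² -> lambda = 2621.44
        cfg_kw = dict(
            image_size_px=(1280, 1280), density_per_um2=4.0, crowd_fraction=0.0
        )
        lam = 4.0 * (1280 * 20 / 1000.0) ** 2
        counts = [
            len(sample_positions(SimConfig(seed=s, **cfg_kw))) for s in range(100)
        ]
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_degenerate_composition_all_both(self):
        cfg = small_sim_config(frac_both=1.0, frac_a_only=0.0, frac_b_only=0.0)
        truth = sample_positions(cfg)
        assert (truth.table["membership"] == "both").all()

    def test_fully_crowded_children_per_crowd(self):
        # large field; interior crowds (child centroid > 5 sigma from the
        # border) are unaffected by the edge-discard rule
        cfg_kw = dict(
            image_size_px=(2560, 2560),
            density_per_um2=4.0,
            crowd_fraction=1.0,
            assemblies_per_crowd=10.0,
            crowd_radius_nm=450.0,
        )
        sizes = []
        for s in range(100):
            truth = sample_positions(SimConfig(seed=s, **cfg_kw))
            t = truth.table
            assert (t["crowd_id"] >= 0).all()
            g = t.groupby("crowd_id")
            cen = g[["x_nm", "y_nm"]].mean()
            margin = 5 * 450.0
            side = 2560 * 20.0
            interior = (
                (cen["x_nm"] > margin) & (cen["x_nm"] < side - margin)
                & (cen["y_nm"] > margin) & (cen["y_nm"] < side - margin)
            )
            sizes.extend(g.size()[interior].tolist())
        se = np.sqrt(10.0 / len(sizes))
        assert abs(np.mean(sizes) - 10.0) < 3 * se

    def test_positions_inside_field(self):
        cfg = small_sim_config(crowd_fraction=0.5, assemblies_per_crowd=8.0)
        t = sample_positions(cfg).table
        w, h = cfg.field_size_nm
        assert ((t.x_nm >= 0) & (t.x_nm < w) & (t.y_nm >= 0) & (t.y_nm < h)).all()

    def test_seed_determinism(self):
        cfg = small_sim_config(crowd_fraction=0.3)
        a = sample_positions(cfg).table
        b = sample_positions(cfg).table
        assert a.equals(b)

    def test_composition_recovery_at_large_n(self):
        cfg = SimConfig(image_size_px=(2560, 2560), density_per_um2=4.0, seed=11)
        t = sample_positions(cfg).table  # ~10500 assemblies
        assert len(t) >= 10_000
        assert abs((t.membership == "both").mean() - cfg.frac_both) < 0.02

    def test_csr_nearest_neighbor_distribution(self):
        # interior-point NN distances against 1 - exp(-lambda*pi*r^2);
        # query points are thinned 4x because mutual-neighbour pairs make
        # the full set of NN distances dependent, which a KS test assumes away
        lam_nm2 = 4.0 / 1e6
        cdf = lambda r: 1.0 - np.exp(-lam_nm2 * np.pi * np.asarray(r) ** 2)
        passed = 0
        from scipy.spatial import cKDTree

        for s in range(100):
            cfg = SimConfig(
                image_size_px=(1280, 1280), seed=s,
                density_per_um2=4.0, crowd_fraction=0.0,
            )
            xy = sample_positions(cfg).table[["x_nm", "y_nm"]].to_numpy()
            tree = cKDTree(xy)
            d, _ = tree.query(xy, k=2)
            side = 1280 * 20.0
            interior = (
                (xy[:, 0] > 1000) & (xy[:, 0] < side - 1000)
                & (xy[:, 1] > 1000) & (xy[:, 1] < side - 1000)
            )
            if sps.kstest(d[interior, 1][::4], cdf).pvalue > 0.01:
                passed += 1
        assert passed >= 95

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            small_sim_config(frac_both=0.9)  # fractions no longer sum to 1
        with pytest.raises(ValidationError):
            small_sim_config(density_per_um2=-1.0)
        with pytest.raises(ValidationError):
            small_sim_config(psf_fwhm_nm=float("nan"))
        with pytest.raises(ValidationError):
            small_sim_config(detect_prob=0.0)


class TestRendering:
    def test_empty_field_background_is_poisson(self):
        cfg = SimConfig(
            image_size_px=(128, 128), density_per_um2=1e-9,
            background_offset=10.0, read_noise_sd=0.0, seed=5,
        )
        truth = sample_positions(cfg)
        img = render_image(truth, cfg, "A")
        se = np.sqrt(10.0 / img.values.size)
        assert abs(img.values.mean() - 10.0) < 3 * se
        assert img.values.var() == pytest.approx(10.0, rel=0.1)

    def test_single_spot_integrates_to_amplitude(self):
        cfg = small_sim_config(psf_fwhm_nm=100.0)
        truth = sample_positions(cfg)
        t = truth.table.iloc[0:0].copy()
        t.loc[0] = [0, 2560.0, 2560.0, "both", 5000.0, 0.0, -1, True, False]
        truth.table = t
        signal = render_signal(truth, cfg, "A")
        assert signal.sum() == pytest.approx(5000.0, rel=0.005)

    def test_peak_to_total_ratio_matches_gaussian_normalization(self):
        cfg = small_sim_config(psf_fwhm_nm=100.0)
        sigma_px = cfg.psf_sigma_px
        truth = sample_positions(cfg)
        t = truth.table.iloc[0:0].copy()
        # spot exactly on the centre of pixel (64, 64)
        t.loc[0] = [0, 64.5 * 20, 64.5 * 20, "both", 1000.0, 0.0, -1, True, False]
        truth.table = t
        signal = render_signal(truth, cfg, "A")
        ratio = signal.max() / signal.sum()
        # pixel integration flattens the peak slightly relative to the
        # point density 1/(2*pi*sigma^2) (~1.8% at sigma = 2.12 px)
        assert ratio == pytest.approx(1.0 / (2 * np.pi * sigma_px**2), rel=0.03)

    def test_rendering_linear_in_amplitude(self):
        cfg = small_sim_config()
        truth = sample_positions(cfg)
        doubled = sample_positions(cfg)
        doubled.table = truth.table.assign(
            amp_a=truth.table.amp_a * 2, amp_b=truth.table.amp_b * 2
        )
        np.testing.assert_allclose(
            render_signal(doubled, cfg, "A"),
            2.0 * render_signal(truth, cfg, "A"),
            rtol=1e-12,
        )

    def test_bad_channel_label_rejected(self):
        cfg = small_sim_config()
        truth = sample_positions(cfg)
        with pytest.raises(ValidationError):
            render_signal(truth, cfg, "C")

    def test_detect_prob_drops_spots_from_render_not_truth(self):
        cfg = small_sim_config(detect_prob=0.5, seed=3)
        truth = sample_positions(cfg)
        t = truth.table
        has_a = t.membership != "b_only"
        assert has_a.sum() > 20
        assert 0 < t.loc[has_a, "det_a"].sum() < has_a.sum()
        # undetected spots contribute nothing to the image
        undetected = t[has_a & ~t.det_a]
        assert len(undetected) > 0
        signal = render_signal(truth, cfg, "A")
        detected_total = t.loc[t.det_a, "amp_a"].sum()
        assert signal.sum() <= detected_total + 1e-6


class TestWriteDataset:
    def test_round_trip_and_manifest(self, tmp_path):
        import tifffile

        cfg = small_sim_config(seed=9)
        truth = sample_positions(cfg)
        images = {ch: render_image(truth, cfg, ch) for ch in ("A", "B")}
        manifest = write_dataset(truth, images, tmp_path)
        back = tifffile.imread(tmp_path / "channel_A.tif")
        np.testing.assert_array_equal(back, images["A"].values.astype(np.uint16))
        import pandas as pd

        table = pd.read_csv(tmp_path / "truth.csv")
        assert len(table) == len(truth)
        assert set(manifest["files"]) == {
            "channel_A.tif", "channel_B.tif", "truth.csv", "config.toml",
        }

    def test_byte_identical_outputs_for_identical_config(self, tmp_path):
        cfg = small_sim_config(seed=21)
        for sub in ("one", "two"):
            truth = sample_positions(cfg)
            images = {ch: render_image(truth, cfg, ch) for ch in ("A", "B")}
            write_dataset(truth, images, tmp_path / sub)
        for name in ("channel_A.tif", "channel_B.tif", "truth.csv", "config.toml", "manifest.json"):
            assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()

    def test_checksum_tracks_content(self, tmp_path):
        cfg1, cfg2 = small_sim_config(seed=1), small_sim_config(seed=2)
        m1 = write_dataset(
            sample_positions(cfg1),
            {"A": render_image(sample_positions(cfg1), cfg1, "A")},
            tmp_path / "a",
        )
        m2 = write_dataset(
            sample_positions(cfg2),
            {"A": render_image(sample_positions(cfg2), cfg2, "A")},
            tmp_path / "b",
        )
        assert m1["files"]["channel_A.tif"] != m2["files"]["channel_A.tif"]
        assert m1["files"]["truth.csv"] != m2["files"]["truth.csv"]


def test_crowding_counts_mixture_moments(rng):
    counts = sample_crowding_counts(20000, 0.32, rng=rng)
    assert counts.min() >= 0
    expected_mean = 0.68 * 3.5 + 0.32 * 12.0
    assert np.mean(counts) == pytest.approx(expected_mean, rel=0.05)
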