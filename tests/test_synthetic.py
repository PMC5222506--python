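"""Generators: determinism, ground-truth bookkeeping, density contracts."""

import dataclasses

import numpy as np
import pytest

from coneflow.angio import AnnulusSpec, annulus_membership
from coneflow.synthetic import (
    CohortSimConfig,
    SyntheticAngioConfig,
    SyntheticMosaicConfig,
    carve_lesion,
    generate_angiogram,
    generate_cohort,
    generate_mosaic,
    generate_mosaic_points,
    lattice_sites,
)
from oracles import disk_pixel_count, lattice_count_loop


class TestMosaic:
    def test_unperturbed_count_matches_lattice_enumeration(self):
        """With no jitter/dropout the cone count equals a direct loop
        over triangular-lattice indices (spec'd 8 um spacing, 1.445
        um/px, 200x200 ROI), and across other geometries."""
        for w, h, um, spacing in [
            (200, 200, 1.445, 8.0),
            (150, 220, 1.445, 8.0),
            (200, 200, 2.0, 7.0),
        ]:
            cfg = SyntheticMosaicConfig(
                roi_width_px=w, roi_height_px=h, um_per_px=um,
                lattice_spacing_um=spacing, jitter_sd_frac=0.0,
                dropout_frac=0.0, seed=0,
            )
            points, _ = generate_mosaic(cfg)
            assert len(points) == lattice_count_loop(w, h, um, spacing)

    def test_same_seed_bit_identical(self):
        cfg = SyntheticMosaicConfig(jitter_sd_frac=0.1, dropout_frac=0.2,
                                    seed=42)
        p1, img1 = generate_mosaic(cfg)
        p2, img2 = generate_mosaic(cfg)
        np.testing.assert_array_equal(p1.points, p2.points)
        np.testing.assert_array_equal(img1, img2)

    def test_different_seed_differs(self):
        cfg = SyntheticMosaicConfig(jitter_sd_frac=0.1, seed=1)
        cfg2 = dataclasses.replace(cfg, seed=2)
        assert not np.array_equal(generate_mosaic_points(cfg).points,
                                  generate_mosaic_points(cfg2).points)

    def test_unresolvable_spacing_rejected(self):
        cfg = SyntheticMosaicConfig(lattice_spacing_um=2.0, um_per_px=1.445)
        with pytest.raises(ValueError, match="unresolvable"):
            generate_mosaic_points(cfg)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            generate_mosaic_points(SyntheticMosaicConfig(dropout_frac=1.5))
        with pytest.raises(ValueError):
            generate_mosaic_points(
                SyntheticMosaicConfig(lesion_dropouts=[(50, 50, 20, 1.7)]))

    def test_dropout_mean_count_within_binomial_se(self):
        """Mean realized cone count over 50 seeds stays within 3
        binomial SEs of lattice_count * (1 - dropout)."""
        base = SyntheticMosaicConfig(jitter_sd_frac=0.05, dropout_frac=0.3)
        n_lattice = len(lattice_sites(base))
        counts = [
            len(generate_mosaic_points(dataclasses.replace(base, seed=s)))
            for s in range(50)
        ]
        expected = n_lattice * 0.7
        se = np.sqrt(n_lattice * 0.3 * 0.7)
        assert abs(np.mean(counts) - expected) <= 3 * se / np.sqrt(50)

    def test_lesion_dropout_removes_only_inside(self):
        lesion = (144.5, 144.5, 60.0, 1.0)  # certain deletion in the disc
        cfg = SyntheticMosaicConfig(jitter_sd_frac=0.0, dropout_frac=0.0,
                                    lesion_dropouts=[lesion], seed=3)
        pts = generate_mosaic_points(cfg)
        full = generate_mosaic_points(
            dataclasses.replace(cfg, lesion_dropouts=[]))
        center_px = np.array([lesion[0], lesion[1]]) / cfg.um_per_px
        r_px = lesion[2] / cfg.um_per_px
        d = np.hypot(*(pts.points - center_px).T)
        assert (d > r_px).all()
        d_full = np.hypot(*(full.points - center_px).T)
        assert len(pts) == len(full) - int((d_full <= r_px).sum())

    def test_rendered_image_range_and_shape(self):
        cfg = SyntheticMosaicConfig(seed=5)
        _, img = generate_mosaic(cfg)
        assert img.shape == (cfg.roi_height_px, cfg.roi_width_px)
        assert img.min() >= 0.0 and img.max() <= 255.0
        assert img.max() > cfg.background_level  # spots visible


class TestAngiogram:
    def test_saturated_field_all_ones(self):
        cfg = SyntheticAngioConfig(target_density_pct=100.0, seed=0)
        mask, lesions = generate_angiogram(cfg)
        assert mask.all() and lesions == []

    def test_annulus_density_within_two_points_of_target(self):
        for target in (35.0, 55.0, 70.0):
            cfg = SyntheticAngioConfig(target_density_pct=target, seed=9)
            mask, _ = generate_angiogram(cfg)
            ann = AnnulusSpec(center=((cfg.image_size_px - 1) / 2.0,) * 2)
            member = annulus_membership(mask.shape, ann, cfg.um_per_px)
            density = 100.0 * (mask & member).sum() / member.sum()
            assert abs(density - target) <= 2.0

    def test_lesion_interiors_carved_to_nonvessel(self):
        cfg = SyntheticAngioConfig(
            target_density_pct=60.0,
            lesion_specs=[(1000.0, 1200.0, 150.0), (2000.0, 900.0, 220.0)],
            seed=4,
        )
        mask, lesions = generate_angiogram(cfg)
        assert [r["diameter_um"] for r in lesions] == [150.0, 220.0]
        yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]].astype(float)
        for cx, cy, diam in cfg.lesion_specs:
            inside = (
                (xx - cx / cfg.um_per_px) ** 2 + (yy - cy / cfg.um_per_px) ** 2
                <= (diam / 2.0 / cfg.um_per_px) ** 2
            )
            assert not mask[inside].any()

    def test_carve_disk_pixel_count_matches_loop_oracle(self):
        """Planting a 150 um lesion in an all-ones mask removes exactly
        the rasterized-disk pixel count."""
        um_per_px = 10.0
        mask = np.ones((120, 120), dtype=bool)
        carved = carve_lesion(mask, 600.0, 500.0, 150.0, um_per_px)
        removed = int(mask.sum() - carved.sum())
        assert removed == disk_pixel_count(
            mask.shape, 600.0 / um_per_px, 500.0 / um_per_px,
            75.0 / um_per_px)

    def test_carving_idempotent(self):
        cfg = SyntheticAngioConfig(target_density_pct=55.0, seed=2)
        mask, _ = generate_angiogram(cfg)
        once = carve_lesion(mask, 1500.0, 1500.0, 300.0, cfg.um_per_px)
        twice = carve_lesion(once, 1500.0, 1500.0, 300.0, cfg.um_per_px)
        np.testing.assert_array_equal(once, twice)

    def test_same_seed_identical_masks(self):
        cfg = SyntheticAngioConfig(seed=7)
        m1, _ = generate_angiogram(cfg)
        m2, _ = generate_angiogram(cfg)
        np.testing.assert_array_equal(m1, m2)

    def test_lesions_on_degenerate_field_rejected(self):
        for target in (0.0, 100.0):
            cfg = SyntheticAngioConfig(target_density_pct=target,
                                       lesion_specs=[(1500.0, 1500.0, 150.0)])
            with pytest.raises(ValueError, match="undetectable"):
                generate_angiogram(cfg)

    def test_lesion_outside_image_rejected(self):
        cfg = SyntheticAngioConfig(lesion_specs=[(40.0, 1500.0, 200.0)])
        with pytest.raises(ValueError, match="inside the image"):
            generate_angiogram(cfg)


class TestCohort:
    def test_zero_sd_gives_exact_group_means(self):
        cfg = CohortSimConfig(hpi_sd_normal=0.0, hpi_sd_nonflow=0.0,
                              density_sd_normal=0.0, density_sd_nonflow=0.0,
                              missing_density_count=0, seed=11)
        table = generate_cohort(cfg)
        normal = table[table["group"] == "normal_dcp"]
        nonflow = table[table["group"] == "dcp_nonflow"]
        assert (normal["hpi"] == cfg.hpi_mean_normal).all()
        assert (nonflow["hpi"] == cfg.hpi_mean_nonflow).all()
        assert (normal["dcp_density_pct"] == cfg.density_mean_normal).all()

    def test_row_and_missing_cell_bookkeeping(self):
        cfg = CohortSimConfig(n_normal=3, n_nonflow=8,
                              missing_density_count=1, seed=0)
        table = generate_cohort(cfg)
        assert len(table) == 11
        assert table["dcp_density_pct"].isna().sum() == 1
        assert (table.loc[table["dcp_density_pct"].isna(), "group"]
                == "dcp_nonflow").all()
        assert (table["group"].value_counts()["normal_dcp"] == 3)

    def test_large_sample_means_match_configured_distribution(self):
        """Monte-Carlo: with n=200/group over 50 seeds, sample group
        means stay within 3 SEs of the configured means."""
        base = CohortSimConfig(n_normal=200, n_nonflow=200,
                               missing_density_count=0)
        hpi_means = []
        dens_means = []
        for seed in range(50):
            t = generate_cohort(dataclasses.replace(base, seed=seed))
            g = t[t["group"] == "dcp_nonflow"]
            hpi_means.append(g["hpi"].mean())
            dens_means.append(g["dcp_density_pct"].mean())
        se_hpi = base.hpi_sd_nonflow / np.sqrt(200 * 50)
        se_dens = base.density_sd_nonflow / np.sqrt(200 * 50)
        assert abs(np.mean(hpi_means) - base.hpi_mean_nonflow) <= 3 * se_hpi
        assert abs(np.mean(dens_means) - base.density_mean_nonflow) <= 3 * se_dens

    def test_deterministic_under_seed(self):
        cfg = CohortSimConfig(seed=123)
        t1, t2 = generate_cohort(cfg), generate_cohort(cfg)
        assert t1.equals(t2)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortSimConfig(n_normal=1))
        with pytest.raises(ValueError):
            generate_cohort(CohortSimConfig(hpi_sd_normal=-0.1))
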