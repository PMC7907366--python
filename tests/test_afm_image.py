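"""Height-map IO, flattening, segmentation, morphometry, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conformetry.afm_image import (HeightMap, analyze_heightmap,
                                   classify_conformation, flatten,
                                   measure_particle, measure_particles,
                                   read_heightmap, segment, tip_correct,
                                   write_heightmap)


class TestIO:
    def test_text_matrix(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 0\n0 1\n")
        hm = read_heightmap(p, pixel_nm=4.0)
        assert hm.values.shape == (2, 2)
        assert hm.values.max() == 1.0
        assert hm.pixel_nm == 4.0

    def test_tiff_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        hm = HeightMap(rng.random((16, 16)).astype(np.float32), 2.0)
        path = write_heightmap(hm, tmp_path / "m.tif")
        back = read_heightmap(path)
        np.testing.assert_array_equal(back.values, hm.values)
        assert back.pixel_nm == 2.0

    def test_argument_overrides_sidecar(self, tmp_path):
        hm = HeightMap(np.zeros((4, 4)), 2.0)
        path = write_heightmap(hm, tmp_path / "m.txt")
        assert read_heightmap(path).pixel_nm == 2.0
        assert read_heightmap(path, pixel_nm=7.0).pixel_nm == 7.0

    def test_missing_pixel_size_rejected(self, tmp_path):
        p = tmp_path / "bare.txt"
        np.savetxt(p, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="pixel size"):
            read_heightmap(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_heightmap(tmp_path / "nope.txt", pixel_nm=1.0)

    def test_non_rectangular_rejected(self, tmp_path):
        p = tmp_path / "ragged.txt"
        p.write_text("0 1 2\n0 1\n")
        with pytest.raises(ValueError):
            read_heightmap(p, pixel_nm=1.0)


class TestFlatten:
    def test_exact_plane_removed(self):
        cols, rows = np.meshgrid(np.arange(64.0), np.arange(64.0))
        hm = HeightMap(0.05 * cols + 0.02 * rows + 3.0, 1.0)
        out = flatten(hm)
        assert np.max(np.abs(out.values)) < 1e-9

    def test_idempotent(self, rendered_scene):
        hmap, _ = rendered_scene
        once = flatten(hmap)
        twice = flatten(once)
        assert np.max(np.abs(twice.values - once.values)) < 1e-6

    def test_tilt_recovery_matches_lstsq_oracle(self):
        """The fitted background agrees with a least-squares plane fit
        restricted to true background pixels to within 1 %."""
        rng = np.random.default_rng(7)
        n = 128
        cols, rows = np.meshgrid(np.arange(float(n)), np.arange(float(n)))
        a, b = 0.03, -0.015
        vals = a * cols + b * rows + rng.normal(0, 0.05, (n, n))
        bump = np.zeros((n, n))
        bump[40:60, 40:60] = 2.0       # a particle that must not bias the fit
        hm = HeightMap(vals + bump, 1.0)
        out = flatten(hm).values
        # oracle: plane fit on background-only pixels of the raw map
        bg = bump == 0
        design = np.column_stack([np.ones(bg.sum()), cols[bg], rows[bg]])
        coef, *_ = np.linalg.lstsq(design, vals[bg], rcond=None)
        residual_oracle = vals[bg] - design @ coef
        # flatten's background must be as flat as the oracle's residual
        assert np.std(out[bg]) < 1.01 * np.std(residual_oracle)
        # the particle survives levelling
        assert out[40:60, 40:60].max() > 1.5

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError):
            flatten(HeightMap(np.zeros((4, 4)), 1.0), line_order=3)


def _bruteforce_components(mask: np.ndarray) -> int:
    """Flood-fill (8-connected) component count, independent of skimage."""
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    for i, j in zip(*np.nonzero(mask)):
        if seen[i, j]:
            continue
        n += 1
        stack = [(i, j)]
        seen[i, j] = True
        while stack:
            a, b = stack.pop()
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    x, y = a + da, b + db
                    if (0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]
                            and mask[x, y] and not seen[x, y]):
                        seen[x, y] = True
                        stack.append((x, y))
    return n


class TestSegment:
    def test_flat_map_no_particles(self):
        hm = HeightMap(np.zeros((64, 64)), 1.0)
        assert segment(hm).n_components == 0

    def test_three_blobs_against_floodfill_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.05, (96, 96))
        for r, c in ((20, 20), (20, 70), (70, 45)):
            vals[r - 3:r + 4, c - 3:c + 4] += 2.0
        hm = HeightMap(vals, 1.0)
        seg = segment(hm)
        mask = seg.labels > 0
        assert seg.n_components == _bruteforce_components(mask)
        # the three seeded blobs dominate the component list
        areas = np.bincount(seg.labels.ravel())[1:]
        assert (areas >= 40).sum() == 3

    def test_border_blob_marked_excluded(self):
        vals = np.zeros((64, 64))
        vals[0:6, 30:36] = 2.0         # touches row 0
        vals[30:36, 30:36] = 2.0
        hm = HeightMap(vals, 1.0)
        seg = segment(hm)
        table = measure_particles(seg, hm)
        assert len(table) == 2
        border = table[table.touches_border]
        assert len(border) == 1
        assert (border.label == "excluded").all()
        assert (~table.touches_border).sum() == 1


class TestMeasureParticle:
    def test_single_pixel_R_is_one(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        hm = HeightMap(mask * 1.5, 1.0)
        rec = measure_particle(mask, hm)
        assert rec.aspect_ratio == 1.0
        assert rec.max_height_nm == 1.5

    def test_rasterized_ellipse_moment_axes(self):
        """A 40 x 20 nm ellipse measures R = 2.0 +- 0.1 via the
        moment-equivalent ellipse axes."""
        cols, rows = np.meshgrid(np.arange(64.0), np.arange(64.0))
        mask = ((cols - 32) / 20.0) ** 2 + ((rows - 32) / 10.0) ** 2 <= 1.0
        hm = HeightMap(mask.astype(float), 1.0)
        rec = measure_particle(mask, hm)
        assert rec.aspect_ratio == pytest.approx(2.0, abs=0.1)
        assert rec.length_nm == pytest.approx(40.0, rel=0.05)

    def test_rasterized_circle(self):
        cols, rows = np.meshgrid(np.arange(48.0), np.arange(48.0))
        mask = (cols - 24) ** 2 + (rows - 24) ** 2 <= 15.0**2
        hm = HeightMap(mask.astype(float), 1.0)
        rec = measure_particle(mask, hm)
        assert rec.aspect_ratio == pytest.approx(1.0, abs=0.05)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            measure_particle(np.zeros((4, 4), dtype=bool),
                             HeightMap(np.zeros((4, 4)), 1.0))


class TestClassify:
    @pytest.mark.parametrize("R,label", [
        (1.0, "closed"), (2.0, "closed"), (3.0, "closed"),
        (3.0001, "open"), (5.0, "open"), (10.0, "open"),
        (10.5, "excluded"), (12.0, "excluded"),
    ])
    def test_boundaries(self, R, label):
        assert classify_conformation(R) == label

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            classify_conformation(0.5)

    @given(st.floats(min_value=1.0, max_value=100.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, R):
        """Every finite R >= 1 maps to exactly one label."""
        label = classify_conformation(R)
        assert label in ("closed", "open", "excluded")
        assert (label == "closed") == (R <= 3.0)
        assert (label == "open") == (3.0 < R <= 10.0)
        assert (label == "excluded") == (R > 10.0)


class TestAnalyzePipeline:
    def test_count_conservation(self, rendered_scene):
        hmap, _ = rendered_scene
        table = analyze_heightmap(hmap, tip_radius_nm=8.0)
        n = len(table)
        counts = table.label.value_counts()
        assert counts.get("closed", 0) + counts.get("open", 0) \
            + counts.get("excluded", 0) == n

    def test_tip_deconvolution_recovers_true_axes(self, quiet_scan):
        """Noise-free single particles measure within 0.25 in R after
        model-based tip deconvolution."""
        from conformetry.synthetic_afm import ParticleSpec, render_heightmap
        from conformetry.synthetic_afm import _geometry_for

        for R in (1.5, 2.5, 4.0, 6.0):
            cls, L, W = _geometry_for(R)
            sp = ParticleSpec(cls, L / W, L, W, 1.8, (256.0, 256.0), 0.6)
            hmap, _ = render_heightmap([sp], quiet_scan, seed=None)
            rec = analyze_heightmap(hmap, tip_radius_nm=quiet_scan.tip_radius_nm)
            assert len(rec) == 1
            assert rec.iloc[0].aspect_ratio == pytest.approx(R, abs=0.25)

    def test_erosion_reconstruction_bounds_surface(self, rendered_scene):
        """Eroding the imaged map by the tip gives the morphological
        opening: below the image, above wherever the image is a pure
        dilation."""
        hmap, _ = rendered_scene
        flat = flatten(hmap)
        rec = tip_correct(flat, 8.0)
        assert np.all(rec.values <= flat.values + 1e-9)
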