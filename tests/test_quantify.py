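"""Quantification oracles: registration shifts, segmentation phantoms,
pixel-sum feature identities, brute-force ring geometry, artifact screening."""

import numpy as np
import pandas as pd
import pytest
import scipy.ndimage as ndi
from skimage.draw import ellipse

from senetrace import quantify as q
from senetrace import synthetic as syn


@pytest.fixture(scope="module")
def textured():
    rng = np.random.default_rng(1)
    return ndi.gaussian_filter(rng.gamma(2, 50, (256, 256)), 3)


class TestRegistration:
    def test_identical_images(self, textured):
        reg = q.register_rounds(textured, textured)
        assert reg.offset == (0, 0)
        assert reg.score == pytest.approx(1.0)
        assert reg.ok

    def test_recovers_constructed_shift(self, textured):
        moving = q.apply_shift(textured, (5, -3))
        assert q.register_rounds(textured, moving).offset == (5, -3)

    def test_inverse_consistency(self, textured):
        moving = q.apply_shift(textured, (5, -3))
        fwd = q.register_rounds(textured, moving).offset
        bwd = q.register_rounds(moving, textured).offset
        assert (fwd[0], fwd[1]) == (-bwd[0], -bwd[1])

    def test_within_one_pixel_under_noise(self, textured):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            moving = q.apply_shift(textured, (5, -3)) + rng.normal(
                0, 0.1 * textured.std(), textured.shape)
            dy, dx = q.register_rounds(textured, moving).offset
            hits += abs(dy - 5) <= 1 and abs(dx + 3) <= 1
        assert hits == 20

    def test_constant_image_flagged(self, textured):
        with pytest.warns(UserWarning, match="constant"):
            reg = q.register_rounds(textured, np.ones_like(textured))
        assert not reg.ok

    def test_dimension_mismatch_rejected(self, textured):
        with pytest.raises(ValueError, match="dimensions"):
            q.register_rounds(textured, textured[:-1])


class TestSegmentNuclei:
    def test_disjoint_ellipses_one_label_each(self):
        img = np.zeros((300, 300))
        rng = np.random.default_rng(3)
        for i in range(10):
            r, c = 30 + 60 * (i // 4), 40 + 70 * (i % 4)
            rr, cc = ellipse(r, c, 11, 9, shape=img.shape)
            img[rr, cc] = 80 + 10 * rng.random()
        labels = q.segment_nuclei(img)
        # connected-components oracle
        cc_truth, n_truth = ndi.label(img > 0)
        assert n_truth == 10
        assert len(np.unique(labels)) - 1 == 10

    def test_blank_field(self):
        with pytest.warns(UserWarning, match="empty"):
            labels = q.segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0

    def test_touching_ellipses_split_by_watershed(self):
        img = np.zeros((80, 120))
        rr, cc = ellipse(40, 40, 16, 14)
        img[rr, cc] = 100
        rr, cc = ellipse(40, 68, 16, 14)
        img[rr, cc] = 100
        assert len(np.unique(q.segment_nuclei(img))) - 1 == 2


class TestNuclearFeatures:
    def test_uniform_field(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[5:15, 5:15] = 1
        chan = np.full((20, 20), 2.5)
        row = q.nuclear_features(mask, chan).iloc[0]
        assert row["area"] == 100
        assert row["mean"] == pytest.approx(2.5)
        assert row["total"] == pytest.approx(250.0)

    def test_single_pixel_total_is_value(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 2] = 1
        chan = np.zeros((5, 5))
        chan[2, 2] = 7.25
        assert q.nuclear_features(mask, chan).iloc[0]["total"] == pytest.approx(7.25)

    def test_total_equals_pixel_sum_oracle(self, rng):
        mask = (rng.random((50, 50)) < 0.3).astype(int) * 1
        mask[:25] *= 2  # labels 1 and 2
        chan = rng.gamma(2, 10, (50, 50))
        feats = q.nuclear_features(mask, chan).set_index("label")
        for lab in (1, 2):
            assert feats.loc[lab, "total"] == pytest.approx(
                chan[mask == lab].sum(), rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            q.nuclear_features(np.zeros((4, 4), int), np.zeros((5, 5)))


def brute_force_ring(mask, width):
    """Independent ring construction by exhaustive pixel scan."""
    h, w = mask.shape
    labels = sorted(set(mask.ravel()) - {0})
    out = np.zeros_like(mask, dtype=int)
    for y in range(h):
        for x in range(w):
            if mask[y, x] != 0:
                continue
            best, best_d = 0, width + 1
            for lab in labels:
                ys, xs = np.nonzero(mask == lab)
                d = np.max(
                    np.abs(np.stack([ys - y, xs - x])), axis=0).min()
                if d < best_d or (d == best_d and 0 < lab < best):
                    if d <= width:
                        best, best_d = lab, d
            out[y, x] = best
    return out


class TestCytoplasmRing:
    def test_isolated_square_ring_area(self):
        mask = np.zeros((40, 40), dtype=int)
        mask[15:25, 15:25] = 1  # 10x10 square
        ring = q.cytoplasm_ring(mask, width_px=5)
        assert (ring == 1).sum() == 20 * 20 - 10 * 10  # 300 px
        np.testing.assert_array_equal(ring, brute_force_ring(mask, 5))

    def test_far_apart_nuclei_have_disjoint_rings(self):
        mask = np.zeros((60, 60), dtype=int)
        mask[5:12, 5:12] = 1
        mask[40:47, 40:47] = 2
        ring = q.cytoplasm_ring(mask, 5)
        assert set(np.unique(ring)) == {0, 1, 2}
        assert ((ring == 1) & (ring == 2)).sum() == 0

    def test_border_clipping(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[0:8, 0:8] = 1  # touches two borders
        ring = q.cytoplasm_ring(mask, 5)
        np.testing.assert_array_equal(ring, brute_force_ring(mask, 5))

    def test_contested_pixels_to_nearest_then_smaller_label(self):
        mask = np.zeros((20, 40), dtype=int)
        mask[8:12, 5:9] = 1
        mask[8:12, 16:20] = 2  # 7-px gap: column 12 is exactly equidistant
        ring = q.cytoplasm_ring(mask, 5)
        np.testing.assert_array_equal(ring, brute_force_ring(mask, 5))
        mid = ring[:, 12]      # tie goes to the smaller label
        assert set(mid[mid > 0]) == {1}

    def test_ring_partition_property(self, rng):
        # rings of distinct labels are disjoint and exclude all nuclei
        mask = np.zeros((80, 80), dtype=int)
        for i, (y, x) in enumerate([(10, 10), (18, 30), (50, 50), (70, 12)], 1):
            rr, cc = ellipse(y, x, 6, 5, shape=mask.shape)
            mask[rr, cc] = i
        ring = q.cytoplasm_ring(mask, 5)
        assert (ring[mask > 0] == 0).all()


class TestScreenArtifacts:
    def _records(self):
        return pd.DataFrame({
            "cell_id": [1, 2, 3, 4],
            "nuclear_area_px": [10.0, 200.0, 300.0, 20_000.0],
            "touches_border": [False, True, False, False],
        })

    def test_reason_codes(self):
        kept, log = q.screen_artifacts(self._records(), (50, 10_000))
        assert set(kept["cell_id"]) == {3}
        reasons = dict(zip(log["cell_id"], log["reason"]))
        assert reasons == {1: "area_min", 2: "border", 4: "area_max"}

    def test_identity_when_all_pass(self):
        rec = self._records().iloc[[2]]
        kept, log = q.screen_artifacts(rec, (50, 10_000))
        pd.testing.assert_frame_equal(kept, rec)
        assert log.empty

    def test_idempotent(self):
        kept, _ = q.screen_artifacts(self._records(), (50, 10_000))
        kept2, log2 = q.screen_artifacts(kept, (50, 10_000))
        pd.testing.assert_frame_equal(kept, kept2)
        assert log2.empty

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="min"):
            q.screen_artifacts(self._records(), (100, 100))

    def test_border_touching_phantom(self):
        mask = np.zeros((60, 60), dtype=int)
        mask[0:6, 10:16] = 1          # on border
        mask[20:26, 20:26] = 2
        mask[40:46, 55:60] = 3        # on border
        rec, _ = q.quantify_scene(mask, [{"DNA": mask.astype(float),
                                          "p53": mask.astype(float)}], day=0)
        kept, log = q.screen_artifacts(rec, (1, 1000))
        assert set(kept["cell_id"]) == {2}
        assert (log["reason"] == "border").all()


class TestQuantifySceneEndToEnd:
    def test_noisefree_scene_recovered_exactly(self, noisefree_scene):
        scene = noisefree_scene
        rec, reg = q.quantify_scene(scene.mask, scene.rounds, day=11)
        truth = scene.truth.set_index("cell_id")
        rec = rec.set_index("cell_id")
        np.testing.assert_array_equal(
            rec["nuclear_area_px"].values,
            truth.loc[rec.index, "nuclear_area_px"].values)
        for m in ("p53", "IL-6"):
            np.testing.assert_allclose(
                rec[f"{m}_nuc_mean"], truth.loc[rec.index, f"{m}_nuc_mean"],
                rtol=1e-9)
            np.testing.assert_allclose(
                rec[f"{m}_cyto_mean"], truth.loc[rec.index, f"{m}_cyto_mean"],
                rtol=1e-9)

    def test_registration_table_recovers_round_offsets(self, noisefree_scene):
        scene = noisefree_scene
        _, reg = q.quantify_scene(scene.mask, scene.rounds, day=11)
        got = list(zip(reg["dy"], reg["dx"]))
        assert got == [tuple(o) for o in scene.offsets]

    def test_total_identity_exact(self, noisefree_scene):
        scene = noisefree_scene
        rec, _ = q.quantify_scene(scene.mask, scene.rounds, day=11)
        for m in ("p53", "GATA4"):
            np.testing.assert_array_equal(
                rec[f"{m}_nuc_total"].values,
                (rec["nuclear_area_px"] * rec[f"{m}_nuc_mean"]).values)
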