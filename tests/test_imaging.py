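"""Segmentation, triage and morphometry against simulator ground truth."""

import numpy as np
import pandas as pd
import pytest

from oralcyto.imaging import (
    aggregate_patient,
    cell_crops,
    evaluate_segmentation,
    extract_all_features,
    extract_features,
    segment_cells,
    segment_nuclei,
    triage_objects,
)
from oralcyto.simdata import ImageSimConfig, simulate_image


def _disk(h, w, cy, cx, r):
    yy, xx = np.mgrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestSegmentNuclei:
    def test_counts_match_truth_when_well_separated(self, small_bundle):
        labels = segment_nuclei(small_bundle.image[0])
        assert labels.max() == (small_bundle.truth["type"] == "cell").sum()

    def test_blank_channel_gives_empty_mask(self):
        assert segment_nuclei(np.zeros((128, 128))).max() == 0

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((96, 96))
        img[_disk(96, 96, 48, 36, 12)] = 0.9
        img[_disk(96, 96, 48, 58, 12)] = 0.9  # overlapping pair
        labels = segment_nuclei(img)
        assert labels.max() == 2


class TestSegmentCells:
    def test_cell_contains_nucleus_and_is_larger(self, small_bundle):
        nuclei = segment_nuclei(small_bundle.image[0])
        cells = segment_cells(small_bundle.image, nuclei)
        for lab in np.unique(nuclei[nuclei > 0]):
            owners = np.unique(cells[nuclei == lab])
            assert len(owners) == 1 and owners[0] != 0
            assert (cells == owners[0]).sum() >= (nuclei == lab).sum()

    def test_recovery_against_ground_truth(self, small_bundle):
        nuclei = segment_nuclei(small_bundle.image[0])
        cells = segment_cells(small_bundle.image, nuclei)
        m = evaluate_segmentation(small_bundle.cell_labels, small_bundle.truth,
                                  cells, nuclei)
        assert m["detection_rate"] >= 0.95
        assert m["nc_ratio_mae"] < 0.05


class TestTriage:
    def test_rules_on_synthetic_clutter(self):
        cfg = ImageSimConfig(width=768, height=768, n_cells=18,
                             cluster_fraction=0.35, artefact_count=3, seed=2)
        b = simulate_image(cfg)
        triage = triage_objects(b.cell_labels, b.nucleus_labels)
        kinds = {t.object_id: t.kind for t in triage}
        truth = b.truth.set_index("object_id")["type"]
        agree = np.mean([kinds[i] == truth[i] for i in truth.index])
        assert agree >= 0.9

    def test_nucleus_free_blob_is_artefact(self):
        cells = np.zeros((64, 64), dtype=int)
        cells[_disk(64, 64, 32, 32, 14)] = 1
        nuclei = np.zeros_like(cells)
        triage = triage_objects(cells, nuclei)
        assert triage[0].kind == "artefact"

    def test_two_nuclei_region_is_cluster(self):
        cells = np.zeros((64, 64), dtype=int)
        cells[_disk(64, 64, 32, 32, 20)] = 1
        nuclei = np.zeros_like(cells)
        nuclei[_disk(64, 64, 28, 26, 5)] = 1
        nuclei[_disk(64, 64, 36, 40, 5)] = 2
        assert triage_objects(cells, nuclei)[0].kind == "cluster"


class TestFeatures:
    def test_area_ratio_arithmetic(self):
        cell = _disk(64, 64, 32, 32, 16)
        nucleus = _disk(64, 64, 32, 32, 8)
        channels = np.ones((1, 64, 64)) * 0.5
        rec = extract_features(cell, nucleus, channels, ("DAPI",))
        # radius ratio 1/2 -> area ratio 1/4 (up to pixelation)
        assert rec.morph["nc_area_ratio"] == pytest.approx(0.25, abs=0.02)
        assert rec.morph["diameter_ratio"] == pytest.approx(0.5, abs=0.02)

    def test_circle_has_low_eccentricity(self):
        cell = _disk(100, 100, 50, 50, 20)
        nucleus = _disk(100, 100, 50, 50, 10)
        rec = extract_features(cell, nucleus, np.ones((1, 100, 100)), ("DAPI",))
        assert rec.morph["eccentricity_cell"] < 0.2
        # hull rasterisation keeps a disk's solidity near but below 1
        assert rec.morph["solidity_cell"] > 0.95

    def test_rectangle_has_exact_solidity(self):
        cell = np.zeros((60, 60), dtype=bool)
        cell[10:50, 15:45] = True
        nucleus = np.zeros_like(cell)
        nucleus[25:35, 25:35] = True
        rec = extract_features(cell, nucleus, np.ones((1, 60, 60)), ("DAPI",))
        assert rec.morph["solidity_cell"] == pytest.approx(1.0, abs=0.02)

    def test_degenerate_mask_flagged_invalid(self):
        cell = np.zeros((32, 32), dtype=bool)
        cell[5, 5] = True
        rec = extract_features(cell, cell, np.ones((1, 32, 32)), ("DAPI",))
        assert not rec.valid

    def test_translation_invariance(self):
        cell = _disk(96, 96, 40, 36, 15)
        nucleus = _disk(96, 96, 40, 36, 7)
        channels = np.zeros((1, 96, 96))
        channels[0][cell] = 0.6
        r1 = extract_features(cell, nucleus, channels, ("M",))
        shift = lambda m: np.roll(np.roll(m, 9, axis=0), 13, axis=1)
        r2 = extract_features(shift(cell), shift(nucleus),
                              shift(channels[0])[None], ("M",))
        for key, val in r1.morph.items():
            assert r2.morph[key] == pytest.approx(val, abs=1e-9), key
        assert r2.intensity == r1.intensity

    def test_area_features_scale_quadratically(self):
        cell = _disk(80, 80, 40, 40, 14)
        nucleus = _disk(80, 80, 40, 40, 7)
        up = lambda m: np.kron(m, np.ones((2, 2), dtype=m.dtype))
        r1 = extract_features(cell, nucleus, np.ones((1, 80, 80)), ("M",))
        r2 = extract_features(up(cell), up(nucleus), np.ones((1, 160, 160)), ("M",))
        assert r2.morph["convex_area_cell"] == pytest.approx(
            4 * r1.morph["convex_area_cell"], rel=0.05)
        assert r2.morph["nc_area_ratio"] == pytest.approx(
            r1.morph["nc_area_ratio"], rel=0.05)

    def test_feature_table_deterministic(self, small_bundle):
        nuclei = segment_nuclei(small_bundle.image[0])
        cells = segment_cells(small_bundle.image, nuclei)
        t1 = extract_all_features(small_bundle.image, cells, nuclei,
                                  small_bundle.channels)
        t2 = extract_all_features(small_bundle.image, cells, nuclei,
                                  small_bundle.channels)
        assert t1.equals(t2)


class TestAggregate:
    def _cells(self, values, probs=None):
        n = len(values)
        return pd.DataFrame({
            "object_id": range(n), "valid": [True] * n,
            "nc_area_ratio": values,
            "atypia_prob": probs if probs is not None else [0.1] * n,
        })

    def test_hand_aggregates(self):
        out = aggregate_patient(self._cells([0.2, 0.4]))
        assert out["nc_area_ratio_avg"] == pytest.approx(0.3)
        assert out["nc_area_ratio_max"] == pytest.approx(0.4)
        assert out["nc_area_ratio_sd"] == pytest.approx(0.1)  # population SD

    def test_single_cell(self):
        out = aggregate_patient(self._cells([0.25]))
        assert out["nc_area_ratio_avg"] == out["nc_area_ratio_max"] == 0.25
        assert out["nc_area_ratio_sd"] == 0.0

    def test_atypical_ratio_threshold(self):
        out = aggregate_patient(self._cells([0.2, 0.5], probs=[0.9, 0.1]))
        assert out["atypical_ratio"] == 0.5
        assert out["mean_atypia_prob"] == pytest.approx(0.5)

    def test_clinical_passthrough_and_empty_error(self):
        out = aggregate_patient(self._cells([0.3]), clinical={"age": 52})
        assert out["age"] == 52
        with pytest.raises(ValueError):
            aggregate_patient(self._cells([])[0:0])


class TestCrops:
    def test_crop_shapes_and_ids(self, small_bundle):
        nuclei = segment_nuclei(small_bundle.image[0])
        cells = segment_cells(small_bundle.image, nuclei)
        triage = triage_objects(cells, nuclei)
        crops, ids = cell_crops(small_bundle.image, cells, triage, size=64)
        assert crops.shape[1:] == (small_bundle.image.shape[0], 64, 64)
        assert len(ids) == len(crops) > 0
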