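"""Per-slide TILs scoring: region assignment, counts, percentage,
co-occurrence matrix and derived features."""

import logging
import math

import numpy as np
import pytest

from tilscape.region_ops import AnalysisRegions, capture_tas
from tilscape.slide_model import CM_TYPES, RegionMaskSet, SlideFeatures
from tilscape.til_features import (
    CoocConfig,
    FeatureConfig,
    RegionLabel,
    assign_regions,
    cm_features,
    compute_slide_features,
    cooccurrence_matrix,
    count_tils,
    stils_percentage,
)

from _oracles import cm_all_pairs
from conftest import make_masks, nucleus

T, S, I = CM_TYPES.index("tumour"), CM_TYPES.index("stromal"), CM_TYPES.index("immune")


def simple_regions(shape=(20, 20)):
    """tumour rows 0-4, tas rows 5-9, other rows 10-14; rows 15+ excluded."""
    tumour = np.zeros(shape, bool)
    tumour[0:5] = True
    tas = np.zeros(shape, bool)
    tas[5:10] = True
    other = np.zeros(shape, bool)
    other[10:15] = True
    return AnalysisRegions(tumour, tas, other)


class TestAssignRegions:
    def test_membership_labels(self):
        regions = simple_regions()
        labelled = assign_regions(
            [nucleus(3, 7, "immune"), nucleus(3, 2, "immune"),
             nucleus(3, 12, "stromal"), nucleus(3, 17, "immune")],
            regions,
        )
        assert [ln.region_label for ln in labelled] == [
            RegionLabel.TAS, RegionLabel.TUMOUR_REGION, RegionLabel.OTHER, RegionLabel.EXCLUDED,
        ]

    def test_out_of_bounds_excluded_with_warning(self, caplog):
        regions = simple_regions()
        with caplog.at_level(logging.WARNING, logger="tilscape"):
            labelled = assign_regions([nucleus(25, 5, "immune")], regions)
        assert labelled[0].region_label is RegionLabel.EXCLUDED
        assert any("out of bounds" in r.message for r in caplog.records)

    def test_boundary_rounds_half_up(self):
        regions = simple_regions()
        # y=4.5 rounds to row 5 -> tas, not tumour
        labelled = assign_regions([nucleus(3, 4.5, "immune")], regions)
        assert labelled[0].region_label is RegionLabel.TAS


class TestCountTils:
    def test_definition(self):
        regions = simple_regions()
        nuclei = (
            [nucleus(x, 7, "immune", nid=f"a{x}") for x in range(3)]      # 3 in tas
            + [nucleus(x, 2, "immune", nid=f"b{x}") for x in range(2)]    # 2 in tumour
            + [nucleus(0, 12, "immune")]                                   # 1 in other
            + [nucleus(1, 12, "stromal"), nucleus(2, 12, "tumour")]
        )
        assert count_tils(assign_regions(nuclei, regions)) == (3, 2, 6)

    def test_no_immune(self):
        regions = simple_regions()
        labelled = assign_regions([nucleus(0, 2, "tumour")], regions)
        assert count_tils(labelled) == (0, 0, 0)

    def test_matches_brute_force_tally_on_random_nuclei(self, rng):
        regions = simple_regions()
        nuclei = [
            nucleus(float(rng.integers(0, 20)), float(rng.integers(0, 20)),
                    rng.choice(["immune", "tumour", "stromal", "other"]), nid=f"r{i}")
            for i in range(500)
        ]
        labelled = assign_regions(nuclei, regions)
        got = count_tils(labelled)
        # exhaustive per-nucleus recount
        stils = ttils = total = 0
        for n in nuclei:
            if n.nucleus_type.value != "immune":
                continue
            r, c = int(n.y), int(n.x)
            if regions.tumour_eff[r, c]:
                ttils += 1; total += 1
            elif regions.tas[r, c]:
                stils += 1; total += 1
            elif regions.other[r, c]:
                total += 1
        assert got == (stils, ttils, total)


class TestStilsPercentage:
    def test_arithmetic(self):
        tas = np.zeros((40, 40), bool)
        tas[0:25] = True  # 1000 px
        regions = AnalysisRegions(np.zeros((40, 40), bool), tas, np.zeros((40, 40), bool))
        nuclei = [nucleus(x, 3, "immune", area=19.0, nid=f"i{x}") for x in range(4)]
        labelled = assign_regions(nuclei, regions)
        assert stils_percentage(labelled, regions) == pytest.approx(7.6)

    def test_no_immune_is_zero_but_empty_tas_is_none(self, caplog):
        tas = np.zeros((10, 10), bool)
        tas[0] = True
        regions = AnalysisRegions(np.zeros((10, 10), bool), tas, np.zeros((10, 10), bool))
        assert stils_percentage([], regions) == 0.0
        empty = AnalysisRegions(*[np.zeros((10, 10), bool)] * 3)
        with caplog.at_level(logging.WARNING, logger="tilscape"):
            assert stils_percentage([], empty) is None

    def test_clamped_at_100_with_warning(self, caplog):
        tas = np.zeros((10, 10), bool)
        tas[0, 0:2] = True  # area 2
        regions = AnalysisRegions(np.zeros((10, 10), bool), tas, np.zeros((10, 10), bool))
        labelled = assign_regions([nucleus(0, 0, "immune", area=50.0)], regions)
        with caplog.at_level(logging.WARNING, logger="tilscape"):
            assert stils_percentage(labelled, regions) == 100.0
        assert any("clamping" in r.message for r in caplog.records)

    def test_default_area_used_when_absent(self):
        tas = np.zeros((40, 40), bool)
        tas[0:25] = True  # 1000 px
        regions = AnalysisRegions(np.zeros((40, 40), bool), tas, np.zeros((40, 40), bool))
        labelled = assign_regions([nucleus(1, 1, "immune")], regions)
        assert stils_percentage(labelled, regions, default_nucleus_area=28.0) == pytest.approx(2.8)


def label_all(nuclei, shape=(200, 200)):
    """Label every nucleus `other` (nothing excluded) for CM tests."""
    other = np.ones(shape, bool)
    regions = AnalysisRegions(np.zeros(shape, bool), np.zeros(shape, bool), other)
    return assign_regions(nuclei, regions)


class TestCooccurrenceMatrix:
    def test_single_pair_inside_and_outside_radius(self):
        labelled = label_all([nucleus(0, 0, "immune"), nucleus(0, 10, "stromal")])
        cm12 = cooccurrence_matrix(labelled, CoocConfig(radius_px=12))
        assert cm12[I, S] == 1 and cm12[S, I] == 1 and cm12.sum() == 2
        cm5 = cooccurrence_matrix(labelled, CoocConfig(radius_px=5))
        assert cm5.sum() == 0

    def test_three_mutual_cross_pairs(self):
        labelled = label_all(
            [nucleus(0, 0, "tumour"), nucleus(3, 0, "stromal"), nucleus(0, 3, "immune")]
        )
        cm = cooccurrence_matrix(labelled, CoocConfig(radius_px=10))
        assert cm[T, S] == cm[T, I] == cm[S, I] == 1
        assert cm[T, T] == cm[S, S] == cm[I, I] == 0

    def test_same_type_pair_counts_once_on_diagonal(self):
        labelled = label_all([nucleus(0, 0, "immune"), nucleus(0, 1, "immune")])
        cm = cooccurrence_matrix(labelled, CoocConfig(radius_px=5))
        assert cm[I, I] == 1 and cm.sum() == 1

    def test_excluded_and_out_of_scope_nuclei_ignored(self):
        shape = (20, 20)
        regions = AnalysisRegions(np.zeros(shape, bool), np.zeros(shape, bool),
                                  np.zeros(shape, bool))  # everything excluded
        labelled = assign_regions([nucleus(0, 0, "immune"), nucleus(1, 0, "stromal")], regions)
        assert cooccurrence_matrix(labelled, CoocConfig(radius_px=5)).sum() == 0
        labelled2 = label_all([nucleus(0, 0, "immune"), nucleus(1, 0, "normal_epithelial")])
        assert cooccurrence_matrix(labelled2, CoocConfig(radius_px=5)).sum() == 0

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            CoocConfig(radius_px=0)

    def test_exact_equality_with_all_pairs_oracle(self, rng):
        pts = rng.uniform(0, 300, size=(800, 2))
        types = rng.integers(0, 3, 800)
        labelled = label_all(
            [nucleus(x, y, CM_TYPES[t], nid=f"p{i}")
             for i, ((x, y), t) in enumerate(zip(pts, types))],
            shape=(301, 301),
        )
        got = cooccurrence_matrix(labelled, CoocConfig(radius_px=32))
        want = cm_all_pairs(pts, types, 3, 32.0)
        assert np.array_equal(got, want)

    def test_monotone_in_radius(self, rng):
        pts = rng.uniform(0, 100, size=(200, 2))
        types = rng.integers(0, 3, 200)
        labelled = label_all(
            [nucleus(x, y, CM_TYPES[t], nid=f"p{i}")
             for i, ((x, y), t) in enumerate(zip(pts, types))],
            shape=(101, 101),
        )
        cm1 = cooccurrence_matrix(labelled, CoocConfig(radius_px=10))
        cm2 = cooccurrence_matrix(labelled, CoocConfig(radius_px=20))
        assert (cm1 <= cm2).all()


class TestCmFeatures:
    def test_single_cell_mass_has_zero_entropy(self):
        cm = np.zeros((3, 3), np.int64)
        cm[T, T] = 9
        _, _, het, contrast = cm_features(cm)
        assert het == 0.0 and contrast == 0.0

    def test_uniform_over_six_pairs_gives_log2_6(self):
        cm = np.ones((3, 3), np.int64)  # upper triangle: 6 cells each mass 1
        _, _, het, _ = cm_features(cm)
        assert het == pytest.approx(math.log2(6))

    def test_contrast_hand_example(self):
        cm = np.zeros((3, 3), np.int64)
        cm[S, I] = cm[I, S] = 8
        cm[T, I] = cm[I, T] = 4
        cm[T, S] = cm[S, T] = 4
        si, ti, het, contrast = cm_features(cm)
        assert (si, ti) == (8, 4)
        assert contrast == pytest.approx(12 / 16)

    def test_all_zero_cm_gives_zero_features(self):
        assert cm_features(np.zeros((3, 3), np.int64)) == (0, 0, 0.0, 0.0)

    def test_asymmetric_cm_rejected(self):
        cm = np.zeros((3, 3), np.int64)
        cm[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            cm_features(cm)


class TestComputeSlideFeatures:
    def test_no_tumour_degenerate_composition(self):
        masks = make_masks((40, 40), stroma=np.ones((40, 40), bool))
        nuclei = [nucleus(5, 5, "immune")]
        f = compute_slide_features(nuclei, masks)
        assert f.ttils_count == 0 and f.stils_count == 0
        assert f.total_tils == 1  # the immune nucleus sits in `other`
        assert f.stils_pct is None  # TAS empty -> percentage undefined

    def test_order_invariance(self, square_tumour_masks, rng):
        nuclei = [
            nucleus(float(rng.integers(0, 96)), float(rng.integers(0, 96)),
                    rng.choice(["immune", "tumour", "stromal"]), nid=f"n{i}")
            for i in range(150)
        ]
        f1 = compute_slide_features(nuclei, square_tumour_masks)
        perm = list(rng.permutation(len(nuclei)))
        f2 = compute_slide_features([nuclei[i] for i in perm], square_tumour_masks)
        assert f1 == f2

    def test_conservation_no_double_counting(self, square_tumour_masks, rng):
        nuclei = [
            nucleus(float(rng.integers(0, 96)), float(rng.integers(0, 96)), "immune", nid=f"n{i}")
            for i in range(200)
        ]
        from tilscape.region_ops import apply_exclusions

        clean = apply_exclusions(square_tumour_masks)
        regions = capture_tas(clean["tumour"], clean["stroma"], tissue=clean["tissue"])
        labelled = assign_regions(nuclei, regions)
        stils, ttils, total = count_tils(labelled)
        n_other = sum(
            1 for ln in labelled if ln.region_label is RegionLabel.OTHER
        )
        assert stils + ttils + n_other == total

    def test_translation_invariance(self, rng):
        shape = (120, 120)
        tumour = np.zeros(shape, bool)
        tumour[30:50, 30:50] = True
        stroma = np.zeros(shape, bool)
        stroma[20:80, 20:80] = True
        stroma &= ~tumour
        nuclei = [
            nucleus(float(rng.integers(20, 80)), float(rng.integers(20, 80)),
                    rng.choice(["immune", "tumour", "stromal"]), nid=f"n{i}")
            for i in range(100)
        ]
        masks = make_masks(shape, tumour=tumour, stroma=stroma,
                           tissue=np.zeros(shape, bool) | tumour | stroma)
        f1 = compute_slide_features(nuclei, masks)

        dy, dx = 17, 9
        shift = lambda m: np.roll(np.roll(m, dy, axis=0), dx, axis=1)
        masks2 = make_masks(shape, tumour=shift(tumour), stroma=shift(stroma),
                            tissue=shift(tumour | stroma))
        nuclei2 = [nucleus(n.x + dx, n.y + dy, n.nucleus_type.value, nid=n.id) for n in nuclei]
        f2 = compute_slide_features(nuclei2, masks2)
        assert f1 == f2
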