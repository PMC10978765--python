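"""Landmark-rule SAS partition: predicate oracle, properties, volumes."""

import numpy as np
import pytest

from deshkit import labels as L
from deshkit.io import LabelMap
from deshkit.partition import (
    CompartmentVolumes,
    Landmarks,
    compartment_volumes,
    high_convexity_mask,
    partition_sas,
)
from deshkit.stats import dice_score


def _landmarks(**over):
    base = dict(
        ac_mm=(8.0, 10.0, 4.0),
        pc_mm=(8.0, 2.0, 4.0),
        midsagittal_point_mm=(8.0, 8.0, 8.0),
        midsagittal_normal=(1.0, 0.0, 0.0),
        genu_front_mm=(8.0, 13.0, 6.0),
        ventricle_body_top_z_mm=9.0,
        callosomarginal_posterior_mm=3.0,
    )
    base.update(over)
    return Landmarks(**base)


def predicate_oracle(shape, lm, spacing, lateral=30.0):
    """Per-voxel loop evaluating the four rules in world mm."""
    d = np.asarray(lm.ac_mm) - np.asarray(lm.pc_mm)
    d = d / np.linalg.norm(d)
    n = np.asarray(lm.midsagittal_normal)
    p0 = np.asarray(lm.midsagittal_point_mm)
    g = np.asarray(lm.genu_front_mm)
    out = np.zeros(shape, bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                p = np.array([i * spacing[0], j * spacing[1], k * spacing[2]])
                above = p[2] >= lm.ventricle_body_top_z_mm
                medial = abs(np.dot(p - p0, n)) <= lateral
                post_genu = np.dot(p, d) <= np.dot(g, d) + 1e-9
                ant_cm = np.dot(p, d) >= lm.callosomarginal_posterior_mm - 1e-9
                out[i, j, k] = above and medial and post_genu and ant_cm
    return out


def test_high_convexity_rule_matches_per_voxel_oracle(rng):
    lm = _landmarks()
    for spacing in [(1.0, 1.0, 1.0), (1.0, 1.5, 2.0)]:
        shape = (10, 12, 9)
        sas = rng.random(shape) < 0.5
        got = high_convexity_mask(sas, lm, spacing)
        want = sas & predicate_oracle(shape, lm, spacing)
        np.testing.assert_array_equal(got, want)


def test_high_convexity_rule_with_oblique_acpc(rng):
    lm = _landmarks(ac_mm=(8.0, 10.0, 6.0), pc_mm=(7.0, 2.0, 4.0))
    shape = (12, 12, 12)
    sas = rng.random(shape) < 0.6
    got = high_convexity_mask(sas, lm, (1.3, 1.0, 0.8))
    want = sas & predicate_oracle(shape, lm, (1.3, 1.0, 0.8))
    np.testing.assert_array_equal(got, want)


def test_lateral_and_genu_exclusions():
    # single SAS voxel 35 mm lateral to the midline: excluded
    lm = _landmarks(midsagittal_point_mm=(0.0, 8.0, 8.0), ventricle_body_top_z_mm=0.0)
    sas = np.zeros((40, 16, 16), bool)
    sas[35, 8, 8] = True  # x = 35 mm
    assert not high_convexity_mask(sas, lm, (1, 1, 1)).any()
    sas2 = np.zeros((40, 16, 16), bool)
    sas2[20, 8, 8] = True  # x = 20 mm, inside all bounds
    assert high_convexity_mask(sas2, lm, (1, 1, 1)).sum() == 1
    # voxel anterior to the genu coronal plane: excluded
    sas3 = np.zeros((40, 16, 16), bool)
    sas3[20, 15, 8] = True  # y = 15 mm > genu y = 13 mm
    assert not high_convexity_mask(sas3, lm, (1, 1, 1)).any()


def test_lateral_bound_monotonicity(rng):
    lm = _landmarks()
    sas = rng.random((16, 16, 16)) < 0.5
    narrow = high_convexity_mask(sas, lm, (2, 2, 2), lateral_bound_mm=10.0)
    wide = high_convexity_mask(sas, lm, (2, 2, 2), lateral_bound_mm=30.0)
    assert np.all(wide[narrow])  # enlarging the bound can only grow the mask


def test_degenerate_acpc_rejected():
    with pytest.raises(ValueError, match="AC-PC"):
        _landmarks(pc_mm=(8.0, 10.0, 4.0))
    with pytest.raises(ValueError, match="unit"):
        _landmarks(midsagittal_normal=(2.0, 0.0, 0.0))


def test_partition_recovers_generator_labels(desh_subject, normal_subject):
    """Self-consistency: phantoms are built with the same landmark rule."""
    for sub in (desh_subject, normal_subject):
        sas = sub.labelmap.mask(*L.SAS_CATEGORIES)
        part = partition_sas(sas, sub.sylvian_seeds_mm, sub.landmarks,
                             sub.labelmap.voxel_size_mm)
        for code in L.SAS_CATEGORIES:
            d = dice_score(part.data == code, sub.labelmap.data == code)
            assert d >= 0.99
        # exhaustive + disjoint partition of the SAS
        np.testing.assert_array_equal(part.data > 0, sas)
        # sylvian volume within 2% of generator truth
        vox_ml = sub.labelmap.voxel_volume_mm3 / 1000
        got = np.count_nonzero(part.data == L.SYLVIAN_BASAL) * vox_ml
        assert got == pytest.approx(sub.true_volumes.sylvian_basal_ml, rel=0.02)


def test_partition_is_idempotent(desh_subject):
    sub = desh_subject
    sas = sub.labelmap.mask(*L.SAS_CATEGORIES)
    part1 = partition_sas(sas, sub.sylvian_seeds_mm, sub.landmarks,
                          sub.labelmap.voxel_size_mm)
    part2 = partition_sas(part1.data > 0, sub.sylvian_seeds_mm, sub.landmarks,
                          part1.voxel_size_mm)
    np.testing.assert_array_equal(part1.data, part2.data)


def test_partition_empty_mask_and_bad_seed():
    lm = _landmarks()
    empty = np.zeros((8, 8, 8), bool)
    part = partition_sas(empty, [], lm, (1, 1, 1))
    assert not part.data.any()
    some = np.zeros((8, 8, 8), bool)
    some[2, 2, 2] = True
    with pytest.raises(ValueError, match="outside the SAS"):
        partition_sas(some, [(5.0, 5.0, 5.0)], lm, (1, 1, 1))


def test_compartment_volumes_arithmetic():
    data = np.zeros((10, 10, 10), np.uint8)
    data[:1] = L.VENTRICLES  # 100 voxels
    m = LabelMap(data, (1.0, 1.0, 1.0))
    vols = compartment_volumes(m)
    assert vols.total_ventricles_ml == pytest.approx(0.1)  # 100 mm^3
    # doubling the voxel size scales every volume by 8
    m2 = LabelMap(data, (2.0, 2.0, 2.0))
    vols2 = compartment_volumes(m2)
    assert vols2.total_ventricles_ml == pytest.approx(0.8)
    assert vols2.intracranial_csf_ml == pytest.approx(8 * vols.intracranial_csf_ml)


def test_compartment_volumes_identities(desh_subject):
    vols = desh_subject.true_volumes
    assert vols.total_sas_ml == pytest.approx(
        vols.sylvian_basal_ml + vols.high_convexity_sas_ml + vols.other_sas_ml
    )
    assert vols.intracranial_csf_ml == pytest.approx(
        vols.total_sas_ml + vols.total_ventricles_ml
    )


def test_unknown_label_code_rejected():
    data = np.full((4, 4, 4), 7, np.uint8)
    m = LabelMap(data, (1.0, 1.0, 1.0), categories=(7,))
    with pytest.raises(ValueError, match="unknown label codes"):
        compartment_volumes(m)
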