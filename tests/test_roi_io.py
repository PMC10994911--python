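"""Volume loading, ROI extraction and tabular round trips."""

import nibabel as nib
import numpy as np
import pandas as pd
import pytest

from suscnet import (
    AtlasParcellation,
    CohortDesign,
    SusceptibilityMap,
    extract_roi_samples,
    load_map_and_atlas,
    read_cohort_table,
    read_roi_table,
    write_cohort_table,
    write_roi_table,
)
from suscnet.errors import (
    CatalogError,
    CompletenessError,
    DimensionError,
    FormatError,
)
from suscnet.roi_io import SusceptibilityROISamples


def _write_nifti(path, data):
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4)), str(path))


def _toy_volumes(tmp_path, mask_shape=(4, 4, 4), atlas_extra_label=None):
    rng = np.random.default_rng(0)
    shape = (4, 4, 4)
    vol = rng.normal(size=shape)
    atlas = np.zeros(shape)
    atlas[:2, :, :] = 1
    atlas[2:, :, :] = 2
    if atlas_extra_label:
        atlas[0, 0, 0] = atlas_extra_label
    mask = np.ones(mask_shape)
    _write_nifti(tmp_path / "map.nii.gz", vol)
    _write_nifti(tmp_path / "mask.nii.gz", mask)
    _write_nifti(tmp_path / "atlas.nii.gz", atlas)
    pd.DataFrame(
        {
            "region_id": [1, 2],
            "name": ["left", "right"],
            "abbreviation": ["L", "R"],
            "network": ["DMN", "VN"],
        }
    ).to_csv(tmp_path / "regions.tsv", sep="\t", index=False)
    paths = tuple(tmp_path / f for f in ("map.nii.gz", "mask.nii.gz",
                                         "atlas.nii.gz", "regions.tsv"))
    return vol, paths


def test_load_toy_volumes_builds_two_region_atlas(tmp_path):
    _, paths = _toy_volumes(tmp_path)
    smap, atlas, mask = load_map_and_atlas(*paths)
    assert atlas.n_regions == 2
    assert smap.voxels.shape == atlas.labels.shape == mask.shape
    assert atlas.network_partition() == {1: "DMN", 2: "VN"}


def test_load_rejects_shape_mismatch(tmp_path):
    _, paths = _toy_volumes(tmp_path, mask_shape=(4, 4, 3))
    with pytest.raises(DimensionError):
        load_map_and_atlas(*paths)


def test_load_rejects_unknown_region_label(tmp_path):
    _, paths = _toy_volumes(tmp_path, atlas_extra_label=7)
    with pytest.raises(CatalogError):
        load_map_and_atlas(*paths)


def test_non_integer_atlas_is_a_format_error():
    with pytest.raises(FormatError):
        AtlasParcellation(
            labels=np.full((2, 2, 2), 1.5),
            region_table=pd.DataFrame(
                {"name": ["a"], "abbreviation": ["A"], "network": ["DMN"]},
                index=pd.Index([1], name="region_id"),
            ),
        )


def test_extraction_reads_masked_values_in_scan_order():
    vol = np.zeros((1, 1, 3))
    vol[0, 0, :] = [0.1, 0.2, 0.3]
    labels = np.ones((1, 1, 3), dtype=int)
    table = pd.DataFrame(
        {"name": ["a", "b"], "abbreviation": ["A", "B"], "network": ["DMN", "VN"]},
        index=pd.Index([1, 2], name="region_id"),
    )
    labels_2 = labels.copy()
    labels_2[0, 0, 2] = 2
    atlas = AtlasParcellation(labels=labels_2, region_table=table)
    smap = SusceptibilityMap(voxels=vol)
    out = extract_roi_samples(smap, atlas, np.ones_like(vol), min_voxels=1)
    assert out.region_values[1].tolist() == [0.1, 0.2]
    assert out.region_values[2].tolist() == [0.3]

    mask = np.ones_like(vol)
    mask[0, 0, 1] = 0  # drop the 0.2 voxel
    out = extract_roi_samples(smap, atlas, mask, min_voxels=1)
    assert out.region_values[1].tolist() == [0.1]


def test_extraction_counts_match_bruteforce_tally(rng):
    shape = (6, 5, 4)
    vol = rng.normal(size=shape)
    labels = rng.integers(0, 4, size=shape)
    mask = rng.random(shape) > 0.3
    table = pd.DataFrame(
        {
            "name": list("abc"),
            "abbreviation": list("ABC"),
            "network": ["DMN", "VN", "SN"],
        },
        index=pd.Index([1, 2, 3], name="region_id"),
    )
    atlas = AtlasParcellation(labels=labels, region_table=table)
    out = extract_roi_samples(SusceptibilityMap(voxels=vol), atlas, mask, min_voxels=1)
    counts = {1: 0, 2: 0, 3: 0}
    total_in_mask = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                total_in_mask += int(mask[i, j, k])
                if mask[i, j, k] and labels[i, j, k] in counts:
                    counts[labels[i, j, k]] += 1
    for r in (1, 2, 3):
        assert out.region_values[r].size == counts[r]
    # masking never increases counts beyond the in-mask voxel budget
    assert sum(v.size for v in out.region_values.values()) <= total_in_mask


def test_small_regions_are_flagged_degenerate_not_dropped():
    s = SusceptibilityROISamples(
        subject_id="s", region_values={1: np.arange(20.0), 2: np.arange(3.0)}
    )
    assert s.degenerate == frozenset({2})
    assert 2 in s.region_values


def test_roi_table_roundtrip_is_lossless(tmp_path, rng):
    samples = [
        SusceptibilityROISamples(
            subject_id=f"s{i}",
            region_values={r: rng.normal(size=15) for r in (1, 2, 3)},
        )
        for i in range(2)
    ]
    path = tmp_path / "roi.tsv"
    write_roi_table(samples, path)
    back = read_roi_table(path)
    assert [b.subject_id for b in back] == ["s0", "s1"]
    for orig, got in zip(samples, back):
        for r in (1, 2, 3):
            np.testing.assert_array_equal(orig.region_values[r], got.region_values[r])


def test_roi_table_missing_region_is_completeness_error(tmp_path):
    df = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b"],
            "region_id": [1, 2, 1],  # subject b is missing region 2
            "value": [0.1, 0.2, 0.3],
        }
    )
    path = tmp_path / "bad.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(CompletenessError):
        read_roi_table(path)


def test_large_roi_table_parse_count_matches_line_count(tmp_path, rng):
    n_subj, n_reg, n_vox = 10, 10, 1000  # 100k data rows
    samples = [
        SusceptibilityROISamples(
            subject_id=f"s{i:02d}",
            region_values={r: rng.normal(size=n_vox) for r in range(1, n_reg + 1)},
        )
        for i in range(n_subj)
    ]
    path = tmp_path / "big.tsv"
    write_roi_table(samples, path)
    n_lines = sum(1 for _ in open(path))
    back = read_roi_table(path)
    parsed = sum(v.size for s in back for v in s.region_values.values())
    assert parsed == n_lines - 1


def test_cohort_table_roundtrip_and_validation(tmp_path):
    df = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "group": ["HC", "MCI-AD"],
            "age": [70.0, 68.0],
            "gender": ["F", "M"],
            "education": [12.0, 9.0],
        }
    )
    design = CohortDesign(table=df)
    path = tmp_path / "cohort.tsv"
    write_cohort_table(design, path)
    back = read_cohort_table(path)
    pd.testing.assert_frame_equal(back.table, df)
    with pytest.raises(FormatError):
        CohortDesign(table=pd.concat([df, df]))  # duplicate ids
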