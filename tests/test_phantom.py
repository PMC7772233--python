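"""Generator contracts: geometry, partial-volume model, cohort manifests."""

import numpy as np
import pandas as pd
import pytest

from ventseg.evaluation import dice
from ventseg.imaging import read_volume
from ventseg.phantom import PhantomSpec, generate_phantom, make_cohort
from ventseg.volume import Domain


def test_spec_rejects_inconsistent_thickness():
    with pytest.raises(ValueError, match="exceed 3 mm"):
        PhantomSpec(thin_spacing=1.0, thick_factor=2)
    with pytest.raises(ValueError, match="thin_spacing"):
        PhantomSpec(thin_spacing=4.0)
    with pytest.raises(ValueError, match="ventricle_scale"):
        PhantomSpec(ventricle_scale=0.2)
    with pytest.raises(ValueError, match="below brain"):
        PhantomSpec(intensity_means=(0.0, 0.5, 0.9))


def test_thick_slice_count_and_tags(tiny_spec):
    thin, thick = generate_phantom(tiny_spec)
    assert thin.n_slices == 12
    assert thick.n_slices == 12 // 4
    assert thin.domain == Domain.THIN
    assert thick.domain == Domain.THICK
    assert thick.spacing[0] == pytest.approx(tiny_spec.thin_spacing * 4)


def test_trailing_slices_truncated_and_recorded():
    spec = PhantomSpec(n_slices=14, thick_factor=4, thin_spacing=0.8,
                       in_plane_size=(32, 32), seed=1)
    _, thick = generate_phantom(spec)
    assert thick.n_slices == 3
    assert thick.meta["truncated_slices"] == 2


def test_ventricle_volume_monotone_in_scale(tiny_spec):
    from dataclasses import replace
    counts = []
    for s in (0.5, 1.0, 1.5, 2.0, 2.5):
        thin, _ = generate_phantom(replace(tiny_spec, ventricle_scale=s))
        counts.append(int(thin.mask.sum()))
    assert counts == sorted(counts)
    thin1, _ = generate_phantom(replace(tiny_spec, ventricle_scale=1.0))
    thin2, _ = generate_phantom(replace(tiny_spec, ventricle_scale=2.0))
    assert thin2.mask.sum() > thin1.mask.sum()


def test_noiseless_thick_is_exact_block_mean(tiny_spec):
    from dataclasses import replace
    spec = replace(tiny_spec, noise_sd=0.0)
    thin, thick = generate_phantom(spec)
    k = spec.thick_factor
    # brute-force voxel loop oracle on a sub-grid plus exact global check
    for b in range(thick.n_slices):
        for i in range(0, 32, 7):
            for j in range(0, 32, 7):
                expect = np.mean([thin.intensity[b * k + t, i, j]
                                  for t in range(k)])
                assert thick.intensity[b, i, j] == pytest.approx(expect, abs=1e-12)
    block = thin.intensity[: thick.n_slices * k].reshape(
        thick.n_slices, k, *thin.intensity.shape[1:]).mean(axis=1)
    np.testing.assert_array_equal(block, thick.intensity)
    # totals conserved: sum(thick) * k == sum(thin over covered slices)
    assert thick.intensity.sum() * k == pytest.approx(
        thin.intensity[: thick.n_slices * k].sum(), rel=1e-12)


def test_thick_mask_majority_vote_with_ties_foreground(tiny_spec):
    from dataclasses import replace
    spec = replace(tiny_spec, noise_sd=0.0)
    thin, thick = generate_phantom(spec)
    k = spec.thick_factor
    votes = thin.mask[: thick.n_slices * k].reshape(
        thick.n_slices, k, *thin.mask.shape[1:]).sum(axis=1)
    np.testing.assert_array_equal(thick.mask, (votes * 2 >= k).astype(np.uint8))
    # ties actually occur somewhere, so the rule is exercised
    assert (votes * 2 == k).any()


def test_nesting_ventricle_head_volume(tiny_spec):
    from ventseg.phantom import _build_thin
    rng = np.random.default_rng(0)
    head, vent = _build_thin(tiny_spec, rng)
    assert vent.sum() > 0
    assert (vent & ~head).sum() == 0 and vent.sum() < head.sum()
    assert head.sum() < head.size  # head strictly inside the volume


def test_domain_gap_exists(tiny_spec):
    """Upsampled thick masks disagree with thin masks: the gap is real."""
    from dataclasses import replace
    slice_dices = []
    for seed in range(3):
        thin, thick = generate_phantom(replace(tiny_spec, seed=seed))
        up = np.repeat(thick.mask, tiny_spec.thick_factor, axis=0)
        for s in range(up.shape[0]):
            if thin.mask[s].sum() + up[s].sum() > 0:
                slice_dices.append(dice(up[s], thin.mask[s]))
    assert np.mean(slice_dices) < 1.0


def test_generation_deterministic(tiny_spec):
    a = generate_phantom(tiny_spec)
    b = generate_phantom(tiny_spec)
    for va, vb in zip(a, b):
        np.testing.assert_array_equal(va.intensity, vb.intensity)
        np.testing.assert_array_equal(va.mask, vb.mask)


def test_cohort_manifest_byte_identical(tmp_path, tiny_spec):
    m1 = make_cohort(2, 2, 1, tmp_path / "a", seed=7, spec_template=tiny_spec)
    m2 = make_cohort(2, 2, 1, tmp_path / "b", seed=7, spec_template=tiny_spec)
    assert m1.read_bytes() == m2.read_bytes()
    vols1 = sorted((tmp_path / "a").glob("*.nii.gz"))
    vols2 = sorted((tmp_path / "b").glob("*.nii.gz"))
    assert [v.name for v in vols1] == [v.name for v in vols2]
    for va, vb in zip(vols1, vols2):
        assert va.read_bytes() == vb.read_bytes()


def test_cohort_empty_test_split(tmp_path, tiny_spec):
    manifest = make_cohort(1, 1, 0, tmp_path, seed=0, spec_template=tiny_spec)
    df = pd.read_csv(manifest, keep_default_na=False)
    assert (df["split"] == "test").sum() == 0


def test_manifest_domain_tags_match_file_spacing(tiny_cohort):
    df = pd.read_csv(tiny_cohort, keep_default_na=False)
    root = tiny_cohort.parent
    for _, row in df.iterrows():
        vol = read_volume(root / row["path"], modality=row["modality"])
        assert vol.domain.value == row["domain"]
        assert (vol.spacing[0] > 3.0) == (row["domain"] == "thick")


def test_unlabeled_and_test_masks_withheld(tiny_cohort):
    df = pd.read_csv(tiny_cohort, keep_default_na=False)
    train_thin = df[(df.split == "train") & (df.domain == "thin")]
    assert (train_thin["mask_path"] == "").all()
    assert (df[df.split == "test"]["mask_path"] == "").all()
    truth = pd.read_csv(tiny_cohort.parent / "ground_truth.csv")
    withheld = set(train_thin["volume_id"]) | set(df[df.split == "test"]["volume_id"])
    assert set(truth["volume_id"]) == withheld


def test_unwritable_out_dir_raises(tiny_spec, tmp_path):
    blocker = tmp_path / "file"
    blocker.write_text("x")
    with pytest.raises(OSError, match="not writable|exists"):
        make_cohort(1, 0, 0, blocker / "sub", seed=0, spec_template=tiny_spec)
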