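"""Dataset construction: renderer, augmentation, split rule, manifest I/O."""

import os

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from rfcottnet.data import (AUGMENT_FACTOR, CCDPHD11_CLASS_TOTALS,
                            CCDPHD11_CLASSES, N_FIELD_ORIGINALS, N_ONLINE,
                            AugmentationPolicy, ClassSpec, DatasetManifest,
                            ImageSample, VisualSignature, apply_augmentation,
                            augment_dataset, augment_image,
                            default_class_signatures,
                            generate_synthetic_dataset, merge_manifests,
                            read_manifest, render_leaf, rotate_image,
                            scaled_ccdphd11_specs, split_counts,
                            stratified_split, write_manifest)


# -- split arithmetic -------------------------------------------------------

def test_published_split_table_reproduced_exactly():
    """Per-class floor(0.8 n) over the published totals gives 15,159/3,794."""
    counts = split_counts(list(CCDPHD11_CLASS_TOTALS.values()), 0.8)
    assert sum(t for t, _ in counts) == 15_159
    assert sum(t for _, t in counts) == 3_794
    by_class = dict(zip(CCDPHD11_CLASS_TOTALS, counts))
    assert by_class["Healthy"] == (5155, 1289)
    assert by_class["Fusarium wilt"] == (704, 177)


@given(st.lists(st.integers(0, 10_000), min_size=1, max_size=20),
       st.floats(0.05, 0.95))
@settings(max_examples=100, deadline=None)
def test_split_counts_conserve_totals(totals, frac):
    for (tr, te), n in zip(split_counts(totals, frac), totals):
        assert tr + te == n and tr == int(np.floor(frac * n)) and te >= 0


def test_split_counts_exact_division():
    assert split_counts([10], 0.8) == [(8, 2)]


def test_stratified_split_membership_and_determinism(tmp_path):
    samples = [ImageSample(f"img_{c}_{i}.png", c)
               for c in ("a", "b") for i in range(13)]
    man = DatasetManifest(samples, ("a", "b"))
    s1 = stratified_split(man, 0.8, seed=3)
    s2 = stratified_split(man, 0.8, seed=3)
    assert [x.split for x in s1.samples] == [x.split for x in s2.samples]
    counts = s1.class_counts()
    assert counts["a"] == (10, 3, 13)
    # different seed permutes membership but not counts
    s3 = stratified_split(man, 0.8, seed=4)
    assert s3.class_counts()["a"] == (10, 3, 13)
    assert [x.split for x in s3.samples] != [x.split for x in s1.samples]


def test_split_keeps_augmented_variants_with_original():
    samples = []
    for k in range(10):
        for v in range(6):
            samples.append(ImageSample(f"leaf_{k:03d}_aug{v}.png", "a", "augmented"))
    man = DatasetManifest(samples, ("a",))
    out = stratified_split(man, 0.8, seed=0)
    by_origin = {}
    for s in out.samples:
        by_origin.setdefault(s.path.split("_aug")[0], set()).add(s.split)
    assert all(len(v) == 1 for v in by_origin.values())


def test_empty_class_contributes_zero():
    man = DatasetManifest([ImageSample("x.png", "a")], ("a", "b"))
    out = stratified_split(man, 0.8, seed=0)
    assert out.class_counts()["b"] == (0, 0, 0)


# -- renderer / generator ---------------------------------------------------

def test_generate_writes_class_directories_with_requested_counts(tmp_path):
    specs = scaled_ccdphd11_specs(1 / 100)
    man = generate_synthetic_dataset(specs, tmp_path, 32, seed=1)
    assert set(os.listdir(tmp_path)) >= set(CCDPHD11_CLASSES)
    counts = man.class_counts()
    for spec in specs:
        assert counts[spec.name][2] == spec.n_images
        assert len(os.listdir(tmp_path / spec.name)) == spec.n_images


def test_generate_zero_images_gives_empty_class(tmp_path):
    man = generate_synthetic_dataset([ClassSpec("only", 0)], tmp_path, 32, seed=0)
    assert len(man) == 0 and os.listdir(tmp_path / "only") == []


def test_generate_deterministic_bytes(tmp_path):
    spec = [ClassSpec("c", 3)]
    m1 = generate_synthetic_dataset(spec, tmp_path / "a", 48, seed=9)
    m2 = generate_synthetic_dataset(spec, tmp_path / "b", 48, seed=9)
    for s1, s2 in zip(m1.samples, m2.samples):
        assert open(s1.path, "rb").read() == open(s2.path, "rb").read()


def test_generate_rejects_duplicate_classes(tmp_path):
    with pytest.raises(ValueError, match="duplicate"):
        generate_synthetic_dataset([ClassSpec("a", 1), ClassSpec("a", 1)],
                                   tmp_path, 32, seed=0)


def test_renderer_class_signatures_are_visually_distinct(rng):
    """Mean colors of different classes separate more than within-class."""
    sigs = default_class_signatures()
    means = {}
    for name, sig in sigs.items():
        imgs = [render_leaf(sig, 48, np.random.default_rng(i)) for i in range(3)]
        means[name] = np.stack([im.mean(axis=(0, 1)) for im in imgs])
    names = list(means)
    within = max(np.ptp(means[n], axis=0).max() for n in names)
    between = min(np.linalg.norm(means[a].mean(0) - means[b].mean(0))
                  for i, a in enumerate(names) for b in names[i + 1:])
    # every pair of classes sits at least a few intensity levels apart in
    # mean color (full separability is shown by the end-to-end training test)
    assert between > 5.0
    assert within < 255.0


# -- augmentation -----------------------------------------------------------

def _leaf(seed=0, size=48):
    return render_leaf(VisualSignature(), size, np.random.default_rng(seed))


def test_augment_count_law_and_original_first():
    img = _leaf()
    out = augment_image(img, AugmentationPolicy(variants_per_original=6), seed=1)
    assert len(out) == 6
    np.testing.assert_array_equal(out[0], img)


def test_augment_single_variant_is_identity():
    img = _leaf()
    out = augment_image(img, AugmentationPolicy(variants_per_original=1), seed=1)
    assert len(out) == 1
    np.testing.assert_array_equal(out[0], img)


def test_augment_variants_differ_from_original():
    img = _leaf()
    out, params = augment_image(img, AugmentationPolicy(), seed=2,
                                return_params=True)
    for var, p in zip(out[1:], params[1:]):
        assert p.is_identity or (var != img).any()


def test_rotation_only_variant_matches_direct_affine_oracle():
    """A rotation-only draw equals rotating the input at the logged angle."""
    img = _leaf(3)
    policy = AugmentationPolicy(brightness_delta=0.0, flip_modes=(),
                                mask_size_range=(0.0, 0.0), noise_sigma=0.0,
                                rotation_range=25.0, variants_per_original=4)
    out, params = augment_image(img, policy, seed=5, return_params=True)
    for var, p in zip(out[1:], params[1:]):
        assert p.rotation is not None
        oracle = np.asarray(
            Image.fromarray(img).rotate(p.rotation, resample=Image.BILINEAR))
        np.testing.assert_array_equal(var, oracle)


def test_augment_rejects_invalid_policy():
    with pytest.raises(ValueError):
        AugmentationPolicy(variants_per_original=0)
    with pytest.raises(ValueError):
        AugmentationPolicy(mask_count_range=(0, 25))


def test_mask_count_within_bounds():
    img = _leaf(4)
    policy = AugmentationPolicy(brightness_delta=0.0, flip_modes=(),
                                noise_sigma=0.0, rotation_range=0.0,
                                variants_per_original=30)
    _, params = augment_image(img, policy, seed=6, return_params=True)
    counts = [len(p.masks) for p in params[1:]]
    assert all(1 <= c <= 20 for c in counts)


def test_augment_dataset_accounting(tmp_path):
    """12 field originals x 6 variants = 72 outputs, all tagged augmented."""
    specs = [ClassSpec("a", 7), ClassSpec("b", 5)]
    field = generate_synthetic_dataset(specs, tmp_path / "field", 32, seed=0,
                                       source="field")
    aug = augment_dataset(field, AugmentationPolicy(), seed=1, out_dir=tmp_path / "aug")
    assert len(aug) == AUGMENT_FACTOR * len(field)
    assert all(s.source == "augmented" for s in aug.samples)
    merged = merge_manifests(field, aug)
    assert len(merged) == len(field) + len(aug)


def test_augment_empty_dataset(tmp_path):
    empty = DatasetManifest([], ("a",))
    out = augment_dataset(empty, AugmentationPolicy(), seed=0, out_dir=tmp_path)
    assert len(out) == 0


# -- manifest I/O -----------------------------------------------------------

def test_manifest_round_trip(tmp_path):
    samples = [ImageSample("a/x.png", "a", "online", "train"),
               ImageSample("b/y.png", "b", "field", "test")]
    man = DatasetManifest(samples, ("a", "b"))
    path = tmp_path / "m.csv"
    write_manifest(man, path)
    back = read_manifest(path, classes=("a", "b"))
    assert [vars(s) for s in back.samples] == [vars(s) for s in man.samples]


def test_manifest_errors_name_the_row(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("path,label,source,split\nx.png,zzz,online,train\n")
    with pytest.raises(ValueError, match="row 2"):
        read_manifest(path, classes=("a",))
    path.write_text("path,label,source,split\nx.png,a,online,nope\n")
    with pytest.raises(ValueError, match="row 2"):
        read_manifest(path)
    with pytest.raises(FileNotFoundError):
        read_manifest(tmp_path / "missing.csv")
    path.write_text("wrong,header\n")
    with pytest.raises(ValueError, match="header"):
        read_manifest(path)


def test_manifest_empty_file_with_header(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("path,label,source,split\n")
    assert len(read_manifest(path)) == 0


# -- corpus-level accounting ------------------------------------------------

def test_field_share_of_merged_corpus():
    """796 x 6 = 4,776 augmented; + 14,177 online = 18,953; field share 25.2%."""
    n_aug = N_FIELD_ORIGINALS * AUGMENT_FACTOR
    assert n_aug == 4_776
    total = N_ONLINE + n_aug
    assert total == 18_953
    assert round(100 * n_aug / total, 1) == 25.2
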