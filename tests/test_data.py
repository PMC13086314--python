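"""Synthetic generator determinism, counts, splitting and folder IO."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from PIL import Image

from awpfnet.data import (DEFAULT_CLASSES, ClassSpec, DatasetSpec,
                          LabeledImageSet, ImageItem, generate_synthetic_dataset,
                          load_image_folder, render_image, stratified_split)


def tree_hash(root):
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*.png")):
        h.update(p.relative_to(root).as_posix().encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def test_generator_is_byte_deterministic(tmp_path):
    # arbitrary class names get deterministic derived styles
    spec = DatasetSpec(classes=(ClassSpec("A_sp", 3, 1),
                                ClassSpec("B_sp", 2, 1)), seed=0)
    generate_synthetic_dataset(spec, tmp_path / "a")
    generate_synthetic_dataset(spec, tmp_path / "b")
    assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")


def test_different_seeds_give_different_pixels():
    a = render_image("Boletus", np.random.default_rng(0))
    b = render_image("Boletus", np.random.default_rng(1))
    assert not np.array_equal(a, b)


def test_default_spec_matches_published_counts():
    spec = DatasetSpec()
    by = {c.name: c for c in spec.classes}
    assert spec.total == 2435
    assert sum(c.train_n for c in spec.classes) == 1713
    assert sum(c.val_n for c in spec.classes) == 722
    assert by["Lentinula_edodes"].train_n == 446
    assert by["Mix"] == ClassSpec("Mix", 14, 10)
    assert len(spec.classes) == 7


def test_generated_counts_match_spec_exactly(tmp_path):
    spec = DatasetSpec(classes=(ClassSpec("Boletus", 4, 2),
                                ClassSpec("Mix", 2, 1),
                                ClassSpec("Tremella", 3, 1)),
                       image_size=(64, 64))
    ds = generate_synthetic_dataset(spec, tmp_path)
    assert len(ds) == 13
    assert len(ds.subset("train")) == 9
    assert len(ds.subset("val")) == 4
    assert sorted(ds.class_names) == ["Boletus", "Mix", "Tremella"]
    assert (tmp_path / "train" / "Boletus" / "00003.png").exists()
    assert (tmp_path / "manifest.csv").read_text().count("\n") == 14


def test_generator_rejects_empty_spec(tmp_path):
    spec = DatasetSpec(classes=(ClassSpec("Boletus", 0, 0),))
    with pytest.raises(ValueError, match="zero images"):
        generate_synthetic_dataset(spec, tmp_path)


def test_spec_validation():
    with pytest.raises(ValueError):
        DatasetSpec(classes=(ClassSpec("X", 1, 1), ClassSpec("X", 1, 1)))
    with pytest.raises(ValueError):
        DatasetSpec(classes=(ClassSpec("X", -1, 1),))


def test_load_image_folder_roundtrip(tmp_path):
    spec = DatasetSpec(classes=(ClassSpec("Boletus", 3, 1),
                                ClassSpec("Tremella", 2, 1)),
                       image_size=(64, 64))
    generate_synthetic_dataset(spec, tmp_path)
    ds = load_image_folder(tmp_path / "train", image_size=(64, 64))
    assert ds.class_names == ["Boletus", "Tremella"]  # alphabetical indices
    assert len(ds) == 5
    arr = ds.load_array(0)
    assert arr.shape == (3, 64, 64)
    assert arr.dtype == np.float32
    assert 0.0 <= arr.min() and arr.max() <= 1.0


def test_load_image_folder_resizes_small_images(tmp_path):
    d = tmp_path / "cls"
    d.mkdir()
    Image.fromarray(np.zeros((10, 10, 3), np.uint8)).save(d / "x.png")
    ds = load_image_folder(tmp_path)
    assert ds.load_array(0).shape == (3, 224, 224)


def test_load_image_folder_skips_corrupt_file(tmp_path):
    spec = DatasetSpec(classes=(ClassSpec("Boletus", 3, 1),),
                       image_size=(64, 64))
    generate_synthetic_dataset(spec, tmp_path)
    (tmp_path / "train" / "Boletus" / "bad.png").write_bytes(b"not a png")
    ds = load_image_folder(tmp_path / "train", image_size=(64, 64))
    assert len(ds) == 3


def test_load_image_folder_rejects_empty_root(tmp_path):
    with pytest.raises(ValueError):
        load_image_folder(tmp_path)


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def fake_set(counts):
    items = [ImageItem(f"img{c}_{i}", c) for c, n in enumerate(counts)
             for i in range(n)]
    return LabeledImageSet(items, [f"c{c}" for c in range(len(counts))])


def test_split_seven_three_on_ten_items():
    train, val = stratified_split(fake_set([10]), 0.7, seed=0)
    assert (len(train), len(val)) == (7, 3)


def test_split_rounds_half_up_single_item():
    train, val = stratified_split(fake_set([1]), 0.7, seed=0)
    assert (len(train), len(val)) == (1, 0)


def test_split_is_disjoint_and_exhaustive(rng):
    counts = [13, 7, 1, 29]
    items = fake_set(counts)
    train, val = stratified_split(items, 0.7, seed=3)
    train_ids = {it.source for it in train.items}
    val_ids = {it.source for it in val.items}
    assert not train_ids & val_ids
    assert len(train_ids | val_ids) == sum(counts)
    # per-class rounding
    for c, n in enumerate(counts):
        n_train = sum(1 for it in train.items if it.class_index == c)
        assert n_train == int(np.floor(n * 0.7 + 0.5))


def test_split_warns_and_skips_empty_class():
    items = fake_set([4, 0, 3])
    with pytest.warns(UserWarning, match="c1"):
        train, val = stratified_split(items, 0.7, seed=0)
    assert all(it.class_index != 1 for it in train.items + val.items)


def test_split_rejects_bad_fraction():
    with pytest.raises(ValueError):
        stratified_split(fake_set([4]), 1.5)


# ---------------------------------------------------------------------------
# separability of the full default set (linear probe on colour statistics)
# ---------------------------------------------------------------------------

def colour_features(arr):
    a = arr.astype(np.float32) / 255.0
    return np.concatenate([a.mean(axis=(0, 1)), a.std(axis=(0, 1))])


def test_default_set_linearly_separable_by_colour_probe(default_dataset):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    _, ds = default_dataset
    feats, labels, splits = [], [], []
    for it in ds.items:
        with Image.open(it.source) as im:
            feats.append(colour_features(np.asarray(im)))
        labels.append(it.class_index)
        splits.append(it.split)
    feats, labels = np.array(feats), np.array(labels)
    tr = np.array(splits) == "train"
    probe = make_pipeline(StandardScaler(),
                          LogisticRegression(max_iter=3000))
    probe.fit(feats[tr], labels[tr])
    assert probe.score(feats[~tr], labels[~tr]) >= 0.90
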