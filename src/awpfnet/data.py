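"""Dataset handling and the synthetic mushroom-image generator.

The generator procedurally renders a 7-class edible-mushroom dataset
whose default per-class train/validation counts match the curated
collection the classifier is aimed at (2,435 images, split 7:3, with a
rare "Mix" class of only 14 train / 10 validation images drawn from the
other six species' renderers).  Every class has a distinct cap/stipe
silhouette, colour palette and procedural texture, with seeded jitter
in pose, scale and illumination plus background clutter — so classes
are separable by a linear probe on colour statistics by construction,
while single images still vary.  Identical (spec, seed) produce
byte-identical PNG trees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassSpec:
    name: str
    train_n: int
    val_n: int


# default composition of the 7-class edible-mushroom collection
DEFAULT_CLASSES = (
    ClassSpec("Agaricus_bisporus", 187, 71),
    ClassSpec("Boletus", 233, 106),
    ClassSpec("Hericium_erinaceus", 304, 108),
    ClassSpec("Lentinula_edodes", 446, 174),
    ClassSpec("Mix", 14, 10),
    ClassSpec("Pleurotus_eryngii", 283, 148),
    ClassSpec("Tremella", 246, 105),
)


@dataclass
class DatasetSpec:
    classes: tuple[ClassSpec, ...] = DEFAULT_CLASSES
    image_size: tuple[int, int] = (224, 224)
    seed: int = 0

    def __post_init__(self):
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if any(c.train_n < 0 or c.val_n < 0 for c in self.classes):
            raise ValueError("class counts must be nonnegative")

    @property
    def total(self) -> int:
        return sum(c.train_n + c.val_n for c in self.classes)

    def scaled(self, factor: float, min_train: int = 2, min_val: int = 1) -> "DatasetSpec":
        """Proportionally reduced spec (for desk-scale experiments)."""
        classes = tuple(
            ClassSpec(c.name, max(min_train, round(c.train_n * factor)),
                      max(min_val, round(c.val_n * factor)))
            for c in self.classes)
        return replace(self, classes=classes)


@dataclass
class ImageItem:
    source: object            # path (str) or uint8 array
    class_index: int
    split: str = ""


@dataclass
class LabeledImageSet:
    items: list[ImageItem]
    class_names: list[str]
    image_size: tuple[int, int] = (224, 224)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([it.class_index for it in self.items], dtype=np.int64)

    def subset(self, split: str) -> "LabeledImageSet":
        return LabeledImageSet([it for it in self.items if it.split == split],
                               self.class_names, self.image_size)

    def load_array(self, i: int) -> np.ndarray:
        """One image as float32 (3, H, W) in [0, 1], resized to image_size."""
        src = self.items[i].source
        if isinstance(src, np.ndarray):
            arr = src
            if arr.shape[:2] != self.image_size:
                arr = np.asarray(Image.fromarray(arr).resize(
                    self.image_size[::-1], Image.BILINEAR))
        else:
            with Image.open(src) as im:
                arr = np.asarray(im.convert("RGB").resize(
                    self.image_size[::-1], Image.BILINEAR))
        return (arr.astype(np.float32) / 255.0).transpose(2, 0, 1)

    def load_batch(self, indices) -> np.ndarray:
        return np.stack([self.load_array(int(i)) for i in indices])


# ---------------------------------------------------------------------------
# procedural renderer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesStyle:
    cap_color: tuple[int, int, int]
    stipe_color: tuple[int, int, int]
    cap_aspect: float      # cap half-width / half-height
    cap_frac: float        # cap half-width as fraction of image side
    stipe_w: float         # stipe half-width fraction
    stipe_h: float         # stipe length fraction
    texture: str           # gills | ridges | speckle | cracks | wavy


STYLES: dict[str, SpeciesStyle] = {
    # white button mushroom: clean white dome, narrow short stipe, gills
    "Agaricus_bisporus": SpeciesStyle((246, 243, 238), (232, 228, 220),
                                      1.35, 0.34, 0.07, 0.20, "gills"),
    # bolete: mid-brown broad cap, stout pale stipe, smooth ridged sheen
    "Boletus": SpeciesStyle((148, 92, 44), (214, 192, 150),
                            1.8, 0.40, 0.12, 0.24, "ridges"),
    # lion's mane: cream pom-pom, almost no stipe, shaggy speckle
    "Hericium_erinaceus": SpeciesStyle((236, 222, 168), (222, 208, 160),
                                       1.05, 0.40, 0.05, 0.06, "speckle"),
    # shiitake: dark umber cap with pale cracks, slim tan stipe
    "Lentinula_edodes": SpeciesStyle((88, 54, 30), (190, 168, 130),
                                     1.6, 0.38, 0.06, 0.18, "cracks"),
    # king oyster: small tan cap on a massive pale stipe
    "Pleurotus_eryngii": SpeciesStyle((196, 168, 120), (235, 230, 214),
                                      1.5, 0.22, 0.15, 0.40, "gills"),
    # tremella: golden wavy folds, no visible stipe
    "Tremella": SpeciesStyle((252, 196, 70), (244, 188, 80),
                             1.2, 0.40, 0.06, 0.05, "wavy"),
}

MIX_CLASS = "Mix"
BACKGROUND = np.array([112, 116, 98], dtype=np.float32)
_TEXTURES = ("gills", "ridges", "speckle", "cracks", "wavy")


def style_for(class_name: str) -> SpeciesStyle:
    """Style for a class: named species directly, other names get a
    deterministic procedurally derived palette/silhouette."""
    if class_name in STYLES:
        return STYLES[class_name]
    import hashlib
    digest = hashlib.sha256(class_name.encode()).digest()
    r = np.random.default_rng(np.frombuffer(digest[:8], dtype=np.uint64))
    cap = tuple(int(v) for v in r.integers(60, 250, 3))
    stipe = tuple(int(v) for v in r.integers(120, 245, 3))
    return SpeciesStyle(cap, stipe,
                        cap_aspect=float(r.uniform(1.0, 1.9)),
                        cap_frac=float(r.uniform(0.25, 0.4)),
                        stipe_w=float(r.uniform(0.05, 0.14)),
                        stipe_h=float(r.uniform(0.05, 0.35)),
                        texture=_TEXTURES[int(r.integers(len(_TEXTURES)))])


def _smooth_noise(rng: np.random.Generator, hw: tuple[int, int],
                  cells: int = 7) -> np.ndarray:
    """Low-frequency noise field in [-1, 1] via upscaled coarse grid."""
    H, W = hw
    coarse = rng.uniform(-1, 1, size=(cells, cells)).astype(np.float32)
    img = Image.fromarray(((coarse + 1) * 127.5).astype(np.uint8))
    fine = np.asarray(img.resize((W, H), Image.BILINEAR), dtype=np.float32)
    return fine / 127.5 - 1.0


def render_image(class_name: str, rng: np.random.Generator,
                 size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Render one uint8 (H, W, 3) mushroom image for a species class."""
    if class_name == MIX_CLASS:
        class_name = sorted(STYLES)[rng.integers(len(STYLES))]
    style = style_for(class_name)
    H, W = size
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float32)

    # background: tinted low-frequency field plus a few clutter blobs
    img = np.empty((H, W, 3), dtype=np.float32)
    base = BACKGROUND * rng.uniform(0.92, 1.08)
    field = _smooth_noise(rng, (H, W))
    for c in range(3):
        img[:, :, c] = base[c] * (1.0 + 0.12 * field)
    for _ in range(rng.integers(2, 5)):
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        a, b = rng.uniform(8, 24, size=2)
        blob = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1
        tint = rng.uniform(0.85, 1.15)
        img[blob] *= tint

    # pose / scale jitter
    scale = rng.uniform(0.88, 1.08)
    cx = W * (0.5 + rng.uniform(-0.06, 0.06))
    cy = H * (0.42 + rng.uniform(-0.05, 0.05))
    b = style.cap_frac * H * scale / style.cap_aspect * rng.uniform(0.92, 1.08)
    a = b * style.cap_aspect * rng.uniform(0.95, 1.05)

    hue_jitter = rng.uniform(-10, 10, size=3).astype(np.float32)
    cap_color = np.clip(np.array(style.cap_color, np.float32) + hue_jitter, 0, 255)
    stipe_color = np.clip(np.array(style.stipe_color, np.float32) + hue_jitter, 0, 255)

    # stipe: rectangle descending from the cap centre
    sw = style.stipe_w * W * scale
    sh = style.stipe_h * H * scale
    stipe = ((np.abs(xx - cx) <= sw) & (yy >= cy) & (yy <= cy + b + sh * 2))
    img[stipe] = stipe_color * rng.uniform(0.94, 1.0)

    # cap: upper-half-weighted ellipse
    cap = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1
    shade = 1.0 - 0.2 * np.clip((yy - cy + b) / (2 * b), 0, 1)  # lit from top
    img[cap] = cap_color * shade[cap, None]

    # procedural texture on the cap
    if style.texture == "gills":
        lower = cap & (yy > cy)
        stripes = (np.sin((xx - cx) * (np.pi / 4.0)) > 0.2)
        img[lower & stripes] *= 0.85
    elif style.texture == "ridges":
        bands = np.sin((yy - cy) * (np.pi / 7.0) + rng.uniform(0, np.pi)) > 0.3
        img[cap & bands] *= 0.9
    elif style.texture == "speckle":
        spots = rng.random((H, W)) > 0.85
        img[cap & spots] *= 1.1
    elif style.texture == "cracks":
        cracks = _smooth_noise(rng, (H, W), cells=12) > 0.55
        img[cap & cracks] = np.clip(cap_color * 1.9, 0, 255)
    elif style.texture == "wavy":
        folds = np.sin((xx - cx) * 0.25 + (yy - cy) * 0.18) > 0.1
        img[cap & folds] *= 0.87

    # illumination: global gain plus a soft vertical gradient
    gain = rng.uniform(0.94, 1.06)
    grad = 1.0 + 0.05 * (0.5 - yy / H)
    img *= gain * grad[:, :, None]
    img += rng.normal(0, 4.0, size=img.shape).astype(np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


def _image_rng(seed: int, class_index: int, split_idx: int,
               image_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((seed, class_index, split_idx, image_index)))


def generate_synthetic_dataset(spec: DatasetSpec, out_dir) -> LabeledImageSet:
    """Write the synthetic dataset tree ``out_dir/<split>/<class>/<idx>.png``.

    Deterministic: the same (spec, seed) always produces byte-identical
    files.  Returns the full labelled set (train + val, tagged by split)
    and writes a ``manifest.csv`` of (path, class, split).
    """
    if spec.total == 0:
        raise ValueError("dataset spec contains zero images")
    out_dir = Path(out_dir)
    names = sorted(c.name for c in spec.classes)
    index_of = {n: i for i, n in enumerate(names)}
    items: list[ImageItem] = []
    manifest = ["path,class,split"]
    by_name = {c.name: c for c in spec.classes}
    for name in names:
        cs = by_name[name]
        ci = index_of[name]
        for split_idx, (split, count) in enumerate(
                (("train", cs.train_n), ("val", cs.val_n))):
            folder = out_dir / split / name
            folder.mkdir(parents=True, exist_ok=True)
            for i in range(count):
                rng = _image_rng(spec.seed, ci, split_idx, i)
                arr = render_image(name, rng, spec.image_size)
                path = folder / f"{i:05d}.png"
                Image.fromarray(arr).save(path, format="PNG")
                items.append(ImageItem(str(path), ci, split))
                manifest.append(f"{path},{name},{split}")
    (out_dir / "manifest.csv").write_text("\n".join(manifest) + "\n")
    return LabeledImageSet(items, names, spec.image_size)


# ---------------------------------------------------------------------------
# folder loading and splitting
# ---------------------------------------------------------------------------

def load_image_folder(root, image_size: tuple[int, int] = (224, 224)) -> LabeledImageSet:
    """Read a class-subdirectory tree; alphabetical order fixes class indices."""
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories found under {root}")
    names = [d.name for d in class_dirs]
    items: list[ImageItem] = []
    for ci, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                with Image.open(f) as im:
                    im.verify()
            except Exception:
                log.warning("skipping unreadable image %s", f)
                continue
            items.append(ImageItem(str(f), ci))
    if not items:
        raise ValueError(f"no readable images found under {root}")
    return LabeledImageSet(items, names, image_size)


def stratified_split(items: LabeledImageSet, train_fraction: float,
                     seed: int = 0) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Per-class split: round-half-up of n * fraction to train, rest to val."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    labels = items.labels
    train_items, val_items = [], []
    for ci, name in enumerate(items.class_names):
        idx = np.nonzero(labels == ci)[0]
        if idx.size == 0:
            warnings.warn(f"class {name!r} has no items; skipped in split")
            continue
        rng.shuffle(idx)
        n_train = int(np.floor(idx.size * train_fraction + 0.5))
        for j in idx[:n_train]:
            it = items.items[j]
            train_items.append(ImageItem(it.source, it.class_index, "train"))
        for j in idx[n_train:]:
            it = items.items[j]
            val_items.append(ImageItem(it.source, it.class_index, "val"))
    return (LabeledImageSet(train_items, items.class_names, items.image_size),
            LabeledImageSet(val_items, items.class_names, items.image_size))
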