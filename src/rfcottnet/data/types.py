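"""Dataset record types and the CCDPHD-11 class table.

CCDPHD-11 is an 11-class cotton leaf disease/pest corpus (10 disease or pest
categories plus healthy leaves, 18,953 images, strongly class-imbalanced).
The real images are not required anywhere in this package: the synthetic
renderer emulates the class structure so the full pipeline stays exercisable
offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SOURCES = ("online", "field", "augmented", "synthetic")
SPLITS = ("train", "test", "unassigned")

#: Published per-class image totals of the CCDPHD-11 corpus.
CCDPHD11_CLASS_TOTALS: dict[str, int] = {
    "Healthy": 6444,
    "Aphids": 1582,
    "Army worm": 1360,
    "Bacterial blight": 2477,
    "Cotton curl virus": 2530,
    "Fusarium wilt": 881,
    "Herbicide growth damage": 280,
    "Leaf redding": 578,
    "Leaf variegation": 116,
    "Powdery mildew": 1350,
    "Target spot": 1355,
}

CCDPHD11_CLASSES = tuple(CCDPHD11_CLASS_TOTALS)

#: Field-collection accounting of the corpus: 796 usable field images were
#: augmented 6-fold (originals included) to 4,776 and merged with 14,177
#: online images into 18,953.
N_FIELD_ORIGINALS = 796
N_ONLINE = 14_177
AUGMENT_FACTOR = 6


@dataclass
class ImageSample:
    """One labeled image record."""

    path: str
    label: str
    source: str = "synthetic"
    split: str = "unassigned"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")


@dataclass
class VisualSignature:
    """Parameters of the synthetic leaf renderer for one class.

    The signature is what makes classes visually distinct (and therefore
    learnable by construction): lesion count, lesion hue, background hue and
    texture noise are drawn per class.
    Hues are in [0, 1) (HSV), sizes are fractions of the image side.
    """

    lesion_count_range: tuple[int, int] = (3, 8)
    lesion_hue: float = 0.08
    leaf_hue: float = 0.30
    background_hue: float = 0.12
    texture_noise_sigma: float = 6.0
    lesion_size_range: tuple[float, float] = (0.04, 0.12)

    def __post_init__(self):
        lo, hi = self.lesion_count_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid lesion_count_range")
        for h in (self.lesion_hue, self.leaf_hue, self.background_hue):
            if not 0.0 <= h < 1.0:
                raise ValueError("hues must lie in [0, 1)")
        if self.texture_noise_sigma < 0:
            raise ValueError("texture_noise_sigma must be >= 0")


@dataclass
class ClassSpec:
    """How many images to synthesize for a class, and how they should look."""

    name: str
    n_images: int
    visual_signature: VisualSignature = field(default_factory=VisualSignature)

    def __post_init__(self):
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")


@dataclass
class AugmentationPolicy:
    """The five stochastic augmentation operators and how many outputs to make.

    ``variants_per_original`` counts the unmodified original among its
    outputs, matching the corpus accounting (796 x 6 = 4,776 including
    originals).  Each further variant applies an independently sampled,
    non-empty subset of {brightness, flip, masking, noise, rotation}.
    """

    brightness_delta: float = 0.30
    flip_modes: tuple[str, ...] = ("horizontal", "vertical")
    mask_count_range: tuple[int, int] = (1, 20)
    mask_size_range: tuple[float, float] = (0.02, 0.20)
    noise_sigma: float = 10.0
    rotation_range: float = 30.0
    variants_per_original: int = AUGMENT_FACTOR

    def __post_init__(self):
        if self.variants_per_original < 1:
            raise ValueError("variants_per_original must be >= 1")
        lo, hi = self.mask_count_range
        if not (1 <= lo <= hi <= 20):
            raise ValueError("mask_count_range must lie within [1, 20]")
        for m in self.flip_modes:
            if m not in ("horizontal", "vertical"):
                raise ValueError(f"unknown flip mode {m!r}")


@dataclass
class DatasetManifest:
    """Ordered collection of samples plus split accounting."""

    samples: list[ImageSample] = field(default_factory=list)
    classes: tuple[str, ...] = CCDPHD11_CLASSES
    seed: int = 0

    def __len__(self) -> int:
        return len(self.samples)

    def class_counts(self) -> dict[str, tuple[int, int, int]]:
        """Per class (train, test, total); train + test = total once split."""
        counts = {c: [0, 0, 0] for c in self.classes}
        for s in self.samples:
            counts[s.label][2] += 1
            if s.split == "train":
                counts[s.label][0] += 1
            elif s.split == "test":
                counts[s.label][1] += 1
        return {c: tuple(v) for c, v in counts.items()}

    def subset(self, *, source: str | None = None, split: str | None = None) -> "DatasetManifest":
        keep = [s for s in self.samples
                if (source is None or s.source == source)
                and (split is None or s.split == split)]
        return DatasetManifest([replace(s) for s in keep], self.classes, self.seed)


def default_class_signatures() -> dict[str, VisualSignature]:
    """One distinct renderer signature per CCDPHD-11 class.

    Lesion/background hues are spread over the color circle and lesion counts
    differ so that the 11 classes are separable; Healthy carries no lesions.
    """
    sigs: dict[str, VisualSignature] = {}
    for i, name in enumerate(CCDPHD11_CLASSES):
        if name == "Healthy":
            sigs[name] = VisualSignature(lesion_count_range=(0, 0),
                                         leaf_hue=0.33, background_hue=0.10)
        else:
            sigs[name] = VisualSignature(
                lesion_count_range=(2 + (i % 4) * 3, 6 + (i % 4) * 3),
                lesion_hue=(0.02 + 0.09 * i) % 1.0,
                leaf_hue=0.26 + 0.015 * (i % 5),
                background_hue=(0.55 + 0.04 * i) % 1.0,
                texture_noise_sigma=4.0 + (i % 3) * 3.0,
            )
    return sigs
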