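"""Manifest CSV I/O and the stratified 8:2 splitter."""

from __future__ import annotations

import csv
import os
import re
from dataclasses import replace
from typing import Sequence

import numpy as np

from .types import SOURCES, SPLITS, DatasetManifest, ImageSample

MANIFEST_HEADER = ["path", "label", "source", "split"]
_AUG_SUFFIX = re.compile(r"_aug\d+$")


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_HEADER)
        for s in manifest.samples:
            writer.writerow([s.path, s.label, s.source, s.split])


def read_manifest(path: str | os.PathLike,
                  classes: Sequence[str] | None = None) -> DatasetManifest:
    """Read a manifest CSV, validating every row (errors name the row)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    samples: list[ImageSample] = []
    seen_labels: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != MANIFEST_HEADER:
            raise ValueError(f"bad manifest header {header!r}, "
                             f"expected {MANIFEST_HEADER!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 4:
                raise ValueError(f"row {lineno}: expected 4 fields, got {len(row)}")
            p, label, source, split = row
            if classes is not None and label not in classes:
                raise ValueError(f"row {lineno}: unknown label {label!r}")
            if source not in SOURCES:
                raise ValueError(f"row {lineno}: unknown source {source!r}")
            if split not in SPLITS:
                raise ValueError(f"row {lineno}: unknown split {split!r}")
            samples.append(ImageSample(p, label, source, split))
            if label not in seen_labels:
                seen_labels.append(label)
    cls = tuple(classes) if classes is not None else tuple(seen_labels)
    return DatasetManifest(samples, cls)


def split_counts(totals: Sequence[int], train_fraction: float) -> list[tuple[int, int]]:
    """Count-level split rule: per class, train = floor(f*n), test = n - train.

    This per-class floor rule reproduces the published CCDPHD-11 split table
    exactly (15,159 / 3,794 over the 11 class totals at f = 0.8).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    out = []
    for n in totals:
        tr = int(np.floor(train_fraction * n))
        out.append((tr, n - tr))
    return out


def _origin_key(sample: ImageSample) -> str:
    stem = os.path.splitext(os.path.basename(sample.path))[0]
    return _AUG_SUFFIX.sub("", stem) if sample.source == "augmented" else stem


def stratified_split(manifest: DatasetManifest, train_fraction: float = 0.8,
                     seed: int = 0, group_variants: bool = True) -> DatasetManifest:
    """Assign train/test per class by seeded shuffle.

    Per class of size n the train count is floor(train_fraction * n) with the
    remainder going to test.  With ``group_variants`` (default) augmented
    variants stay in the same split as their original — stricter than any
    published protocol, avoiding train/test leakage of near-duplicates; the
    floor rule then applies to origin groups rather than raw images.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    new_samples = [replace(s) for s in manifest.samples]
    for cls in manifest.classes:
        idx = [i for i, s in enumerate(new_samples) if s.label == cls]
        if group_variants:
            groups: dict[str, list[int]] = {}
            for i in idx:
                groups.setdefault(_origin_key(new_samples[i]), []).append(i)
            units = list(groups.values())
        else:
            units = [[i] for i in idx]
        order = rng.permutation(len(units))
        n_train = int(np.floor(train_fraction * len(units)))
        for rank, ui in enumerate(order):
            split = "train" if rank < n_train else "test"
            for i in units[ui]:
                new_samples[i].split = split
    return DatasetManifest(new_samples, manifest.classes, seed)
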