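"""Patient indexing, triplet/pair sampling and image preprocessing.

Metadata follows the NIH ChestX-ray14 ``Data_Entry`` dialect: a CSV with an
``Image Index`` column (the PNG filename) and a ``Patient ID`` column.  A
column mapping supports other layouts (e.g. CheXpert-style paths).  Patients
with fewer than two radiographs are excluded: a single image can serve
neither as an anchor-positive pair nor as a verifiable identity.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

logger = logging.getLogger(__name__)

#: default NIH-dialect column names (image filename, patient identifier)
NIH_COLUMNS = {"image": "Image Index", "patient": "Patient ID"}


class PatientImageIndex(dict):
    """Ordered mapping patient_id -> list of image references.

    Every retained patient has at least two images; lists preserve a
    deterministic (sorted) order so downstream sampling is replayable.
    """

    @property
    def n_images(self) -> int:
        return sum(len(v) for v in self.values())


@dataclass
class Triplet:
    anchor: object
    positive: object
    negative: object
    anchor_patient: str
    negative_patient: str

    def __post_init__(self):
        if self.anchor_patient == self.negative_patient:
            raise ValueError("negative must come from a different patient")
        if _ref_equal(self.anchor, self.positive):
            raise ValueError("anchor and positive must be distinct images")


@dataclass
class LabeledPair:
    image_a: object
    image_b: object
    same_patient: bool


def _ref_equal(a, b) -> bool:
    if isinstance(a, str) and isinstance(b, str):
        return a == b
    return a is b


def index_patients(metadata, image_dir=None, columns=None) -> PatientImageIndex:
    """Build a patient -> images index, keeping patients with >= 2 images.

    ``metadata`` is a pandas DataFrame or a CSV path.  When ``image_dir`` is
    given, references are absolute file paths; otherwise the raw image IDs.
    """
    cols = dict(NIH_COLUMNS)
    if columns:
        cols.update(columns)
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata)
    for role in ("image", "patient"):
        if cols[role] not in metadata.columns:
            raise ValueError(
                f"metadata is missing the {cols[role]!r} column "
                f"(available: {list(metadata.columns)})"
            )
    index = PatientImageIndex()
    if len(metadata) == 0:
        warnings.warn("empty metadata table: no patients retained", stacklevel=2)
        return index
    grouped = metadata.groupby(metadata[cols["patient"]].astype(str), sort=True)
    for patient, group in grouped:
        images = sorted(dict.fromkeys(group[cols["image"]].astype(str)))
        if len(images) < 2:
            continue
        if image_dir is not None:
            images = [str(Path(image_dir) / name) for name in images]
        index[patient] = images
    if not index:
        warnings.warn(
            "no patient has two or more radiographs; index is empty",
            stacklevel=2,
        )
    return index


def sample_triplets(index: PatientImageIndex, n: int, seed: int) -> list[Triplet]:
    """Sample ``n`` anchor/positive/negative triplets, replayable from seed.

    Each pass over the (shuffled) patients takes one anchor per patient, a
    positive drawn uniformly from that patient's remaining images, and a
    negative drawn uniformly from another patient's images.
    """
    patients = list(index.keys())
    if len(patients) < 2:
        raise ValueError("triplet sampling needs at least two patients")
    rng = np.random.default_rng(seed)
    triplets: list[Triplet] = []
    while len(triplets) < n:
        for pi in rng.permutation(len(patients)):
            if len(triplets) >= n:
                break
            patient = patients[pi]
            images = index[patient]
            a, p = rng.choice(len(images), size=2, replace=False)
            j = int(rng.integers(len(patients) - 1))  # uniform over others
            if j >= pi:
                j += 1
            other = patients[j]
            neg_images = index[other]
            negative = neg_images[int(rng.integers(len(neg_images)))]
            triplets.append(
                Triplet(images[int(a)], images[int(p)], negative, patient, other)
            )
    return triplets


def sample_pairs(index: PatientImageIndex, n: int, seed: int) -> list[LabeledPair]:
    """Sample ``n`` labeled verification pairs, alternating positive/negative."""
    patients = list(index.keys())
    if len(patients) < 2:
        raise ValueError("pair sampling needs at least two patients")
    rng = np.random.default_rng(seed)
    pairs: list[LabeledPair] = []
    for k in range(n):
        if k % 2 == 0:  # positive: two images of one patient
            patient = patients[int(rng.integers(len(patients)))]
            i, j = rng.choice(len(index[patient]), size=2, replace=False)
            pairs.append(LabeledPair(index[patient][int(i)], index[patient][int(j)], True))
        else:  # negative: one image from each of two patients
            pi, pj = rng.choice(len(patients), size=2, replace=False)
            a = index[patients[int(pi)]]
            b = index[patients[int(pj)]]
            pairs.append(
                LabeledPair(
                    a[int(rng.integers(len(a)))],
                    b[int(rng.integers(len(b)))],
                    False,
                )
            )
    return pairs


def preprocess_image(ref, size: int = 200) -> np.ndarray:
    """Load and normalize one radiograph to ``size x size x 3`` in [0, 1].

    ``ref`` is a PNG path or an array (grayscale H x W or H x W x 3).
    8-bit inputs are scaled by 1/255; grayscale planes are replicated to
    three channels; resizing is bilinear with anti-aliasing.
    """
    if isinstance(ref, (str, Path)):
        try:
            with Image.open(ref) as img:
                arr = np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read image {ref!r}: {exc}") from exc
    else:
        arr = np.asarray(ref, dtype=np.float64)
        if arr.max(initial=0.0) > 1.0:  # 8-bit array input
            arr = arr / 255.0
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValueError(f"unsupported image shape {arr.shape}")
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[:2] != (size, size):
        arr = resize(arr, (size, size), order=1, anti_aliasing=True,
                     preserve_range=True)
    return np.clip(arr, 0.0, 1.0)


def write_triplet_manifest(triplets: list[Triplet], path):
    """Audit CSV of sampled triplets (anchor, positive, negative, patients)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["anchor", "positive", "negative",
                        "anchor_patient", "negative_patient"])
        for t in triplets:
            writer.writerow([t.anchor, t.positive, t.negative,
                            t.anchor_patient, t.negative_patient])
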