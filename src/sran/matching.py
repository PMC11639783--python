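"""Embedding galleries, top-k identification, verification and evaluation.

The testing phase never retrains the network: every enrolled radiograph is
mapped once to its embedding and stored alongside its image and patient
identifiers.  Identification ranks a gallery by Euclidean distance to a
query embedding and returns the top-k closest entries; verification
declares two images the same person iff their embedding distance falls
below a threshold.  Because no operating threshold is prescribed a priori,
:func:`calibrate_threshold` sweeps the midpoints of observed labeled-pair
distances for the accuracy-maximizing threshold and also reports the
equal-error-rate operating point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabeledPair, PatientImageIndex, preprocess_image
from .network import EmbeddingGenerator, euclidean_distance

logger = logging.getLogger(__name__)


class EmbeddingStore:
    """Gallery of (image_id, patient_id, embedding) rows."""

    def __init__(self, embedding_dim: int):
        self.embedding_dim = int(embedding_dim)
        self.image_ids: list[str] = []
        self.patient_ids: list[str] = []
        self._rows: list[np.ndarray] = []

    def __len__(self):
        return len(self.image_ids)

    @property
    def embeddings(self) -> np.ndarray:
        if not self._rows:
            return np.zeros((0, self.embedding_dim))
        return np.vstack(self._rows)

    def add(self, image_id: str, patient_id: str, embedding):
        embedding = np.asarray(embedding, dtype=np.float64).ravel()
        if embedding.shape[0] != self.embedding_dim:
            raise ValueError(
                f"embedding length {embedding.shape[0]} != store dim {self.embedding_dim}"
            )
        if image_id in self.image_ids:
            raise ValueError(f"duplicate image_id {image_id!r}")
        self.image_ids.append(str(image_id))
        self.patient_ids.append(str(patient_id))
        self._rows.append(embedding)

    def get(self, image_id: str) -> np.ndarray:
        return self._rows[self.image_ids.index(image_id)]

    def patient_of(self, image_id: str) -> str:
        return self.patient_ids[self.image_ids.index(image_id)]

    # -- persistence: npz embeddings + CSV manifest ----------------------
    def save(self, path):
        path = Path(path)
        np.savez(
            path,
            embeddings=self.embeddings,
            image_ids=np.array(self.image_ids),
            patient_ids=np.array(self.patient_ids),
            embedding_dim=np.array(self.embedding_dim),
        )
        manifest = path.with_suffix(".manifest.csv")
        pd.DataFrame({"image_id": self.image_ids, "patient_id": self.patient_ids}).to_csv(
            manifest, index=False
        )

    @classmethod
    def load(cls, path) -> "EmbeddingStore":
        path = Path(path)
        if path.suffix != ".npz" and not path.exists():
            path = path.with_suffix(".npz")
        with np.load(path) as archive:
            store = cls(int(archive["embedding_dim"]))
            for image_id, patient_id, row in zip(
                archive["image_ids"], archive["patient_ids"], archive["embeddings"]
            ):
                store.add(str(image_id), str(patient_id), row)
        return store


@dataclass
class IdentificationResult:
    query_id: str | None
    entries: list[tuple[str, str, float]]  # (image_id, patient_id, distance)

    @property
    def top_patient(self) -> str:
        return self.entries[0][1]


@dataclass
class VerificationDecision:
    distance: float
    threshold: float
    same_person: bool


@dataclass
class ThresholdCalibration:
    threshold: float
    accuracy: float
    eer_threshold: float
    eer: float


@dataclass
class EvalProtocol:
    k: int = 5
    n_pairs: int = 200
    pair_seed: int = 0
    calibration_fraction: float = 0.5


@dataclass
class EvalReport:
    top1_accuracy: float
    top5_hit_rate: float
    verification_accuracy: float
    verification_precision: float
    verification_recall: float
    threshold: float
    n_queries: int
    n_pairs: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        return (
            f"identification: top-1 {self.top1_accuracy:.3f}, "
            f"top-5 hit rate {self.top5_hit_rate:.3f} ({self.n_queries} queries)\n"
            f"verification:   accuracy {self.verification_accuracy:.3f}, "
            f"precision {self.verification_precision:.3f}, "
            f"recall {self.verification_recall:.3f} "
            f"@ threshold {self.threshold:.4f} ({self.n_pairs} held-out pairs)"
        )


def embed_collection(model: EmbeddingGenerator, index: PatientImageIndex,
                     size: int | None = None, batch_size: int = 32) -> EmbeddingStore:
    """Embed every indexed image (inference mode) into a store.

    Unreadable images are skipped with a logged warning and counted in
    ``store.n_skipped``.
    """
    size = size or model.cfg.input_height
    store = EmbeddingStore(model.cfg.embedding_dim)
    refs, image_ids, patient_ids = [], [], []
    skipped = 0
    for patient, images in index.items():
        for ref in images:
            image_id = Path(ref).name if isinstance(ref, (str, Path)) else f"array-{len(image_ids)}"
            try:
                refs.append(preprocess_image(ref, size=size))
            except OSError as exc:
                logger.warning("skipping unreadable image %s: %s", image_id, exc)
                skipped += 1
                continue
            image_ids.append(image_id)
            patient_ids.append(patient)
    for start in range(0, len(refs), batch_size):
        batch = np.stack(refs[start : start + batch_size])
        for image_id, patient, emb in zip(
            image_ids[start:], patient_ids[start:], model.embed(batch)
        ):
            store.add(image_id, patient, emb)
    store.n_skipped = skipped
    return store


def identify_topk(query, store: EmbeddingStore, k: int = 5,
                  query_id: str | None = None,
                  exclude: set[str] | None = None) -> IdentificationResult:
    """Rank the gallery by Euclidean distance; keep the k closest entries.

    Ties are broken lexicographically by image_id.  ``exclude`` removes
    gallery entries (e.g. the query's own image) before ranking.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(store) == 0:
        raise ValueError("empty embedding store")
    query = np.asarray(query, dtype=np.float64).ravel()
    if query.shape[0] != store.embedding_dim:
        raise ValueError("query embedding length does not match the store")
    mask = [image_id not in exclude for image_id in store.image_ids] if exclude else None
    rows = [
        (float(np.sqrt(np.sum((emb - query) ** 2))), image_id, patient)
        for i, (image_id, patient, emb) in enumerate(
            zip(store.image_ids, store.patient_ids, store.embeddings)
        )
        if mask is None or mask[i]
    ]
    rows.sort(key=lambda r: (r[0], r[1]))
    if k > len(rows):
        logger.warning("k=%d exceeds gallery size %d; returning all", k, len(rows))
    top = rows[:k]
    return IdentificationResult(query_id, [(iid, pid, d) for d, iid, pid in top])


def verify_pair(a, b, threshold: float) -> VerificationDecision:
    """One-to-one check: same person iff the embedding distance < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = euclidean_distance(a, b)
    return VerificationDecision(distance=d, threshold=threshold, same_person=d < threshold)


def _pair_distances(pairs: list[LabeledPair], store: EmbeddingStore):
    ids = [Path(r).name if isinstance(r, (str, Path)) else r for p in pairs for r in (p.image_a, p.image_b)]
    d = np.array([
        euclidean_distance(store.get(ids[2 * i]), store.get(ids[2 * i + 1]))
        for i in range(len(pairs))
    ])
    labels = np.array([p.same_patient for p in pairs], dtype=bool)
    return d, labels


def calibrate_from_distances(distances, labels) -> ThresholdCalibration:
    """Accuracy-maximizing threshold over midpoints of sorted distances.

    Candidate thresholds are the midpoints between consecutive distinct
    observed distances plus sentinels below and above all of them; ties in
    accuracy resolve to the smallest threshold.  The equal-error-rate
    operating point (|FAR - FRR| minimal) is reported alongside.
    """
    distances = np.asarray(distances, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("calibration needs both same- and different-person pairs")
    uniq = np.unique(distances)
    below = uniq[0] / 2.0 if uniq[0] > 0 else uniq[0] - 1.0
    candidates = np.concatenate(([below], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]))
    candidates = candidates[candidates > 0]
    if candidates.size == 0:
        candidates = np.array([1e-12])
    pred = distances[None, :] < candidates[:, None]
    acc = (pred == labels[None, :]).mean(axis=1)
    best = int(np.argmax(acc))  # argmax returns the first (smallest) maximizer
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    frr = ((~pred) & labels[None, :]).sum(axis=1) / n_pos  # false reject
    far = (pred & ~labels[None, :]).sum(axis=1) / n_neg    # false accept
    eer_i = int(np.argmin(np.abs(far - frr)))
    return ThresholdCalibration(
        threshold=float(candidates[best]),
        accuracy=float(acc[best]),
        eer_threshold=float(candidates[eer_i]),
        eer=float((far[eer_i] + frr[eer_i]) / 2.0),
    )


def calibrate_threshold(pairs: list[LabeledPair], store: EmbeddingStore) -> ThresholdCalibration:
    d, labels = _pair_distances(pairs, store)
    return calibrate_from_distances(d, labels)


def verification_metrics(distances, labels, threshold: float):
    """(accuracy, precision, recall) of ``distance < threshold`` decisions."""
    distances = np.asarray(distances, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    pred = distances < threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    accuracy = float((pred == labels).mean()) if labels.size else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return accuracy, precision, recall


def evaluate(store: EmbeddingStore, protocol: EvalProtocol = EvalProtocol()) -> EvalReport:
    """Closed-set identification + thresholded verification on one store.

    Queries are every image whose patient has at least one other image in
    the store; the query's own image is excluded from its gallery.  Labeled
    verification pairs are sampled from the store, split into a calibration
    half (threshold selection) and a held-out half (reported metrics).
    """
    ids = np.array(store.image_ids)
    patients = np.array(store.patient_ids)
    emb = store.embeddings
    counts = pd.Series(patients).value_counts()
    multi = set(counts[counts >= 2].index)
    queries = [i for i, p in enumerate(patients) if p in multi]
    if not queries:
        raise ValueError("no patient has >= 2 images; identification undefined")
    top1 = 0
    top5 = 0
    # full pairwise distance matrix (galleries are small at this scale)
    sq = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(sq)
    for qi in queries:
        rows = [(dist[qi, j], ids[j], patients[j]) for j in range(len(ids)) if j != qi]
        rows.sort(key=lambda r: (r[0], r[1]))
        top = rows[: protocol.k]
        if top[0][2] == patients[qi]:
            top1 += 1
        if any(r[2] == patients[qi] for r in top):
            top5 += 1
    # verification pairs over image ids present in the store
    index = PatientImageIndex()
    for p in sorted(multi):
        index[p] = sorted(ids[patients == p])
    from .data import sample_pairs

    pairs = sample_pairs(index, protocol.n_pairs, protocol.pair_seed)
    d, labels = _pair_distances(pairs, store)
    n_cal = max(2, int(len(pairs) * protocol.calibration_fraction))
    cal = calibrate_from_distances(d[:n_cal], labels[:n_cal])
    held_d, held_l = d[n_cal:], labels[n_cal:]
    accuracy, precision, recall = verification_metrics(held_d, held_l, cal.threshold)
    return EvalReport(
        top1_accuracy=top1 / len(queries),
        top5_hit_rate=top5 / len(queries),
        verification_accuracy=accuracy,
        verification_precision=precision,
        verification_recall=recall,
        threshold=cal.threshold,
        n_queries=len(queries),
        n_pairs=int(held_l.size),
    )
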