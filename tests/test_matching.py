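"""Gallery store, top-k retrieval, verification and evaluation tests."""

import numpy as np
import pytest

from sran.data import LabeledPair, index_patients
from sran.matching import (
    EmbeddingStore,
    EvalProtocol,
    calibrate_from_distances,
    calibrate_threshold,
    embed_collection,
    evaluate,
    identify_topk,
    verification_metrics,
    verify_pair,
)
from sran.network import NetworkConfig, build_embedding_generator, euclidean_distance


def _random_store(rng, n=20, dim=8, n_patients=5) -> EmbeddingStore:
    store = EmbeddingStore(dim)
    for i in range(n):
        store.add(f"img{i:03d}.png", f"p{i % n_patients}", rng.normal(size=dim))
    return store


class TestEmbeddingStore:
    def test_duplicate_image_id_rejected(self, rng):
        store = _random_store(rng, n=3)
        with pytest.raises(ValueError, match="duplicate"):
            store.add("img000.png", "p0", np.zeros(8))

    def test_dimension_mismatch_rejected(self, rng):
        store = _random_store(rng, n=2)
        with pytest.raises(ValueError, match="dim"):
            store.add("new.png", "p9", np.zeros(5))

    def test_round_trip_preserves_pairwise_distances(self, rng, tmp_path):
        store = _random_store(rng)
        path = tmp_path / "store.npz"
        store.save(path)
        loaded = EmbeddingStore.load(path)
        assert loaded.image_ids == store.image_ids
        assert loaded.patient_ids == store.patient_ids
        for i in range(0, len(store), 3):
            for j in range(1, len(store), 4):
                d0 = euclidean_distance(store.embeddings[i], store.embeddings[j])
                d1 = euclidean_distance(loaded.embeddings[i], loaded.embeddings[j])
                assert d1 == pytest.approx(d0, abs=1e-6)
        assert (tmp_path / "store.manifest.csv").exists()


class TestEmbedCollection:
    @pytest.fixture()
    def setup(self, phantom_dataset):
        out, _, _ = phantom_dataset
        index = index_patients(out / "metadata.csv", image_dir=out)
        model = build_embedding_generator(NetworkConfig.tiny(size=48, embedding_dim=16))
        return model, index

    def test_one_row_per_image(self, setup):
        model, index = setup
        store = embed_collection(model, index)
        assert len(store) == 15
        assert store.embedding_dim == 16
        assert store.n_skipped == 0

    def test_repeat_runs_identical(self, setup):
        model, index = setup
        a = embed_collection(model, index)
        b = embed_collection(model, index)
        np.testing.assert_allclose(a.embeddings, b.embeddings, atol=1e-6)

    def test_unreadable_image_skipped_and_counted(self, setup, tmp_path, caplog):
        model, index = setup
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"junk")
        patient = next(iter(index))
        index[patient] = index[patient] + [str(bad)]
        store = embed_collection(model, index)
        assert store.n_skipped == 1
        assert len(store) == 15


class TestIdentifyTopK:
    def test_self_retrieval_at_rank_one(self, rng):
        store = _random_store(rng)
        query = store.embeddings[7]
        result = identify_topk(query, store, k=5)
        assert result.entries[0][0] == "img007.png"
        assert result.entries[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_topk_matches_brute_force_sort(self, rng):
        store = _random_store(rng, n=100, n_patients=20)
        for _ in range(10):
            query = rng.normal(size=8)
            result = identify_topk(query, store, k=5)
            brute = sorted(
                (euclidean_distance(query, e), iid, pid)
                for iid, pid, e in zip(store.image_ids, store.patient_ids, store.embeddings)
            )[:5]
            assert len(result.entries) == 5
            dists = [d for _, _, d in result.entries]
            assert dists == sorted(dists)
            for (iid, pid, d), (bd, biid, bpid) in zip(result.entries, brute):
                assert (iid, pid) == (biid, bpid)
                assert d == pytest.approx(bd, abs=1e-9)

    def test_small_gallery_truncates_with_warning(self, rng, caplog):
        store = _random_store(rng, n=3)
        with caplog.at_level("WARNING"):
            result = identify_topk(rng.normal(size=8), store, k=5)
        assert len(result.entries) == 3
        assert "exceeds" in caplog.text

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError, match="k"):
            identify_topk(rng.normal(size=8), _random_store(rng), k=0)

    def test_exact_ties_break_lexicographically(self):
        store = EmbeddingStore(2)
        for name in ["b.png", "a.png", "c.png"]:
            store.add(name, "p", np.array([1.0, 0.0]))
        result = identify_topk(np.zeros(2), store, k=3)
        assert [e[0] for e in result.entries] == ["a.png", "b.png", "c.png"]


class TestVerifyPair:
    def test_identical_embeddings_always_match(self, rng):
        x = rng.normal(size=16)
        assert verify_pair(x, x, threshold=1e-6).same_person

    def test_distance_above_threshold_rejects(self):
        d = verify_pair(np.zeros(2), np.array([3.0, 4.0]), threshold=4.0)
        assert d.distance == pytest.approx(5.0)
        assert not d.same_person

    def test_decisions_match_comparison_oracle(self, rng):
        for _ in range(200):
            a, b = rng.normal(size=4), rng.normal(size=4)
            t = float(rng.uniform(0.1, 5.0))
            decision = verify_pair(a, b, t)
            assert decision.same_person == (euclidean_distance(a, b) < t)

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ValueError):
            verify_pair(np.zeros(2), np.zeros(2), threshold=0.0)


class TestCalibrateThreshold:
    def test_separable_distances_reach_perfect_accuracy(self):
        d = np.array([0.1, 0.2, 0.3, 1.0, 1.2, 1.5])
        labels = np.array([True, True, True, False, False, False])
        cal = calibrate_from_distances(d, labels)
        assert cal.accuracy == 1.0
        assert 0.3 < cal.threshold < 1.0
        assert cal.eer == 0.0

    def test_all_equal_distances_give_majority_accuracy(self):
        d = np.full(10, 2.0)
        labels = np.array([True] * 3 + [False] * 7)
        cal = calibrate_from_distances(d, labels)
        assert cal.accuracy == pytest.approx(0.7)

    def test_matches_exhaustive_sweep_oracle(self, rng):
        for trial in range(20):
            d = rng.uniform(0, 3, size=40)
            labels = rng.uniform(size=40) < 0.5
            if labels.all() or (~labels).all():
                continue
            cal = calibrate_from_distances(d, labels)
            # oracle: accuracy of every candidate threshold on a fine grid
            grid = np.linspace(1e-6, 3.5, 20_000)
            accs = ((d[None, :] < grid[:, None]) == labels[None, :]).mean(axis=1)
            assert cal.accuracy == pytest.approx(accs.max(), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            calibrate_from_distances([1.0, 2.0], [True, True])

    def test_store_based_calibration(self, rng):
        store = EmbeddingStore(2)
        store.add("a0", "a", np.zeros(2))
        store.add("a1", "a", np.array([0.1, 0.0]))
        store.add("b0", "b", np.array([5.0, 0.0]))
        pairs = [
            LabeledPair("a0", "a1", True),
            LabeledPair("a0", "b0", False),
            LabeledPair("a1", "b0", False),
        ]
        cal = calibrate_threshold(pairs, store)
        assert cal.accuracy == 1.0
        assert 0.1 < cal.threshold < 4.9


class TestEvaluate:
    def test_hand_built_store_with_unique_nearest_matches(self):
        # 3 patients x 2 images; same-patient embeddings 0.1 apart,
        # different patients 10 apart -> perfect retrieval
        store = EmbeddingStore(2)
        for i, p in enumerate(["x", "y", "z"]):
            base = np.array([10.0 * i, 0.0])
            store.add(f"{p}0", p, base)
            store.add(f"{p}1", p, base + [0.1, 0.0])
        report = evaluate(store, EvalProtocol(k=5, n_pairs=20, pair_seed=0))
        assert report.top1_accuracy == 1.0
        assert report.top5_hit_rate == 1.0
        assert report.verification_accuracy == 1.0

    def test_confusion_arithmetic_on_hand_counts(self):
        # TP, FP, TN, FN = 1 each
        distances = np.array([0.5, 0.5, 2.0, 2.0])
        labels = np.array([True, False, False, True])
        acc, prec, rec = verification_metrics(distances, labels, threshold=1.0)
        assert (acc, prec, rec) == (0.5, 0.5, 0.5)

    def test_singleton_patients_cannot_be_queries(self, rng):
        store = EmbeddingStore(2)
        store.add("a0", "a", rng.normal(size=2))
        with pytest.raises(ValueError, match=">= 2"):
            evaluate(store)
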