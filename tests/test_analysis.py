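import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmcodex.analysis import (
    MAX_DIAG_DIST,
    codeword_diagonal_profile,
    cosine_distance,
    diagonal_distance,
    nearest_neighbor_accuracy,
    pca_embed,
    pearson_r,
    relative_frequency,
    unique_word_ratio,
)
from dmcodex.bovw import CodewordHistogram, Feature
from dmcodex.structure_io import parse_scop_sid


def _hist(counts, image_id="h"):
    counts = np.asarray(counts, dtype=int)
    return CodewordHistogram(
        counts=counts, image_id=image_id, n_features=int(counts.sum())
    )


class TestCosineDistance:
    def test_identity(self):
        h = _hist([3, 1, 0, 2])
        assert cosine_distance(h, h) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance(_hist([1, 0]), _hist([0, 2])) == pytest.approx(1.0)

    def test_closed_form(self):
        d = cosine_distance(_hist([1, 1, 0]), _hist([1, 0, 0]))
        assert d == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_distance(_hist([0, 0]), _hist([1, 0]))

    @given(
        counts=st.lists(st.integers(0, 50), min_size=2, max_size=10).filter(
            lambda c: sum(c) > 0
        ),
        scale=st.integers(1, 7),
    )
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, counts, scale):
        h = _hist(counts)
        hs = _hist([c * scale for c in counts])
        assert cosine_distance(h, hs) == pytest.approx(0.0, abs=1e-9)


class TestNearestNeighbor:
    def test_duplicates_give_perfect_accuracy(self):
        hists, labels = [], []
        rng = np.random.default_rng(0)
        for i, sid in enumerate(["a.1.1.1", "b.2.1.1", "c.3.2.1"]):
            c = rng.integers(1, 10, size=6)
            for rep in range(2):
                hists.append(_hist(c, image_id=f"i{i}{rep}"))
                labels.append(parse_scop_sid(sid))
        for level in ("class", "fold", "superfamily", "family"):
            assert nearest_neighbor_accuracy(hists, labels, level) == 1.0

    def test_two_items_different_class(self):
        hists = [_hist([1, 0], "a"), _hist([0, 1], "b")]
        labels = [parse_scop_sid("a.1.1.1"), parse_scop_sid("b.1.1.1")]
        assert nearest_neighbor_accuracy(hists, labels, "class") == 0.0

    def test_matches_exhaustive_scan_oracle(self):
        """Leave-one-out accuracy must equal a brute-force all-pairs scan
        implemented independently with explicit cosine arithmetic."""
        rng = np.random.default_rng(1)
        sids = ["a.1.1.1", "a.1.2.1", "b.1.1.1", "b.2.1.1", "c.1.1.1"]
        hists, labels = [], []
        for i in range(20):
            hists.append(_hist(rng.integers(0, 8, size=12) + (i % 3 == 0),
                               image_id=f"im{i:02d}"))
            labels.append(parse_scop_sid(sids[i % len(sids)]))
        hists = [h for h in hists if h.n_features > 0]
        labels = labels[: len(hists)]

        def cos(a, b):
            a, b = np.asarray(a, float), np.asarray(b, float)
            return 1 - (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))

        for level in ("class", "fold", "family"):
            correct = 0
            for i, hi in enumerate(hists):
                best = min(
                    (round(cos(hi.counts, hj.counts), 12), hj.image_id, j)
                    for j, hj in enumerate(hists) if j != i
                )
                same = labels[i].level(level) == labels[best[2]].level(level)
                correct += same
            oracle = correct / len(hists)
            assert nearest_neighbor_accuracy(hists, labels, level) == pytest.approx(
                oracle
            )

    def test_unlabeled_errors(self):
        hists = [_hist([1], "a"), _hist([1], "b")]
        with pytest.raises(ValueError):
            nearest_neighbor_accuracy(hists, [parse_scop_sid("a.1.1.1"), None], "class")


class TestRelativeFrequency:
    def test_presence_counting(self):
        hists = [_hist([1, 0]), _hist([5, 0]), _hist([2, 1])] + [
            _hist([0, 1]) for _ in range(7)
        ]
        freq = relative_frequency(hists)
        assert freq[0] == pytest.approx(0.3)
        assert freq[1] == pytest.approx(0.8)

    def test_bounds(self):
        hists = [_hist([1, 0, 2]), _hist([3, 0, 1])]
        freq = relative_frequency(hists)
        assert freq[0] == 1.0 and freq[1] == 0.0 and freq[2] == 1.0

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            relative_frequency([])


class TestDiagonalDistance:
    def test_on_diagonal_is_zero(self):
        for n in (2, 10, 500):
            assert diagonal_distance(3 % n, 3 % n, n) == 0.0

    def test_corner_attains_bound(self):
        for n in (2, 7, 100):
            assert diagonal_distance(0, n - 1, n) == pytest.approx(MAX_DIAG_DIST)
            assert round(diagonal_distance(0, n - 1, n), 1) == 0.7

    def test_closed_form(self):
        # normalized coordinates (0.5, 0.25) on a 5x5 image
        assert diagonal_distance(2, 1, 5) == pytest.approx(0.25 / np.sqrt(2))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            diagonal_distance(0, 0, 1)
        with pytest.raises(ValueError):
            diagonal_distance(5, 0, 4)

    @given(
        n=st.integers(2, 300),
        x=st.integers(0, 299),
        y=st.integers(0, 299),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_bound(self, n, x, y):
        x, y = x % n, y % n
        d = diagonal_distance(x, y, n)
        assert d == diagonal_distance(y, x, n)
        assert 0 <= d <= MAX_DIAG_DIST + 1e-12


class TestDiagonalProfile:
    def _corpus(self):
        # 2 images, 3 codewords; assignments chosen by hand
        f = lambda x, y: Feature(x=x, y=y, scale=1.0,
                                 descriptor=np.zeros(64), image_id="")
        feats1 = [f(0, 0), f(4, 4), f(0, 4)]
        feats2 = [f(2, 2), f(4, 0)]
        h1 = CodewordHistogram(counts=np.array([2, 0, 1]), image_id="a",
                               n_features=3, assignments=np.array([0, 0, 2]))
        h2 = CodewordHistogram(counts=np.array([1, 0, 1]), image_id="b",
                               n_features=2, assignments=np.array([0, 2]))
        return [feats1, feats2], [h1, h2], [5, 5]

    def test_hand_computed_means(self):
        fsets, hists, sizes = self._corpus()
        stats = codeword_diagonal_profile(fsets, hists, sizes)
        # codeword 0: features on the diagonal only -> mean 0
        assert stats.mean_diag_dist[0] == pytest.approx(0.0)
        # codeword 2: offsets |x̂-ŷ| of 1 and 1 -> mean √2/2
        assert stats.mean_diag_dist[2] == pytest.approx(MAX_DIAG_DIST)
        # codeword 1 never assigned -> undefined
        assert np.isnan(stats.mean_diag_dist[1])
        assert stats.n_assigned.tolist() == [3, 0, 2]

    def test_mixed_offsets_average(self):
        f0 = Feature(x=0, y=0, scale=1, descriptor=np.zeros(64))
        f1 = Feature(x=0, y=4, scale=1, descriptor=np.zeros(64))
        h = CodewordHistogram(counts=np.array([2]), image_id="a",
                              n_features=2, assignments=np.array([0, 0]))
        stats = codeword_diagonal_profile([[f0, f1]], [h], [5])
        assert stats.mean_diag_dist[0] == pytest.approx(np.sqrt(2) / 4)

    def test_matches_flat_recomputation(self):
        """Per-codeword means must equal an independent aggregation over the
        flattened (codeword, distance) table."""
        rng = np.random.default_rng(3)
        k, fsets, hists, sizes = 6, [], [], []
        flat = []
        for i in range(5):
            n = int(rng.integers(10, 30))
            m = int(rng.integers(1, 15))
            feats = [Feature(x=float(rng.integers(0, n)), y=float(rng.integers(0, n)),
                             scale=1, descriptor=np.zeros(64)) for _ in range(m)]
            assign = rng.integers(0, k, size=m)
            hists.append(CodewordHistogram(
                counts=np.bincount(assign, minlength=k), image_id=f"i{i}",
                n_features=m, assignments=assign))
            fsets.append(feats)
            sizes.append(n)
            for ft, a in zip(feats, assign):
                flat.append((a, abs(ft.x / (n - 1) - ft.y / (n - 1)) / np.sqrt(2)))
        stats = codeword_diagonal_profile(fsets, hists, sizes)
        for cw in range(k):
            ds = [d for a, d in flat if a == cw]
            if ds:
                assert stats.mean_diag_dist[cw] == pytest.approx(np.mean(ds))
            else:
                assert np.isnan(stats.mean_diag_dist[cw])

    def test_rank_orders_by_frequency(self):
        fsets, hists, sizes = self._corpus()
        stats = codeword_diagonal_profile(fsets, hists, sizes)
        assert stats.rank_by_freq[0] == 1  # in both images
        assert stats.rank_by_freq[1] == 3  # in none


class TestUniqueWordRatio:
    def test_worked_example_400_of_500(self):
        counts = np.zeros(1000, dtype=int)
        counts[:300] = 1
        counts[300:400] = 2
        h = CodewordHistogram(counts=counts, image_id="x", n_features=500)
        rec = unique_word_ratio(h)
        assert rec.n_unique == 400
        assert rec.ratio == pytest.approx(0.8)

    def test_all_unique_gives_one(self):
        h = _hist([1, 1, 1, 1])
        assert unique_word_ratio(h).ratio == 1.0

    def test_single_codeword(self):
        h = _hist([5, 0])
        assert unique_word_ratio(h).ratio == pytest.approx(0.2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            unique_word_ratio(_hist([0, 0]))

    @given(counts=st.lists(st.integers(0, 9), min_size=1, max_size=30).filter(
        lambda c: sum(c) > 0))
    @settings(max_examples=40, deadline=None)
    def test_bounded_by_one_iff_all_singletons(self, counts):
        h = _hist(counts)
        r = unique_word_ratio(h).ratio
        assert r <= 1.0
        all_singletons = all(c in (0, 1) for c in counts)
        assert (r == 1.0) == all_singletons


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPcaEmbed:
    def test_rank_one_data_has_zero_second_variance(self):
        rng = np.random.default_rng(4)
        v = rng.integers(1, 5, size=6)
        H = [_hist(v * m) for m in (1, 2, 3, 4)]
        _, var = pca_embed(H, n_components=2)
        assert var[1] == pytest.approx(0.0, abs=1e-18)

    def test_variances_sorted_descending(self):
        rng = np.random.default_rng(5)
        H = [_hist(rng.integers(0, 9, size=8) + 1) for _ in range(12)]
        _, var = pca_embed(H, n_components=2)
        assert var[0] >= var[1]

    def test_matches_eigendecomposition_oracle(self):
        """Scores must agree (up to component sign) with an explicit
        eigendecomposition of the sample covariance matrix."""
        rng = np.random.default_rng(6)
        X = rng.integers(0, 10, size=(10, 6))
        H = [_hist(row) for row in X]
        scores, var = pca_embed(H, n_components=2)

        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / (len(X) - 1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        oracle = Xc @ V[:, :2]
        for c in range(2):
            assert var[c] == pytest.approx(w[c], rel=1e-9)
            match = np.allclose(scores[:, c], oracle[:, c], atol=1e-8)
            flipped = np.allclose(scores[:, c], -oracle[:, c], atol=1e-8)
            assert match or flipped

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            pca_embed([_hist([1, 2, 3])], n_components=2)
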