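import numpy as np
import pytest

from somamap import (
    SimilarityMatrix,
    cut_clusters,
    make_dotprops,
    nblast_matrix,
    nblast_raw,
    ward_cluster,
)
from somamap.errors import SomamapError
from somamap.morphology import DEFAULT_SIGMA_UM, Dotprops, to_newick


def line_dotprops(n=20, offset=(0.0, 0.0, 0.0), spacing=1.0, neuron_id="line"):
    pts = np.zeros((n, 3))
    pts[:, 0] = np.arange(n) * spacing
    return make_dotprops(pts + np.asarray(offset), k=5, neuron_id=neuron_id)


def nblast_brute(query, target, sigma=DEFAULT_SIGMA_UM):
    """Independent oracle: all-pairs nearest neighbor, plain loops."""
    total = 0.0
    for p, u in zip(query.points, query.tangents):
        d = np.sqrt(((target.points - p) ** 2).sum(axis=1))
        i = int(np.argmin(d))
        total += np.exp(-d[i] / sigma) * abs(float(u @ target.tangents[i]))
    return total


def manual_ward(dist):
    """Lance-Williams Ward agglomeration, written independently of scipy.

    Returns merge rows (left, right, height, size) with scipy id numbering.
    """
    n = len(dist)
    active = {i: 1 for i in range(n)}  # cluster id -> size
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist[i][j])
    merges = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = active[a], active[b]
        merges.append((a, b, h, na + nb))
        new = next_id
        next_id += 1
        for c in list(active):
            if c in (a, b):
                continue
            nc = active[c]
            dac = d[tuple(sorted((a, c)))]
            dbc = d[tuple(sorted((b, c)))]
            dab = h
            t = na + nb + nc
            val = np.sqrt(
                ((na + nc) * dac ** 2 + (nb + nc) * dbc ** 2 - nc * dab ** 2) / t
            )
            d[tuple(sorted((new, c)))] = float(val)
        for key in [k for k in d if a in k or b in k]:
            del d[key]
        del active[a], active[b]
        active[new] = na + nb
    return merges


class TestMakeDotprops:
    def test_collinear_points(self):
        dp = line_dotprops(20)
        assert np.allclose(dp.tangents, [1.0, 0.0, 0.0])
        assert np.allclose(dp.alpha, 1.0)

    def test_isotropic_sphere_alpha_third(self, rng):
        # uniform shell: covariance isotropic, dominant fraction -> 1/3
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        dp = make_dotprops(v, k=4000)
        assert np.allclose(dp.alpha, 1 / 3, atol=0.02)

    def test_single_point_defaults(self):
        dp = make_dotprops(np.array([[1.0, 2.0, 3.0]]), k=5)
        assert dp.tangents.tolist() == [[1.0, 0.0, 0.0]]
        assert dp.alpha.tolist() == [1.0]

    def test_k_clamped(self):
        dp = make_dotprops(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]), k=50)
        assert len(dp) == 3
        assert np.allclose(np.linalg.norm(dp.tangents, axis=1), 1.0)

    def test_sign_canonical(self, rng):
        pts = rng.normal(size=(30, 3))
        dp = make_dotprops(pts, k=5)
        for t in dp.tangents:
            nz = t[np.abs(t) > 1e-12]
            assert nz[0] > 0

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            make_dotprops(np.empty((0, 3)))


class TestNblastRaw:
    def test_self_match_scores_n(self, rng):
        pts = rng.normal(0, 10, size=(37, 3))
        dp = make_dotprops(pts, k=5)
        assert nblast_raw(dp, dp) == pytest.approx(len(dp), abs=1e-9)

    def test_parallel_lines_closed_form(self):
        d0 = 2.5
        a = line_dotprops(25)
        b = line_dotprops(25, offset=(0, d0, 0), neuron_id="b")
        expected = 25 * np.exp(-d0 / DEFAULT_SIGMA_UM)
        assert nblast_raw(a, b) == pytest.approx(expected, abs=1e-9)

    def test_far_apart_score_vanishes(self):
        a = line_dotprops(10)
        b = make_dotprops(
            np.c_[np.zeros(10), np.arange(10), np.zeros(10)] + [0, 0, 500.0],
            neuron_id="far",
        )
        assert nblast_raw(a, b) < 1e-9

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            a = make_dotprops(rng.normal(0, 5, size=(40, 3)), k=5)
            b = make_dotprops(rng.normal(0, 5, size=(35, 3)), k=5)
            assert nblast_raw(a, b) == pytest.approx(nblast_brute(a, b), abs=1e-9)

    def test_custom_score_fn(self):
        a = line_dotprops(10)
        b = line_dotprops(10, offset=(0, 1, 0), neuron_id="b")
        assert nblast_raw(a, b, score_fn=lambda d, dp: np.ones_like(d)) == 10


class TestNblastMatrix:
    def test_duplicate_neuron_scores_one(self, rng):
        pts = rng.normal(0, 5, size=(30, 3))
        a = make_dotprops(pts, k=5, neuron_id="a")
        b = make_dotprops(pts.copy(), k=5, neuron_id="b")
        c = make_dotprops(rng.normal(0, 5, size=(30, 3)), k=5, neuron_id="c")
        sim = nblast_matrix([a, b, c])
        assert sim.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_unit_diagonal(self, rng):
        dps = [make_dotprops(rng.normal(0, 5, size=(25, 3)), k=5, neuron_id=str(i))
               for i in range(6)]
        sim = nblast_matrix(dps)
        sim.check(atol=1e-9)
        assert np.all(sim.values <= 1 + 1e-12)

    def test_self_similarity_maximal(self, rng):
        dps = [make_dotprops(rng.normal(0, 5, size=(25, 3)), k=5, neuron_id=str(i))
               for i in range(5)]
        sim = nblast_matrix(dps)
        for i in range(5):
            assert sim.values[i, i] >= sim.values[i].max() - 1e-12

    def test_rigid_motion_invariance(self, rng):
        dps = [make_dotprops(rng.normal(0, 5, size=(30, 3)), k=5, neuron_id=str(i))
               for i in range(4)]
        before = nblast_matrix(dps).values
        # one rigid motion applied to ALL neurons
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([10.0, -3.0, 4.0])
        moved = [make_dotprops(dp.points @ rot.T + shift, k=5,
                               neuron_id=dp.neuron_id) for dp in dps]
        after = nblast_matrix(moved).values
        assert np.allclose(before, after, atol=1e-6)

    def test_needs_two_neurons(self, rng):
        dp = make_dotprops(rng.normal(size=(10, 3)), k=5)
        with pytest.raises(ValueError):
            nblast_matrix([dp])


class TestWardCluster:
    def test_duplicates_merge_at_zero(self, rng):
        pts = rng.normal(0, 5, size=(20, 3))
        dps = [make_dotprops(pts, k=5, neuron_id="a"),
               make_dotprops(pts.copy(), k=5, neuron_id="b"),
               make_dotprops(rng.normal(0, 5, size=(20, 3)), k=5, neuron_id="c")]
        res = ward_cluster(nblast_matrix(dps))
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}

    def test_heights_non_decreasing(self, rng):
        dps = [make_dotprops(rng.normal(0, 5, size=(15, 3)), k=5, neuron_id=str(i))
               for i in range(8)]
        res = ward_cluster(nblast_matrix(dps))
        assert np.all(np.diff(res.heights) >= -1e-12)

    def test_non_symmetric_rejected(self):
        values = np.eye(3)
        values[0, 1] = 0.9
        sim = SimilarityMatrix(ids=["a", "b", "c"], values=values)
        with pytest.raises(SomamapError):
            ward_cluster(sim)

    def test_matches_manual_ward_on_4_items(self):
        # hand-built symmetric dissimilarity
        dist = np.array([
            [0.0, 0.1, 0.8, 0.9],
            [0.1, 0.0, 0.7, 0.85],
            [0.8, 0.7, 0.0, 0.2],
            [0.9, 0.85, 0.2, 0.0],
        ])
        sim = SimilarityMatrix(ids=list("abcd"), values=1 - dist)
        res = ward_cluster(sim)
        expected = manual_ward(dist)
        for row, (ea, eb, eh, esize) in zip(res.linkage, expected):
            assert {int(row[0]), int(row[1])} == {ea, eb}
            assert row[2] == pytest.approx(eh, abs=1e-9)
            assert int(row[3]) == esize

    def test_two_block_structure(self, rng):
        pts1 = rng.normal(0, 3, size=(20, 3))
        pts2 = pts1 + [200.0, 0, 0]
        dps = [make_dotprops(pts1, k=5, neuron_id=f"a{i}") for i in range(3)]
        dps += [make_dotprops(pts2, k=5, neuron_id=f"b{i}") for i in range(3)]
        res = ward_cluster(nblast_matrix(dps))
        mid = 0.5 * (res.heights[-2] + res.heights[-1])
        labels = cut_clusters(res, height=mid)
        assert len(set(labels.values())) == 2
        assert len({labels[f"a{i}"] for i in range(3)}) == 1
        assert len({labels[f"b{i}"] for i in range(3)}) == 1


class TestCutClusters:
    @pytest.fixture
    def four_item_result(self):
        dist = np.array([
            [0.0, 0.1, 0.8, 0.9],
            [0.1, 0.0, 0.7, 0.85],
            [0.8, 0.7, 0.0, 0.2],
            [0.9, 0.85, 0.2, 0.0],
        ])
        return ward_cluster(SimilarityMatrix(ids=list("abcd"), values=1 - dist))

    def test_cut_above_top_is_one_cluster(self, four_item_result):
        labels = cut_clusters(four_item_result,
                              height=four_item_result.heights[-1] + 1)
        assert set(labels.values()) == {1}

    def test_cut_at_zero_plus_all_distinct(self, four_item_result):
        labels = cut_clusters(four_item_result, height=1e-12)
        assert len(set(labels.values())) == 4

    def test_cut_between_merges_matches_manual(self, four_item_result):
        h = 0.5 * (four_item_result.heights[1] + four_item_result.heights[2])
        labels = cut_clusters(four_item_result, height=h)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_k_equals_height_cut(self, four_item_result):
        assert (cut_clusters(four_item_result, k=2)
                == cut_clusters(four_item_result,
                                height=0.5 * (four_item_result.heights[1]
                                              + four_item_result.heights[2])))

    def test_exactly_one_argument(self, four_item_result):
        with pytest.raises(ValueError):
            cut_clusters(four_item_result)
        with pytest.raises(ValueError):
            cut_clusters(four_item_result, height=1.0, k=2)

    def test_k_out_of_range(self, four_item_result):
        with pytest.raises(ValueError):
            cut_clusters(four_item_result, k=5)


class TestNewick:
    def test_newick_contains_all_ids(self, rng):
        dps = [make_dotprops(rng.normal(0, 5, size=(15, 3)), k=5, neuron_id=f"n{i}")
               for i in range(5)]
        nwk = to_newick(ward_cluster(nblast_matrix(dps)))
        assert nwk.endswith(";")
        for i in range(5):
            assert f"n{i}" in nwk


class TestDotpropsValidation:
    def test_non_unit_tangent_rejected(self):
        with pytest.raises(ValueError):
            Dotprops("x", np.zeros((1, 3)), np.array([[2.0, 0, 0]]), np.ones(1))

    def test_nonfinite_points_rejected(self):
        with pytest.raises(ValueError):
            Dotprops("x", np.array([[np.nan, 0, 0]]),
                     np.array([[1.0, 0, 0]]), np.ones(1))
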