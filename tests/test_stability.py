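import itertools

import numpy as np
import pytest

from sfica.decomposition import complex_pca
from sfica.stability import (cluster_components, iq_index, run_icasso,
                             similarity_matrix)


def _average_linkage_oracle(similarity, k):
    """Exhaustive greedy average-linkage on a handful of components."""
    d = 1.0 - similarity
    clusters = [[i] for i in range(similarity.shape[0])]
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean([d[i, j] for i in clusters[a]
                            for j in clusters[b]])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(similarity.shape[0], dtype=int)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


class TestSimilarityMatrix:
    def test_self_similarity_is_one(self, rng):
        c = rng.standard_normal((2, 50)) + 1j * rng.standard_normal((2, 50))
        assert np.allclose(np.diag(similarity_matrix(c)), 1.0)

    def test_invariant_to_unit_modulus_phase(self, rng):
        c = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        pair = np.vstack([c, c * np.exp(1j * 1.234)])
        assert similarity_matrix(pair)[0, 1] == pytest.approx(1.0)

    def test_independent_vectors_nearly_orthogonal(self, rng):
        c = rng.standard_normal((2, 10 ** 4)) + 1j * rng.standard_normal(
            (2, 10 ** 4))
        assert similarity_matrix(c)[0, 1] < 0.05

    def test_zero_variance_component_warned_and_zeroed(self, rng):
        c = np.vstack([np.ones(50) + 0j, rng.standard_normal(50) + 0j])
        with pytest.warns(UserWarning):
            sim = similarity_matrix(c)
        assert sim[0, 1] == 0.0 and sim[0, 0] == 1.0


class TestClusterComponents:
    def test_prototype_copies_separate_perfectly(self, rng):
        protos = np.eye(3)[:, :, None] * np.ones((1, 1, 40))
        protos = protos.reshape(3, -1) + 0.0
        comps = np.repeat(protos, 100, axis=0)
        comps = comps + 0.001 * rng.standard_normal(comps.shape)
        labels = cluster_components(similarity_matrix(comps), 3)
        truth = np.repeat(np.arange(3), 100)
        # same partition up to label names
        assert len({(a, b) for a, b in zip(labels, truth)}) == 3

    def test_matches_exhaustive_linkage_oracle(self, rng):
        comps = rng.standard_normal((6, 300))
        sim = similarity_matrix(comps + 0j)
        ours = cluster_components(sim, 3)
        oracle = _average_linkage_oracle(sim, 3)
        assert len({(a, b) for a, b in zip(ours, oracle)}) == 3

    def test_k_equals_n_gives_singletons(self, rng):
        sim = similarity_matrix(rng.standard_normal((5, 100)) + 0j)
        assert sorted(cluster_components(sim, 5)) == [0, 1, 2, 3, 4]

    def test_invalid_k_rejected(self, rng):
        sim = similarity_matrix(rng.standard_normal((4, 10)) + 0j)
        with pytest.raises(ValueError):
            cluster_components(sim, 0)


class TestIqIndex:
    def test_orthogonal_duplicates_reach_one(self):
        sim = np.kron(np.eye(3), np.ones((2, 2)))
        part = np.repeat(np.arange(3), 2)
        assert np.allclose(iq_index(sim, part), 1.0)

    def test_pair_plus_noise_components(self):
        sim = np.eye(4)
        sim[0, 1] = sim[1, 0] = 1.0
        part = np.array([0, 0, 1, 2])
        iq = iq_index(sim, part)
        assert iq[0] == pytest.approx(1.0)

    def test_degenerate_all_identical_is_zero(self):
        sim = np.ones((4, 4))
        assert np.allclose(iq_index(sim, np.array([0, 0, 1, 1])), 0.0)

    def test_invariant_to_run_permutation(self, rng):
        comps = rng.standard_normal((8, 200)) + 1j * rng.standard_normal(
            (8, 200))
        sim = similarity_matrix(comps)
        part = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        perm = rng.permutation(8)
        iq_a = np.sort(iq_index(sim, part))
        iq_b = np.sort(iq_index(sim[np.ix_(perm, perm)], part[perm]))
        assert np.allclose(iq_a, iq_b)

    def test_extra_noise_cannot_hurt_a_tight_cluster(self, rng):
        # appending near-zero-similarity components dilutes inter-cluster
        # similarity, so the tight cluster's Iq cannot decrease
        base = np.eye(4)
        base[0, 1] = base[1, 0] = 0.95
        part = np.array([0, 0, 1, 2])
        iq_before = iq_index(base, part)[0]
        bigger = np.eye(6)
        bigger[:4, :4] = base
        part2 = np.array([0, 0, 1, 2, 3, 4])
        iq_after = iq_index(bigger, part2)[0]
        assert iq_after >= iq_before - 1e-12


@pytest.fixture(scope="module")
def whitened_fixture():
    rng = np.random.default_rng(0)
    mag = rng.exponential(1.0, (4, 4000))
    S = mag * np.exp(2j * np.pi * rng.uniform(size=(4, 4000)))
    A = rng.standard_normal((16, 4)) + 1j * rng.standard_normal((16, 4))
    return A @ S + 0.01 * (rng.standard_normal((16, 4000))
                           + 1j * rng.standard_normal((16, 4000)))


class TestRunIcasso:
    def test_identical_seeds_give_iq_one(self, whitened_fixture):
        report, _ = run_icasso(whitened_fixture, order=4, n_runs=2, seed=0,
                               seeds=[42, 42])
        # intra-cluster similarity is exactly 1 for duplicated runs; Iq
        # falls short of 1 only by the tiny chance extra-cluster similarity
        assert np.allclose(report.iq, 1.0, atol=0.02)
        for lab in range(4):
            members = np.flatnonzero(report.partition == lab)
            block = report.similarity[np.ix_(members, members)]
            assert np.allclose(block, 1.0, atol=1e-8)

    def test_iq_within_unit_interval(self, whitened_fixture):
        report, _ = run_icasso(whitened_fixture, order=4, n_runs=5, seed=1)
        assert (report.iq >= 0.0).all() and (report.iq <= 1.0 + 1e-12).all()

    def test_planted_networks_are_stable(self, small_subject):
        dm = small_subject["dm"]
        truth = small_subject["truth"]
        report, rep = run_icasso(dm.X0, order=6, n_runs=10, seed=2)
        for net in truth.networks:
            rs = []
            for k in range(6):
                row = rep.S_hat[k].reshape(dm.n_sources, dm.n_freqs)
                power = np.mean(np.abs(row) ** 2, axis=1)
                rs.append(abs(np.corrcoef(power, net.weights ** 2)[0, 1]))
            assert report.iq[int(np.argmax(rs))] > 0.9

    def test_report_shapes(self, whitened_fixture):
        report, rep = run_icasso(whitened_fixture, order=4, n_runs=3, seed=5)
        assert report.similarity.shape == (12, 12)
        assert report.partition.shape == (12,)
        assert len(report.centrotypes) == 4
        assert rep.A_hat.shape == (16, 4)
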