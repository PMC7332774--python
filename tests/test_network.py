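"""Coupling graph: coherence, surrogates, topological indices."""

import numpy as np
import pytest
from helpers import brute_force_graph_indices, brute_force_nsup

import neostress as ns
from neostress.network import PARTITIONS, _nsup_chart, topology_features
from neostress.records import BAND_LF


class _Epoch:
    def __init__(self, start_s, end_s):
        self.start_s, self.end_s = start_s, end_s


class TestCoherence:
    def test_self_coherence_unit_modulus_zero_imag(self):
        x = np.random.default_rng(0).standard_normal(2880)
        C, freqs, valid = ns.wavelet_coherence(x, x)
        assert np.max(np.abs(np.abs(C) - 1.0)) < 1e-6
        assert np.max(np.abs(C.imag)) < 1e-6

    def test_quarter_lagged_sinusoid_imaginary(self):
        rng = np.random.default_rng(1)
        t = np.arange(2880) / 8.0
        x = np.sin(2 * np.pi * 0.05 * t) + 0.05 * rng.standard_normal(t.size)
        y = np.sin(2 * np.pi * 0.05 * t - np.pi / 2) + 0.05 * rng.standard_normal(t.size)
        C, freqs, valid = ns.wavelet_coherence(x, y)
        coupling = ns.band_coupling(C, freqs, (0.04, 0.0625), valid)
        assert np.nanmean(coupling) >= 0.9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ns.ValidationError):
            ns.wavelet_coherence(np.zeros(1024), np.zeros(1000))

    def test_band_coupling_matches_brute_force(self):
        rng = np.random.default_rng(2)
        C, freqs, valid = ns.wavelet_coherence(rng.standard_normal(1024),
                                               rng.standard_normal(1024))
        band = (0.08, 0.2)
        got = ns.band_coupling(C, freqs, band)
        idx = [k for k, f in enumerate(freqs) if band[0] < f <= band[1]]
        expected = np.abs(C.imag)[idx].max(axis=0)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestSurrogates:
    def test_amplitude_multiset_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000) ** 3
        s = ns.aaft_surrogate(x, 7)
        np.testing.assert_array_equal(np.sort(s), np.sort(x))

    def test_spectrum_approximately_preserved(self):
        rng = np.random.default_rng(1)
        x = np.convolve(rng.standard_normal(2200), np.ones(20) / 20, "valid")
        s = ns.aaft_surrogate(x, 3)
        fx = np.abs(np.fft.rfft(x - x.mean())) ** 2
        fs = np.abs(np.fft.rfft(s - s.mean())) ** 2
        assert np.corrcoef(fx, fs)[0, 1] > 0.9

    def test_distinct_seeds_distinct_orderings(self):
        x = np.random.default_rng(2).standard_normal(512)
        assert not np.array_equal(ns.aaft_surrogate(x, 0), ns.aaft_surrogate(x, 1))

    def test_constant_series_rejected(self):
        with pytest.raises(ns.ValidationError):
            ns.aaft_surrogate(np.ones(128), 0)


class TestCouplingValidation:
    def test_identical_signals_not_significant(self):
        x = np.random.default_rng(3).standard_normal(1024)
        weight, sig = ns.validate_coupling(x, x, BAND_LF, seed=0)
        assert not sig and weight == 0.0

    def test_lagged_pair_detected(self):
        t = np.arange(2880) / 8.0
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.sin(2 * np.pi * 0.1 * t) + 0.3 * rng.standard_normal(t.size)
            y = np.sin(2 * np.pi * 0.1 * t - np.pi / 2) + 0.3 * rng.standard_normal(t.size)
            hits += ns.validate_coupling(x, y, BAND_LF, seed=seed)[1]
        assert hits >= 9

    def test_false_positive_rate_near_alpha(self):
        hits = 0
        n = 60
        for seed in range(n):
            rng = np.random.default_rng(10_000 + seed)
            _, sig = ns.validate_coupling(rng.standard_normal(600),
                                          rng.standard_normal(600),
                                          BAND_LF, seed=seed)
            hits += sig
        # exact binomial 99% band for p=0.05, n=60: 0..8 successes
        assert hits <= 8


class TestGraphIndices:
    def test_complete_unit_graph(self):
        A = np.ones((5, 5)) - np.eye(5)
        assert ns.graph_indices(A) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_three_node_chain(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        A[1, 2] = A[2, 1] = 0.5
        pl, eff, clu, ecc = ns.graph_indices(A)
        # distances: d(A,B)=1, d(B,C)=2, d(A,C)=3
        assert pl == pytest.approx(2.0)
        assert eff == pytest.approx((1 + 1 / 2 + 1 / 3) / 3)
        assert clu == 0.0
        assert ecc == pytest.approx((3 + 2 + 3) / 3)

    def test_clustering_matches_networkx(self):
        """Library cross-check: the node-averaged Onnela coefficient agrees
        with networkx's weighted clustering."""
        import networkx as nx
        rng = np.random.default_rng(4)
        for _ in range(10):
            A = rng.uniform(0, 1, (10, 10)) * (rng.random((10, 10)) < 0.5)
            A = np.triu(A, 1)
            A = A + A.T
            _, _, clu, _ = ns.graph_indices(A)
            expected = nx.average_clustering(nx.from_numpy_array(A),
                                             weight="weight")
            assert clu == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            A = rng.uniform(0, 1, (10, 10)) * (rng.random((10, 10)) < 0.4)
            A = np.triu(A, 1)
            A = A + A.T
            got = ns.graph_indices(A)
            expected = brute_force_graph_indices(A)
            for g, e in zip(got, expected):
                if np.isnan(e):
                    assert np.isnan(g)
                else:
                    assert g == pytest.approx(e, abs=1e-9)

    def test_asymmetric_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 1.0
        with pytest.raises(ns.ValidationError):
            ns.graph_indices(A)


class TestSuperfluousConnections:
    def test_single_edge_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 0.7
        assert ns.n_superfluous(A) == 0

    @pytest.mark.parametrize("objective", ["H+E", "H-E"])
    def test_matches_exhaustive_search(self, objective):
        rng = np.random.default_rng(1)
        for _ in range(30):
            A = rng.uniform(0, 1, (8, 8)) * (rng.random((8, 8)) < 0.6)
            A = np.triu(A, 1)
            A = A + A.T
            assert ns.n_superfluous(A, objective) == brute_force_nsup(A, objective)

    def test_ties_resolve_to_smallest(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = rng.uniform(0.2, 0.8, 4)
            w = np.repeat(w, 2)                      # injected duplicates
            A = np.zeros((5, 5))
            iu = np.triu_indices(5, 1)
            A[iu[0][:8], iu[1][:8]] = w
            A = np.maximum(A, A.T)
            assert ns.n_superfluous(A) == brute_force_nsup(A)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1, (10, 10)) * (rng.random((10, 10)) < 0.5)
        A = np.triu(A, 1)
        A = A + A.T
        base = ns.n_superfluous(A)
        for _ in range(20):
            p = rng.permutation(10)
            assert ns.n_superfluous(A[np.ix_(p, p)]) == base


class TestTopologyFeatures:
    def _graph_from_A(self, A_t, valid=None):
        T = A_t.shape[0]
        return ns.CouplingGraph(
            nodes=tuple("n%d" % i for i in range(10)), A=A_t,
            valid=np.ones(T, dtype=bool) if valid is None else valid,
            significant=(A_t.sum(axis=0) > 0), band=BAND_LF, rate=8.0, t0=0.0)

    def test_constant_adjacency_zero_sd(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 1, (10, 10)) * (rng.random((10, 10)) < 0.5)
        A = np.triu(A, 1)
        A = A + A.T
        A_t = np.repeat(A[None], 80, axis=0)
        g = self._graph_from_A(A_t)
        feats = topology_features(g, {"pre": _Epoch(0, 5), "during": _Epoch(5, 7),
                                      "post": _Epoch(7, 10)})
        sds = [v for k, v in feats.items() if "__sd__" in k and np.isfinite(v)]
        assert sds and max(abs(v) for v in sds) < 1e-12

    def test_partition_excludes_foreign_edges(self):
        A = np.zeros((10, 10))
        A[0, 8] = A[8, 0] = 0.9                     # EEG1 <-> RR only
        A_t = np.repeat(A[None], 40, axis=0)
        g = self._graph_from_A(A_t)
        feats = topology_features(g, {"pre": _Epoch(0, 5)})
        assert np.isnan(feats["net_eeg_eeg__path_length__mu__pre"])
        assert feats["net_eeg_rr__path_length__mu__pre"] == pytest.approx(1 / 0.9)

    def test_full_partition_equals_whole_graph(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 1, (10, 10)) * (rng.random((10, 10)) < 0.4)
        A = np.triu(A, 1)
        A = A + A.T
        A_t = np.repeat(A[None], 16, axis=0)
        g = self._graph_from_A(A_t)
        feats = topology_features(g, {"pre": _Epoch(0, 2)})
        pl, eff, clu, ecc = ns.graph_indices(A)
        assert feats["net_eeg_spo2_rr__path_length__mu__pre"] == pytest.approx(pl)
        assert feats["net_eeg_spo2_rr__efficiency__mu__pre"] == pytest.approx(eff)
        assert feats["net_eeg_spo2_rr__clustering__mu__pre"] == pytest.approx(clu)
        assert feats["net_eeg_spo2_rr__eccentricity__mu__pre"] == pytest.approx(ecc)

    def test_only_injected_pair_survives_masking(self):
        """A record-level check: one genuinely lagged-coupled pair among
        independent noises keeps (at least) that edge after surrogates."""
        rng = np.random.default_rng(8)
        t = np.arange(2880) / 8.0
        base = np.sin(2 * np.pi * 0.12 * t)
        nodes = rng.standard_normal((10, t.size))
        nodes[0] = base + 0.3 * rng.standard_normal(t.size)
        nodes[8] = np.sin(2 * np.pi * 0.12 * t - np.pi / 2) \
            + 0.3 * rng.standard_normal(t.size)
        g = ns.build_coupling_graph(nodes, BAND_LF, seed=1)
        assert g.significant[0, 8]
        assert np.allclose(g.A, np.transpose(g.A, (0, 2, 1)))
        assert np.all(g.A[:, np.arange(10), np.arange(10)] == 0)
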