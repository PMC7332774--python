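"""Network physiology: the 10-node coupling graph and its topology.

Nodes are the delta-band power envelopes of the 8 EEG channels, the RR
(HRV) series and SpO2, all on a common 8 Hz grid over the event window.
Edge weights are the maximum absolute imaginary part of the smoothed
wavelet coherence inside the group's coupling band (VLF for the 5-days
group, LF otherwise), evaluated per time sample; the imaginary part
ignores zero-lag co-variation, so only genuinely lagged coupling counts.
Each pair is kept only if its window-mean coupling exceeds the maximum of
19 amplitude-adjusted Fourier-transform (AAFT) surrogates (one-sided
alpha = 1/20).

From the per-sample adjacency charts, weighted-graph indices are derived:
characteristic path length, global efficiency, the node-averaged Onnela
clustering coefficient, node-averaged eccentricity, and the redundancy
optimum n_sup — the number of weakest edges whose removal maximizes the
entropy of the renormalized remaining weights plus the squared deviation
from the original weights.  Indices are computed on four adjacency
partitions (EEG-EEG, EEG-SpO2, EEG-RRi, and all connections) and
summarized as mean and SD per pre/during/post epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import PipelineConfig, ValidationError
from .wavelets import band_indices, coi_mask, cwt_morlet, freq_grid, smooth_scalogram

logger = logging.getLogger("neostress")

__all__ = [
    "CouplingGraph", "PARTITIONS", "wavelet_coherence", "band_coupling",
    "aaft_surrogate", "validate_coupling", "build_coupling_graph",
    "graph_indices", "n_superfluous", "topology_features",
]

NODE_LABELS = ("Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2", "RR", "SpO2")
_EEG = tuple(range(8))
_RR, _SPO2 = 8, 9

#: Partition name -> node subset; only edges between EEG nodes and the
#: listed counterpart(s) are retained (EEG-EEG keeps intra-EEG edges).
PARTITIONS = ("eeg_eeg", "eeg_spo2", "eeg_rr", "eeg_spo2_rr")


def _partition_nodes_edges(name: str) -> tuple[list[int], np.ndarray]:
    mask = np.zeros((10, 10), dtype=bool)
    if name == "eeg_eeg":
        nodes = list(_EEG)
        for i in _EEG:
            for j in _EEG:
                mask[i, j] = i != j
    elif name == "eeg_spo2":
        nodes = list(_EEG) + [_SPO2]
        for i in _EEG:
            mask[i, _SPO2] = mask[_SPO2, i] = True
    elif name == "eeg_rr":
        nodes = list(_EEG) + [_RR]
        for i in _EEG:
            mask[i, _RR] = mask[_RR, i] = True
    elif name == "eeg_spo2_rr":
        nodes = list(range(10))
        mask[:] = True
        np.fill_diagonal(mask, False)
    else:
        raise ValidationError(f"unknown partition {name!r}")
    return nodes, mask


@dataclass
class CouplingGraph:
    """Per-time-sample symmetric adjacency over the 10 physiological nodes."""
    nodes: tuple[str, ...]
    A: np.ndarray                  # (T, 10, 10), weights in [0, 1], zero diagonal
    valid: np.ndarray              # (T,) True outside the cone of influence
    significant: np.ndarray        # (10, 10) boolean pair mask
    band: tuple[float, float]
    rate: float
    t0: float

    def epoch_index(self, start_s: float, end_s: float) -> tuple[int, int]:
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.rate - 1e-9)))
        i1 = min(self.A.shape[0], int(np.ceil((end_s - self.t0) * self.rate - 1e-9)))
        return i0, max(i0, i1)


# --------------------------------------------------------------------------
# Coherence and surrogates
# --------------------------------------------------------------------------

def wavelet_coherence(x, y, rate: float = 8.0, freqs=None,
                      voices_per_octave: int = 12):
    """Smoothed analytic-Morlet wavelet coherence of two equal-length series.

    Returns (C, freqs, valid): complex coherence (k, n), the frequency grid,
    and the (k, n) outside-cone mask.  |C| <= 1 up to roundoff.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D series")
    if x.size < 512:
        raise ValidationError("need >= 512 samples for wavelet coherence")
    if freqs is None:
        freqs = freq_grid(0.02, min(1.0, rate / 2), voices_per_octave)
    freqs = np.asarray(freqs, dtype=float)
    W = cwt_morlet(np.vstack((x, y)), rate, freqs)
    Sxy = smooth_scalogram(W[0] * np.conj(W[1]), rate, freqs)
    Sxx = smooth_scalogram(np.abs(W[0]) ** 2, rate, freqs)
    Syy = smooth_scalogram(np.abs(W[1]) ** 2, rate, freqs)
    denom = np.sqrt(np.clip(Sxx * Syy, 1e-300, None))
    C = Sxy / denom
    return C, freqs, coi_mask(x.size, rate, freqs)


def band_coupling(C: np.ndarray, freqs: np.ndarray, band: tuple[float, float],
                  valid: np.ndarray | None = None) -> np.ndarray:
    """Per-sample max over in-band scales of |imag C|; NaN inside the cone."""
    idx = band_indices(freqs, band)
    out = np.max(np.abs(C[idx].imag), axis=0)
    if valid is not None:
        ok = np.asarray(valid, dtype=bool)[idx].all(axis=0)
        out = np.where(ok, out, np.nan)
    return out


def aaft_surrogate(x, rng) -> np.ndarray:
    """Amplitude-adjusted Fourier-transform surrogate: exactly the same
    sorted amplitudes, approximately the same power spectrum."""
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValidationError("need >= 64 samples for an AAFT surrogate")
    if np.allclose(x, x[0]):
        raise ValidationError("constant series has no surrogate")
    rng = np.random.default_rng(rng)
    n = x.size
    ranks = np.argsort(np.argsort(x))
    gauss = np.sort(rng.standard_normal(n))[ranks]       # rank-remap to Gaussian
    F = np.fft.rfft(gauss)
    phases = rng.uniform(0, 2 * np.pi, F.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    shuffled = np.fft.irfft(np.abs(F) * np.exp(1j * phases), n)
    return np.sort(x)[np.argsort(np.argsort(shuffled))]  # rank-remap back


def _coupling_stat(coupling_t: np.ndarray) -> float:
    good = np.isfinite(coupling_t)
    return float(np.mean(coupling_t[good])) if np.any(good) else np.nan


def validate_coupling(x, y, band: tuple[float, float], rate: float = 8.0,
                      n_surr: int = 19, seed=0, freqs=None):
    """Surrogate test of the band coupling between two series.

    The observed statistic is the window-mean band coupling; the pair is
    significant iff it exceeds the maximum over ``n_surr`` AAFT surrogates
    of x (y untouched), a one-sided test at alpha = 1/(n_surr+1).
    Returns (weight, significant): weight is the observed statistic when
    significant, else 0.
    """
    C, freqs, valid = wavelet_coherence(x, y, rate, freqs)
    obs = _coupling_stat(band_coupling(C, freqs, band, valid))
    rng = np.random.default_rng(seed)
    surr_stats = []
    for _ in range(n_surr):
        xs = aaft_surrogate(x, rng)
        Cs, _, _ = wavelet_coherence(xs, y, rate, freqs)
        surr_stats.append(_coupling_stat(band_coupling(Cs, freqs, band, valid)))
    significant = bool(np.isfinite(obs) and obs > np.max(surr_stats))
    return (obs if significant else 0.0), significant


# --------------------------------------------------------------------------
# Graph construction (batched over pairs and surrogates)
# --------------------------------------------------------------------------

def build_coupling_graph(node_series: np.ndarray, band: tuple[float, float],
                         rate: float = 8.0, t0: float = 0.0,
                         n_surr: int = 19, seed=0,
                         voices_per_octave: int = 6,
                         node_labels=NODE_LABELS) -> CouplingGraph:
    """Coupling graph from the (M, n) matrix of node series on a common grid.

    For every unordered pair the per-sample band coupling and its surrogate
    validation are computed; non-significant pairs are masked to 0.  The
    surrogate is applied to the lower-index node of each pair.  The scale
    grid defaults to 6 voices per octave: the coupling bands span ~1.3
    octaves, so this still leaves ~8 scales under the 3-point scale boxcar.
    """
    X = np.asarray(node_series, dtype=float)
    if X.ndim != 2:
        raise ValidationError("node_series must be (M, n)")
    M, n = X.shape
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValidationError("constant node series cannot be analyzed")
    X = (X - X.mean(axis=1, keepdims=True)) / sd
    lo, hi = band
    freqs = freq_grid(lo / 1.3, min(hi * 1.3, rate / 2), voices_per_octave)
    idx = band_indices(freqs, band)
    cmask = coi_mask(n, rate, freqs)
    valid_t = cmask[idx].all(axis=0)

    # single precision: the coupling statistic needs ~3 decimals, and the
    # box-filter smoothing is memory-bandwidth bound
    W = cwt_morlet(X, rate, freqs).astype(np.complex64)  # (M, k, n)
    P = smooth_scalogram(np.abs(W) ** 2, rate, freqs)    # smoothed autos

    rng = np.random.default_rng(seed)
    A = np.zeros((n, M, M))
    significant = np.zeros((M, M), dtype=bool)

    def pair_coupling(Wx, Px, Wy, Py):
        """Band coupling chart(s); leading axes of Wx broadcast over y."""
        Sxy = smooth_scalogram(Wx * np.conj(Wy), rate, freqs)
        C = Sxy / np.sqrt(np.clip(Px * Py, 1e-300, None))
        return np.max(np.abs(C[..., idx, :].imag), axis=-2)

    for i in range(M - 1):
        surr = np.stack([aaft_surrogate(X[i], rng) for _ in range(n_surr)])
        Wsi = np.concatenate((W[i][None],
                              cwt_morlet(surr, rate, freqs).astype(np.complex64)))
        Psi = np.concatenate((P[i][None],
                              smooth_scalogram(np.abs(Wsi[1:]) ** 2, rate, freqs)))
        for j in range(i + 1, M):
            charts = pair_coupling(Wsi, Psi, W[j][None], P[j][None])
            chart = charts[0]                                    # observed
            obs = _coupling_stat(np.where(valid_t, chart, np.nan))
            s_stats = [
                _coupling_stat(np.where(valid_t, charts[s], np.nan))
                for s in range(1, n_surr + 1)
            ]
            if np.isfinite(obs) and obs > np.max(s_stats):
                significant[i, j] = significant[j, i] = True
                A[:, i, j] = A[:, j, i] = np.where(valid_t, chart, 0.0)
    return CouplingGraph(tuple(node_labels), A, valid_t, significant,
                         (lo, hi), rate, t0)


# --------------------------------------------------------------------------
# Topological indices (vectorized over time)
# --------------------------------------------------------------------------

def _shortest_paths(A: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances, d_ij = 1/A_ij, by Floyd-Warshall
    vectorized over the leading (time) axis.  A is (T, M, M)."""
    T, M, _ = A.shape
    with np.errstate(divide="ignore"):
        D = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), np.inf)
    for i in range(M):
        D[:, i, i] = 0.0
    for k in range(M):
        D = np.minimum(D, D[:, :, k, None] + D[:, k, None, :])
    return D


def _index_charts(A: np.ndarray) -> dict[str, np.ndarray]:
    """path_length, efficiency, clustering, eccentricity, n_sup for a stack
    of symmetric adjacencies (T, M, M)."""
    T, M, _ = A.shape
    D = _shortest_paths(A)
    off = ~np.eye(M, dtype=bool)
    Doff = D[:, off].reshape(T, -1)
    finite = np.isfinite(Doff)
    with np.errstate(invalid="ignore"):
        path_length = np.where(finite.any(axis=1),
                               np.nansum(np.where(finite, Doff, np.nan), axis=1)
                               / np.maximum(finite.sum(axis=1), 1), np.nan)
    inv = np.where(finite, 1.0 / np.where(finite, Doff, 1.0), 0.0)
    efficiency = inv.mean(axis=1)
    # Onnela clustering, normalized by the per-matrix max weight
    wmax = A.max(axis=(1, 2), keepdims=True)
    What = np.where(wmax > 0, A / np.where(wmax > 0, wmax, 1.0), 0.0)
    cb = np.cbrt(What)
    tri = np.einsum("tij,tjk,tki->ti", cb, cb, cb)
    k_deg = (A > 0).sum(axis=2)
    denom = k_deg * (k_deg - 1)
    ci = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    clustering = ci.mean(axis=1)
    # eccentricity: per-node max finite distance; isolated nodes excluded
    Dm = np.where(np.isfinite(D) & (D > 0), D, -np.inf)
    ecc_node = Dm.max(axis=2)
    connected = np.isfinite(ecc_node)
    n_conn = connected.sum(axis=1)
    eccentricity = np.where(
        n_conn > 0,
        np.where(connected, ecc_node, 0.0).sum(axis=1) / np.maximum(n_conn, 1),
        np.nan)
    # redundancy optimum
    iu = np.triu_indices(M, 1)
    n_sup = _nsup_chart(A[:, iu[0], iu[1]])
    return {"path_length": path_length, "efficiency": efficiency,
            "clustering": clustering, "eccentricity": eccentricity,
            "n_sup": n_sup.astype(float)}


def _nsup_chart(Wt: np.ndarray, objective: str = "H+E") -> np.ndarray:
    """Vectorized redundancy optimum for (T, e) upper-triangle weight rows.

    For each row: order weights descending; removing the n smallest leaves
    kept weights renormalized to a distribution for the entropy term
    H = -sum p ln p, and the squared-error term E sums (0 - w)^2 over
    removed plus (w/S - w)^2 over kept; n_sup = argmax over n = 0..e-1 of
    H + E (or H - E), smallest n on ties.  Rows with no positive weight
    yield 0.
    """
    Wt = np.atleast_2d(np.asarray(Wt, dtype=float))
    T, e = Wt.shape
    if e == 0:
        return np.zeros(T, dtype=int)
    ws = -np.sort(-Wt, axis=1)                         # descending, zeros last
    npos = (ws > 0).sum(axis=1)                        # actual edges per row
    csum = np.cumsum(ws, axis=1)
    csum2 = np.cumsum(ws ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wlw = np.where(ws > 0, ws * np.log(ws), 0.0)
    cwlw = np.cumsum(wlw, axis=1)
    total2 = np.take_along_axis(csum2, np.maximum(npos - 1, 0)[:, None], axis=1)[:, 0]
    obj = np.full((T, e), -np.inf)
    rows = np.arange(T)
    for nrm in range(e):                               # nrm = removed edge count
        kidx = npos - nrm - 1                          # index of last kept weight
        ok = kidx >= 0
        ki = np.maximum(kidx, 0)
        S = csum[rows, ki]
        kept2 = csum2[rows, ki]
        klw = cwlw[rows, ki]
        ok &= S > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            H = np.log(S) - klw / S
            E = (total2 - kept2) + (1.0 / S - 1.0) ** 2 * kept2
        val = H + E if objective == "H+E" else H - E
        obj[:, nrm] = np.where(ok, val, -np.inf)
    out = np.argmax(obj, axis=1)                       # first max = smallest n
    out[npos == 0] = 0
    return out


def graph_indices(A: np.ndarray) -> tuple[float, float, float, float]:
    """(path_length, efficiency, clustering, eccentricity) of one symmetric
    non-negative adjacency matrix."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if np.any(A < 0):
        raise ValidationError("adjacency weights must be non-negative")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    ch = _index_charts(A[None])
    return (float(ch["path_length"][0]), float(ch["efficiency"][0]),
            float(ch["clustering"][0]), float(ch["eccentricity"][0]))


def n_superfluous(A: np.ndarray, objective: str = "H+E") -> int:
    """Redundancy optimum of one symmetric adjacency (see ``_nsup_chart``)."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    iu = np.triu_indices(A.shape[0], 1)
    return int(_nsup_chart(A[iu][None], objective)[0])


def topology_features(graph: CouplingGraph, epochs: dict,
                      objective: str = "H+E") -> dict[str, float]:
    """Mean and SD of each topological index per partition and epoch.

    ``epochs`` maps role -> object with start_s / end_s attributes
    (pre, during, post).  5 indices x 2 stats x len(epochs) x 4 partitions.
    """
    out: dict[str, float] = {}
    for part in PARTITIONS:
        nodes, mask = _partition_nodes_edges(part)
        Ap = np.where(mask[None], graph.A, 0.0)[:, nodes][:, :, nodes]
        charts = _index_charts(Ap)
        if objective != "H+E":
            iu = np.triu_indices(len(nodes), 1)
            charts["n_sup"] = _nsup_chart(Ap[:, iu[0], iu[1]], objective).astype(float)
        for role, ep in epochs.items():
            if role == "whole":
                continue
            i0, i1 = graph.epoch_index(ep.start_s, ep.end_s)
            sel = graph.valid[i0:i1]
            for name, chart in charts.items():
                vals = chart[i0:i1][sel]
                vals = vals[np.isfinite(vals)]
                mu = float(np.mean(vals)) if vals.size else np.nan
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
                out[f"net_{part}__{name}__mu__{role}"] = mu
                out[f"net_{part}__{name}__sd__{role}"] = sd
    return out
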