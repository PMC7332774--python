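"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive quantities from first principles (plain loops
over definitions) so they share no code path with the package internals.
"""

import numpy as np


def brute_force_bradycardias(tach, factor=1.5, min_dur_s=4.0, merge_gap=5,
                             stat_factor=1.1, stat_beats=5):
    """Run-scan bradycardia detection over the definition: maximal runs of
    beats with RR above factor * whole-record mean, merged over short gaps,
    kept when the summed supra-threshold RR reaches the duration criterion.
    Returns (i_start, i_end) inclusive beat-index pairs."""
    rr = tach.rr
    rbar = sum(rr) / len(rr)
    above = [r > factor * rbar for r in rr]
    runs = []
    i = 0
    while i < len(rr):
        if above[i]:
            j = i
            while j + 1 < len(rr) and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kept = []
    for s, e in merged:
        dur = sum(rr[k] for k in range(s, e + 1) if above[k])
        if dur >= min_dur_s:
            kept.append((s, e))
    return kept


def brute_force_graph_indices(A):
    """Path length / efficiency / clustering / eccentricity via explicit
    Floyd-Warshall and the Onnela triangle definition."""
    M = A.shape[0]
    D = np.full((M, M), np.inf)
    for i in range(M):
        D[i, i] = 0.0
        for j in range(M):
            if i != j and A[i, j] > 0:
                D[i, j] = 1.0 / A[i, j]
    for k in range(M):
        for i in range(M):
            for j in range(M):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    finite = []
    effs = []
    for i in range(M):
        for j in range(M):
            if i == j:
                continue
            if np.isfinite(D[i, j]):
                finite.append(D[i, j])
                effs.append(1.0 / D[i, j])
            else:
                effs.append(0.0)
    path_length = float(np.mean(finite)) if finite else np.nan
    efficiency = float(np.mean(effs))
    wmax = A.max()
    ci = []
    for i in range(M):
        nbrs = [j for j in range(M) if j != i and A[i, j] > 0]
        k = len(nbrs)
        if k < 2 or wmax == 0:
            ci.append(0.0)
            continue
        tot = 0.0
        for a in range(len(nbrs)):
            for b in range(len(nbrs)):
                if a == b:
                    continue
                ja, jb = nbrs[a], nbrs[b]
                tot += ((A[i, ja] / wmax) * (A[i, jb] / wmax)
                        * (A[ja, jb] / wmax)) ** (1.0 / 3.0)
        ci.append(tot / (k * (k - 1)))
    clustering = float(np.mean(ci))
    eccs = []
    for i in range(M):
        row = [D[i, j] for j in range(M) if j != i and np.isfinite(D[i, j])]
        if row:
            eccs.append(max(row))
    eccentricity = float(np.mean(eccs)) if eccs else np.nan
    return path_length, efficiency, clustering, eccentricity


def brute_force_nsup(A, objective="H+E"):
    """Exhaustive evaluation of the redundancy objective over all removal
    counts n = 0 .. e-1."""
    M = A.shape[0]
    w = sorted((A[i, j] for i in range(M) for j in range(i + 1, M)
                if A[i, j] > 0), reverse=True)
    e = len(w)
    if e == 0:
        return 0
    best_val, best_n = None, 0
    for n in range(e):
        kept = w[: e - n]
        removed = w[e - n:]
        S = sum(kept)
        p = [x / S for x in kept]
        H = -sum(q * np.log(q) for q in p)
        E = sum(x ** 2 for x in removed) + sum((q - x) ** 2 for q, x in zip(p, kept))
        val = H + E if objective == "H+E" else H - E
        if best_val is None or val > best_val + 1e-15:
            best_val, best_n = val, n
    return best_n


def trapezoid_auc(scores, labels):
    """ROC AUC by explicit threshold sweep and trapezoidal integration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    P, N = labels.sum(), (~labels).sum()
    for t in thresholds:
        pred = scores >= t
        pts.append(((pred & ~labels).sum() / N, (pred & labels).sum() / P))
    pts.append((1.0, 1.0))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return auc
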