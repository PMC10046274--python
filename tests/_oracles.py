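"""Independent brute-force oracles used only by the tests.

These are deliberately naive transcriptions of the definitions (double loops,
greedy scans) kept separate from the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def naive_tanimoto_matrix(bits: np.ndarray) -> np.ndarray:
    """Double-loop pairwise Tanimoto similarity."""
    n = bits.shape[0]
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            inter = int(np.logical_and(bits[i], bits[j]).sum())
            union = int(np.logical_or(bits[i], bits[j]).sum())
            sim[i, j] = inter / union if union else 0.0
    return sim


def naive_silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    """Direct transcription of the per-molecule a_i / b_i / SC(i) definitions."""
    n = d.shape[0]
    clusters = {q: np.flatnonzero(labels == q) for q in np.unique(labels)}
    scs = []
    for i in range(n):
        own = clusters[labels[i]]
        if len(own) == 1:
            scs.append(0.0)
            continue
        a = sum(d[i, j] for j in own if j != i) / (len(own) - 1)
        b = min(
            sum(d[i, j] for j in members) / len(members)
            for q, members in clusters.items()
            if q != labels[i]
        )
        scs.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scs))


def naive_calinski_harabasz(x: np.ndarray, labels: np.ndarray) -> float:
    """tr(B_k)/tr(W_k) * (n-k)/(k-1) via explicit dispersion matrices."""
    n, p = x.shape
    ks = np.unique(labels)
    k = len(ks)
    c_e = x.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for q in ks:
        pts = x[labels == q]
        c_q = pts.mean(axis=0)
        for row in pts:
            diff = (row - c_q)[:, None]
            W += diff @ diff.T
        diff = (c_q - c_e)[:, None]
        B += len(pts) * (diff @ diff.T)
    return float((np.trace(B) / np.trace(W)) * (n - k) / (k - 1))


def naive_davies_bouldin(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of max_{j != i} (s_i + s_j) / d_ij."""
    ks = np.unique(labels)
    cents = {q: x[labels == q].mean(axis=0) for q in ks}
    s = {
        q: float(np.mean([np.linalg.norm(row - cents[q]) for row in x[labels == q]]))
        for q in ks
    }
    total = 0.0
    for qi in ks:
        total += max(
            (s[qi] + s[qj]) / np.linalg.norm(cents[qi] - cents[qj])
            for qj in ks
            if qj != qi
        )
    return float(total / len(ks))


def brute_force_ward(d_square: np.ndarray) -> np.ndarray:
    """Greedy Ward agglomeration via an explicit cluster list and pair scan.

    Returns a (n-1, 4) merge table (left, right, height, size) with new
    nodes numbered n, n+1, ... in merge order; ties resolve to the first
    pair in (i, j) scan order over current node creation order.
    """
    n = d_square.shape[0]
    # cluster id -> (member leaf set, node id); squared distances between cluster ids
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    d2: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = d_square[i, j] ** 2
    merges = []
    next_id = n
    order = list(range(n))  # node ids sorted by creation
    for _ in range(n - 1):
        best = None
        for a_pos in range(len(order)):
            for b_pos in range(a_pos + 1, len(order)):
                a, b = order[a_pos], order[b_pos]
                key = (min(a, b), max(a, b))
                if best is None or d2[key] < best[0] - 1e-15:
                    best = (d2[key], key)
        h2, (a, b) = best
        na, nb = len(clusters[a]), len(clusters[b])
        merges.append((a, b, np.sqrt(max(h2, 0.0)), na + nb))
        new = next_id
        next_id += 1
        for c in order:
            if c in (a, b):
                continue
            nc = len(clusters[c])
            dac = d2[(min(a, c), max(a, c))]
            dbc = d2[(min(b, c), max(b, c))]
            dab = d2[(min(a, b), max(a, b))]
            d2[(c, new)] = ((na + nc) * dac + (nb + nc) * dbc - nc * dab) / (na + nb + nc)
        clusters[new] = clusters.pop(a) | clusters.pop(b)
        order = [c for c in order if c not in (a, b)] + [new]
    return np.array(merges, dtype=np.float64)
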