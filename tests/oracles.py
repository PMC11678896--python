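"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literal, loop-based transcriptions of the
definitions — no code shared with the package — so agreement is evidence,
not tautology.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Literal BH step-up: adj_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        candidate = min(1.0, p[order[rank - 1]] * m / rank)
        running_min = min(running_min, candidate)
        adj_sorted[rank - 1] = running_min
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def complete_linkage_agglomerate(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Exhaustive max-linkage agglomeration; merges as (left set, right set, height)."""
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        left, right = clusters[i], clusters[j]
        merges.append((left, right, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [left | right]
    return merges


def tanimoto_loops(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.zeros((x.shape[0], y.shape[1]))
    for i in range(x.shape[0]):
        for j in range(y.shape[1]):
            dot = sum(x[i, k] * y[k, j] for k in range(x.shape[1]))
            denom = sum(v * v for v in x[i, :]) + sum(v * v for v in y[:, j]) - abs(dot)
            out[i, j] = dot / math.sqrt(denom) if denom > 0 else 0.0
    return out


def zscore_two_pass(x: np.ndarray) -> np.ndarray:
    """Literal (Zrow + Zcol)/sqrt(2) with overall-z fallback for flat rows/cols."""
    n_r, n_c = x.shape
    flat = x.ravel()
    omean = sum(flat) / flat.size
    osd = math.sqrt(sum((v - omean) ** 2 for v in flat) / (flat.size - 1))
    overall = (x - omean) / osd
    zr = np.empty_like(x, dtype=float)
    for i in range(n_r):
        mu = sum(x[i, :]) / n_c
        sd = math.sqrt(sum((v - mu) ** 2 for v in x[i, :]) / (n_c - 1)) if n_c > 1 else 0.0
        zr[i, :] = (x[i, :] - mu) / sd if sd > 0 else overall[i, :]
    zc = np.empty_like(x, dtype=float)
    for j in range(n_c):
        mu = sum(x[:, j]) / n_r
        sd = math.sqrt(sum((v - mu) ** 2 for v in x[:, j]) / (n_r - 1)) if n_r > 1 else 0.0
        zc[:, j] = (x[:, j] - mu) / sd if sd > 0 else overall[:, j]
    return (zr + zc) / math.sqrt(2.0)


def panda_transcription(
    motif: np.ndarray,
    ppi: np.ndarray,
    coexpr: np.ndarray,
    alpha: float,
    tolerance: float,
    max_iterations: int,
) -> np.ndarray:
    """Second, loop-based transcription of the message-passing updates."""

    def diag_refresh(m: np.ndarray, t: int) -> None:
        n = m.shape[0]
        for i in range(n):
            off = [m[i, j] for j in range(n) if j != i]
            mu = sum(off) / len(off)
            denom = len(off) - 1 if len(off) > 1 else 1
            sd = math.sqrt(sum((v - mu) ** 2 for v in off) / denom)
            m[i, i] = sd * n * math.exp(2.0 * alpha * t)

    w = zscore_two_pass(motif)
    p = zscore_two_pass(ppi)
    c = zscore_two_pass(coexpr)
    for t in range(1, max_iterations + 1):
        r = tanimoto_loops(p, w)
        a = tanimoto_loops(w, c)
        w_new = (1 - alpha) * w + alpha * (r + a) / 2.0
        delta = float(np.mean(np.abs(w_new - w)))
        w = w_new
        p = (1 - alpha) * p + alpha * tanimoto_loops(w, w.T)
        diag_refresh(p, t)
        c = (1 - alpha) * c + alpha * tanimoto_loops(w.T, w)
        diag_refresh(c, t)
        if delta < tolerance:
            break
    return w


def gsea_es_two_pass(stats: np.ndarray, hits: np.ndarray, exponent: float = 1.0):
    """Literal running-sum walk; returns (es, running, leading positions)."""
    n = len(stats)
    n_hits = int(hits.sum())
    nr = sum(abs(stats[i]) ** exponent for i in range(n) if hits[i])
    running, total = [], 0.0
    for i in range(n):
        if hits[i]:
            total += (abs(stats[i]) ** exponent) / nr if nr > 0 else 1.0 / n_hits
        else:
            total -= 1.0 / (n - n_hits)
        running.append(total)
    running = np.array(running)
    mx, mn = running.max(), running.min()
    if mx >= -mn:
        idx = int(np.argmax(running))
        return float(mx), running, [i for i in range(idx + 1) if hits[i]]
    idx = int(np.argmin(running))
    return float(mn), running, [i for i in range(n - 1, idx - 1, -1) if hits[i]]


def exact_permutation_p(stats: np.ndarray, k: int, observed_es: float) -> float:
    """Exact random-set null by exhaustive enumeration (small N choose k only)."""
    from itertools import combinations

    n = len(stats)
    total, extreme = 0, 0
    for combo in combinations(range(n), k):
        hits = np.zeros(n, dtype=bool)
        hits[list(combo)] = True
        es, _, _ = gsea_es_two_pass(stats, hits)
        total += 1
        if abs(es) >= abs(observed_es):
            extreme += 1
    return extreme / total
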