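"""Brute-force reference implementations of the weighted graph metrics.

Everything here is written for transparency, not speed: triangle sums by
triple loops, shortest paths by exhaustive enumeration of simple paths.
Usable only for small graphs (<= ~8 nodes), which is exactly the point —
these are the independent oracles the fast implementations are checked
against.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_transitivity(w: np.ndarray) -> float:
    n = w.shape[0]
    mx = w.max()
    if mx == 0:
        return 0.0
    wh = w / mx
    num = 0.0
    denom = 0.0
    for i in range(n):
        k = int((w[i] > 0).sum())
        denom += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j != i and h != i and h != j:
                    num += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
    return num / denom if denom > 0 else 0.0


def brute_clustering(w: np.ndarray) -> float:
    n = w.shape[0]
    mx = w.max()
    if mx == 0:
        return 0.0
    wh = w / mx
    cs = []
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            cs.append(0.0)
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and h != j:
                    t += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        cs.append(t / (k * (k - 1)))
    return float(np.mean(cs))


def _all_simple_paths(w: np.ndarray, s: int, t: int):
    n = w.shape[0]
    for r in range(n):
        for mid in itertools.permutations([x for x in range(n) if x not in (s, t)], r):
            path = (s, *mid, t)
            if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                yield path


def brute_shortest_paths(w: np.ndarray, s: int, t: int):
    """(distance, list of shortest simple paths) on 1/weight distances."""
    best = np.inf
    paths = []
    for path in _all_simple_paths(w, s, t):
        d = sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))
        if d < best - 1e-12:
            best = d
            paths = [path]
        elif abs(d - best) <= 1e-12:
            paths.append(path)
    return best, paths


def brute_path_length(w: np.ndarray) -> float:
    n = w.shape[0]
    total, cnt = 0.0, 0
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            d, _ = brute_shortest_paths(w, s, t)
            if np.isfinite(d):
                total += d
                cnt += 1
    return total / cnt if cnt else float("inf")


def brute_betweenness(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            d, paths = brute_shortest_paths(w, s, t)
            if not np.isfinite(d) or not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def brute_closeness(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    cc = np.zeros(n)
    for s in range(n):
        dists = []
        for t in range(n):
            if t == s:
                continue
            d, _ = brute_shortest_paths(w, s, t)
            if np.isfinite(d):
                dists.append(d)
        r = len(dists) + 1
        if r > 1 and n > 1:
            cc[s] = ((r - 1) / sum(dists)) * ((r - 1) / (n - 1))
    return cc


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, straight from the
    definition: q_(i) = min_{j >= i} min(1, m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for idx in range(m - 1, -1, -1):
        i = order[idx]
        running = min(running, m * p[i] / (idx + 1))
        q[i] = running
    return q
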