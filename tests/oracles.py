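"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, quadratic time) and sharing no code with
the package, so they can serve as oracles for the optimised implementations.
"""

from __future__ import annotations

import numpy as np


def moran_brute(values, weights):
    """Moran's I by direct double sum over a dense weight matrix."""
    z = np.asarray(values, float)
    w = np.asarray(weights, float)
    n = z.size
    z = z - z.mean()
    s0 = w.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    den = (z**2).sum()
    return (n / s0) * num / den


def ripley_k_brute(points, r, area):
    """K(r) by explicit ordered-pair counting, no edge correction."""
    pts = np.asarray(points, float)
    n = len(pts)
    count = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.hypot(*(pts[i] - pts[j])) <= r:
                count += 1
    return area / (n * (n - 1)) * count


def ripley_l_brute(points, r, area):
    return np.sqrt(ripley_k_brute(points, r, area) / np.pi)


def ripley_g_brute(points, r):
    """Nearest-neighbour function by explicit distance scan."""
    pts = np.asarray(points, float)
    n = len(pts)
    hits = 0
    for i in range(n):
        dmin = np.inf
        for j in range(n):
            if i != j:
                dmin = min(dmin, np.hypot(*(pts[i] - pts[j])))
        if dmin <= r:
            hits += 1
    return hits / n


def ball_hall_brute(points, labels):
    pts = np.asarray(points, float)
    labels = np.asarray(labels)
    total = 0.0
    ks = np.unique(labels)
    for k in ks:
        sel = pts[labels == k]
        mu = sel.mean(axis=0)
        total += np.mean([np.sum((p - mu) ** 2) for p in sel])
    return total / len(ks)


def banfeld_raftery_brute(points, labels):
    pts = np.asarray(points, float)
    labels = np.asarray(labels)
    total = 0.0
    for k in np.unique(labels):
        sel = pts[labels == k]
        mu = sel.mean(axis=0)
        tr = sum(np.sum((p - mu) ** 2) for p in sel)
        if tr <= 0:
            return -np.inf
        total += len(sel) * np.log(tr / len(sel))
    return total


def c_index_brute(points, labels):
    pts = np.asarray(points, float)
    labels = np.asarray(labels)
    n = len(pts)
    all_d = []
    within = []
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(pts[i] - pts[j]))
            all_d.append(d)
            if labels[i] == labels[j]:
                within.append(d)
    nw = len(within)
    if nw == 0:
        return np.nan
    all_d = sorted(all_d)
    s_w = sum(within)
    s_min = sum(all_d[:nw])
    s_max = sum(all_d[-nw:])
    if s_max == s_min:
        return np.nan
    return (s_w - s_min) / (s_max - s_min)


def det_ratio_brute(points, labels):
    pts = np.asarray(points, float)
    labels = np.asarray(labels)
    mu = pts.mean(axis=0)
    t = np.zeros((2, 2))
    for p in pts:
        d = (p - mu).reshape(2, 1)
        t += d @ d.T
    wg = np.zeros((2, 2))
    for k in np.unique(labels):
        sel = pts[labels == k]
        muk = sel.mean(axis=0)
        for p in sel:
            d = (p - muk).reshape(2, 1)
            wg += d @ d.T
    det_wg = np.linalg.det(wg)
    if abs(det_wg) < 1e-12:
        return np.inf
    return np.linalg.det(t) / det_wg


def harrell_c_brute(times, events, risk):
    """Concordance by enumerating comparable pairs; ties in risk count 0.5."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = np.asarray(risk, float)
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must fail before j's observed time to be comparable
            if events[i] == 1 and times[i] < times[j]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def km_brute(times, events):
    """Product-limit curve by hand: returns (times, survival) at event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(times)
    times, events = times[order], events[order]
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(times[events == 1]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def group_centrality_brute(adj, til_idx):
    """Group degree/closeness of the TIL set by explicit BFS."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    til = set(int(i) for i in til_idx)
    others = [v for v in range(n) if v not in til]
    if not others:
        return np.nan, np.nan
    hits = sum(1 for v in others if any(adj[v, u] for u in til))
    deg = hits / len(others)
    # multi-source BFS from the TIL set
    dist = {u: 0 for u in til}
    frontier = list(til)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    reach = [dist[v] for v in others if v in dist]
    clo = len(reach) / sum(reach) if reach and sum(reach) > 0 else np.nan
    return deg, clo


def clustering_coefficient_brute(adj, node):
    """Local clustering coefficient by counting neighbour pairs."""
    adj = np.asarray(adj)
    nbrs = [v for v in range(adj.shape[0]) if adj[node, v]]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = 0
    for a in range(k):
        for b in range(a + 1, k):
            if adj[nbrs[a], nbrs[b]]:
                links += 1
    return 2 * links / (k * (k - 1))
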