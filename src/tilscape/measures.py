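"""The 14 spatial heterogeneity measures plus TIL fraction.

Four families:

* Point-pattern / graph statistics on the TIL patches: Ripley's F, G and L at
  a fixed search radius (default 50 patch units), Moran's I spatial
  autocorrelation over a k-NN graph, and group centrality scores of the TIL
  node set (degree, closeness, average clustering).
* Cluster-validity indices on an affinity-propagation clustering of the TIL
  patch coordinates: Ball-Hall, Banfeld-Raftery, C-index, determinant ratio.
* Texture scores on the ROI image itself: weighted GLCM sums M1/M2 (8 grey
  levels) and spatial chaos (mean nearest-neighbour distance among detected
  edge pixels; low for coherent structures, high for scattered intensities).
* The TIL fraction (%TIL) of the ROI.

NA is encoded as ``numpy.nan`` and infinities as ``numpy.inf``; both are
legitimate outputs (degenerate clusterings, constant fields) and are
preserved rather than clipped.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Optional, Tuple

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter, median_filter
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from skimage.feature import graycomatrix
from skimage.filters import sobel, threshold_otsu
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .graphs import DEFAULT_K, SpatialGraph, knn_graph
from .types import ROI, MEASURE_NAMES, PointPattern, point_pattern_from_roi

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 50.0
GLCM_LEVELS = 8
AP_DAMPING = 0.9
AP_MAX_ITER = 500
AP_MAX_POINTS = 5000


# ---------------------------------------------------------------------------
# Ripley's summary functions
# ---------------------------------------------------------------------------

def ripley_stats(
    pattern: PointPattern, radius: float = DEFAULT_RADIUS, periodic: bool = False
) -> Tuple[float, float, float]:
    """Ripley's (F, G, L) of the TIL points at a single search radius.

    G(r): fraction of TIL points whose nearest other TIL point lies within r.
    F(r): empty-space function — fraction of reference points (the regular
    unit grid over the window) whose nearest TIL point lies within r.
    L(r) = sqrt(K(r)/pi) with K(r) = A/(n(n-1)) * #{ordered pairs with d <= r}.

    No edge correction is applied by default; ``periodic=True`` evaluates
    distances on the torus, which removes edge bias and is used to validate
    the CSR expectation L(r) = r.
    """
    pts = pattern.til_coords
    n = len(pts)
    h, w = pattern.window
    area = float(h * w)
    if n == 0:
        return np.nan, np.nan, np.nan

    boxsize = (h, w) if periodic else None
    if periodic:
        pts = np.mod(pts, (h, w))
    tree = cKDTree(pts, boxsize=boxsize)

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    refs = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d_ref, _ = tree.query(refs, k=1)
    f_val = float(np.mean(d_ref <= radius))

    if n < 2:
        return f_val, np.nan, np.nan

    d_nn, _ = tree.query(pts, k=2)
    g_val = float(np.mean(d_nn[:, 1] <= radius))

    n_pairs = len(tree.query_pairs(radius))  # unordered
    k_val = area / (n * (n - 1)) * 2.0 * n_pairs
    l_val = float(np.sqrt(k_val / np.pi))
    return f_val, g_val, l_val


# ---------------------------------------------------------------------------
# Moran's I spatial autocorrelation
# ---------------------------------------------------------------------------

def spatial_autocorrelation(values: np.ndarray, graph: SpatialGraph) -> float:
    """Moran's I of ``values`` under the graph's binary weights.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values and S0 the total weight.  A constant field has zero variance and
    returns NA.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n != graph.n_nodes:
        raise ValueError("values length must match graph node count")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0 or n < 2:
        return np.nan
    w = graph.adjacency
    s0 = float(w.sum())
    if s0 == 0.0:
        return np.nan
    num = float(z @ (w @ z))
    return (n / s0) * num / denom


# ---------------------------------------------------------------------------
# Group centrality of the TIL node set
# ---------------------------------------------------------------------------

def centrality_scores(
    graph: SpatialGraph, is_til: np.ndarray
) -> Tuple[float, float, float]:
    """Group degree centrality, group closeness centrality and average
    clustering of the TIL node set.

    * degree: fraction of non-TIL nodes adjacent to at least one TIL node;
    * closeness: |reachable non-TIL nodes| / sum of their graph distances to
      the TIL set (unreachable nodes are excluded and the count adjusted);
    * average clustering: mean local clustering coefficient over TIL nodes.
    """
    is_til = np.asarray(is_til, dtype=bool)
    if is_til.size != graph.n_nodes:
        raise ValueError("is_til length must match graph node count")
    til_idx = np.flatnonzero(is_til)
    if til_idx.size == 0:
        raise ValueError("TIL group is empty")
    other_idx = np.flatnonzero(~is_til)

    adj = graph.adjacency
    if other_idx.size == 0:
        deg = np.nan
        clo = np.nan
    else:
        til_adj_counts = np.asarray(adj[:, til_idx].sum(axis=1)).ravel()
        deg = float(np.mean(til_adj_counts[other_idx] > 0))
        g = graph.to_networkx()
        dists = nx.multi_source_dijkstra_path_length(g, set(til_idx.tolist()))
        d_others = [dists[v] for v in other_idx if v in dists]
        clo = float(len(d_others) / sum(d_others)) if d_others and sum(d_others) > 0 else np.nan

    g = graph.to_networkx()
    cc = nx.clustering(g, nodes=til_idx.tolist())
    avg_clust = float(np.mean(list(cc.values()))) if cc else np.nan
    return deg, clo, avg_clust


# ---------------------------------------------------------------------------
# Affinity-propagation clustering and validity indices
# ---------------------------------------------------------------------------

def ap_cluster(
    coords: np.ndarray,
    max_points: int = AP_MAX_POINTS,
    seed: int = 0,
    damping: float = AP_DAMPING,
    max_iter: int = AP_MAX_ITER,
) -> np.ndarray:
    """Affinity-propagation labels for TIL coordinates.

    Similarity is the negative squared Euclidean distance with the median
    similarity as preference (the classical defaults).  Patterns larger than
    ``max_points`` are clustered on a seeded uniform subsample, the remaining
    points being assigned to the nearest exemplar; affinity propagation is
    quadratic in the point count, so the cap keeps large ROIs tractable.  If
    message passing fails to converge the fall-back is one cluster per
    connected component of the k-NN graph (logged).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return np.zeros(n, dtype=int)
    rng = np.random.default_rng(seed)
    if n > max_points:
        sub = np.sort(rng.choice(n, size=max_points, replace=False))
    else:
        sub = np.arange(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ap = AffinityPropagation(
            damping=damping,
            max_iter=max_iter,
            random_state=int(seed) % (2**31),
        ).fit(coords[sub])
    centers = getattr(ap, "cluster_centers_", np.empty((0, coords.shape[1])))
    if centers.shape[0] == 0 or (ap.labels_ < 0).any():
        logger.warning("affinity propagation did not converge; falling back to k-NN components")
        g = knn_graph(coords).to_networkx()
        labels = np.empty(n, dtype=int)
        for ci, comp in enumerate(nx.connected_components(g)):
            labels[list(comp)] = ci
        return labels
    tree = cKDTree(centers)
    _, labels = tree.query(coords, k=1)
    return labels.astype(int)


def cluster_indices(
    points: np.ndarray, labels: np.ndarray
) -> Tuple[float, float, float, float]:
    """Ball-Hall, Banfeld-Raftery, C-index and determinant ratio.

    * Ball-Hall: mean over clusters of the mean squared distance to the
      cluster centroid.
    * Banfeld-Raftery: sum_k n_k * log(tr(W_k)/n_k); a zero-scatter cluster
      contributes -inf, which is preserved.
    * C-index: (S_W - S_min)/(S_max - S_min) where S_W sums the within-
      cluster pairwise distances (N_W pairs) and S_min/S_max sum the N_W
      smallest/largest pairwise distances of the whole set; NA when the
      denominator vanishes or no within-cluster pair exists.
    * Determinant ratio: det(T)/det(WG) with T the total scatter matrix and
      WG the pooled within-cluster scatter; a singular WG yields +inf.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n, d = pts.shape
    if n < 2:
        raise ValueError("need at least 2 points")
    uniq = np.unique(labels)

    ball_hall = 0.0
    banfeld = 0.0
    wg = np.zeros((d, d))
    n_within_pairs = 0
    s_within = 0.0
    dists = pdist(pts)
    for lab in uniq:
        sel = pts[labels == lab]
        nk = len(sel)
        mu = sel.mean(axis=0)
        dev = sel - mu
        sq = float((dev**2).sum())
        ball_hall += sq / nk
        with np.errstate(divide="ignore"):
            banfeld += nk * np.log(sq / nk) if sq > 0 else -np.inf
        wg += dev.T @ dev
        if nk >= 2:
            s_within += float(pdist(sel).sum())
            n_within_pairs += nk * (nk - 1) // 2
    ball_hall /= len(uniq)

    if n_within_pairs == 0 or dists.size == 0:
        c_index = np.nan
    else:
        part = np.sort(dists)
        s_min = float(part[:n_within_pairs].sum())
        s_max = float(part[-n_within_pairs:].sum())
        c_index = (s_within - s_min) / (s_max - s_min) if s_max > s_min else np.nan

    devt = pts - pts.mean(axis=0)
    t_mat = devt.T @ devt
    det_t = float(np.linalg.det(t_mat))
    det_wg = float(np.linalg.det(wg))
    if abs(det_wg) < 1e-12:
        det_ratio = np.inf
    else:
        det_ratio = det_t / det_wg
    return float(ball_hall), float(banfeld), float(c_index), det_ratio


# ---------------------------------------------------------------------------
# GLCM texture scores
# ---------------------------------------------------------------------------

def _quantize(grid: np.ndarray, levels: int = GLCM_LEVELS) -> Optional[np.ndarray]:
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:
        return None
    q = np.floor((grid - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def default_glcm_weights(levels: int = GLCM_LEVELS) -> Tuple[np.ndarray, np.ndarray]:
    """Default weight matrices emphasising co-occurring low (M1) and high
    (M2) intensities: w_ij = (levels+1-i)(levels+1-j) on the low quarter and
    w_ij = i*j on the high quarter (1-based levels)."""
    i = np.arange(1, levels + 1)
    low = np.outer(levels + 1 - i, levels + 1 - i).astype(float)
    high = np.outer(i, i).astype(float)
    return low, high


def glcm_m1_m2(
    grid: np.ndarray,
    levels: int = GLCM_LEVELS,
    low_weights: Optional[np.ndarray] = None,
    high_weights: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Weighted grey-level co-occurrence sums M1 (low block) and M2 (high).

    The ROI is quantised to ``levels`` equal-width intensity levels, a
    symmetric co-occurrence matrix is accumulated at distance 1 in four
    directions (0, 45, 90, 135 degrees) and normalised to probabilities; M1
    sums the weighted lower-left quarter (levels 1..levels/2 against each
    other) and M2 the upper-right quarter.  Constant ROIs quantise
    degenerately and return NA.
    """
    q = _quantize(np.asarray(grid, dtype=float), levels)
    if q is None:
        return np.nan, np.nan
    glcm = graycomatrix(
        q.astype(np.uint8),
        distances=[1],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels,
        symmetric=True,
        normed=False,
    )
    counts = glcm[:, :, 0, :].sum(axis=-1).astype(float)
    total = counts.sum()
    if total == 0:
        return np.nan, np.nan
    p = counts / total
    low_w, high_w = default_glcm_weights(levels)
    if low_weights is not None:
        low_w = np.asarray(low_weights, dtype=float)
    if high_weights is not None:
        high_w = np.asarray(high_weights, dtype=float)
    half = levels // 2
    m1 = float((low_w[:half, :half] * p[:half, :half]).sum())
    m2 = float((high_w[half:, half:] * p[half:, half:]).sum())
    return m1, m2


# ---------------------------------------------------------------------------
# Spatial chaos
# ---------------------------------------------------------------------------

def spatial_chaos(grid: np.ndarray, prefilter: str = "gaussian", sigma: float = 1.0) -> float:
    """Mean nearest-neighbour distance among detected edge pixels.

    Two-step edge detection for noisy images: a smoothing prefilter followed
    by the Sobel gradient magnitude thresholded at its Otsu level.  Spatially
    coherent structures produce contiguous edge bands (score near 1);
    scattered intensities produce sparser, partly isolated edge pixels and a
    higher score.  NA when fewer than two edge pixels are found.

    The default prefilter is Gaussian (``sigma`` patches): on coarse binary
    patch grids a median prefilter either erases sparse patterns outright or
    leaves plateaus whose Sobel edges are contiguous bands, collapsing the
    score to exactly 1 for structured and chaotic patterns alike; Gaussian
    smoothing keeps the gradient field continuous so Otsu isolates the
    strongest edges only.  Set ``prefilter="median"`` (3x3) for the variant
    suited to finer-grained imagery, or ``"none"`` to skip smoothing.
    """
    img = np.asarray(grid, dtype=float)
    if prefilter == "gaussian":
        smooth = gaussian_filter(img, sigma)
    elif prefilter == "median":
        smooth = median_filter(img, size=3)
    elif prefilter == "none":
        smooth = img
    else:
        raise ValueError("prefilter must be 'gaussian', 'median' or 'none'")
    grad = sobel(smooth)
    finite = grad[np.isfinite(grad)]
    if finite.size == 0 or finite.max() == finite.min():
        return np.nan
    try:
        thr = threshold_otsu(grad)
    except ValueError:
        return np.nan
    edges = np.argwhere(grad > thr)
    if len(edges) < 2:
        return np.nan
    tree = cKDTree(edges.astype(float))
    d, _ = tree.query(edges.astype(float), k=2)
    return float(np.mean(d[:, 1]))


# ---------------------------------------------------------------------------
# TIL fraction and the full measure vector
# ---------------------------------------------------------------------------

def pct_tils(grid: np.ndarray) -> float:
    """Fraction of TIL-positive patches in the ROI grid, in [0, 1]."""
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        return np.nan
    return float(np.mean(g > 0))


def compute_measures(
    roi: ROI,
    k: int = DEFAULT_K,
    radius: float = DEFAULT_RADIUS,
    ap_max_points: int = AP_MAX_POINTS,
    seed: int = 0,
    glcm_low_weights: Optional[np.ndarray] = None,
    glcm_high_weights: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """All 14 spatial measures plus ``pct_tils`` for one ROI.

    Point/graph statistics are computed on the patch point pattern (every
    patch is a point; TIL membership is value > 0 on the binary scale and
    value >= 0.5 on the probability scale); texture scores are computed on
    the ROI grid itself, so they respond to the map scale.  Affinity
    propagation is the only stochastic stage and is controlled by ``seed``.
    """
    pattern = point_pattern_from_roi(roi)
    out: Dict[str, float] = {name: np.nan for name in MEASURE_NAMES}

    f_val, g_val, l_val = ripley_stats(pattern, radius=radius)
    out["ripley_f"], out["ripley_g"], out["ripley_l"] = f_val, g_val, l_val

    graph = knn_graph(pattern.coords, k=k)
    out["spatial_autocorrelation"] = spatial_autocorrelation(pattern.values, graph)

    if pattern.is_til.any():
        deg, clo, avg = centrality_scores(graph, pattern.is_til)
        out["degree_centrality"] = deg
        out["closeness_centrality"] = clo
        out["average_clustering"] = avg

    til_pts = pattern.til_coords
    if len(til_pts) >= 2:
        labels = ap_cluster(til_pts, max_points=ap_max_points, seed=seed)
        bh, br, ci, dr = cluster_indices(til_pts, labels)
        out["ball_hall"] = bh
        out["banfeld_raftery"] = br
        out["c_index"] = ci
        out["det_ratio"] = dr

    m1, m2 = glcm_m1_m2(
        roi.grid, low_weights=glcm_low_weights, high_weights=glcm_high_weights
    )
    out["glcm_m1"], out["glcm_m2"] = m1, m2
    out["spatial_chaos"] = spatial_chaos(roi.grid)
    out["pct_tils"] = pct_tils(roi.grid)
    return out
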