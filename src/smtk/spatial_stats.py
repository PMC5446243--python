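"""Spatial statistics for two-color super-resolution point patterns.

Two complementary questions about localization maps of two nuclear factors:

1. Do the two colors co-cluster? The edge-corrected pair cross-correlation
   C(r) is the density of channel-B points at distance r from channel-A
   points, normalized by the product of the overall channel intensities;
   C(r) = 1 at all r when the channels are independent (complete spatial
   randomness), C(r) > 1 at short r reports co-clustering.

2. Are apparent clusters real multi-molecule assemblies or photo-blinking
   artifacts? When one protein is labeled stochastically with two dyes, a
   genuine cluster of N molecules carries Binomial(N, p1) molecules of
   channel 1, while a blinking artifact is single-colored (k = 0 or N). The
   composition test compares the observed k/N distribution of clusters
   (N ≥ 10 detections) against a resampled binomial reference and summarizes
   the deviation as a Kullback–Leibler divergence in bits.

Cluster assignment is an input; a plain density-based assigner (radius +
minimum neighbors, i.e. DBSCAN) ships as plumbing for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "PointPattern",
    "CrossCorrelation",
    "ClusterComposition",
    "pair_cross_correlation",
    "average_cross_correlations",
    "binomial_composition_test",
    "assign_clusters",
]

#: Minimum detections for a cluster to enter the composition test.
MIN_CLUSTER_SIZE = 10


@dataclass
class PointPattern:
    """Labeled 2D localizations inside a polygonal ROI (coordinates in μm)."""

    x: np.ndarray
    y: np.ndarray
    channel: np.ndarray
    roi: Polygon

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.channel = np.asarray(self.channel)
        if not (len(self.x) == len(self.y) == len(self.channel)):
            raise ValueError("x, y, channel must have equal length")
        if not isinstance(self.roi, Polygon):
            self.roi = Polygon(self.roi)

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, ch) -> np.ndarray:
        """(n, 2) coordinates of one channel."""
        m = self.channel == ch
        return np.column_stack([self.x[m], self.y[m]])


@dataclass
class CrossCorrelation:
    """Binned pair cross-correlation estimate."""

    r: np.ndarray  # bin centers, μm
    C: np.ndarray
    se: np.ndarray | None = None  # across-cell standard error, if averaged
    bin_width: float = 0.010


@dataclass
class ClusterComposition:
    """Two-color composition of detected clusters."""

    N: np.ndarray  # total detections per cluster
    k: np.ndarray  # channel-1 detections per cluster
    p1: float = field(default=None)  # overall channel-1 fraction

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=int)
        self.k = np.asarray(self.k, dtype=int)
        if np.any(self.k < 0) or np.any(self.k > self.N):
            raise ValueError("need 0 <= k <= N per cluster")
        if np.any(self.N < MIN_CLUSTER_SIZE):
            raise ValueError(f"clusters must have N >= {MIN_CLUSTER_SIZE}")
        if self.p1 is None:
            self.p1 = float(self.k.sum() / self.N.sum())


def _annulus_weights(pts: np.ndarray, edges: np.ndarray, roi: Polygon) -> np.ndarray:
    """Fraction of each annulus area inside the ROI, per point.

    Points farther from the ROI boundary than the outer radius have weight 1
    for that bin; only near-boundary points pay for a shapely intersection.
    """
    n_bins = len(edges) - 1
    w = np.ones((len(pts), n_bins))
    boundary_dist = np.array([roi.exterior.distance(Point(p)) for p in pts])
    for i, p in enumerate(pts):
        d = boundary_dist[i]
        if d >= edges[-1]:
            continue
        center = Point(p)
        for b in range(n_bins):
            r_out = edges[b + 1]
            if d >= r_out:
                continue
            outer = center.buffer(r_out, quad_segs=32)
            inner = center.buffer(edges[b], quad_segs=32) if edges[b] > 0 else None
            annulus = outer.difference(inner) if inner is not None else outer
            area = annulus.area
            if area <= 0:
                continue
            w[i, b] = annulus.intersection(roi).area / area
    return np.maximum(w, 1e-6)


def pair_cross_correlation(
    pp: PointPattern,
    ch_a,
    ch_b,
    r_max: float = 0.5,
    bin_width: float = 0.010,
) -> CrossCorrelation:
    """Edge-corrected pair cross-correlation C(r) between two channels.

    Estimator: pair counts per distance annulus, each pair weighted by the
    inverse fraction of the annulus (around the reference point) inside the
    ROI, divided by the CSR expectation n_a·n_b·area(annulus)/area(ROI).
    The two orientations (A→B and B→A) are averaged, making the estimate
    symmetric in the channels by construction.
    """
    a = pp.subset(ch_a)
    b = pp.subset(ch_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both channels must contain points")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    area_roi = pp.roi.area
    annulus_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)

    from scipy.spatial import cKDTree

    same = ch_a == ch_b

    def one_direction(ref, other, self_pairs: bool):
        tree = cKDTree(other)
        w = _annulus_weights(ref, edges, pp.roi)
        counts = np.zeros(n_bins)
        for i, p in enumerate(ref):
            d = tree.query_ball_point(p, r=edges[-1], return_sorted=False)
            dists = np.linalg.norm(other[d] - p, axis=1)
            if self_pairs:
                dists = dists[dists > 0]  # drop the point itself
            idx = np.searchsorted(edges, dists, side="right") - 1
            idx = idx[(idx >= 0) & (idx < n_bins)]
            np.add.at(counts, idx, 1.0 / w[i, idx] if len(idx) else 0.0)
        n_other = len(other) - (1 if self_pairs else 0)
        expected = len(ref) * n_other * annulus_area / area_roi
        return counts / expected

    C_ab = one_direction(a, b, same)
    C = C_ab if same else 0.5 * (C_ab + one_direction(b, a, same))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CrossCorrelation(r=centers, C=C, bin_width=bin_width)


def average_cross_correlations(curves: list[CrossCorrelation]) -> CrossCorrelation:
    """Average per-cell C(r) curves; standard error across cells per bin."""
    if not curves:
        raise ValueError("no curves")
    r = curves[0].r
    for c in curves[1:]:
        if len(c.r) != len(r) or not np.allclose(c.r, r):
            raise ValueError("inconsistent radius grids")
    mat = np.vstack([c.C for c in curves])
    se = mat.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else None
    return CrossCorrelation(r=r, C=mat.mean(axis=0), se=se, bin_width=curves[0].bin_width)


def _composition_histogram(k: np.ndarray, N: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Add-one-smoothed histogram of k/N on [0, 1]."""
    frac = k / N
    hist, _ = np.histogram(frac, bins=n_bins, range=(0.0, 1.0))
    hist = hist.astype(float) + 1.0  # smoothing: KL undefined on empty bins
    return hist / hist.sum()


def binomial_composition_test(
    cc: ClusterComposition,
    n_resample: int = 100,
    seed: int = 0,
    n_bins: int = 20,
):
    """Compare observed cluster compositions with the binomial expectation.

    For each observed cluster of size N, ``n_resample`` reference clusters
    are drawn with k ~ Binomial(N, p1); the observed and reference k/N
    histograms (``n_bins`` bins on [0, 1], add-one smoothed) are compared by
    the Kullback–Leibler divergence D(observed ‖ reference) in bits.
    Single-color labeling (p1 of 0 or 1) is rejected: composition carries no
    information there.

    Returns (observed histogram, reference histogram, kl_bits).
    """
    if not (0.0 < cc.p1 < 1.0):
        raise ValueError("overall channel-1 fraction must be strictly inside (0, 1)")
    if len(cc.N) < 1:
        raise ValueError("no clusters")
    rng = np.random.default_rng(seed)
    obs = _composition_histogram(cc.k, cc.N, n_bins)
    N_rep = np.repeat(cc.N, n_resample)
    k_rep = rng.binomial(N_rep, cc.p1)
    ref = _composition_histogram(k_rep, N_rep, n_bins)
    kl_bits = float(np.sum(obs * np.log2(obs / ref)))
    return obs, ref, kl_bits


def assign_clusters(
    pp: PointPattern, radius: float = 0.05, min_points: int = 5
) -> ClusterComposition:
    """Density-based cluster assignment (DBSCAN) and two-color composition.

    Plumbing for synthetic data — a plain radius/min-neighbors assigner, not
    a model-based cluster-identification method. Clusters with fewer than
    ``MIN_CLUSTER_SIZE`` detections are dropped.
    """
    from sklearn.cluster import DBSCAN

    xy = np.column_stack([pp.x, pp.y])
    if len(xy) == 0:
        raise ValueError("empty point pattern")
    labels = DBSCAN(eps=radius, min_samples=min_points).fit_predict(xy)
    ch1 = pp.channel == np.unique(pp.channel)[0]
    Ns, ks = [], []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        m = labels == lab
        if m.sum() >= MIN_CLUSTER_SIZE:
            Ns.append(int(m.sum()))
            ks.append(int((m & ch1).sum()))
    if not Ns:
        raise ValueError("no clusters with enough detections")
    p1 = float(ch1.sum() / len(pp))
    return ClusterComposition(N=np.array(Ns), k=np.array(ks), p1=p1)
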