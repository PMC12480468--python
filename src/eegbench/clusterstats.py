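"""Cluster-based permutation statistics over channel x frequency x time.

Each time-frequency bin during stimulation is compared against the per-
frequency baseline average with a paired t-test across trials. Bins with
|t| above the cluster-forming threshold (1.28, the 90th percentile of the
standard normal) are grouped into same-sign clusters; two bins are
neighbors when they share a (frequency, time) coordinate on adjacent
sensors, or sit on the same sensor at an adjacent frequency or time step
(rook adjacency, no diagonals). Family-wise-corrected p-values come from a
sign-flip permutation null of the maximum cluster statistic; the cluster
statistic is the maximum absolute t within the cluster (cluster mass, the
sum of t, is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

#: 90th percentile of the standard normal distribution, the default
#: cluster-forming threshold applied to |t|.
CLUSTER_THRESHOLD = 1.28


# ---------------------------------------------------------------------------
# adjacency

@dataclass
class Adjacency:
    """Sensor neighbor graph; time/frequency adjacency is the implicit
    ±1-step lattice."""

    matrix: np.ndarray          # (n_ch, n_ch) bool, symmetric, no self-loops
    channels: list

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=bool)
        if not (m == m.T).all():
            raise ValueError("sensor adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("sensor adjacency must have no self-loops")
        if m.shape[0] > 1 and not m.any(axis=1).all():
            raise ValueError("every channel needs at least one neighbor")
        self.matrix = m


def _azimuthal_projection(positions: np.ndarray) -> np.ndarray:
    """Project unit-sphere electrode positions to the plane (vertex-centered
    azimuthal equidistant projection, the usual flattened-scalp view)."""
    x, y, z = positions.T
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def sensor_adjacency(positions: np.ndarray, channels: list,
                     distance_cap: float = 1.6) -> Adjacency:
    """Delaunay neighbors on the projected montage with a distance cap.

    Edges longer than ``distance_cap`` times the median Delaunay edge length
    are pruned (they connect across the scalp on concave montages); if
    pruning isolates a channel its shortest edge is restored.
    """
    n = len(channels)
    mat = np.zeros((n, n), dtype=bool)
    if n < 3:
        mat[:] = ~np.eye(n, dtype=bool)
        return Adjacency(mat, list(channels))
    pts = _azimuthal_projection(np.asarray(positions, dtype=float))
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((a, b))
    lengths = {e: np.linalg.norm(pts[e[0]] - pts[e[1]]) for e in edges}
    med = np.median(list(lengths.values()))
    for (a, b), l in lengths.items():
        if l <= distance_cap * med:
            mat[a, b] = mat[b, a] = True
    for i in range(n):
        if not mat[i].any():
            cand = [(l, e) for e, l in lengths.items() if i in e]
            _, (a, b) = min(cand)
            mat[a, b] = mat[b, a] = True
    return Adjacency(mat, list(channels))


def bin_adjacency(adj: Adjacency, n_freqs: int, n_times: int) -> sparse.csr_matrix:
    """Sparse adjacency over flattened (channel, freq, time) bins.

    Bin index = c * n_freqs * n_times + f * n_times + t. Neighbors: adjacent
    sensors at identical (f, t); same sensor at f±1 or t±1.
    """
    n_ch = adj.matrix.shape[0]
    ft = n_freqs * n_times
    n_bins = n_ch * ft
    rows, cols = [], []

    idx = np.arange(n_bins).reshape(n_ch, n_freqs, n_times)
    # time neighbors
    a, b = idx[:, :, :-1].ravel(), idx[:, :, 1:].ravel()
    rows.append(a), cols.append(b)
    # frequency neighbors
    a, b = idx[:, :-1, :].ravel(), idx[:, 1:, :].ravel()
    rows.append(a), cols.append(b)
    # sensor neighbors (upper triangle only; symmetrized below)
    ci, cj = np.nonzero(np.triu(adj.matrix))
    if len(ci):
        base = np.arange(ft)
        for i, j in zip(ci, cj):
            rows.append(i * ft + base), cols.append(j * ft + base)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(len(r), dtype=bool)
    m = sparse.coo_matrix((data, (r, c)), shape=(n_bins, n_bins))
    return (m + m.T).tocsr()


# ---------------------------------------------------------------------------
# paired statistics

@dataclass
class StatMap:
    """Per-bin paired t statistics (post minus baseline)."""

    t: np.ndarray               # (n_ch, n_freqs, n_times)
    dof: int
    channels: list
    freqs: np.ndarray
    times: np.ndarray
    zero_variance_bins: int = 0

    def __post_init__(self):
        if not np.isfinite(self.t).all():
            raise ValueError("t map must be finite")


def trial_differences(tfr_data: np.ndarray, times: np.ndarray,
                      baseline=(-0.5, -0.1), baseline_mean: np.ndarray = None):
    """Per-trial (bin power minus per-frequency baseline mean) differences.

    ``tfr_data`` is (n_trials, n_ch, n_freqs, n_times). The baseline mean is
    per trial, channel and frequency (averaged over baseline times); pass
    ``baseline_mean`` (n_ch, n_freqs) to use a fixed external baseline.
    """
    if baseline_mean is not None:
        return tfr_data - baseline_mean[None, :, :, None]
    sel = (times >= baseline[0] - 1e-9) & (times < baseline[1] - 1e-9)
    if not sel.any():
        raise ValueError(f"no baseline samples in window {baseline}")
    base = tfr_data[..., sel].mean(axis=-1)
    return tfr_data - base[..., None]


def _t_from_diffs(diffs: np.ndarray):
    """Paired t across the trial axis; zero-variance bins get t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero = sd == 0
    sd = np.where(zero, 1.0, sd)
    t = mean / (sd / np.sqrt(n))
    t[zero] = 0.0
    return t, int(zero.sum())


def paired_t_map(tfr_data: np.ndarray, times: np.ndarray, channels: list,
                 freqs: np.ndarray, baseline=(-0.5, -0.1),
                 baseline_mean: np.ndarray = None) -> StatMap:
    """Per-bin paired t of stimulation power against the baseline average."""
    if tfr_data.shape[0] < 10:
        raise ValueError("need >= 10 trials for the paired t map")
    diffs = trial_differences(tfr_data, times, baseline, baseline_mean)
    t, n_zero = _t_from_diffs(diffs)
    return StatMap(t=t, dof=tfr_data.shape[0] - 1, channels=list(channels),
                   freqs=np.asarray(freqs), times=np.asarray(times),
                   zero_variance_bins=n_zero)


# ---------------------------------------------------------------------------
# clustering

@dataclass
class Cluster:
    bins: np.ndarray            # flat bin indices into (n_ch, n_f, n_t)
    sign: int                   # +1 or -1
    stat_max_abs: float         # max |t| within the cluster
    stat_mass: float            # sum of t within the cluster
    p_fwer: float = np.nan


@dataclass
class ClusterSet:
    clusters: list
    shape: tuple                # (n_ch, n_freqs, n_times)
    threshold: float
    channels: list
    freqs: np.ndarray
    times: np.ndarray
    n_permutations: int = 0
    statistic: str = "max"

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_fwer < alpha]


def _components(flat_idx: np.ndarray, bin_adj: sparse.csr_matrix) -> list:
    if len(flat_idx) == 0:
        return []
    sub = bin_adj[flat_idx][:, flat_idx]
    n_comp, labels = connected_components(sub, directed=False)
    return [flat_idx[labels == k] for k in range(n_comp)]


def find_clusters(stat_map: StatMap, adj: Adjacency,
                  threshold: float = CLUSTER_THRESHOLD,
                  bin_adj: sparse.csr_matrix = None) -> ClusterSet:
    """Connected components of supra-threshold bins, split by sign."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    shape = stat_map.t.shape
    if bin_adj is None:
        bin_adj = bin_adjacency(adj, shape[1], shape[2])
    tflat = stat_map.t.ravel()
    clusters = []
    for sign in (1, -1):
        idx = np.nonzero(sign * tflat > threshold)[0]
        for bins in _components(idx, bin_adj):
            tvals = tflat[bins]
            clusters.append(Cluster(bins=bins, sign=sign,
                                    stat_max_abs=float(np.abs(tvals).max()),
                                    stat_mass=float(tvals.sum())))
    clusters.sort(key=lambda c: -c.stat_max_abs)
    return ClusterSet(clusters=clusters, shape=shape, threshold=threshold,
                      channels=list(stat_map.channels), freqs=stat_map.freqs,
                      times=stat_map.times)


def permutation_test(tfr_data: np.ndarray, times: np.ndarray, channels: list,
                     freqs: np.ndarray, adj: Adjacency, baseline=(-0.5, -0.1),
                     n_perm: int = 1000, threshold: float = CLUSTER_THRESHOLD,
                     seed: int = 0, statistic: str = "max",
                     baseline_mean: np.ndarray = None) -> ClusterSet:
    """Cluster permutation test with trial-wise sign flips.

    The exchangeable quantity is each trial's (post minus baseline)
    difference map; under the null its sign is arbitrary. Per permutation
    the maximum cluster-level statistic is recorded and each observed
    cluster gets p_fwer = (1 + #{perm >= observed}) / (n_perm + 1).

    With the default max-|t| cluster statistic the permutation maximum over
    clusters equals the largest supra-threshold |t| in the permuted map, so
    no per-permutation clustering is required; the mass statistic clusters
    every permutation.
    """
    if statistic not in ("max", "mass"):
        raise ValueError("statistic must be 'max' or 'mass'")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution")
    diffs = trial_differences(tfr_data, times, baseline, baseline_mean)
    n_trials = diffs.shape[0]
    t_obs, _ = _t_from_diffs(diffs)
    stat_map = StatMap(t=t_obs, dof=n_trials - 1, channels=list(channels),
                       freqs=np.asarray(freqs), times=np.asarray(times))
    bin_adj = bin_adjacency(adj, diffs.shape[2], diffs.shape[3])
    cset = find_clusters(stat_map, adj, threshold, bin_adj=bin_adj)

    rng = np.random.default_rng(seed)
    flat = diffs.reshape(n_trials, -1)
    null = np.zeros(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_trials)
        t_p, _ = _t_from_diffs(flat * signs[:, None])
        if statistic == "max":
            supra = np.abs(t_p) > threshold
            null[p] = np.abs(t_p[supra]).max() if supra.any() else 0.0
        else:
            t_p = t_p.reshape(diffs.shape[1:])
            sm = StatMap(t=t_p, dof=n_trials - 1, channels=list(channels),
                         freqs=np.asarray(freqs), times=np.asarray(times))
            cs = find_clusters(sm, adj, threshold, bin_adj=bin_adj)
            null[p] = max((abs(c.stat_mass) for c in cs.clusters), default=0.0)

    for c in cset.clusters:
        obs = c.stat_max_abs if statistic == "max" else abs(c.stat_mass)
        c.p_fwer = float((1 + np.sum(null >= obs)) / (n_perm + 1))
    cset.n_permutations = n_perm
    cset.statistic = statistic
    return cset


# ---------------------------------------------------------------------------
# summaries

def summarize_clusters(cset: ClusterSet, alpha: float = 0.05,
                       roi_boxes: dict = None):
    """Electrode / time-frequency percentage summaries of significant clusters.

    Returns, separately for positive and negative clusters:

    * ``tf_percentages[sign]`` (n_freqs, n_times): percentage of electrodes
      belonging to a significant cluster at each time-frequency bin;
    * ``topo_percentages[sign]`` (n_channels,): percentage of the ROI
      time-frequency bins (all bins when ``roi_boxes`` is None) in which the
      electrode belongs to a significant cluster.
    """
    n_ch, n_f, n_t = cset.shape
    member = {1: np.zeros(cset.shape, dtype=bool),
              -1: np.zeros(cset.shape, dtype=bool)}
    for c in cset.significant(alpha):
        member[c.sign].ravel()[c.bins] = True

    if roi_boxes:
        fsel = np.zeros(n_f, dtype=bool)
        tsel = np.zeros(n_t, dtype=bool)
        roi = np.zeros((n_f, n_t), dtype=bool)
        for flo, fhi, tlo, thi in roi_boxes.values():
            fs = (cset.freqs >= flo - 1e-9) & (cset.freqs < fhi - 1e-9)
            ts = (cset.times >= tlo - 1e-9) & (cset.times < thi - 1e-9)
            roi |= np.outer(fs, ts)
    else:
        roi = np.ones((n_f, n_t), dtype=bool)

    tf_pct, topo_pct = {}, {}
    for sign in (1, -1):
        tf_pct[sign] = 100.0 * member[sign].mean(axis=0)
        n_roi = roi.sum()
        topo_pct[sign] = 100.0 * (member[sign] & roi[None]).sum(axis=(1, 2)) / n_roi
    return tf_pct, topo_pct
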