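"""Nonparametric cluster-based permutation test over electrodes.

Per-electrode t statistics (dependent or independent, two-tailed) are
thresholded at the parametric critical value; suprathreshold electrodes are
grouped into spatial clusters via the neighbor graph; the cluster statistic
is the signed sum of t values ('mass').  The null distribution of the
maximum absolute cluster mass is built from sign flips (paired) or label
shuffles (independent); cluster p = (r + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core_io import NeighborGraph


@dataclass
class Cluster:
    electrodes: list[int]
    mass: float
    p: float


@dataclass
class ClusterTestResult:
    t: np.ndarray                  # per-electrode statistic
    clusters: list[Cluster]
    n_permutations: int
    test: str                      # 'dependent' | 'independent'
    alpha: float
    threshold: float               # cluster-forming |t| threshold
    channel_names: tuple[str, ...]

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]

    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    return m / (sd / np.sqrt(n) + 1e-300)


def _independent_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (a.mean(axis=0) - b.mean(axis=0)) / \
        (np.sqrt(sp * (1 / na + 1 / nb)) + 1e-300)


def _clusters_from_t(t: np.ndarray, threshold: float,
                     neigh: list[np.ndarray]) -> list[tuple[list[int], float]]:
    """Connected suprathreshold sets, positive and negative tails separately."""
    out: list[tuple[list[int], float]] = []
    for sign in (1.0, -1.0):
        supra = sign * t > threshold
        seen = np.zeros(len(t), dtype=bool)
        for start in np.flatnonzero(supra):
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            members = []
            while stack:
                u = stack.pop()
                members.append(int(u))
                for v in neigh[u]:
                    if supra[v] and not seen[v]:
                        seen[v] = True
                        stack.append(v)
            out.append((members, float(t[members].sum())))
    return out


def _max_mass(t: np.ndarray, threshold: float, neigh: list[np.ndarray]) -> float:
    clusters = _clusters_from_t(t, threshold, neigh)
    return max((abs(m) for _, m in clusters), default=0.0)


def cluster_permutation_test(a: np.ndarray, b: np.ndarray, nb: NeighborGraph,
                             paired: bool = True, n_perm: int = 1000,
                             alpha: float = 0.05, seed: int = 0) -> ClusterTestResult:
    """Compare per-unit electrode maps ``a`` vs ``b`` (units x electrodes)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n_elec = a.shape[1]
    if b.shape[1] != n_elec:
        raise ValueError("electrode counts differ")
    if nb.adjacency.shape[0] != n_elec:
        raise ValueError("neighbor graph does not match electrode count")
    if not nb.adjacency.any():
        raise ValueError("empty neighbor graph")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired test requires equal unit counts")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    neigh = [np.flatnonzero(nb.adjacency[i]) for i in range(n_elec)]
    rng = np.random.default_rng(seed)

    if paired:
        diffs = a - b
        n = diffs.shape[0]
        df = n - 1
        threshold = float(sps.t.ppf(1 - alpha / 2, df))
        t_obs = _paired_t(diffs)
        # vectorized sign-flip null: sum of squares is flip-invariant
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        means = signs @ diffs / n
        ss = (diffs ** 2).sum(axis=0)
        sd = np.sqrt(np.maximum(ss - n * means ** 2, 0.0) / df)
        t_null = means / (sd / np.sqrt(n) + 1e-300)
    else:
        na = a.shape[0]
        pooled = np.vstack([a, b])
        df = pooled.shape[0] - 2
        threshold = float(sps.t.ppf(1 - alpha / 2, df))
        t_obs = _independent_t(a, b)
        t_null = np.empty((n_perm, n_elec))
        for p in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t_null[p] = _independent_t(pooled[perm[:na]], pooled[perm[na:]])

    observed = _clusters_from_t(t_obs, threshold, neigh)
    null_max = np.array([_max_mass(t_null[p], threshold, neigh)
                         for p in range(n_perm)])
    clusters = []
    for members, mass in observed:
        r = int((null_max >= abs(mass)).sum())
        clusters.append(Cluster(members, mass, (r + 1) / (n_perm + 1)))
    clusters.sort(key=lambda c: c.p)
    return ClusterTestResult(t_obs, clusters, n_perm,
                             "dependent" if paired else "independent",
                             alpha, threshold, tuple(nb.channel_names))
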