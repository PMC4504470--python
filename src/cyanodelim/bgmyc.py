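"""Multitree GMYC sampling and the co-assignment consensus partition.

Running the single-threshold GMYC over a posterior sample of trees with
a Metropolis-Hastings sampler yields a cloud of delimitations.  Their
pairwise co-assignment frequencies form a probability matrix P; the
consensus partition is obtained by k-medoids (PAM) clustering of the
dissimilarity correlate D = 1 - P, with the cluster count chosen by the
optimum average silhouette width.

Sampler priors (weakly informative): threshold index uniform over
internodes, log-rates uniform on [-10, 10], exponents uniform on [0, 3].
Proposals: Gaussian steps (sd 0.3) on log-rates and exponents; on the
threshold index a +/-1 step mixed with an occasional uniform jump so
chains can cross likelihood valleys between threshold modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import CyanodelimError, TreeSample, UltrametricTree
from .gmyc import (LOG_RATE_BOUNDS, P_BOUNDS, candidate_thresholds,
                   interval_decomposition, model_loglik)

__all__ = [
    "PartitionSample",
    "CoassignmentMatrix",
    "ConsensusResult",
    "sample_partitions",
    "coassignment_matrix",
    "pam_cluster",
    "silhouette_width",
    "consensus_partition",
]


@dataclass
class PartitionSample:
    """Sampled delimitations: an (S, n) label array over a fixed tip order."""

    labels: np.ndarray          # (S, n) integer entity labels per sample
    tip_labels: list[str]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2 or self.labels.shape[1] != len(self.tip_labels):
            raise CyanodelimError("labels must be (n_samples, n_tips)")
        if self.labels.shape[0] == 0:
            raise CyanodelimError("empty partition sample")

    def __len__(self) -> int:
        return self.labels.shape[0]


@dataclass
class CoassignmentMatrix:
    """P[i, j] = fraction of sampled partitions placing tips i and j together."""

    P: np.ndarray
    tip_labels: list[str]

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if not np.allclose(P, P.T):
            raise CyanodelimError("co-assignment matrix must be symmetric")
        if not np.allclose(np.diag(P), 1.0):
            raise CyanodelimError("co-assignment diagonal must be 1")
        if P.min() < 0 or P.max() > 1 + 1e-12:
            raise CyanodelimError("co-assignment entries must lie in [0, 1]")
        self.P = P

    def dissimilarity(self) -> np.ndarray:
        D = 1.0 - self.P
        np.fill_diagonal(D, 0.0)
        return D

    def heatmap_order(self, partition: np.ndarray) -> np.ndarray:
        """Tip order grouping consensus blocks for heatmap-style output."""
        return np.argsort(partition, kind="stable")


def _precompute_tables(tree: UltrametricTree):
    cands = candidate_thresholds(tree)
    tables, labels = [], []
    n = tree.n_tips
    for T in cands:
        tab = interval_decomposition(tree, float(T))
        lab = np.empty(n, dtype=int)
        for ent, tips in enumerate(tab.entities):
            lab[tips] = ent
        tables.append(tab)
        labels.append(lab)
    return tables, labels


def sample_partitions(trees: TreeSample, n_trees: int = 100,
                      chain_length: int = 50_000, burnin: int = 40_000,
                      thin: int = 100, seed: int = 0,
                      proposal_sd: float = 0.3) -> PartitionSample:
    """MH sampling of single-threshold GMYC delimitations over many trees.

    ``n_trees`` trees are drawn uniformly at random (without replacement)
    from the sample; per tree a Metropolis-Hastings chain over
    (log-rates, exponents, threshold index) targets the GMYC likelihood
    under the priors above, retaining ``(chain_length - burnin) / thin``
    partitions per tree.
    """
    if n_trees > len(trees):
        raise CyanodelimError("n_trees exceeds the size of the tree sample")
    if chain_length <= burnin:
        raise CyanodelimError("chain_length must exceed burnin")
    rng = np.random.default_rng(seed)
    picked = sorted(rng.choice(len(trees), size=n_trees, replace=False))
    ref_order = trees.tip_labels
    all_labels, prov = [], []
    lo_r, hi_r = LOG_RATE_BOUNDS
    lo_p, hi_p = P_BOUNDS
    n_acc = n_prop = 0
    for tree_idx in picked:
        tree = trees.trees[tree_idx]
        tables, labels = _precompute_tables(tree)
        # map this tree's tip order onto the sample-wide reference order
        remap = np.array([tree.tip_labels.index(lbl) for lbl in ref_order])
        m = len(tables)
        state = np.array([rng.uniform(-2, 2), rng.uniform(-2, 2),
                          rng.uniform(lo_p, hi_p), rng.uniform(lo_p, hi_p)])
        tidx = int(rng.integers(m))

        def loglik(th, ti):
            return model_loglik(tables[ti], np.exp(th[0]), th[2],
                                np.exp(th[1]), th[3])

        cur_ll = loglik(state, tidx)
        bounds = [(lo_r, hi_r), (lo_r, hi_r), (lo_p, hi_p), (lo_p, hi_p)]
        for step in range(1, chain_length + 1):
            # random-scan: one Gaussian step on a single continuous
            # parameter, or a +/-1 step on the threshold index
            comp = int(rng.integers(5))
            n_prop += 1
            if comp < 4:
                prop = state.copy()
                prop[comp] += rng.normal(0.0, proposal_sd)
                lo, hi = bounds[comp]
                if lo <= prop[comp] <= hi:
                    new_ll = loglik(prop, tidx)
                    if np.log(rng.random()) < new_ll - cur_ll:
                        state, cur_ll = prop, new_ll
                        n_acc += 1
            else:
                # mostly +/-1 local steps; an occasional uniform jump lets
                # the chain cross likelihood valleys between threshold modes
                if rng.random() < 0.2:
                    pt = int(rng.integers(m))
                else:
                    pt = tidx + int(rng.choice([-1, 1]))
                if 0 <= pt < m and pt != tidx:
                    new_ll = loglik(state, pt)
                    if np.log(rng.random()) < new_ll - cur_ll:
                        tidx, cur_ll = pt, new_ll
                        n_acc += 1
            if step > burnin and (step - burnin) % thin == 0:
                all_labels.append(labels[tidx][remap])
                prov.append({"tree_index": int(tree_idx), "step": step})
    if not all_labels:
        raise CyanodelimError("zero retained samples; lengthen the chain")
    rate = n_acc / max(n_prop, 1)
    if not 0.05 <= rate <= 0.8:
        warnings.warn(
            f"MH acceptance rate {rate:.2f} outside [0.05, 0.80]; "
            "tune proposal_sd (larger to lower acceptance, smaller to raise it)")
    return PartitionSample(np.array(all_labels), list(ref_order), prov)


def coassignment_matrix(samples: PartitionSample) -> CoassignmentMatrix:
    """Pairwise conspecificity frequencies across sampled partitions."""
    L = samples.labels
    S, n = L.shape
    same = (L[:, :, None] == L[:, None, :])
    P = same.mean(axis=0)
    np.fill_diagonal(P, 1.0)
    return CoassignmentMatrix(P, samples.tip_labels)


# --------------------------------------------------------------------------
# PAM k-medoids and silhouettes
# --------------------------------------------------------------------------


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise CyanodelimError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T):
        raise CyanodelimError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise CyanodelimError("dissimilarity diagonal must be zero")
    if D.min() < 0:
        raise CyanodelimError("dissimilarities must be non-negative")
    return D


def pam_cluster(D: np.ndarray, k: int, seed: int = 0,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning Around Medoids: BUILD then SWAP to a local optimum.

    Deterministic given D: candidate scans run in index order and ties
    break toward the lowest index (the seed argument is accepted for
    interface symmetry but the algorithm draws nothing from it).
    Returns (labels, medoid indices); the objective sum_i D[i, medoid(i)]
    is non-increasing across SWAP steps.
    """
    D = _check_dissimilarity(D)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise CyanodelimError(f"k={k} outside [1, {n}]")
    medoids: list[int] = []
    # BUILD: greedily add the medoid giving the largest cost reduction
    dmin = np.full(n, np.inf)
    for _ in range(k):
        costs = np.minimum(dmin[None, :], D).sum(axis=1)
        best = int(np.argmin(costs))  # argmin takes the lowest index on ties
        medoids.append(best)
        dmin = np.minimum(dmin, D[best])
    medoids = sorted(set(medoids))
    while len(medoids) < k:  # duplicate guard for degenerate D
        extra = [i for i in range(n) if i not in medoids]
        medoids.append(extra[0])
        medoids = sorted(medoids)

    def objective(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    cur = objective(medoids)
    improved = True
    while improved:
        improved = False
        dmat = D[:, medoids]
        order = np.argsort(dmat, axis=1)
        d1 = dmat[np.arange(n), order[:, 0]]
        d2 = dmat[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        nearest = np.array(medoids)[order[:, 0]]
        best_delta, best_swap = -1e-12, None
        non_med = [x for x in range(n) if x not in medoids]
        for mi, m_out in enumerate(medoids):
            # distance to nearest medoid excluding m_out
            alt = np.where(nearest == m_out, d2, d1)
            if not non_med:
                continue
            cand = np.minimum(alt[:, None], D[:, non_med])
            deltas = cur - cand.sum(axis=0)
            j = int(np.argmax(deltas))
            if deltas[j] > best_delta + 1e-12:
                best_delta, best_swap = float(deltas[j]), (mi, non_med[j])
        if best_swap is not None and best_delta > 1e-12:
            mi, x_in = best_swap
            medoids[mi] = x_in
            medoids.sort()
            new_cost = objective(medoids)
            assert new_cost <= cur + 1e-9  # SWAP must not increase the objective
            cur = new_cost
            improved = True
    meds = np.array(medoids)
    labels_m = np.argmin(D[:, meds], axis=1)
    return labels_m, meds


def silhouette_width(D: np.ndarray, labels: np.ndarray,
                     ) -> tuple[np.ndarray, float]:
    """Per-point silhouette s(i) = (b - a)/max(a, b); singletons get 0."""
    D = _check_dissimilarity(D)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise CyanodelimError("silhouette undefined for a single cluster")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        size = own.sum()
        if size == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (size - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s, float(s.mean())


@dataclass
class ConsensusResult:
    """Consensus delimitation chosen by the silhouette profile."""

    k: int
    partition: dict[str, int]
    silhouette_profile: dict[int, float]
    medoids: list[str]
    average_silhouette: float
    k1_degenerate: bool = False

    def to_dict(self) -> dict:
        return {"k": self.k, "partition": self.partition,
                "silhouette_profile": {int(k): v for k, v
                                       in self.silhouette_profile.items()},
                "medoids": self.medoids,
                "average_silhouette": self.average_silhouette,
                "k1_degenerate": self.k1_degenerate}


def consensus_partition(P: CoassignmentMatrix, k_max: int = 30,
                        ) -> ConsensusResult:
    """PAM over D = 1 - P for k = 2..k_max; keep the best silhouette.

    Ties in average silhouette break toward the smallest k.  When every
    pair co-assigns with probability >= 0.5 the degenerate one-cluster
    solution is flagged alongside the chosen k.
    """
    n = len(P.tip_labels)
    if n < 3:
        raise CyanodelimError("consensus needs at least 3 tips")
    if k_max < 2:
        raise CyanodelimError("k_max must be >= 2")
    D = P.dissimilarity()
    profile: dict[int, float] = {}
    best = None
    for k in range(2, min(k_max, n - 1) + 1):
        labels, meds = pam_cluster(D, k)
        _, avg = silhouette_width(D, labels)
        profile[k] = avg
        if best is None or avg > best[1] + 1e-12:
            best = (k, avg, labels, meds)
    k, avg, labels, meds = best
    part = {lbl: int(labels[i]) for i, lbl in enumerate(P.tip_labels)}
    return ConsensusResult(k, part, profile,
                           [P.tip_labels[m] for m in meds], avg,
                           k1_degenerate=bool(P.P.min() >= 0.5))
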