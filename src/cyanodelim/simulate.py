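"""Seeded generators for every input the pipeline consumes.

Three generators emulate the statistical structure the analyses assume:

* ultrametric gene trees from a pure-birth species process with
  within-species Kingman coalescents grafted onto the terminal branches,
  plus posterior-like tree samples obtained by re-drawing coalescent
  times and jittering branch lengths;
* alignments evolved along a tree under a single-rate symmetric
  (Jukes-Cantor-style) substitution process, with optional single-column
  indels to exercise gap policies;
* locality x OTU presence/absence tables whose composition is driven by
  a known subset of environmental variables through a logistic
  occurrence model.

Every generator is a pure function of its parameters and seed, and each
dataset ships with a :class:`SyntheticTruth` sufficient to score
downstream recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (Alignment, CommunityMatrix, CyanodelimError, EnvTable,
                      TreeSample, UltrametricTree)

__all__ = [
    "SyntheticTruth",
    "simulate_species_tree_sample",
    "simulate_alignment",
    "simulate_community",
]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    species_partition: dict[str, int] | None = None
    drivers: list[str] | None = None
    effect_sizes: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


class _N:
    __slots__ = ("children", "height", "label", "_new_height")

    def __init__(self, label=None):
        self.children: list["_N"] = []
        self.height = 0.0
        self.label = label


def _to_newick(node: _N, parent_height: float | None = None) -> str:
    if node.children:
        inner = ",".join(_to_newick(c, node.height) for c in node.children)
        s = f"({inner})"
    else:
        s = str(node.label)
    if parent_height is None:
        return s + ";"
    return f"{s}:{parent_height - node.height:.12g}"


def _yule_species_tree(n_species: int, birth_rate: float,
                       rng: np.random.Generator) -> tuple[_N, list[_N]]:
    """Forward pure-birth simulation; returns root and species tip nodes."""
    root = _N()
    lineages = [root]
    t = 0.0
    events = []  # (node, time)
    while len(lineages) < n_species:
        t += rng.exponential(1.0 / (len(lineages) * birth_rate))
        i = int(rng.integers(len(lineages)))
        node = lineages[i]
        a, b = _N(), _N()
        node.children = [a, b]
        events.append((node, t))
        lineages[i] = a
        lineages.append(b)
    t_end = t + rng.exponential(1.0 / (len(lineages) * birth_rate))
    for node, tt in events:
        node.height = t_end - tt
    for lin in lineages:
        lin.height = 0.0
    if n_species == 1:
        root.height = 0.0
    return root, lineages


def _coalescent(labels: list[str], scale: float, rng: np.random.Generator,
                max_height: float | None = None, max_tries: int = 1000) -> _N:
    """Kingman coalescent over ``labels``; pairwise rate 1/scale."""
    for _ in range(max_tries):
        active = [(_make_tip(lbl), 0.0) for lbl in labels]
        t = 0.0
        ok = True
        while len(active) > 1:
            j = len(active)
            t += rng.exponential(scale / (j * (j - 1) / 2.0))
            if max_height is not None and t >= max_height:
                ok = False
                break
            i1, i2 = rng.choice(j, size=2, replace=False)
            a, b = active[i1], active[i2]
            node = _N()
            node.children = [a[0], b[0]]
            node.height = t
            active = [x for k, x in enumerate(active) if k not in (i1, i2)]
            active.append((node, t))
        if ok:
            return active[0][0]
    raise CyanodelimError(
        "could not fit within-species coalescent under the species branch "
        f"after {max_tries} attempts")


def _make_tip(label: str) -> _N:
    n = _N(label)
    return n


def _species_parents(root: _N, tips: list[_N]) -> dict[int, float]:
    """Height of the parent node of each species tip."""
    parent_h = {}
    stack = [root]
    while stack:
        nd = stack.pop()
        for c in nd.children:
            if not c.children:
                parent_h[id(c)] = nd.height
            stack.append(c)
    return parent_h


def simulate_species_tree_sample(
        n_species: int = 5, tips_per_species: int = 6,
        birth_rate: float = 1.0, theta: float = 1.0,
        separation_ratio: float | None = 20.0,
        n_posterior: int = 0, jitter_sd: float = 0.05,
        seed: int = 0) -> tuple[UltrametricTree, TreeSample | None, SyntheticTruth]:
    """Simulate a species tree with grafted within-species coalescents.

    The species tree follows a pure-birth process.  Each species carries a
    neutral coalescent of its tips; when ``separation_ratio`` is given all
    coalescents share one scale, chosen so the expected within-species
    depth equals the shallowest species divergence divided by that ratio
    (``theta`` is used directly when ``separation_ratio`` is None).  A posterior-like sample
    is built by re-drawing coalescent times, multiplying branch lengths by
    lognormal noise with log-sd ``jitter_sd``, and re-ultrametrizing.
    """
    if separation_ratio is not None and separation_ratio <= 1:
        raise ValueError("separation_ratio must exceed 1")
    if min(n_species, tips_per_species, n_posterior + 1) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)

    sp_root, sp_tips = _yule_species_tree(n_species, birth_rate, rng)
    parent_h = _species_parents(sp_root, sp_tips) if n_species > 1 else {}

    def build_gene_tree(r: np.random.Generator) -> _N:
        if n_species == 1:
            labels = [f"sp1_t{j + 1}" for j in range(tips_per_species)]
            return _coalescent(labels, theta, r)
        root = _clone_internal(sp_root)
        # walk both trees in parallel, replacing species tips
        mapping = {id(sp_root): root}
        stack = [sp_root]
        counter = {"i": 0}
        while stack:
            nd = stack.pop()
            mine = mapping[id(nd)]
            for c in nd.children:
                if c.children:
                    cc = _clone_internal(c)
                    mapping[id(c)] = cc
                    mine.children.append(cc)
                    stack.append(c)
                else:
                    counter["i"] += 1
                    s = counter["i"]
                    labels = [f"sp{s}_t{j + 1}" for j in range(tips_per_species)]
                    if tips_per_species == 1:
                        mine.children.append(_make_tip(labels[0]))
                        continue
                    if separation_ratio is not None:
                        # one global coalescent scale, set by the shallowest
                        # species divergence, so a single threshold separates
                        # all between-species from within-species branching
                        target = min(parent_h.values()) / separation_ratio
                        scale = target / (2.0 * (1.0 - 1.0 / tips_per_species))
                    else:
                        scale = theta
                    sub = _coalescent(labels, scale, r,
                                      max_height=parent_h[id(c)])
                    mine.children.append(sub)
        return root

    true_tree_n = build_gene_tree(rng)
    true_newick = _to_newick(true_tree_n)
    tree = UltrametricTree.from_newick(true_newick)

    sample = None
    if n_posterior > 0:
        posts = []
        for _ in range(n_posterior):
            g = build_gene_tree(rng)
            _jitter_and_ultrametrize(g, jitter_sd, rng)
            posts.append(UltrametricTree.from_newick(_to_newick(g)))
        sample = TreeSample(posts, provenance={"generator": "simulate",
                                               "jitter_sd": jitter_sd})

    partition = {}
    for s in range(1, n_species + 1):
        for j in range(1, tips_per_species + 1):
            partition[f"sp{s}_t{j}"] = s - 1
    truth = SyntheticTruth(seed=seed, params={
        "n_species": n_species, "tips_per_species": tips_per_species,
        "birth_rate": birth_rate, "theta": theta,
        "separation_ratio": separation_ratio, "n_posterior": n_posterior,
        "jitter_sd": jitter_sd}, species_partition=partition)
    return tree, sample, truth


def _clone_internal(nd: _N) -> _N:
    c = _N()
    c.height = nd.height
    return c


def _jitter_and_ultrametrize(root: _N, jitter_sd: float,
                             rng: np.random.Generator) -> None:
    """Multiply branch lengths by lognormal noise, then restore tip-equal depths.

    Re-ultrametrization sets each internal node's height to its mean
    jittered path length to descendant tips, which preserves the local
    depth scale of shallow (within-species) clades instead of dumping the
    ultrametric defect onto terminal branches.
    """
    def assign(nd: _N) -> float:
        if not nd.children:
            return 0.0
        kid_h = [assign(c) for c in nd.children]
        h = nd._new_height
        floor = max(kid_h)
        nd.height = h if h > floor else floor * (1 + 1e-9) + 1e-15
        return nd.height

    # two passes: compute mean path lengths, then enforce monotonicity
    def compute(nd: _N) -> tuple[float, int]:
        if not nd.children:
            return 0.0, 1
        tot, cnt = 0.0, 0
        for c in nd.children:
            bl = nd.height - c.height
            bl *= float(rng.lognormal(0.0, jitter_sd)) if jitter_sd > 0 else 1.0
            sub, k = compute(c)
            tot += (sub + bl) * k
            cnt += k
        nd._new_height = tot / cnt
        return nd._new_height, cnt

    compute(root)
    assign(root)


# --------------------------------------------------------------------------
# Sequence evolution
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_alignment(tree: UltrametricTree, n_sites: int = 582,
                       mut_rate: float = 0.15, indel_rate: float = 0.0,
                       seed: int = 0) -> Alignment:
    """Evolve sequences along ``tree`` under a symmetric one-rate model.

    ``mut_rate`` is the expected number of substitutions per site per unit
    branch length.  With ``indel_rate`` > 0 each column independently
    suffers a single-column deletion event on one random branch (all tips
    below read a gap), exercising gap policies downstream.
    """
    if min(mut_rate, indel_rate) < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    n_nodes = len(tree.parent)
    seqs: dict[int, np.ndarray] = {
        tree.root: rng.integers(0, 4, size=n_sites)}
    order = [tree.root]
    i = 0
    while i < len(order):
        nd = order[i]
        i += 1
        for c in tree.children[nd]:
            h_c = tree.height[c] if c >= tree.n_tips else 0.0
            bl = tree.height[nd] - h_c
            p_diff = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * mut_rate * bl))
            child = seqs[nd].copy()
            hit = rng.random(n_sites) < p_diff
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                child[hit] = (child[hit] + shift) % 4
            seqs[c] = child
            order.append(c)
    mat = np.array([_BASES[seqs[t]] for t in range(tree.n_tips)], dtype="U1")
    if indel_rate > 0:
        non_root = [nd for nd in range(n_nodes) if nd != tree.root]
        for col in range(n_sites):
            if rng.random() < indel_rate:
                branch = non_root[int(rng.integers(len(non_root)))]
                for t in tree.tips_below(branch):
                    mat[t, col] = "-"
    return Alignment(list(tree.tip_labels), ["".join(row) for row in mat])


# --------------------------------------------------------------------------
# Communities and environments
# --------------------------------------------------------------------------


def simulate_community(n_localities: int = 30, otu_pool: int = 20,
                       n_env_vars: int = 10,
                       driver_vars: tuple[int, ...] = (0, 1),
                       effect_size: float = 2.0, noise_sd: float = 0.5,
                       env_corr: float = 0.25, seed: int = 0,
                       ) -> tuple[CommunityMatrix, EnvTable, SyntheticTruth]:
    """Locality x OTU presences driven by a known subset of env variables.

    Environmental variables are equi-correlated Gaussians (pairwise
    correlation ``env_corr``); each OTU occurs with probability
    ``logistic(alpha_o + sum_d beta_od * z_d + eps)`` where the beta are
    nonzero only on the driver variables and scale with ``effect_size``.
    All-absent or all-present OTU columns are resampled.
    """
    if not all(0 <= d < n_env_vars for d in driver_vars):
        raise ValueError("driver_vars must index the environmental variables")
    rng = np.random.default_rng(seed)
    var_names = [f"env{v + 1}" for v in range(n_env_vars)]
    loc_names = [f"L{i + 1:02d}" for i in range(n_localities)]

    common = rng.normal(size=(n_localities, 1))
    z = (np.sqrt(env_corr) * common
         + np.sqrt(1.0 - env_corr) * rng.normal(size=(n_localities, n_env_vars)))

    beta = np.zeros((otu_pool, n_env_vars))
    signs = rng.choice([-1.0, 1.0], size=(otu_pool, len(driver_vars)))
    mags = np.abs(rng.normal(loc=1.0, scale=0.3,
                             size=(otu_pool, len(driver_vars))))
    for j, d in enumerate(driver_vars):
        beta[:, d] = effect_size * signs[:, j] * mags[:, j]
    alpha = rng.normal(scale=0.5, size=otu_pool)

    def draw(col: int) -> np.ndarray:
        eta = alpha[col] + z @ beta[col] + rng.normal(scale=noise_sd,
                                                      size=n_localities)
        return (rng.random(n_localities) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    occ = np.zeros((n_localities, otu_pool), dtype=int)
    for o in range(otu_pool):
        col = draw(o)
        tries = 0
        while col.sum() in (0, n_localities):
            tries += 1
            if tries > 200:
                raise CyanodelimError("degenerate OTU column kept resampling")
            col = draw(o)
        occ[:, o] = col

    cm = CommunityMatrix(pd.DataFrame(
        occ, index=pd.Index(loc_names, name="locality"),
        columns=[f"OTU{o + 1}" for o in range(otu_pool)]))
    env = EnvTable(pd.DataFrame(
        z, index=pd.Index(loc_names, name="locality"), columns=var_names))
    truth = SyntheticTruth(seed=seed, params={
        "n_localities": n_localities, "otu_pool": otu_pool,
        "n_env_vars": n_env_vars, "effect_size": effect_size,
        "noise_sd": noise_sd, "env_corr": env_corr},
        drivers=[var_names[d] for d in driver_vars],
        effect_sizes={var_names[d]: effect_size for d in driver_vars})
    return cm, env, truth
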