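"""Statistical-parsimony haplotype networks.

Haplotypes are connected in increasing order of mutational steps
(Hamming distance over a five-state alphabet when gaps are read as an
informative character) up to a connection limit: the largest step count
for which a parsimonious connection still holds with the requested
probability.  Pairs above the limit stay in separate subnetworks;
connections longer than one step pass through inferred intermediate
node chains.

Connection-limit estimator
--------------------------
The default estimator models per-site substitution counts as Poisson
under a symmetric (Jukes-Cantor-style) process: given two sequences of
length m differing at j sites, the per-site divergence theta is set by
moment matching (the JC correction of j/m) and the probability of
parsimony is the posterior probability that every differing site was
hit exactly once and every identical site never,

    P_j = [P(K=1)/P(diff)]^j * [P(K=0)/P(same)]^(m-j)

with P(diff) = theta*e^-theta + (1 - e^-theta - theta*e^-theta) * 3/4.
P_j decreases in j and the implied limit grows with m.  The estimator
is pluggable and a fixed limit can be supplied for bit-reproducible
runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CyanodelimError
from .popgen import IUPAC, HaplotypeTable

__all__ = [
    "StepMatrix",
    "ParsimonyNetwork",
    "pairwise_steps",
    "parsimony_probability",
    "connection_limit",
    "build_network",
]


@dataclass
class StepMatrix:
    """Integer mutational steps between aligned haplotypes."""

    steps: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        S = np.asarray(self.steps)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise CyanodelimError("step matrix must be square")
        if (S != S.T).any() or np.diag(S).any():
            raise CyanodelimError("step matrix must be symmetric, zero diagonal")
        self.steps = S.astype(int)


def _site_steps(a: str, b: str, gap_as_fifth: bool) -> int | None:
    """Steps at one column; None means the column is skipped."""
    if a == b:
        return 0
    ga, gb = a in "-.", b in "-."
    if ga or gb:
        if not gap_as_fifth:
            return None
        return 0 if (ga and gb) else 1
    return 0 if (IUPAC[a] & IUPAC[b]) else 1


def pairwise_steps(haps: HaplotypeTable, gap_as_fifth: bool = True) -> StepMatrix:
    """Column-wise step counts between haplotype representative sequences.

    With ``gap_as_fifth`` a gap is one more character state (gap vs base
    is one step); without it any column containing a gap is ignored.
    Ambiguity codes count as a mismatch unless compatible.
    """
    seqs = haps.representatives
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise CyanodelimError("haplotype representatives are not aligned")
    if not gap_as_fifth:
        keep = [i for i in range(lengths.pop())
                if all(s[i] not in "-." for s in seqs)]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    n = len(seqs)
    S = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = 0
            for a, b in zip(seqs[i], seqs[j]):
                step = _site_steps(a, b, gap_as_fifth)
                if step:
                    d += step
            S[i, j] = S[j, i] = d
    return StepMatrix(S, list(haps.names))


def parsimony_probability(seq_len: int, j: int) -> float:
    """Probability that a j-step connection over seq_len sites is parsimonious."""
    if j <= 0:
        return 1.0
    m = seq_len
    if j >= 0.75 * m:
        return 0.0
    theta = -0.75 * math.log1p(-4.0 * j / (3.0 * m))
    p0 = math.exp(-theta)
    p1 = theta * p0
    p_multi = max(1.0 - p0 - p1, 0.0)
    p_diff = p1 + 0.75 * p_multi
    p_same = p0 + 0.25 * p_multi
    return ((p1 / p_diff) ** j) * ((p0 / p_same) ** (m - j))


def connection_limit(seq_len: int, prob: float = 0.95,
                     estimator=parsimony_probability) -> int:
    """Largest step count whose probability of parsimony is >= prob.

    Non-increasing in ``prob`` and non-decreasing in ``seq_len``.  Pass a
    different ``estimator(seq_len, j)`` to swap the probability model.
    """
    if seq_len < 1:
        raise CyanodelimError("seq_len must be >= 1")
    if not 0 < prob < 1:
        raise CyanodelimError("prob must lie in (0, 1)")
    j = 0
    while estimator(seq_len, j + 1) >= prob:
        j += 1
        if j > 3 * seq_len:  # safety under a degenerate estimator
            break
    return max(j, 1)


@dataclass
class ParsimonyNetwork:
    """Observed haplotypes, inferred intermediates and their connections.

    ``graph`` holds elementary (single-step) edges; a connection of d
    steps passes through d-1 inferred intermediate nodes.  ``connections``
    records each haplotype-to-haplotype join with its step count,
    subnetwork id and the ambiguous flag for alternative equal-length
    connections that close loops.
    """

    graph: nx.Graph
    connections: pd.DataFrame
    subnetworks: dict[str, int]
    limit: int

    @property
    def n_subnetworks(self) -> int:
        return len(set(self.subnetworks.values()))

    def to_dict(self) -> dict:
        return {"limit": self.limit,
                "n_subnetworks": self.n_subnetworks,
                "subnetworks": self.subnetworks,
                "connections": self.connections.to_dict(orient="records")}


def build_network(steps: StepMatrix, limit: int,
                  counts: dict[str, int] | None = None,
                  annotations: dict[str, dict] | None = None,
                  ) -> ParsimonyNetwork:
    """Agglomerative statistical-parsimony construction.

    Haplotype pairs are processed in increasing step order; a pair at or
    below the limit joins its two components through a chain of inferred
    intermediates.  Within one distance tier every pair bridging
    components that were distinct at the start of the tier is recorded,
    so equal-length alternative connections are kept (flagged ambiguous
    when they close a loop).  Components are never joined above the
    limit.
    """
    if steps.steps.shape[0] == 0:
        raise CyanodelimError("empty step matrix")
    if limit < 1:
        raise CyanodelimError("limit must be >= 1")
    n = steps.steps.shape[0]
    names = steps.names
    counts = counts or {}
    annotations = annotations or {}
    G = nx.Graph()
    for name in names:
        G.add_node(name, inferred=False, count=int(counts.get(name, 1)),
                   **{k: str(v) for k, v in annotations.get(name, {}).items()})

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = sorted(((int(steps.steps[i, j]), i, j)
                    for i in range(n) for j in range(i + 1, n)))
    records = []
    inferred_counter = 0
    idx = 0
    while idx < len(pairs):
        d = pairs[idx][0]
        tier = []
        while idx < len(pairs) and pairs[idx][0] == d:
            tier.append(pairs[idx])
            idx += 1
        if d > limit:
            break
        snapshot = {i: find(i) for i in range(n)}
        for d0, i, j in tier:
            if snapshot[i] == snapshot[j]:
                continue
            ambiguous = find(i) == find(j)  # already merged within this tier
            prev = names[i]
            for _ in range(d0 - 1):
                inferred_counter += 1
                mid = f"i{inferred_counter}"
                G.add_node(mid, inferred=True, count=0)
                G.add_edge(prev, mid, steps=1)
                prev = mid
            G.add_edge(prev, names[j], steps=1)
            records.append({"from": names[i], "to": names[j], "steps": d0,
                            "ambiguous": ambiguous})
            parent[find(i)] = find(j)

    comp_of = {}
    for sub_id, comp in enumerate(sorted(nx.connected_components(G),
                                         key=lambda c: sorted(c)[0])):
        for node in comp:
            comp_of[node] = sub_id
            G.nodes[node]["subnetwork"] = sub_id
    for rec in records:
        rec["subnetwork"] = comp_of[rec["from"]]
    nx.set_edge_attributes(
        G, {e: comp_of[e[0]] for e in G.edges}, "subnetwork")
    conn = pd.DataFrame(records, columns=["from", "to", "steps",
                                          "ambiguous", "subnetwork"])
    subnet = {name: comp_of[name] for name in names}
    return ParsimonyNetwork(G, conn, subnet, limit)
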