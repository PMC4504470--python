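"""Readers, writers and shared domain types.

The pipeline touches five kinds of input: FASTA alignments, posterior
samples of ultrametric trees (NEXUS with translate tables, or plain
Newick), locality x unit community tables, locality x variable
environmental tables, and haplotype networks (written as GraphML plus a
TSV edge list).  Everything downstream consumes the light-weight
containers defined here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("cyanodelim")

__all__ = [
    "CyanodelimError",
    "FormatError",
    "Alignment",
    "UltrametricTree",
    "TreeSample",
    "CommunityMatrix",
    "EnvTable",
    "read_alignment",
    "write_alignment",
    "read_tree_sample",
    "read_community_table",
    "read_env_table",
    "write_network",
    "read_network_edges",
    "write_json",
    "setup_logging",
]


class CyanodelimError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CyanodelimError):
    """An input file violates its format contract."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# --------------------------------------------------------------------------
# Alignments
# --------------------------------------------------------------------------

_VALID_CHARS = set("ACGTUNRYSWKMBDHV-.?")


@dataclass
class Alignment:
    """An aligned set of sequences.

    ids are unique, sequences are upper-case equal-length strings over the
    IUPAC alphabet plus the gap character.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise FormatError("ids and seqs differ in length")
        if not self.ids:
            raise FormatError("empty alignment")
        seen = set()
        for sid in self.ids:
            if sid in seen:
                raise FormatError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
        self.seqs = [s.upper() for s in self.seqs]
        length = len(self.seqs[0])
        if length == 0:
            raise FormatError("zero-length alignment")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != length:
                raise FormatError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(s)}, expected {length}")
            bad = set(s) - _VALID_CHARS
            if bad:
                raise FormatError(f"invalid characters {sorted(bad)} in {sid!r}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n, length) array of single characters."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def subset(self, ids: list[str]) -> "Alignment":
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [sid for sid in ids if sid not in index]
        if missing:
            raise FormatError(f"unknown sequence ids {missing}")
        return Alignment(list(ids), [self.seqs[index[sid]] for sid in ids])


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment; sequences are upper-cased, order preserved."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


# --------------------------------------------------------------------------
# Ultrametric trees
# --------------------------------------------------------------------------


class UltrametricTree:
    """A rooted binary ultrametric tree with node heights above the tips.

    Node heights follow the time-before-present convention: tips sit at
    height 0 and the root at the tree height, so delimitation thresholds
    are times before present.

    Internal layout: nodes are integers 0..2n-2 with tips 0..n-1 in tip
    label order of the source tree; ``parent[root] == -1``; ``children``
    lists are pairs for internal nodes and empty for tips.
    """

    def __init__(self, parent: np.ndarray, children: list[list[int]],
                 height: np.ndarray, tip_labels: list[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.children = children
        self.height = np.asarray(height, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(tip_labels)
        roots = np.nonzero(self.parent < 0)[0]
        if len(roots) != 1:
            raise FormatError("tree must have exactly one root")
        self.root = int(roots[0])
        self._tips_below: list[list[int]] | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, ultra_rtol: float = 1e-6,
                      index: int | None = None) -> "UltrametricTree":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        n = len(leaves)
        if n < 2:
            raise FormatError("tree needs at least 2 tips")
        labels = []
        for lf in leaves:
            if lf.taxon is None or lf.taxon.label is None:
                raise FormatError("unlabelled tip in tree")
            labels.append(str(lf.taxon.label).replace(" ", "_"))
        if len(set(labels)) != n:
            raise FormatError("duplicate tip labels in tree")

        # depth of each node from the root
        depth: dict[dendropy.Node, float] = {}
        nodes = list(tree.preorder_node_iter())
        for nd in nodes:
            if nd.parent_node is None:
                depth[nd] = 0.0
            else:
                bl = nd.edge.length if nd.edge.length is not None else 0.0
                depth[nd] = depth[nd.parent_node] + float(bl)
        tip_depths = np.array([depth[lf] for lf in leaves])
        h = float(tip_depths.max())
        if h <= 0:
            raise FormatError("tree has zero height")
        spread = (tip_depths.max() - tip_depths.min()) / h
        if spread > ultra_rtol:
            where = f" (tree index {index})" if index is not None else ""
            raise FormatError(
                f"tree is not ultrametric{where}: relative tip-depth spread "
                f"{spread:.3g} exceeds tolerance {ultra_rtol:.3g}")

        order = sorted(range(n), key=lambda i: labels[i])
        idx_of: dict[dendropy.Node, int] = {}
        for new_i, old_i in enumerate(order):
            idx_of[leaves[old_i]] = new_i
        internals = [nd for nd in nodes if not nd.is_leaf()]
        for j, nd in enumerate(internals):
            idx_of[nd] = n + j
            if len(nd.child_nodes()) != 2:
                raise FormatError("tree must be strictly bifurcating")
        total = n + len(internals)
        parent = np.full(total, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(total)]
        height = np.zeros(total)
        for nd in nodes:
            i = idx_of[nd]
            if nd.parent_node is not None:
                parent[i] = idx_of[nd.parent_node]
                children[idx_of[nd.parent_node]].append(i)
            if not nd.is_leaf():
                height[i] = h - depth[nd]
                if height[i] <= 0:
                    raise FormatError("internal node height must be positive")
        return cls(parent, children,
                   height, [labels[i] for i in order])

    @classmethod
    def from_newick(cls, newick: str, ultra_rtol: float = 1e-6) -> "UltrametricTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree, ultra_rtol=ultra_rtol)

    # -- queries -----------------------------------------------------------

    @property
    def tree_height(self) -> float:
        return float(self.height[self.root])

    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, len(self.parent))

    def internal_heights(self) -> np.ndarray:
        """Heights of internal nodes, ascending."""
        return np.sort(self.height[self.n_tips:])

    def tips_below(self, node: int) -> list[int]:
        if self._tips_below is None:
            below: list[list[int]] = [[] for _ in range(len(self.parent))]
            # children always have higher index than parents is NOT
            # guaranteed; do an explicit postorder
            stack = [(self.root, False)]
            while stack:
                nd, done = stack.pop()
                if nd < self.n_tips:
                    below[nd] = [nd]
                    continue
                if done:
                    below[nd] = below[self.children[nd][0]] + \
                        below[self.children[nd][1]]
                else:
                    stack.append((nd, True))
                    stack.extend((c, False) for c in self.children[nd])
            self._tips_below = below
        return self._tips_below[node]

    def to_newick(self) -> str:
        def rec(nd: int) -> str:
            if nd < self.n_tips:
                return self.tip_labels[nd]
            a, b = self.children[nd]
            ha = self.height[a] if a >= self.n_tips else 0.0
            hb = self.height[b] if b >= self.n_tips else 0.0
            return (f"({rec(a)}:{self.height[nd] - ha:.10g},"
                    f"{rec(b)}:{self.height[nd] - hb:.10g})")
        return rec(self.root) + ";"


@dataclass
class TreeSample:
    """An ordered posterior-like sample of ultrametric trees on one tip set."""

    trees: list[UltrametricTree]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trees:
            raise FormatError("empty tree sample")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees):
            if set(t.tip_labels) != ref:
                raise FormatError(f"tree {i} has a mismatched tip set")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


def retained_count(n: int, burnin_frac: float, thin: int) -> int:
    """Number of trees kept: drop floor(b*n), then every thin-th of the rest."""
    kept = n - math.floor(burnin_frac * n)
    return math.ceil(kept / thin)


def read_tree_sample(path: str | Path, burnin_frac: float = 0.0,
                     thin: int = 1, ultra_rtol: float = 1e-6) -> TreeSample:
    """Read a multi-tree NEXUS/Newick file, apply burn-in and thinning.

    NEXUS translate tables and ``tree STATE_x =`` labels (the posterior
    sample convention) are resolved by the reader; square-bracket comments
    are ignored.
    """
    path = Path(path)
    if not (0 <= burnin_frac < 1):
        raise ValueError("burnin_frac must be in [0, 1)")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    with open(path) as fh:
        head = fh.read(64).lstrip()
    schema = "nexus" if head.upper().startswith("#NEXUS") else "newick"
    tl = dendropy.TreeList.get(path=str(path), schema=schema)
    if not len(tl):
        raise FormatError(f"no trees in {path}")
    start = math.floor(burnin_frac * len(tl))
    kept = list(tl)[start::thin]
    trees = [UltrametricTree.from_dendropy(t, ultra_rtol=ultra_rtol, index=i)
             for i, t in enumerate(kept)]
    return TreeSample(trees, provenance={
        "path": str(path), "n_read": len(tl),
        "burnin_frac": burnin_frac, "thin": thin})


# --------------------------------------------------------------------------
# Community and environment tables
# --------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Localities x units (OTUs or haplotypes), presence/absence or counts."""

    data: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise FormatError("community matrix entries must be non-negative")

    @property
    def localities(self) -> list[str]:
        return list(self.data.index)

    def presence_absence(self) -> "CommunityMatrix":
        return CommunityMatrix((self.data > 0).astype(int), self.meta)

    def drop_empty(self) -> "CommunityMatrix":
        keep = self.data.sum(axis=1) > 0
        meta = self.meta.loc[keep] if self.meta is not None else None
        return CommunityMatrix(self.data.loc[keep], meta)


@dataclass
class EnvTable:
    """Localities x numeric environmental variables plus optional substrate."""

    data: pd.DataFrame
    substrate: pd.Series | None = None
    normalized: bool = False


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _numeric_or_raise(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = out.index[bad][0]
            raise FormatError(
                f"non-numeric value {out.loc[row, col]!r} in column "
                f"{col!r}, row {row!r}")
        out[col] = coerced
    return out


def read_community_table(path: str | Path, locality_col: str = "locality",
                         meta_cols: tuple[str, ...] = ("region", "species"),
                         ) -> CommunityMatrix:
    df = _read_table(path)
    if locality_col not in df.columns:
        raise FormatError(f"missing locality column {locality_col!r}")
    df = df.set_index(locality_col)
    meta = df[[c for c in meta_cols if c in df.columns]]
    units = [c for c in df.columns if c not in meta.columns]
    df = _numeric_or_raise(df, units)
    return CommunityMatrix(df[units], meta if len(meta.columns) else None)


def read_env_table(path: str | Path, locality_col: str = "locality",
                   substrate_col: str = "substrate") -> EnvTable:
    df = _read_table(path)
    if locality_col not in df.columns:
        raise FormatError(f"missing locality column {locality_col!r}")
    df = df.set_index(locality_col)
    substrate = None
    if substrate_col in df.columns:
        substrate = df[substrate_col].astype(str)
        df = df.drop(columns=[substrate_col])
    df = _numeric_or_raise(df, list(df.columns))
    return EnvTable(df, substrate)


def check_paired(cm: CommunityMatrix, env: EnvTable) -> None:
    """Require identical locality indices in a paired table set."""
    a, b = list(cm.data.index), list(env.data.index)
    if set(a) != set(b):
        missing = set(a) ^ set(b)
        raise FormatError(f"locality mismatch between paired tables: {sorted(missing)}")


# --------------------------------------------------------------------------
# Networks and JSON results
# --------------------------------------------------------------------------


def write_network(net, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a ParsimonyNetwork as GraphML plus a TSV edge list.

    Nodes carry haplotype id, sample count and the inferred/observed flag;
    edges carry step counts and subnetwork ids.  The TSV round-trips
    losslessly through :func:`read_network_edges`.
    """
    path_prefix = Path(path_prefix)
    gml = path_prefix.with_suffix(".graphml")
    tsv = path_prefix.with_suffix(".edges.tsv")
    nx.write_graphml(net.graph, gml)
    net.connections.to_csv(tsv, sep="\t", index=False)
    return gml, tsv


def read_network_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    """Serialize a result object (anything exposing to_dict) to JSON."""
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserializable {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
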