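"""Haplotype collapsing and per-group genetic diversity statistics.

Implements the classical sequence-diversity estimators: segregating
sites S, haplotype diversity Hd with its sampling standard deviation,
and per-site nucleotide diversity pi.  The default site-deletion policy
is complete deletion (columns containing a gap or ambiguity are dropped
for S and pi); haplotype identity is taken over the full aligned
sequence, gaps included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Alignment, CyanodelimError

__all__ = [
    "IUPAC",
    "HaplotypeTable",
    "DiversityStats",
    "collapse_haplotypes",
    "segregating_sites",
    "haplotype_diversity",
    "nucleotide_diversity",
    "diversity_table",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"), "?": frozenset("ACGT-"),
    "-": frozenset("-"), ".": frozenset("-"),
}

_UNAMBIGUOUS = set("ACGT-")


@dataclass
class HaplotypeTable:
    """Unique haplotypes with their members and per-group frequencies."""

    representatives: list[str]      # one aligned sequence per haplotype
    members: list[list[str]]        # sequence ids per haplotype
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.representatives) != len(self.members):
            raise CyanodelimError("representatives/members length mismatch")
        if not self.names:
            self.names = [f"H{i + 1}" for i in range(len(self.members))]

    @property
    def n_haplotypes(self) -> int:
        return len(self.representatives)

    @property
    def n_sequences(self) -> int:
        return sum(len(m) for m in self.members)

    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])

    def frequencies(self) -> np.ndarray:
        c = self.counts()
        return c / c.sum()

    def assignment(self) -> dict[str, str]:
        return {sid: self.names[h]
                for h, mem in enumerate(self.members) for sid in mem}


def _compatible(a: str, b: str) -> bool:
    return bool(IUPAC[a] & IUPAC[b])


def collapse_haplotypes(aln: Alignment, mode: str = "exact") -> HaplotypeTable:
    """Group identical aligned sequences into haplotypes.

    ``exact`` groups byte-identical sequences (gaps count as characters);
    ``ambiguity-aware`` additionally merges a sequence into a haplotype
    when every site is compatible under IUPAC codes and at least one
    current member of the haplotype is unambiguous.  Haplotypes are
    numbered by first occurrence.
    """
    if mode not in {"exact", "ambiguity-aware"}:
        raise ValueError(f"unknown mode {mode!r}")
    reps: list[str] = []
    members: list[list[str]] = []
    unamb: list[bool] = []
    index: dict[str, int] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        if seq in index:
            members[index[seq]].append(sid)
            continue
        placed = False
        if mode == "ambiguity-aware":
            for h, rep in enumerate(reps):
                if not unamb[h] and not set(seq) <= _UNAMBIGUOUS:
                    continue
                if all(_compatible(x, y) for x, y in zip(seq, rep)):
                    members[h].append(sid)
                    if set(seq) <= _UNAMBIGUOUS and not unamb[h]:
                        reps[h] = seq
                        unamb[h] = True
                    placed = True
                    break
        if not placed:
            index[seq] = len(reps)
            reps.append(seq)
            members.append([sid])
            unamb.append(set(seq) <= _UNAMBIGUOUS)
    return HaplotypeTable(reps, members)


def _retained_columns(mat: np.ndarray, policy: str) -> np.ndarray:
    """Boolean mask of columns kept under the site-deletion policy."""
    is_base = np.isin(mat, list("ACGT"))
    if policy == "complete":
        return is_base.all(axis=0)
    if policy == "pairwise":
        return np.ones(mat.shape[1], dtype=bool)
    raise ValueError(f"unknown deletion policy {policy!r}")


def segregating_sites(aln: Alignment, policy: str = "complete") -> int:
    """Columns with more than one nucleotide among {A,C,G,T}.

    Under complete deletion any column containing a gap or ambiguity is
    excluded; under pairwise deletion gaps/ambiguities are ignored within
    each column.
    """
    mat = aln.matrix()
    keep = _retained_columns(mat, policy)
    S = 0
    for col in np.nonzero(keep)[0]:
        states = set(mat[:, col]) & set("ACGT")
        if len(states) >= 2:
            S += 1
    return S


def haplotype_diversity(counts, n: int | None = None,
                        ) -> tuple[float, float]:
    """Haplotype (gene) diversity and its sampling standard deviation.

    Hd = n/(n-1) * (1 - sum p^2) — the probability that two haplotypes
    drawn without replacement differ.  The variance follows the standard
    estimator
    V = 2/(n(n-1)) * {2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2}.
    ``counts`` may be absolute haplotype counts (n inferred) or
    frequencies (n required).
    """
    counts = np.asarray(counts, dtype=float)
    if n is None:
        n = int(round(counts.sum()))
        p = counts / counts.sum()
    else:
        if not math.isclose(counts.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise CyanodelimError("frequencies must sum to 1")
        p = counts
    if n < 2:
        raise CyanodelimError("haplotype diversity needs n >= 2")
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    hd = n / (n - 1.0) * (1.0 - s2)
    var = (2.0 / (n * (n - 1.0))
           * (2.0 * (n - 2.0) * (s3 - s2 ** 2) + s2 - s2 ** 2))
    return hd, math.sqrt(max(var, 0.0))


def nucleotide_diversity(aln: Alignment, policy: str = "complete") -> float:
    """Average pairwise proportion of differing sites (per-site pi)."""
    if aln.n < 2:
        raise CyanodelimError("nucleotide diversity needs >= 2 sequences")
    mat = aln.matrix()
    if policy == "complete":
        keep = _retained_columns(mat, "complete")
        if not keep.any():
            raise CyanodelimError("no sites retained under complete deletion")
        sub = mat[:, keep]
        total = 0.0
        n = aln.n
        for i in range(n):
            for j in range(i + 1, n):
                total += np.mean(sub[i] != sub[j])
        return total / (n * (n - 1) / 2)
    if policy == "pairwise":
        is_base = np.isin(mat, list("ACGT"))
        total, n = 0.0, aln.n
        for i in range(n):
            for j in range(i + 1, n):
                ok = is_base[i] & is_base[j]
                if not ok.any():
                    raise CyanodelimError(
                        f"no shared retained sites between sequences {i} and {j}")
                total += np.mean(mat[i, ok] != mat[j, ok])
        return total / (n * (n - 1) / 2)
    raise ValueError(f"unknown deletion policy {policy!r}")


@dataclass
class DiversityStats:
    """Per-group diversity summary mirroring a classic Table-1 layout."""

    group: str
    n: int
    n_haplotypes: int
    S: int
    Hd: float
    Hd_sd: float
    pi: float

    def __post_init__(self) -> None:
        if self.n_haplotypes > self.n:
            raise CyanodelimError("more haplotypes than sequences")
        if not 0 <= self.Hd <= 1 + 1e-9:
            raise CyanodelimError("Hd outside [0, 1]")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def diversity_table(aln: Alignment, groups: dict[str, list[str]],
                    min_n: int = 10, policy: str = "complete",
                    ) -> pd.DataFrame:
    """S, Hd +/- SD and pi per group of sequence ids.

    Groups with fewer than ``min_n`` sequences are reported with NaN
    statistics (the default of 10 mirrors the common practice of only
    evaluating groups with more than 9 sequences); lower ``min_n`` to
    override.
    """
    rows = []
    for name, ids in groups.items():
        sub = aln.subset(ids)
        if sub.n < min_n:
            rows.append({"group": name, "Nseq": sub.n, "Nhap": np.nan,
                         "S": np.nan, "Hd": np.nan, "Hd_sd": np.nan,
                         "pi": np.nan, "evaluated": False})
            continue
        haps = collapse_haplotypes(sub)
        hd, sd = haplotype_diversity(haps.counts())
        st = DiversityStats(name, sub.n, haps.n_haplotypes,
                            segregating_sites(sub, policy), hd, sd,
                            nucleotide_diversity(sub, policy))
        rows.append({"group": name, "Nseq": st.n, "Nhap": st.n_haplotypes,
                     "S": st.S, "Hd": st.Hd, "Hd_sd": st.Hd_sd,
                     "pi": st.pi, "evaluated": True})
    return pd.DataFrame(rows).set_index("group")
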