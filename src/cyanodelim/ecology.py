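"""Locality-level composition statistics.

Dissimilarity matrices (Sorensen on presence/absence, Bray-Curtis on
counts, Euclidean on normalized environmental rows), rank-based ANOSIM
with permutation tests, SIMPER decomposition of between-group
dissimilarity, BIO-ENV/BVSTEP matching of environmental variable
subsets to a biotic dissimilarity matrix, and Spearman correlation
between two dissimilarity matrices (RELATE-style).

Permutation p-values use (exceedances + 1) / (n_perm + 1) throughout and
are reproducible under a fixed seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from .core_io import CommunityMatrix, CyanodelimError, EnvTable

__all__ = [
    "DissimilarityMatrix",
    "AnosimResult",
    "BioenvResult",
    "normalize_env",
    "dissimilarity",
    "anosim",
    "simper",
    "bioenv_bvstep",
    "bioenv_exhaustive",
    "matrix_correlation",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    for cut, sym in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < cut:
            return sym
    return "n.s."


# --------------------------------------------------------------------------
# Environment normalization
# --------------------------------------------------------------------------


def normalize_env(env: EnvTable) -> EnvTable:
    """Z-score every variable; substrate expands to indicators first.

    Each numeric column is centred and divided by its sample standard
    deviation; a categorical substrate column becomes one 0/1 indicator
    per level before scaling.  Constant columns are rejected by name.
    """
    df = env.data.copy()
    if env.substrate is not None:
        dummies = pd.get_dummies(env.substrate, prefix="substrate").astype(float)
        df = pd.concat([df, dummies], axis=1)
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        sd = df[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise CyanodelimError(f"constant column {col!r} cannot be normalized")
        out[col] = (df[col] - df[col].mean()) / sd
    return EnvTable(out, substrate=None, normalized=True)


# --------------------------------------------------------------------------
# Dissimilarities
# --------------------------------------------------------------------------

_METRICS = {"sorensen", "braycurtis", "euclidean"}


@dataclass
class DissimilarityMatrix:
    """Symmetric locality dissimilarities with a metric tag."""

    matrix: np.ndarray
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (len(self.ids), len(self.ids)):
            raise CyanodelimError("matrix/ids shape mismatch")
        if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 0.0):
            raise CyanodelimError("dissimilarity must be symmetric, zero diagonal")
        if self.metric in {"sorensen", "braycurtis"} and (
                M.min() < -1e-12 or M.max() > 1 + 1e-12):
            raise CyanodelimError(f"{self.metric} entries must lie in [0, 1]")
        self.matrix = M

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    @property
    def n(self) -> int:
        return len(self.ids)


def dissimilarity(data: CommunityMatrix | EnvTable | pd.DataFrame,
                  metric: str) -> DissimilarityMatrix:
    """Sorensen (presence/absence), Bray-Curtis (counts) or Euclidean rows."""
    if metric not in _METRICS:
        raise CyanodelimError(f"unknown metric {metric!r}")
    if isinstance(data, CommunityMatrix):
        df = data.data
    elif isinstance(data, EnvTable):
        df = data.data
    else:
        df = data
    X = df.to_numpy(dtype=float)
    if metric == "sorensen":
        if not np.isin(X, (0.0, 1.0)).all():
            raise CyanodelimError("sorensen requires presence/absence data")
        zero = X.sum(axis=1) == 0
        if zero.any():
            bad = list(df.index[zero])
            raise CyanodelimError(f"all-zero locality rows under sorensen: {bad}")
        cond = pdist(X.astype(bool), metric="dice")
    elif metric == "braycurtis":
        cond = pdist(X, metric="braycurtis")
    else:
        cond = pdist(X, metric="euclidean")
    return DissimilarityMatrix(squareform(cond), list(df.index), metric)


# --------------------------------------------------------------------------
# ANOSIM
# --------------------------------------------------------------------------


@dataclass
class AnosimResult:
    """Global and pairwise analysis-of-similarities statistics."""

    R: float
    p: float
    n_perm: int
    M: int
    pairwise_R: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None
    groups: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"R": self.R, "p": self.p, "n_perm": self.n_perm, "M": self.M,
             "stars": significance_stars(self.p)}
        if self.pairwise_R is not None:
            d["pairwise_R"] = self.pairwise_R.to_dict()
            d["pairwise_p"] = self.pairwise_p.to_dict()
        return d


def _anosim_stat(rank_sq: np.ndarray, labels: np.ndarray,
                 iu: tuple[np.ndarray, np.ndarray]) -> float:
    within = labels[iu[0]] == labels[iu[1]]
    r = rank_sq[iu]
    M = r.size
    rw = r[within].mean()
    rb = r[~within].mean()
    return float((rb - rw) / (M / 2.0))


def anosim(D: DissimilarityMatrix, groups: dict[str, str] | pd.Series,
           n_perm: int = 10_000, seed: int = 0,
           pairwise: bool = True) -> AnosimResult:
    """Rank-based ANOSIM with a seeded label-permutation test.

    R = (mean between-group rank - mean within-group rank) / (M/2) over
    the M = n(n-1)/2 pairwise dissimilarities (mean ranks on ties).
    Pairwise tests rerun the statistic on each pair of groups; a pair
    involving a single-member group is reported as not computable (NaN).
    """
    labels = np.array([str(dict(groups)[i]) for i in D.ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts >= 2).sum() < 2:
        raise CyanodelimError("global ANOSIM needs >= 2 groups with >= 2 members")
    rng = np.random.default_rng(seed)
    rank_sq = squareform(rankdata(D.condensed()), checks=False)
    iu = np.triu_indices(D.n, k=1)
    R_obs = _anosim_stat(rank_sq, labels, iu)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_stat(rank_sq, perm, iu) >= R_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    M = D.n * (D.n - 1) // 2

    pw_R = pw_p = None
    if pairwise:
        pw_R = pd.DataFrame(np.nan, index=uniq, columns=uniq)
        pw_p = pd.DataFrame(np.nan, index=uniq, columns=uniq)
        for a, b in itertools.combinations(uniq, 2):
            sel = np.isin(labels, [a, b])
            na, nb = (labels == a).sum(), (labels == b).sum()
            if min(na, nb) < 2:
                continue  # printed as a dash in study-style tables
            subD = D.matrix[np.ix_(sel, sel)]
            sub_rank = squareform(rankdata(squareform(subD, checks=False)),
                                  checks=False)
            sub_lab = labels[sel]
            sub_iu = np.triu_indices(sub_lab.size, k=1)
            r_ab = _anosim_stat(sub_rank, sub_lab, sub_iu)
            exc = 0
            for _ in range(n_perm):
                if _anosim_stat(sub_rank, rng.permutation(sub_lab),
                                sub_iu) >= r_ab:
                    exc += 1
            pw_R.loc[a, b] = pw_R.loc[b, a] = r_ab
            pw_p.loc[a, b] = pw_p.loc[b, a] = (exc + 1) / (n_perm + 1)
    return AnosimResult(R_obs, p, n_perm, M, pw_R, pw_p,
                        {i: l for i, l in zip(D.ids, labels)})


# --------------------------------------------------------------------------
# SIMPER
# --------------------------------------------------------------------------


def simper(m: CommunityMatrix, groups: dict[str, str] | pd.Series,
           ) -> pd.DataFrame:
    """Per-unit contributions to average between-group Bray-Curtis dissimilarity.

    For each between-group sample pair the unit-level term
    |x_ik - x_jk| / sum_s(x_is + x_js) is averaged over pairs; percent
    contributions normalize to 100 and units are sorted by contribution.
    Exactly two groups are compared.
    """
    lab = {str(k): str(v) for k, v in dict(groups).items()}
    labels = np.array([lab[i] for i in m.data.index])
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise CyanodelimError("simper compares exactly two groups")
    X = m.data.to_numpy(dtype=float)
    ia = np.nonzero(labels == uniq[0])[0]
    ib = np.nonzero(labels == uniq[1])[0]
    terms = []
    for i in ia:
        for j in ib:
            denom = (X[i] + X[j]).sum()
            if denom == 0:
                continue
            terms.append(np.abs(X[i] - X[j]) / denom)
    if not terms:
        warnings.warn("zero total abundance in every between-group pair")
        return pd.DataFrame(columns=["unit", "average", "percent",
                                     "cumulative"]).set_index("unit")
    avg = np.mean(terms, axis=0)
    total = avg.sum()
    if total == 0:
        warnings.warn("identical communities in both groups; empty SIMPER table")
        return pd.DataFrame(columns=["unit", "average", "percent",
                                     "cumulative"]).set_index("unit")
    out = pd.DataFrame({"unit": m.data.columns, "average": avg,
                        "percent": 100.0 * avg / total})
    out = out.sort_values("percent", ascending=False, kind="stable")
    out["cumulative"] = out["percent"].cumsum()
    return out.set_index("unit")


# --------------------------------------------------------------------------
# BIO-ENV / BVSTEP
# --------------------------------------------------------------------------


@dataclass
class BioenvResult:
    """Best environmental subsets, their rank correlations and frequencies."""

    best_vars: tuple[str, ...]
    best_rho: float
    models: list[dict]
    p_value: float | None = None
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"best_vars": list(self.best_vars), "best_rho": self.best_rho,
                "models": self.models, "p_value": self.p_value,
                "excluded": self.excluded}


def _collinearity_filter(df: pd.DataFrame, cut: float | None,
                         mode: str | None) -> tuple[pd.DataFrame, list[str]]:
    if cut is None or mode is None:
        return df, []
    cols = list(df.columns)
    dropped: list[str] = []
    for a, b in itertools.combinations(cols, 2):
        if a in dropped or b in dropped:
            continue
        va, vb = df[a].to_numpy(), df[b].to_numpy()
        if mode == "distance":
            stat = float(np.linalg.norm(va - vb))
        elif mode == "correlation":
            stat = abs(float(np.corrcoef(va, vb)[0, 1]))
        else:
            raise CyanodelimError(f"unknown collin_mode {mode!r}")
        if stat > cut:
            dropped.append(b)  # keep the earlier variable
    keep = [c for c in cols if c not in dropped]
    return df[keep], dropped


def _subset_rho(env_X: np.ndarray, cols: tuple[int, ...],
                bio_rank: np.ndarray) -> float:
    d = pdist(env_X[:, list(cols)], metric="euclidean")
    rho = spearmanr(rankdata(d), bio_rank).statistic
    return float(rho) if np.isfinite(rho) else -1.0


def _bvstep_once(env_X: np.ndarray, n_vars: int, bio_rank: np.ndarray,
                 rng: np.random.Generator, rho_stop: float,
                 delta_stop: float) -> tuple[tuple[int, ...], float]:
    current = tuple(sorted(np.nonzero(rng.random(n_vars) < 0.5)[0]))
    if not current:
        current = (int(rng.integers(n_vars)),)
    rho = _subset_rho(env_X, current, bio_rank)
    while rho <= rho_stop:
        best_move, best_rho = None, rho
        for v in range(n_vars):  # forward additions
            if v in current:
                continue
            cand = tuple(sorted(current + (v,)))
            r = _subset_rho(env_X, cand, bio_rank)
            if r > best_rho:
                best_move, best_rho = cand, r
        if len(current) > 1:  # backward drops
            for v in current:
                cand = tuple(c for c in current if c != v)
                r = _subset_rho(env_X, cand, bio_rank)
                if r > best_rho:
                    best_move, best_rho = cand, r
        if best_move is None or best_rho - rho < delta_stop:
            break
        current, rho = best_move, best_rho
    return current, rho


def bioenv_bvstep(D_bio: DissimilarityMatrix, env: EnvTable,
                  n_restarts: int = 100, rho_stop: float = 0.95,
                  delta_stop: float = 0.001, collin_cut: float | None = 0.80,
                  collin_mode: str | None = "distance",
                  n_perm: int = 0, seed: int = 0) -> BioenvResult:
    """Stepwise BIO-ENV search (BVSTEP) with model-frequency tallies.

    From a random starting subset per restart, forward-add/backward-drop
    steps maximize the Spearman rank correlation between the Euclidean
    distances of the environmental subset and the biotic dissimilarities,
    stopping once rho exceeds ``rho_stop`` or the improvement falls below
    ``delta_stop``.  Subset frequencies across seeded restarts are
    reported; with ``n_perm`` > 0 the best model's significance is
    assessed by relabeling the biotic matrix and re-searching.

    Collinear variables may be excluded beforehand: the literal rule
    drops the later variable of any pair whose Euclidean column distance
    exceeds ``collin_cut`` (``collin_mode='distance'``); an absolute
    Pearson correlation rule and no filtering are also available.
    """
    if env.normalized is False:
        env = normalize_env(env)
    if list(env.data.index) != list(D_bio.ids):
        raise CyanodelimError("localities of D_bio and env are not aligned")
    df, dropped = _collinearity_filter(env.data, collin_cut, collin_mode)
    if df.shape[1] < 2:
        raise CyanodelimError(
            f"fewer than 2 variables remain after collinearity filtering "
            f"(dropped {dropped})")
    env_X = df.to_numpy(dtype=float)
    names = list(df.columns)
    bio_rank = rankdata(D_bio.condensed())
    rng = np.random.default_rng(seed)

    tallies: dict[tuple[int, ...], list] = {}
    for _ in range(n_restarts):
        subset, rho = _bvstep_once(env_X, len(names), bio_rank, rng,
                                   rho_stop, delta_stop)
        rec = tallies.setdefault(subset, [0, rho])
        rec[0] += 1
        rec[1] = max(rec[1], rho)
    models = [{"vars": tuple(names[v] for v in sub), "rho": rho,
               "frequency": cnt / n_restarts}
              for sub, (cnt, rho) in tallies.items()]
    models.sort(key=lambda m: (-m["rho"], -m["frequency"]))
    best = models[0]

    p_value = None
    if n_perm > 0:
        exceed = 0
        sq = D_bio.matrix
        for _ in range(n_perm):
            perm = rng.permutation(D_bio.n)
            perm_rank = rankdata(squareform(sq[np.ix_(perm, perm)],
                                            checks=False))
            null_best = -np.inf
            for _ in range(max(1, n_restarts // 20)):
                _, r = _bvstep_once(env_X, len(names), perm_rank, rng,
                                    rho_stop, delta_stop)
                null_best = max(null_best, r)
            if null_best >= best["rho"]:
                exceed += 1
        p_value = (exceed + 1) / (n_perm + 1)
    return BioenvResult(best["vars"], best["rho"], models, p_value, dropped)


def bioenv_exhaustive(D_bio: DissimilarityMatrix, env: EnvTable,
                      max_vars: int | None = None) -> BioenvResult:
    """All-subsets BIO-ENV: the exact maximum the stepwise search bounds."""
    if env.normalized is False:
        env = normalize_env(env)
    if list(env.data.index) != list(D_bio.ids):
        raise CyanodelimError("localities of D_bio and env are not aligned")
    env_X = env.data.to_numpy(dtype=float)
    names = list(env.data.columns)
    bio_rank = rankdata(D_bio.condensed())
    max_vars = max_vars or len(names)
    best, models = None, []
    for r in range(1, max_vars + 1):
        for combo in itertools.combinations(range(len(names)), r):
            rho = _subset_rho(env_X, combo, bio_rank)
            if best is None or rho > best[1]:
                best = (combo, rho)
    models.append({"vars": tuple(names[v] for v in best[0]),
                   "rho": best[1], "frequency": 1.0})
    return BioenvResult(models[0]["vars"], best[1], models)


# --------------------------------------------------------------------------
# Matrix rank correlation (RELATE)
# --------------------------------------------------------------------------


def matrix_correlation(D1: DissimilarityMatrix, D2: DissimilarityMatrix,
                       n_perm: int = 999, seed: int = 0,
                       ) -> tuple[float, float]:
    """Spearman correlation of off-diagonal entries with a permutation p.

    The null distribution permutes the locality labels of the second
    matrix; p = (exceedances + 1)/(n_perm + 1), one-sided for positive
    association.
    """
    if list(D1.ids) != list(D2.ids):
        raise CyanodelimError("dissimilarity matrices have mismatched indices")
    rng = np.random.default_rng(seed)
    v1 = D1.condensed()
    rho_obs = float(spearmanr(v1, D2.condensed()).statistic)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(D2.n)
        v2 = squareform(D2.matrix[np.ix_(perm, perm)], checks=False)
        if float(spearmanr(v1, v2).statistic) >= rho_obs:
            exceed += 1
    return rho_obs, (exceed + 1) / (n_perm + 1)
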