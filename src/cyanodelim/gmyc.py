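"""Generalized mixed Yule-coalescent (GMYC) model fitting.

The model assumes that an ultrametric gene tree is the outcome of two
processes separated by one or more threshold times: older branching
events reflect diversification between entities (species-like units),
younger ones reflect coalescence within entities.  Fitting locates the
threshold(s) and rate parameters maximizing the likelihood of the
observed inter-node waiting times, and a likelihood-ratio test compares
the mixed model against a one-process null.

Per-interval hazard, with k lineages in the between-entity class and
n_j lineages within entity j::

    b_i = lambda_div * k_i**p_div + lambda_coal * sum_j (n_ij*(n_ij-1))**p_coal

and the log-likelihood is ``sum_i [e_i*ln(b_i) - b_i*x_i]`` over
inter-node intervals with waiting time ``x_i`` and event count ``e_i``.
A threshold falling inside an internode slab splits it; the tips-side
piece carries exposure but no event.  The null model is the same form
with a single class over all lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_io import CyanodelimError, UltrametricTree

__all__ = [
    "IntervalTable",
    "GMYCFit",
    "LRTResult",
    "interval_decomposition",
    "single_class_table",
    "model_loglik",
    "maximize_loglik",
    "candidate_thresholds",
    "fit_null",
    "fit_single",
    "fit_multiple",
    "likelihood_ratio_test",
]

LOG_RATE_BOUNDS = (-10.0, 10.0)
P_BOUNDS = (0.0, 3.0)
_OPT_TOL = 1e-8


@dataclass
class IntervalTable:
    """Inter-node intervals with per-class lineage counts.

    Intervals are ordered root -> tips.  ``x`` holds waiting times,
    ``k`` the between-entity lineage count, ``coal`` a padded matrix of
    n_ij*(n_ij - 1) factors for the within-entity classes, and
    ``n_events`` the number of nodes terminating each interval (0 for
    the censored piece created by a threshold inside a slab).
    """

    x: np.ndarray
    k: np.ndarray
    coal: np.ndarray
    n_events: np.ndarray
    entities: list[list[int]]

    def __post_init__(self) -> None:
        if np.any(self.x < 0):
            raise CyanodelimError("negative waiting time in interval table")

    @property
    def n_entities(self) -> int:
        return len(self.entities)


def _resolve_thresholds(tree: UltrametricTree, tmap: dict[int, float]) -> np.ndarray:
    """Per-node threshold by inheritance from the nearest mapped ancestor."""
    if tree.root not in tmap:
        raise CyanodelimError("threshold map must include the root")
    t = np.empty(len(tree.parent))
    order = [tree.root]
    seen = 0
    while seen < len(order):
        nd = order[seen]
        seen += 1
        t[nd] = tmap.get(nd, t[tree.parent[nd]] if nd != tree.root else tmap[tree.root])
        order.extend(tree.children[nd])
    return t


def interval_decomposition(tree: UltrametricTree,
                           threshold: float | dict[int, float]) -> IntervalTable:
    """Decompose a tree into intervals under a (possibly clade-local) threshold.

    ``threshold`` is a single time before present, or a map from node ids
    to the threshold applying within their subtree (inherited by
    descendants; must contain the root).  Lineages older than their
    threshold form the diversification class; younger lineages belong to
    the coalescent class of their containing entity, the clade subtended
    at the threshold crossing.
    """
    H = tree.tree_height
    if isinstance(threshold, dict):
        tmap = dict(threshold)
    else:
        if not (0 < threshold < H):
            raise CyanodelimError(
                f"threshold {threshold} outside tree depth (0, {H})")
        tmap = {tree.root: float(threshold)}
    t_node = _resolve_thresholds(tree, tmap)
    h = tree.height

    # entity roots: first node at-or-below its threshold on each root path
    n_all = len(tree.parent)
    is_div = np.zeros(n_all, dtype=bool)
    for nd in range(n_all):
        is_div[nd] = h[nd] > t_node[nd]
    entity_of = np.full(n_all, -1, dtype=int)
    entities: list[list[int]] = []
    order = [tree.root]
    seen = 0
    while seen < len(order):
        nd = order[seen]
        seen += 1
        par = tree.parent[nd]
        if not is_div[nd] and (nd == tree.root or is_div[par]):
            entity_of[nd] = len(entities)
            entities.append(sorted(tree.tips_below(nd)))
        elif par >= 0 and entity_of[par] >= 0:
            entity_of[nd] = entity_of[par]
        order.extend(tree.children[nd])

    # slab boundaries: node heights plus every distinct crossing threshold
    # (thresholds sit strictly inside slabs, so exact float comparisons
    # against node heights are safe)
    node_heights = set(float(v) for v in h[tree.n_tips:])
    crossings = set()
    for nd in range(n_all):
        if nd == tree.root:
            continue
        hp, hc = h[tree.parent[nd]], h[nd] if nd >= tree.n_tips else 0.0
        t = t_node[nd]
        if hc < t < hp:
            crossings.add(float(t))
    bounds = sorted(node_heights | crossings | {0.0}, reverse=True)

    branches = [nd for nd in range(n_all) if nd != tree.root]
    bh_lo = np.array([h[nd] if nd >= tree.n_tips else 0.0 for nd in branches])
    bh_hi = np.array([h[tree.parent[nd]] for nd in branches])
    b_thr = np.array([t_node[nd] for nd in branches])
    b_ent = np.array([entity_of[nd] for nd in branches])

    xs, ks, coal_rows, evs = [], [], [], []
    height_arr = h[tree.n_tips:]
    for hi, lo in zip(bounds[:-1], bounds[1:]):
        crossing = (bh_lo <= lo) & (bh_hi >= hi)
        div = crossing & (b_thr <= lo)
        coal_b = crossing & ~div
        counts = np.bincount(b_ent[coal_b], minlength=len(entities)) \
            if coal_b.any() else np.zeros(len(entities), dtype=int)
        xs.append(hi - lo)
        ks.append(int(div.sum()))
        coal_rows.append(counts * (counts - 1))
        evs.append(int(np.sum(height_arr == hi)))
    coal = np.array(coal_rows, dtype=float) if coal_rows else np.zeros((0, 1))
    return IntervalTable(np.array(xs), np.array(ks, dtype=float), coal,
                         np.array(evs), entities)


def single_class_table(tree: UltrametricTree) -> IntervalTable:
    """Null-model table: one coalescent class holding every lineage."""
    h = tree.height
    bounds = sorted(set(float(v) for v in h[tree.n_tips:]), reverse=True) + [0.0]
    n_all = len(tree.parent)
    bh_lo = np.array([h[nd] if nd >= tree.n_tips else 0.0
                      for nd in range(n_all) if nd != tree.root])
    bh_hi = np.array([h[tree.parent[nd]]
                      for nd in range(n_all) if nd != tree.root])
    xs, coal_rows, evs = [], [], []
    harr = h[tree.n_tips:]
    for hi, lo in zip(bounds[:-1], bounds[1:]):
        n = int(np.sum((bh_lo <= lo) & (bh_hi >= hi)))
        xs.append(hi - lo)
        coal_rows.append([n * (n - 1)])
        evs.append(int(np.sum(harr == hi)))
    return IntervalTable(np.array(xs), np.zeros(len(xs)),
                         np.array(coal_rows, dtype=float), np.array(evs),
                         [sorted(range(tree.n_tips))])


def model_loglik(intervals: IntervalTable, lambda_div: float, p_div: float,
                 lambda_coal: float, p_coal: float) -> float:
    """GMYC log-likelihood; -inf when an event interval has zero hazard."""
    if min(lambda_div, lambda_coal) < 0:
        raise CyanodelimError("rates must be non-negative")
    k = intervals.k
    A = np.where(k > 0, np.power(k, p_div, where=k > 0, out=np.ones_like(k)), 0.0)
    C = intervals.coal
    B = np.where(C > 0, np.power(C, p_coal, where=C > 0,
                                 out=np.ones_like(C)), 0.0).sum(axis=1)
    b = lambda_div * A + lambda_coal * B
    ev = intervals.n_events
    if np.any((b <= 0) & (ev > 0)):
        return -np.inf
    with np.errstate(divide="ignore"):
        logb = np.where(b > 0, np.log(np.where(b > 0, b, 1.0)), 0.0)
    return float(np.sum(ev * logb) - np.sum(b * intervals.x))


def _moment_rate(table: IntervalTable, p: float) -> float:
    k = table.k
    A = np.where(k > 0, k ** p, 0.0)
    C = table.coal
    B = np.where(C > 0, C ** p, 0.0).sum(axis=1)
    denom = float(np.sum((A + B) * table.x))
    if denom <= 0:
        return 1.0
    return max(float(table.n_events.sum()) / denom, 1e-6)


def maximize_loglik(table: IntervalTable,
                    warm_start: tuple | None = None) -> tuple[np.ndarray, float]:
    """Bounded quasi-Newton maximization over (log-rates, exponents).

    Five deterministic multi-starts (moment-matched rates at two exponent
    levels, two skewed-rate variants, and an optional warm start); classes
    absent from the table have their parameters pinned.
    """
    has_div = bool(np.any(table.k > 0))
    has_coal = bool(np.any(table.coal > 0))
    lo_r, hi_r = LOG_RATE_BOUNDS

    def unpack(theta):
        ld = np.exp(theta[0]) if has_div else 0.0
        lc = np.exp(theta[1]) if has_coal else 0.0
        return ld, theta[2], lc, theta[3]

    def neg(theta):
        ll = model_loglik(table, *unpack(theta))
        return 1e12 if not np.isfinite(ll) else -ll

    starts = []
    for p0 in (1.0, 0.5):
        r = np.log(np.clip(_moment_rate(table, p0), np.exp(lo_r), np.exp(hi_r)))
        starts.append([r, r, p0, p0])
    base = starts[0]
    starts.append([min(base[0] + 1.6, hi_r), max(base[1] - 1.6, lo_r), 1.0, 1.0])
    starts.append([max(base[0] - 1.6, lo_r), min(base[1] + 1.6, hi_r), 1.0, 1.0])
    if warm_start is not None:
        starts.append(list(warm_start))
    else:
        starts.append([base[0], base[1], 2.0, 2.0])

    bounds = [LOG_RATE_BOUNDS, LOG_RATE_BOUNDS, P_BOUNDS, P_BOUNDS]
    best_theta, best_val = None, np.inf
    for s in starts:
        res = optimize.minimize(neg, s, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": _OPT_TOL, "gtol": 1e-8,
                                         "maxiter": 200})
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None or best_val >= 1e12:
        raise CyanodelimError("likelihood optimization failed at every start")
    return best_theta, -best_val


@dataclass
class GMYCFit:
    """A fitted GMYC model with its implied partition of tips."""

    model: str
    thresholds: list[float]
    lambda_div: float
    p_div: float
    lambda_coal: float
    p_coal: float
    loglik: float
    partition: dict[str, int]
    n_entities: int
    conf_set: list[int] = field(default_factory=list)
    profile: list[dict] = field(default_factory=list)
    threshold_map: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise CyanodelimError("non-finite log-likelihood in fit")
        if self.conf_set and self.n_entities not in self.conf_set:
            self.conf_set = sorted(set(self.conf_set) | {self.n_entities})

    def to_dict(self) -> dict:
        return {
            "model": self.model, "thresholds": list(self.thresholds),
            "lambda_div": self.lambda_div, "p_div": self.p_div,
            "lambda_coal": self.lambda_coal, "p_coal": self.p_coal,
            "loglik": self.loglik, "n_entities": self.n_entities,
            "conf_set": list(self.conf_set), "partition": self.partition,
        }


def _partition_dict(tree: UltrametricTree, entities: list[list[int]]) -> dict[str, int]:
    out = {}
    for ent_id, tips in enumerate(entities):
        for t in tips:
            out[tree.tip_labels[t]] = ent_id
    return out


def candidate_thresholds(tree: UltrametricTree) -> np.ndarray:
    """Midpoints between consecutive distinct node heights (tips included).

    Candidates sit strictly inside internode slabs so lineage counts at
    the threshold are unambiguous.
    """
    levels = np.concatenate([[0.0], np.unique(tree.height[tree.n_tips:])])
    return 0.5 * (levels[:-1] + levels[1:])


def fit_null(tree: UltrametricTree) -> GMYCFit:
    """One-process null: a single coalescent-form class over all lineages."""
    table = single_class_table(tree)
    theta, ll = maximize_loglik(table)
    return GMYCFit("null", [], 0.0, float(theta[2]), float(np.exp(theta[1])),
                   float(theta[3]), ll,
                   {lbl: 0 for lbl in tree.tip_labels}, 1)


def fit_single(tree: UltrametricTree) -> GMYCFit:
    """Single-threshold GMYC: profile the likelihood over all candidates.

    The confidence set collects entity counts of candidates whose profile
    log-likelihood is within 2 units of the maximum.
    """
    if tree.n_tips < 4:
        raise CyanodelimError("single-threshold fit needs >= 4 tips")
    cands = candidate_thresholds(tree)
    profile, warm = [], None
    best = None
    for T in cands:
        table = interval_decomposition(tree, float(T))
        theta, ll = maximize_loglik(table, warm_start=warm)
        warm = tuple(theta)
        rec = {"threshold": float(T), "loglik": ll,
               "n_entities": table.n_entities}
        profile.append(rec)
        if best is None or ll > best[1]:
            best = (float(T), ll, theta, table)
    T, ll, theta, table = best
    conf = sorted({r["n_entities"] for r in profile if r["loglik"] >= ll - 2.0})
    return GMYCFit("single", [T], float(np.exp(theta[0])), float(theta[2]),
                   float(np.exp(theta[1])), float(theta[3]), ll,
                   _partition_dict(tree, table.entities), table.n_entities,
                   conf, profile, threshold_map={tree.root: T})


def _local_candidates(tree: UltrametricTree, node: int, ceiling: float) -> list[float]:
    tips = tree.tips_below(node)
    sub_internal = [nd for nd in tree.internal_nodes()
                    if set(tree.tips_below(int(nd))) <= set(tips)
                    and tree.height[nd] < ceiling]
    levels = np.concatenate([[0.0], np.unique(tree.height[sub_internal])]) \
        if sub_internal else np.array([0.0, ceiling])
    levels = np.append(levels, ceiling)
    mids = 0.5 * (levels[:-1] + levels[1:])
    return [float(m) for m in mids if 0 < m < ceiling]


def fit_multiple(tree: UltrametricTree, max_thresholds: int = 5) -> GMYCFit:
    """Multiple-threshold GMYC by greedy forward search.

    Starting from the best single threshold, repeatedly applies the
    clade-local threshold change that most improves the likelihood,
    stopping when the improvement drops below 1e-6 or ``max_thresholds``
    distinct thresholds are in use.
    """
    if tree.n_tips < 4:
        raise CyanodelimError("multiple-threshold fit needs >= 4 tips")
    single = fit_single(tree)
    tmap = dict(single.threshold_map)
    best_ll, best_theta = single.loglik, None
    profile = list(single.profile)
    while len(set(tmap.values())) < max_thresholds:
        t_res = _resolve_thresholds(tree, tmap)
        improved = None
        for nd in tree.internal_nodes():
            nd = int(nd)
            if tree.height[nd] <= t_res[nd]:
                continue  # only diversification-side clades get local thresholds
            for t_new in _local_candidates(tree, nd, float(tree.height[nd])):
                if abs(t_new - t_res[nd]) < 1e-12:
                    continue
                trial = {**tmap, nd: t_new}
                table = interval_decomposition(tree, trial)
                theta, ll = maximize_loglik(table, warm_start=best_theta)
                if improved is None or ll > improved[1]:
                    improved = (trial, ll, theta, table)
        if improved is None or improved[1] - best_ll < 1e-6:
            break
        tmap, best_ll, best_theta, best_table = improved
        profile.append({"threshold_map": {int(k): float(v) for k, v in tmap.items()},
                        "loglik": best_ll, "n_entities": best_table.n_entities})
    if best_theta is None:  # no improving local move: equals the single fit
        fit = single
        return GMYCFit("multiple", fit.thresholds, fit.lambda_div, fit.p_div,
                       fit.lambda_coal, fit.p_coal, fit.loglik, fit.partition,
                       fit.n_entities, fit.conf_set, profile,
                       threshold_map=dict(tmap))
    thresholds = sorted(set(tmap.values()))
    counts_close = sorted({r["n_entities"] for r in profile
                           if r.get("loglik", -np.inf) >= best_ll - 2.0})
    return GMYCFit("multiple", thresholds, float(np.exp(best_theta[0])),
                   float(best_theta[2]), float(np.exp(best_theta[1])),
                   float(best_theta[3]), best_ll,
                   _partition_dict(tree, best_table.entities),
                   best_table.n_entities, counts_close, profile,
                   threshold_map=dict(tmap))


@dataclass
class LRTResult:
    L_null: float
    L_model: float
    statistic: float
    df: int
    p_value: float
    significant: bool
    stars: str
    clamped: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def likelihood_ratio_test(null: GMYCFit, model: GMYCFit,
                          alpha: float = 0.05) -> LRTResult:
    """Chi-square LRT of a GMYC fit against the one-process null.

    Degrees of freedom follow the free-parameter difference: 3 for the
    single-threshold model, 2 + (number of thresholds) for the multiple
    model.  A model likelihood below the null (optimizer failure) is
    clamped to 0 and flagged.
    """
    lr = 2.0 * (model.loglik - null.loglik)
    clamped = False
    if lr < 0:
        import warnings
        warnings.warn("model likelihood below null; LR clamped to 0 "
                      "(optimizer failure indicator)")
        lr, clamped = 0.0, True
    df = 3 if model.model == "single" else 2 + max(len(model.thresholds), 1)
    p = float(stats.chi2.sf(lr, df)) if lr > 0 else 1.0
    stars = "n.s."
    for cut, sym in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < cut:
            stars = sym
            break
    return LRTResult(null.loglik, model.loglik, lr, df, p, p < alpha,
                     stars, clamped)
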