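"""Affinity-propagation clustering by responsibility/availability message
passing, iterated hierarchically over exemplars.

Affinity propagation (Frey & Dueck) treats every item as a candidate
cluster centre ("exemplar") and exchanges two real-valued messages along
a pairwise-similarity matrix S:

* responsibility  r(i,k) <- s(i,k) - max_{k' != k} { a(i,k') + s(i,k') }
  -- how well suited k is to serve as the exemplar of i, relative to the
  best competing candidate;
* availability    a(i,k) <- min{ 0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)) }
  (i != k) -- how appropriate it is for i to choose k, given the support
  k already receives from other points;
* self-availability a(k,k) <- sum_{i' != k} max(0, r(i',k)) -- the
  accumulated evidence that k is an exemplar.

Messages start at a(i,k) = 0, are damped (old*lambda + new*(1-lambda)) for
numerical stability, and after convergence the exemplar set is
{ k : r(k,k) + a(k,k) > 0 }; every item joins the exemplar with maximal
similarity.  The diagonal of S ("preference") controls how many exemplars
emerge; the number of clusters is otherwise determined entirely by the
data.  All tie-breaks are deterministic lowest-index rules, so repeated
runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (ConfigError, DataError, DegenerateDataError,
                     IntegrityError, NonConvergenceError)


# --------------------------------------------------------------- similarities

@dataclass
class SimilarityMatrix:
    """Square pairwise-similarity matrix with a uniform diagonal preference."""

    items: list[str]
    s: np.ndarray
    metric: str
    preference: float

    def __post_init__(self):
        n = len(self.items)
        if self.s.shape != (n, n):
            raise DataError("similarity matrix shape does not match items")
        off = ~np.eye(n, dtype=bool)
        if n > 1 and not np.isfinite(self.s[off]).all():
            raise DataError("non-finite off-diagonal similarity")


def build_similarity(x: pd.DataFrame, metric: str = "neg_euclidean",
                     preference: str | float | tuple = "median") -> SimilarityMatrix:
    """Pairwise similarities between the rows of an items x features matrix.

    metric="neg_euclidean": s(i,k) = -||x_i - x_k||_2.
    metric="pearson": s(i,k) = cor(x_i, x_k), used directly as similarity.
    preference: "median" (median off-diagonal similarity), ("quantile", q),
    or an explicit float; it becomes the uniform diagonal of S.
    """
    if len(x) < 2:
        raise DataError("need at least 2 items to build a similarity matrix")
    if x.isna().any().any():
        raise DataError("missing feature values")
    vals = x.to_numpy(dtype=float)
    if metric == "neg_euclidean":
        s = -squareform(pdist(vals, metric="euclidean"))
    elif metric == "pearson":
        sds = vals.std(axis=1)
        if (sds == 0).any():
            bad = list(x.index[sds == 0])
            raise DegenerateDataError(
                f"constant feature vector(s) make Pearson correlation undefined: {bad}")
        s = np.corrcoef(vals)
    else:
        raise ConfigError(f"unknown metric {metric!r}")

    off = s[~np.eye(len(s), dtype=bool)]
    if preference == "median":
        pref = float(np.median(off))
    elif isinstance(preference, tuple) and preference[0] == "quantile":
        pref = float(np.quantile(off, preference[1]))
    elif isinstance(preference, (int, float)):
        pref = float(preference)
    else:
        raise ConfigError(f"unknown preference rule {preference!r}")
    np.fill_diagonal(s, pref)
    return SimilarityMatrix(list(map(str, x.index)), s, metric, pref)


# ------------------------------------------------------------------ results

@dataclass
class ClusterResult:
    items: list[str]
    exemplars: list[str]
    assignment: dict[str, str]  # item -> exemplar
    n_iterations: int
    converged: bool

    def __post_init__(self):
        ex = set(self.exemplars)
        for e in self.exemplars:
            if self.assignment.get(e) != e:
                raise IntegrityError(f"exemplar {e} not assigned to itself")
        for item, e in self.assignment.items():
            if e not in ex:
                raise IntegrityError(f"item {item} assigned to non-exemplar {e}")

    def labels(self) -> pd.Series:
        return pd.Series(self.assignment, name="exemplar")


@dataclass
class ClusterHierarchy:
    """Nested AP levels; level l+1 clusters the exemplars of level l."""

    levels: list[ClusterResult] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.levels)

    def membership(self, level: int) -> dict[str, str]:
        """Base item -> exemplar at the given 1-based level, by composing
        the per-level assignments."""
        if not 1 <= level <= self.depth:
            raise ConfigError(f"level must be in 1..{self.depth}")
        comp = dict(self.levels[0].assignment)
        for res in self.levels[1:level]:
            comp = {item: res.assignment[ex] for item, ex in comp.items()}
        return comp


# ------------------------------------------------------------ message passing

def _update_messages(s: np.ndarray, r: np.ndarray, a: np.ndarray,
                     damping: float) -> tuple[np.ndarray, np.ndarray]:
    """One synchronous responsibility + availability update (vectorized).

    At damping 0 this is an exact transcription of the update rules above;
    otherwise each message is damping*old + (1-damping)*new.
    """
    n = s.shape[0]
    rows = np.arange(n)

    # responsibilities: subtract the best competing a+s (per row, excluding k)
    asum = a + s
    top = asum.argmax(axis=1)
    best = asum[rows, top]
    asum[rows, top] = -np.inf
    second = asum.max(axis=1) if n > 1 else best
    r_new = s - best[:, None]
    r_new[rows, top] = s[rows, top] - second
    r = damping * r + (1 - damping) * r_new

    # availabilities: column sums of positive responsibilities
    rp = np.maximum(r, 0)
    rp[rows, rows] = r[rows, rows]  # keep the raw self-responsibility
    colsum = rp.sum(axis=0)
    a_new = colsum[None, :] - rp
    diag = a_new[rows, rows]        # = colsum - r(k,k) = sum of positives
    a_new = np.minimum(a_new, 0)
    a_new[rows, rows] = diag
    a = damping * a + (1 - damping) * a_new
    return r, a


def ap_cluster(S: SimilarityMatrix, damping: float = 0.9, max_iter: int = 1000,
               convergence_window: int = 50) -> ClusterResult:
    """Run affinity propagation on a similarity matrix.

    Convergence means the exemplar set is unchanged over
    ``convergence_window`` consecutive iterations.  If max_iter is reached
    without stability and without any exemplar, a NonConvergenceError
    carrying the last message state is raised; with a (possibly unstable)
    exemplar set the result is returned with ``converged=False``.

    A fully symmetric input (all similarities tied) yields zero evidence
    for every candidate; on convergence of that degenerate state the item
    with maximal evidence -- lowest index on ties -- becomes the single
    exemplar.
    """
    if not 0 <= damping < 1:
        raise ConfigError(f"damping must be in [0, 1), got {damping}")
    items = S.items
    n = len(items)
    if n == 1:
        return ClusterResult(items, [items[0]], {items[0]: items[0]}, 0, True)

    s = S.s.astype(float).copy()
    # Degenerate similarity structures (e.g. a two-point cluster whose
    # members are equally good exemplars) make candidate evidence oscillate
    # around zero and never settle.  The standard remedy is a tiny noise
    # term on S; here it is a deterministic perturbation, decreasing with
    # candidate index, ~1e-9 of the similarity scale -- far below any real
    # margin -- so symmetric ties break reproducibly toward the lowest index.
    scale = np.abs(s).max()
    eps = 1e-9 * (scale if scale > 0 else 1.0)
    s += eps * (np.arange(n, 0, -1, dtype=float)[None, :] / n)
    r = np.zeros((n, n))
    a = np.zeros((n, n))
    # strict ">0" exemplar evidence, with a tiny absolute tolerance so that
    # tie-degenerate inputs whose evidence decays to exactly 0 (with
    # +-1e-15 floating flicker) still stabilize
    tol = 1e-12
    prev_ex: frozenset[int] | None = None
    stable = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r_old, a_old = r, a
        r, a = _update_messages(s, r, a, damping)
        ex = frozenset(np.flatnonzero(np.diag(r) + np.diag(a) > tol))
        # stability only counts once an exemplar set has emerged; the
        # slow-growth phase before any candidate turns positive must not
        # be mistaken for convergence
        stable = stable + 1 if (ex and ex == prev_ex) else (1 if ex else 0)
        prev_ex = ex
        if stable >= convergence_window:
            converged = True
            break
        if (it > 1 and abs(r - r_old).max() < 1e-14
                and abs(a - a_old).max() < 1e-14):
            converged = True  # exact message fixed point (degenerate ties)
            break

    evidence = np.diag(r) + np.diag(a)
    ex_idx = np.flatnonzero(evidence > tol)
    if len(ex_idx) == 0:
        if not converged:
            raise NonConvergenceError(
                f"no exemplar emerged after {it} iterations",
                responsibility=r, availability=a, n_iterations=it)
        ex_idx = np.array([int(np.argmax(evidence))])  # degenerate tie fallback

    # final clean assignment pass: argmax similarity over exemplars
    choice = ex_idx[np.argmax(s[:, ex_idx], axis=1)]
    choice[ex_idx] = ex_idx  # exemplars are their own exemplar
    assignment = {items[i]: items[int(k)] for i, k in enumerate(choice)}
    return ClusterResult(items, [items[int(k)] for k in ex_idx],
                         assignment, it, converged)


def net_similarity(S: SimilarityMatrix, result: ClusterResult) -> float:
    """Sum over items of s(i, exemplar(i)); exemplars contribute their
    preference.  The objective AP approximately maximizes."""
    pos = {item: i for i, item in enumerate(S.items)}
    ex = set(result.exemplars)
    total = 0.0
    for item, e in result.assignment.items():
        if e not in ex:
            raise IntegrityError(f"item {item} assigned to non-exemplar {e}")
        total += S.preference if item == e else S.s[pos[item], pos[e]]
    return total


# ---------------------------------------------------------------- hierarchy

def hierarchical_ap(x: pd.DataFrame, metric: str = "neg_euclidean",
                    preference: str | float | tuple = "median",
                    damping: float = 0.9, max_iter: int = 1000,
                    convergence_window: int = 50) -> ClusterHierarchy:
    """Cluster items, then re-cluster the exemplars (using their original
    feature rows), repeating until a single exemplar remains or the
    exemplar set stops shrinking."""
    if len(x) < 2:
        raise DataError("need at least 2 items for hierarchical clustering")
    hierarchy = ClusterHierarchy()
    current = x
    level = 0
    while len(current) >= 2:
        level += 1
        sim = build_similarity(current, metric=metric, preference=preference)
        try:
            res = ap_cluster(sim, damping=damping, max_iter=max_iter,
                             convergence_window=convergence_window)
        except NonConvergenceError as err:
            raise NonConvergenceError(
                f"level {level}: {err}", err.responsibility, err.availability,
                err.n_iterations) from err
        if hierarchy.levels and len(res.exemplars) >= len(current.index):
            break  # fixed point: no further merging
        hierarchy.levels.append(res)
        current = current.loc[res.exemplars]
    return hierarchy
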