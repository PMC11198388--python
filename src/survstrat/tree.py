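"""Conditional-inference survival tree.

Recursive partitioning in the permutation-test framework of Strasser and
Weber: at every node the per-subject log-rank scores are recomputed, each
candidate covariate is tested for association with the scores through the
linear statistic T = Σ g_i a_i standardised by its exact permutation-null
moments, the most significant covariate (Bonferroni-adjusted across
candidates) is chosen, and the binary cutpoint maximising the standardised
two-sample statistic is taken. A node becomes a terminal leaf when the
adjusted p-value fails the significance level, the node is too small, or no
cutpoint leaves both children above the minimum leaf size.

Variable selection is deliberately separated from cutpoint search, which is
what gives the procedure its unbiasedness towards covariates with many
distinct values and its significance-based stopping rule.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .survival import SurvivalData, kaplan_meier, logrank_scores, survival_at

__all__ = [
    "LinearStatisticResult",
    "SplitConfig",
    "TreeNode",
    "SurvivalTree",
    "linear_statistic",
    "exact_permutation_p",
    "select_split_variable",
    "best_cutpoint",
    "grow_tree",
    "predict_leaf",
]


@dataclass(frozen=True)
class LinearStatisticResult:
    """Linear statistic with its permutation-null moments and p-value.

    For a single transformation column, ``z`` is the standardised statistic
    and ``p`` the two-sided normal p-value; for multi-column g (one-hot
    categorical) the quadratic form against the pseudo-inverted covariance
    is referred to a chi-squared distribution and ``z`` holds its square
    root.
    """

    statistic: np.ndarray
    mu: np.ndarray
    variance: np.ndarray  # covariance matrix (p x p)
    z: float
    p: float
    degenerate: bool
    df: int


def _perm_moments(g: np.ndarray, a: np.ndarray):
    """Exact permutation expectation and covariance of T = g' a.

    With h = a (influence function) permuted against rows of g:
    E[T] = (Σ g_i) ā and Cov[T] = n/(n-1) * V_a * (Σ g g' − (Σg)(Σg)'/n)
    where V_a = (1/n) Σ (a_i − ā)^2.
    """
    n = a.size
    abar = a.mean()
    va = np.mean((a - abar) ** 2)
    gsum = g.sum(axis=0)
    mu = gsum * abar
    gram = g.T @ g - np.outer(gsum, gsum) / n
    cov = (n / (n - 1.0)) * va * gram
    return mu, cov


def linear_statistic(g, a) -> LinearStatisticResult:
    """Standardised linear statistic T = Σ g_i a_i under the permutation null.

    ``g`` may be a vector (numeric covariate or split indicator) or an
    (n, k) matrix (one-hot coded categorical). Degenerate inputs (constant
    g or constant a) yield p = 1 with the degeneracy flag set instead of a
    division error.
    """
    g = np.asarray(g, dtype=float)
    a = np.asarray(a, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    n = a.size
    if g.shape[0] != n:
        raise ValueError("g and a must have equal length")
    if n < 2:
        raise ValueError("need at least two observations")

    t_obs = g.T @ a
    mu, cov = _perm_moments(g, a)
    if g.shape[1] == 1:
        var = float(cov[0, 0])
        if var <= 0:
            return LinearStatisticResult(t_obs, mu, cov, 0.0, 1.0, True, 0)
        z = float((t_obs[0] - mu[0]) / math.sqrt(var))
        p = 2.0 * stats.norm.sf(abs(z))
        return LinearStatisticResult(t_obs, mu, cov, z, p, False, 1)
    # quadratic form with pseudo-inverse (relative tolerance 1e-8)
    diff = t_obs - mu
    scale = np.abs(cov).max()
    if scale <= 0:
        return LinearStatisticResult(t_obs, mu, cov, 0.0, 1.0, True, 0)
    cov_inv = np.linalg.pinv(cov, rcond=1e-8)
    rank = int(np.linalg.matrix_rank(cov, tol=1e-8 * scale))
    if rank == 0:
        return LinearStatisticResult(t_obs, mu, cov, 0.0, 1.0, True, 0)
    chi2 = float(diff @ cov_inv @ diff)
    p = float(stats.chi2.sf(chi2, df=rank))
    return LinearStatisticResult(t_obs, mu, cov, math.sqrt(max(chi2, 0.0)), p, False, rank)


_ENUMERATION_LIMIT = 10


def exact_permutation_p(g, a) -> float:
    """Exact two-sided permutation p-value for T = Σ g_i a_i by enumeration.

    Counts permutations π with |T(π) − μ| >= |T_obs − μ| over all n!
    rearrangements of the scores. Only feasible for tiny samples; larger
    inputs must use the asymptotic ``linear_statistic`` path.
    """
    g = np.asarray(g, dtype=float).ravel()
    a = np.asarray(a, dtype=float).ravel()
    n = a.size
    if n > _ENUMERATION_LIMIT:
        raise ValueError(
            f"n={n} exceeds the enumeration limit ({_ENUMERATION_LIMIT}); "
            "use the asymptotic linear_statistic p-value instead"
        )
    mu = g.sum() * a.mean()
    t_obs = abs(float(g @ a) - mu)
    count = 0
    total = 0
    for perm in itertools.permutations(a):
        t = abs(float(g @ np.asarray(perm)) - mu)
        count += t >= t_obs - 1e-12
        total += 1
    return count / total


@dataclass(frozen=True)
class SplitConfig:
    """Stopping and significance configuration for tree growth.

    ``alpha`` is the per-node significance level for the multiplicity-
    adjusted association test; ``minbucket`` the smallest admissible
    terminal leaf; ``minsplit`` the smallest node a split is attempted in
    (defaults to ``2 * minbucket``).
    """

    alpha: float = 0.05
    minbucket: int = 95
    minsplit: Optional[int] = None
    adjustment: str = "bonferroni"
    max_depth: Optional[int] = None
    seed: int = 0
    landmark_years: tuple = (1.0, 6.0)

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.minbucket < 1:
            raise ValueError("minbucket must be >= 1")
        if self.minsplit is None:
            object.__setattr__(self, "minsplit", 2 * self.minbucket)
        if self.minsplit < 2 * self.minbucket:
            raise ValueError("minsplit must be at least 2 * minbucket")
        if self.adjustment not in ("bonferroni", "none"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")


_MAX_CATEGORICAL_LEVELS = 5


def _encode(values: np.ndarray, categorical: bool):
    """Transformation g for the association test: raw numeric or one-hot."""
    if not categorical:
        return values[:, None]
    levels = np.unique(values)
    if levels.size > _MAX_CATEGORICAL_LEVELS:
        raise ValueError(
            f"categorical covariate has {levels.size} levels; at most "
            f"{_MAX_CATEGORICAL_LEVELS} are supported"
        )
    return (values[:, None] == levels[None, :]).astype(float)


def select_split_variable(covariates: dict, a: np.ndarray, config: SplitConfig,
                          categorical=()):  # -> (name, p_adj) | None
    """Pick the covariate most associated with the node's log-rank scores.

    Each candidate is tested with ``linear_statistic``; the smallest
    p-value is Bonferroni-adjusted across the number of non-degenerate
    candidates. Returns ``None`` (the stop signal) when no candidate is
    testable or the adjusted p fails ``config.alpha``.
    """
    best_name, best_p = None, np.inf
    m = 0
    for name, values in covariates.items():
        g = _encode(np.asarray(values, dtype=float), name in categorical)
        res = linear_statistic(g, a)
        if res.degenerate:
            continue
        m += 1
        if res.p < best_p:
            best_name, best_p = name, res.p
    if best_name is None:
        return None
    p_adj = min(1.0, m * best_p) if config.adjustment == "bonferroni" else best_p
    if p_adj >= config.alpha:
        return None
    return best_name, p_adj


def best_cutpoint(x, a, minbucket: int):  # -> (threshold, |z|) | None
    """Best binary cutpoint of ``x`` against scores ``a``.

    Candidate thresholds are the observed values of x; the split is
    ``x <= c`` versus ``x > c`` and must leave at least ``minbucket``
    subjects on each side. The threshold maximising |z| of the two-sample
    linear statistic is returned, ties broken towards the smallest
    threshold. Returns ``None`` when no admissible cutpoint exists.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    as_ = a[order]
    # prefix sums over the sorted sample: T(c) = sum of scores with x <= c
    csum = np.cumsum(as_)
    uniq, last_idx = np.unique(xs, return_index=True)
    # index of the last occurrence of each unique value
    last = np.concatenate([last_idx[1:], [n]]) - 1
    n_left = last + 1
    admissible = (n_left >= minbucket) & (n - n_left >= minbucket)
    # x <= max(x) is no split
    admissible[-1] = False
    if not admissible.any():
        return None
    abar = a.mean()
    va = np.mean((a - abar) ** 2)
    t_left = csum[last]
    mu = n_left * abar
    var = (n / (n - 1.0)) * va * (n_left - n_left**2 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs((t_left - mu) / np.sqrt(var))
    z = np.where(var > 0, z, 0.0)
    z = np.where(admissible, z, -np.inf)
    best = int(np.argmax(z))  # argmax takes the first (smallest c) on ties
    if not np.isfinite(z[best]) or z[best] <= 0:
        return None
    return float(uniq[best]), float(z[best])


@dataclass
class TreeNode:
    """Internal split node or terminal leaf of a fitted survival tree."""

    n: int
    events: int
    depth: int
    # internal nodes
    variable: Optional[str] = None
    threshold: Optional[float] = None
    p_adj: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    # leaves
    leaf_id: Optional[int] = None
    km_landmarks: Optional[dict] = None
    median_survival: Optional[float] = None
    stop_reason: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None


@dataclass
class SurvivalTree:
    """Fitted conditional-inference survival tree."""

    root: TreeNode
    config: SplitConfig
    covariates: list
    categorical: list = field(default_factory=list)

    @property
    def leaves(self) -> list:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_criteria(self) -> dict:
        """Map leaf_id -> human-readable conjunction of path conditions."""
        out = {}

        def walk(node, conds):
            if node.is_leaf:
                out[node.leaf_id] = "/".join(conds) if conds else "(all patients)"
            else:
                lc, rc = _split_conditions(node)
                walk(node.left, conds + [lc])
                walk(node.right, conds + [rc])

        walk(self.root, [])
        return out

    def to_dict(self) -> dict:
        def encode(node):
            if node.is_leaf:
                return {
                    "leaf_id": node.leaf_id,
                    "n": node.n,
                    "events": node.events,
                    "km_landmarks": node.km_landmarks,
                    "median_survival": node.median_survival,
                    "stop_reason": node.stop_reason,
                }
            return {
                "variable": node.variable,
                "threshold": node.threshold,
                "p_adj": node.p_adj,
                "n": node.n,
                "events": node.events,
                "left": encode(node.left),
                "right": encode(node.right),
            }

        return {
            "config": {
                "alpha": self.config.alpha,
                "minbucket": self.config.minbucket,
                "minsplit": self.config.minsplit,
                "adjustment": self.config.adjustment,
                "max_depth": self.config.max_depth,
                "landmark_years": list(self.config.landmark_years),
            },
            "covariates": self.covariates,
            "categorical": self.categorical,
            "root": encode(self.root),
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "SurvivalTree":
        cfg = payload.get("config", {})
        config = SplitConfig(
            alpha=cfg.get("alpha", 0.05),
            minbucket=cfg.get("minbucket", 95),
            minsplit=cfg.get("minsplit"),
            adjustment=cfg.get("adjustment", "bonferroni"),
            max_depth=cfg.get("max_depth"),
            landmark_years=tuple(cfg.get("landmark_years", (1.0, 6.0))),
        )

        def decode(obj, depth):
            if "leaf_id" in obj:
                return TreeNode(
                    n=obj["n"],
                    events=obj["events"],
                    depth=depth,
                    leaf_id=obj["leaf_id"],
                    km_landmarks=obj.get("km_landmarks"),
                    median_survival=obj.get("median_survival"),
                    stop_reason=obj.get("stop_reason"),
                )
            return TreeNode(
                n=obj["n"],
                events=obj["events"],
                depth=depth,
                variable=obj["variable"],
                threshold=obj["threshold"],
                p_adj=obj.get("p_adj"),
                left=decode(obj["left"], depth + 1),
                right=decode(obj["right"], depth + 1),
            )

        return cls(
            root=decode(payload["root"], 0),
            config=config,
            covariates=list(payload.get("covariates", [])),
            categorical=list(payload.get("categorical", [])),
        )

    @classmethod
    def from_json(cls, source) -> "SurvivalTree":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls.from_dict(payload)

    def format_text(self) -> str:
        lines = []

        def walk(node, indent):
            pad = "  " * indent
            if node.is_leaf:
                lm = node.km_landmarks or {}
                lmtxt = ", ".join(f"S({k}y)={v:.2f}" for k, v in lm.items() if v is not None)
                lines.append(
                    f"{pad}leaf {node.leaf_id}: n={node.n}, events={node.events}"
                    + (f", {lmtxt}" if lmtxt else "")
                )
            else:
                lc, rc = _split_conditions(node)
                lines.append(f"{pad}{lc} (p_adj={node.p_adj:.3g}, n={node.n})")
                walk(node.left, indent + 1)
                lines.append(f"{pad}{rc}")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _split_conditions(node) -> tuple:
    """Human-readable (left, right) conditions of an internal node."""
    if isinstance(node.threshold, (tuple, list)):
        levels = ",".join(f"{v:g}" for v in node.threshold)
        return (
            f"{node.variable} in {{{levels}}}",
            f"{node.variable} not in {{{levels}}}",
        )
    return (
        f"{node.variable} ≤{node.threshold:g}",
        f"{node.variable} >{node.threshold:g}",
    )


def _leaf_stats(data: SurvivalData, landmarks):
    km = kaplan_meier(data)
    lm = {}
    max_t = float(data.time.max())
    for t in landmarks:
        lm[f"{t:g}"] = float(survival_at(km, t)) if t <= max_t else None
    median = None
    below = km.survival <= 0.5
    if below.any():
        median = float(km.time[np.argmax(below)])
    return lm, median


def grow_tree(cohort, covariates, data: SurvivalData, config: SplitConfig,
              categorical=()) -> SurvivalTree:
    """Grow a conditional-inference survival tree.

    Parameters
    ----------
    cohort : DataFrame (or mapping of arrays) holding the covariate columns.
    covariates : ordered list of covariate column names to consider.
    data : SurvivalData aligned with the cohort rows.
    config : SplitConfig with alpha / minbucket / minsplit / adjustment.
    categorical : names treated as unordered categorical (one-hot tested,
        exhaustive binary level partitions for the cutpoint).

    At each node the log-rank scores are recomputed from the node's own
    survival data before variable selection, so deeper splits measure
    association conditional on the partition so far.
    """
    import pandas as pd

    if isinstance(cohort, dict):
        cohort = pd.DataFrame(cohort)
    if len(covariates) == 0:
        raise ValueError("no candidate covariates")
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"covariates not in cohort: {missing}")
    cols = {c: np.asarray(cohort[c], dtype=float) for c in covariates}
    for c, v in cols.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {c!r} contains missing/non-finite values")
    categorical = tuple(categorical)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        sub = SurvivalData(data.time[idx], data.event[idx])
        node = TreeNode(n=idx.size, events=sub.n_events, depth=depth)
        stop = None
        if idx.size < config.minsplit:
            stop = "minsplit"
        elif config.max_depth is not None and depth >= config.max_depth:
            stop = "max_depth"
        elif sub.n_events == 0:
            stop = "no_events"
        selected = None
        if stop is None:
            a = logrank_scores(sub)
            local = {c: cols[c][idx] for c in covariates}
            selected = select_split_variable(local, a, config, categorical)
            if selected is None:
                stop = "not_significant"
        if stop is None:
            name, p_adj = selected
            if name in categorical:
                cut = _best_categorical_partition(local[name], a, config.minbucket)
                if cut is None:
                    stop = "no_admissible_cut"
                else:
                    left_mask = cut[0]
            else:
                cut = best_cutpoint(local[name], a, config.minbucket)
                if cut is None:
                    stop = "no_admissible_cut"
                else:
                    left_mask = local[name] <= cut[0]
        if stop is not None:
            node.km_landmarks, node.median_survival = _leaf_stats(
                sub, config.landmark_years
            )
            node.stop_reason = stop
            return node
        node.variable = name
        if name in categorical:
            node.threshold = tuple(float(v) for v in cut[1])
        else:
            node.threshold = float(cut[0])
        node.p_adj = float(p_adj)
        node.left = build(idx[left_mask], depth + 1)
        node.right = build(idx[~left_mask], depth + 1)
        return node

    root = build(np.arange(data.n), 0)
    # number leaves left-to-right
    counter = itertools.count(1)

    def number(node):
        if node.is_leaf:
            node.leaf_id = next(counter)
        else:
            number(node.left)
            number(node.right)

    number(root)
    return SurvivalTree(root=root, config=config, covariates=list(covariates),
                        categorical=list(categorical))


def _best_categorical_partition(x, a, minbucket):
    """Exhaustive binary partition of categorical levels maximising |z|.

    Returns (left_mask, left_level_set) or None. Levels count must be
    small (enforced at encoding time).
    """
    levels = np.unique(x)
    if levels.size < 2:
        return None
    best = None
    k = levels.size
    n = x.size
    for bits in range(1, 2 ** (k - 1)):
        left_levels = [levels[j] for j in range(k) if bits >> j & 1]
        mask = np.isin(x, left_levels)
        nl = int(mask.sum())
        if nl < minbucket or n - nl < minbucket:
            continue
        res = linear_statistic(mask.astype(float), a)
        if res.degenerate:
            continue
        score = abs(res.z)
        if best is None or score > best[2]:
            best = (mask, tuple(left_levels), score)
    if best is None:
        return None
    return best[0], best[1]


def predict_leaf(tree: SurvivalTree, record) -> int:
    """Route one covariate record (mapping/Series) to its terminal leaf id.

    The split convention is ``value <= threshold`` goes left. A missing or
    non-finite split variable raises; there are no surrogate splits.
    """
    node = tree.root
    while not node.is_leaf:
        try:
            value = record[node.variable]
        except (KeyError, IndexError):
            raise KeyError(f"record is missing split variable {node.variable!r}")
        value = float(value)
        if not np.isfinite(value):
            raise ValueError(f"split variable {node.variable!r} is missing/non-finite")
        if isinstance(node.threshold, (tuple, list)):
            node = node.left if value in node.threshold else node.right
        else:
            node = node.left if value <= node.threshold else node.right
    return node.leaf_id


def predict_leaves(tree: SurvivalTree, cohort) -> np.ndarray:
    """Vectorised ``predict_leaf`` over a cohort DataFrame."""
    n = len(cohort)
    out = np.zeros(n, dtype=int)
    idx_all = np.arange(n)
    cols = {}

    def get(name):
        if name not in cols:
            if name not in cohort.columns:
                raise KeyError(f"cohort is missing split variable {name!r}")
            v = np.asarray(cohort[name], dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"split variable {name!r} has missing values")
            cols[name] = v
        return cols[name]

    def walk(node, idx):
        if node.is_leaf:
            out[idx] = node.leaf_id
            return
        v = get(node.variable)[idx]
        if isinstance(node.threshold, (tuple, list)):
            mask = np.isin(v, np.asarray(node.threshold, dtype=float))
        else:
            mask = v <= node.threshold
        walk(node.left, idx[mask])
        walk(node.right, idx[~mask])

    walk(tree.root, idx_all)
    return out
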