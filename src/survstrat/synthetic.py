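"""Synthetic cohort generator for severe secondary mitral regurgitation in HF.

No patient-level data are distributed with this package, so every
downstream stage (screening, stability selection, tree growth, subgroup
reporting, validation splits) is exercised on synthetic cohorts whose
statistical structure mirrors the published study population:

* covariate marginals match the printed baseline table (median/IQR for
  continuous variables, prevalences for binaries, level frequencies for
  categoricals), tagged by variable domain (clinical / echo / lab);
* a "truth" tree — the published 8-subgroup partition on albumin, age,
  hemoglobin, BUN and NT-proBNP — routes each patient to a leaf;
* each leaf carries a piecewise-exponential hazard; the default ladder is
  proportional hazards with the reference leaf calibrated to 85% survival
  at 6 years and the other leaves scaled by the published subgroup hazard
  ratios;
* right censoring combines uniform staggered entry, an administrative cut
  at study end and a small exponential dropout rate.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MarginalSpec",
    "TruthTree",
    "TruthNode",
    "LeafHazard",
    "CensoringSpec",
    "GeneratorSpec",
    "calibrate_exponential",
    "calibrate_piecewise",
    "sample_covariates",
    "assign_true_leaf",
    "assign_true_leaves",
    "generate_cohort",
    "simulate_leaf_cohort",
    "default_marginals",
    "default_truth_tree",
    "default_hazards",
    "default_generator_spec",
    "DEFAULT_HR_LADDER",
    "REFERENCE_LEAF",
    "WORST_LEAF",
    "write_cohort",
    "read_cohort",
]


# --------------------------------------------------------------------------
# hazard calibration


def calibrate_exponential(surv_frac: float, horizon: float) -> float:
    """Exponential rate λ with exp(−λ·horizon) = surv_frac.

    >>> round(calibrate_exponential(0.85, 6.0), 6)
    0.027086
    """
    if not (0.0 < surv_frac <= 1.0):
        raise ValueError("survival fraction must lie in (0, 1]")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return -math.log(surv_frac) / horizon


def calibrate_piecewise(s1: float, t1: float, s2: float, t2: float):
    """Two-piece exponential rates hitting S(t1)=s1 and S(t2)=s2.

    The first piece runs on [0, t1], the second on (t1, t2] and is held
    open-ended beyond t2. Survival must be non-increasing (s2 <= s1).
    """
    if not (0.0 < t1 < t2):
        raise ValueError("need 0 < t1 < t2")
    if not (0.0 < s1 <= 1.0) or not (0.0 < s2 <= 1.0):
        raise ValueError("survival fractions must lie in (0, 1]")
    if s2 > s1:
        raise ValueError("survival cannot increase: require s2 <= s1")
    rate1 = -math.log(s1) / t1
    rate2 = (math.log(s1) - math.log(s2)) / (t2 - t1)
    return rate1, rate2


# --------------------------------------------------------------------------
# domain types


_MARGINAL_KINDS = ("normal", "lognormal", "bernoulli", "categorical")
_DOMAINS = ("clinical", "echo", "lab")
_IQR_TO_SD = 1.349  # width of the central 50% of a standard normal


@dataclass(frozen=True)
class MarginalSpec:
    """One covariate's marginal law.

    ``location`` is the median for continuous kinds and the prevalence for
    bernoulli; ``scale`` is the standard deviation on the modelled scale
    (log scale for lognormal), conventionally derived from the IQR as
    (q3 − q1)/1.349.
    """

    name: str
    kind: str
    domain_tag: str
    location: float = 0.0
    scale: float = 0.0
    levels: Optional[tuple] = None
    probs: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in _MARGINAL_KINDS:
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.domain_tag not in _DOMAINS:
            raise ValueError(f"unknown domain tag {self.domain_tag!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.kind == "bernoulli" and not (0.0 <= self.location <= 1.0):
            raise ValueError("bernoulli prevalence must lie in [0, 1]")
        if self.kind == "categorical":
            if not self.levels or not self.probs or len(self.levels) != len(self.probs):
                raise ValueError("categorical marginal needs matching levels and probs")
            if abs(sum(self.probs) - 1.0) > 1e-12:
                raise ValueError("categorical probabilities must sum to 1")

    @classmethod
    def from_iqr(cls, name, kind, domain_tag, median, q1, q3):
        """Continuous marginal from a printed median (IQR) summary."""
        if kind == "normal":
            return cls(name, kind, domain_tag, location=median,
                       scale=(q3 - q1) / _IQR_TO_SD)
        if kind == "lognormal":
            return cls(name, kind, domain_tag, location=median,
                       scale=(math.log(q3) - math.log(q1)) / _IQR_TO_SD)
        raise ValueError("from_iqr only supports normal/lognormal")


@dataclass(frozen=True)
class TruthNode:
    """Internal node of the truth tree: ``variable <= threshold`` goes left."""

    variable: str
    threshold: float
    left: object  # TruthNode | int (leaf id)
    right: object


@dataclass(frozen=True)
class TruthTree:
    """Ground-truth recursive partition used by the generator."""

    root: object  # TruthNode | int

    def leaf_ids(self) -> list:
        out = []

        def walk(node):
            if isinstance(node, TruthNode):
                walk(node.left)
                walk(node.right)
            else:
                out.append(int(node))

        walk(self.root)
        return out

    def variables(self) -> list:
        seen = []

        def walk(node):
            if isinstance(node, TruthNode):
                if node.variable not in seen:
                    seen.append(node.variable)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return seen

    def validate(self, marginal_names):
        ids = self.leaf_ids()
        if len(set(ids)) != len(ids):
            raise ValueError("leaf ids must be unique")
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValueError("leaf ids must be contiguous 1..L")
        for v in self.variables():
            if v not in marginal_names:
                raise ValueError(f"truth-tree variable {v!r} has no marginal")

        def walk(node):
            if isinstance(node, TruthNode):
                if not np.isfinite(node.threshold):
                    raise ValueError("thresholds must be finite")
                walk(node.left)
                walk(node.right)

        walk(self.root)


@dataclass(frozen=True)
class LeafHazard:
    """Piecewise-constant hazard of one truth leaf.

    ``pieces`` is an ordered list of (end_time, rate); the last piece is
    treated as open-ended regardless of its end time.
    """

    leaf_id: int
    pieces: tuple  # ((end_time, rate), ...)

    def __post_init__(self):
        if len(self.pieces) == 0:
            raise ValueError("need at least one hazard piece")
        ends = [e for e, _ in self.pieces]
        rates = [r for _, r in self.pieces]
        if any(r < 0 for r in rates):
            raise ValueError("hazard rates must be >= 0")
        if any(b <= a for a, b in zip(ends, ends[1:])):
            raise ValueError("piece end times must be strictly increasing")
        object.__setattr__(self, "pieces", tuple((float(e), float(r)) for e, r in self.pieces))

    def cumulative_hazard(self, t):
        """∫_0^t λ(u) du, vectorised over t."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        start = 0.0
        for i, (end, rate) in enumerate(self.pieces):
            hi = np.inf if i == len(self.pieces) - 1 else end
            out += rate * np.clip(t - start, 0.0, hi - start)
            start = end
        return out

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw event times by inverting the cumulative hazard."""
        e = rng.exponential(size=size)  # target cumulative hazard
        out = np.full(size, np.inf)
        start = 0.0
        h0 = 0.0
        remaining = np.ones(size, dtype=bool)
        for i, (end, rate) in enumerate(self.pieces):
            last = i == len(self.pieces) - 1
            width = np.inf if last else end - start
            h1 = h0 + (rate * width if rate > 0 else 0.0)
            if rate > 0:
                hit = remaining & (e <= h1 if not last else remaining)
                out[hit] = start + (e[hit] - h0) / rate
                remaining &= ~hit
            if not last:
                start, h0 = end, h1
        return out

    @classmethod
    def exponential(cls, leaf_id, rate, horizon=np.inf):
        end = horizon if np.isfinite(horizon) else 1.0
        return cls(leaf_id=leaf_id, pieces=((end, rate),))


@dataclass(frozen=True)
class CensoringSpec:
    """Right-censoring model: staggered entry, administrative cut, dropout.

    Entry times are uniform on [0, min(entry_window, study_end)); each
    subject is administratively censored ``study_end − entry`` years after
    entry and may additionally drop out at an exponential rate per year.
    """

    entry_window: float = 10.0
    study_end: float = 10.0
    dropout_rate: float = 0.02

    def __post_init__(self):
        if self.study_end <= 0:
            raise ValueError("study_end must be > 0")
        if self.entry_window < 0 or self.dropout_rate < 0:
            raise ValueError("entry_window and dropout_rate must be >= 0")

    def sample(self, rng: np.random.Generator, size: int):
        """Censoring times and entry times (years)."""
        window = min(self.entry_window, self.study_end)
        entry = rng.uniform(0.0, window, size=size) if window > 0 else np.zeros(size)
        admin = self.study_end - entry
        if self.dropout_rate > 0:
            dropout = rng.exponential(1.0 / self.dropout_rate, size=size)
            cens = np.minimum(admin, dropout)
        else:
            cens = admin
        return cens, entry


@dataclass(frozen=True, eq=False)
class GeneratorSpec:
    """Full recipe for one synthetic cohort."""

    marginals: tuple
    truth: TruthTree
    hazards: tuple  # one LeafHazard per truth leaf
    censoring: CensoringSpec
    n: int = 1317
    seed: int = 0
    subtype_levels: tuple = ("HFpEF", "HFmrEF", "HFrEF")
    subtype_probs: tuple = (331 / 1317, 330 / 1317, 656 / 1317)
    start_year: int = 2010
    correlation: Optional[np.ndarray] = None  # optional Gaussian-copula matrix

    def __post_init__(self):
        names = [m.name for m in self.marginals]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")
        self.truth.validate(names)
        hazard_ids = sorted(h.leaf_id for h in self.hazards)
        if hazard_ids != sorted(self.truth.leaf_ids()):
            raise ValueError("every truth leaf needs exactly one hazard")
        if abs(sum(self.subtype_probs) - 1.0) > 1e-12:
            raise ValueError("subtype probabilities must sum to 1")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len(self.marginals)
            if c.shape != (k, k):
                raise ValueError("correlation matrix shape must match marginals")

    def hazard_for(self, leaf_id: int) -> LeafHazard:
        for h in self.hazards:
            if h.leaf_id == leaf_id:
                return h
        raise KeyError(leaf_id)

    @property
    def domain_map(self) -> dict:
        return {m.name: m.domain_tag for m in self.marginals}


# --------------------------------------------------------------------------
# sampling


def _marginal_from_uniform(m: MarginalSpec, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF transform of uniforms for one marginal."""
    from scipy import stats as sps

    if m.kind == "normal":
        return m.location + m.scale * sps.norm.ppf(u)
    if m.kind == "lognormal":
        return np.exp(math.log(m.location) + m.scale * sps.norm.ppf(u))
    if m.kind == "bernoulli":
        return (u < m.location).astype(float)
    if m.kind == "categorical":
        edges = np.cumsum(m.probs)
        idx = np.searchsorted(edges, u, side="right").clip(0, len(m.levels) - 1)
        return np.asarray(m.levels, dtype=float)[idx]
    raise ValueError(f"unknown marginal kind {m.kind!r}")


def sample_covariates(spec: GeneratorSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw n rows of covariates from the spec's marginals.

    Covariates are independent unless the spec carries a Gaussian-copula
    correlation matrix, in which case correlated normals are pushed
    through each marginal's inverse CDF. Deterministic in (spec, n, seed).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    k = len(spec.marginals)
    if spec.correlation is None:
        u = rng.random((n, k))
    else:
        chol = np.linalg.cholesky(np.asarray(spec.correlation, dtype=float))
        z = rng.standard_normal((n, k)) @ chol.T
        u = sps.norm.cdf(z)
    data = {}
    for j, m in enumerate(spec.marginals):
        data[m.name] = _marginal_from_uniform(m, u[:, j]) if n else np.empty(0)
    return pd.DataFrame(data, columns=[m.name for m in spec.marginals])


def assign_true_leaf(record, truth: TruthTree) -> int:
    """Route one covariate record through the truth tree (≤ goes left)."""
    node = truth.root
    while isinstance(node, TruthNode):
        try:
            value = record[node.variable]
        except (KeyError, IndexError):
            raise KeyError(f"record is missing split variable {node.variable!r}")
        value = float(value)
        if not np.isfinite(value):
            raise ValueError(f"split variable {node.variable!r} is missing")
        node = node.left if value <= node.threshold else node.right
    return int(node)


def assign_true_leaves(frame: pd.DataFrame, truth: TruthTree) -> np.ndarray:
    """Vectorised truth-tree routing over a covariate table."""
    n = len(frame)
    out = np.zeros(n, dtype=int)

    def walk(node, idx):
        if not isinstance(node, TruthNode):
            out[idx] = int(node)
            return
        v = np.asarray(frame[node.variable], dtype=float)[idx]
        if not np.all(np.isfinite(v)):
            raise ValueError(f"split variable {node.variable!r} has missing values")
        mask = v <= node.threshold
        walk(node.left, idx[mask])
        walk(node.right, idx[~mask])

    walk(truth.root, np.arange(n))
    return out


def _observe(event_time, cens_time):
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    # guard against exact zero follow-up from degenerate censoring specs
    time = np.maximum(time, 1e-9)
    return time, event


def generate_cohort(spec: GeneratorSpec, n: Optional[int] = None,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a full synthetic cohort.

    Returns a DataFrame with ``patient_id, time_years, event,
    inclusion_year, hf_subtype, true_leaf`` followed by the covariate
    columns. Event times are drawn from each patient's true-leaf hazard;
    censoring from the spec's censoring model; the observed time is the
    minimum with the usual event indicator.
    """
    n = spec.n if n is None else n
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cov_seed = int(rng.integers(0, 2**31 - 1))
    covs = sample_covariates(spec, n, cov_seed)
    leaves = assign_true_leaves(covs, spec.truth) if n else np.empty(0, dtype=int)

    event_time = np.empty(n)
    for leaf_id in spec.truth.leaf_ids():
        mask = leaves == leaf_id
        cnt = int(mask.sum())
        if cnt:
            event_time[mask] = spec.hazard_for(leaf_id).sample(rng, cnt)
    cens_time, entry = spec.censoring.sample(rng, n)
    time, event = _observe(event_time, cens_time)

    subtype = _composition_labels(rng, spec.subtype_levels, spec.subtype_probs, n)
    year = spec.start_year + np.floor(entry).astype(int)
    out = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "time_years": time,
            "event": event,
            "inclusion_year": year,
            "hf_subtype": subtype,
            "true_leaf": leaves,
        }
    )
    return pd.concat([out, covs], axis=1)


def _composition_labels(rng, levels, probs, n):
    """Labels with fixed composition (largest-remainder counts), shuffled.

    Keeps the subtype composition exact rather than multinomial, the way a
    real cohort's subtype counts are fixed quantities.
    """
    raw = np.asarray(probs) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    labels = np.repeat(np.asarray(levels, dtype=object), counts)
    return labels[rng.permutation(n)]


def simulate_leaf_cohort(hazards, n: int, seed: int,
                         censoring: Optional[CensoringSpec] = None,
                         leaf_probs=None) -> pd.DataFrame:
    """Simulate survival directly from leaf hazards, skipping covariates.

    Patients are assigned a leaf label (uniformly across the given hazards
    unless ``leaf_probs`` is supplied), draw an event time from that
    leaf's hazard, and are censored by ``censoring`` (no censoring if
    None). Useful for hazard-calibration checks and hazard-ratio recovery
    where the covariate routing is irrelevant.
    """
    hazards = list(hazards)
    rng = np.random.default_rng(seed)
    ids = np.array([h.leaf_id for h in hazards])
    if leaf_probs is None:
        leaf_probs = np.full(len(hazards), 1.0 / len(hazards))
    labels = rng.choice(ids, size=n, p=np.asarray(leaf_probs, dtype=float))
    event_time = np.empty(n)
    for h in hazards:
        mask = labels == h.leaf_id
        cnt = int(mask.sum())
        if cnt:
            event_time[mask] = h.sample(rng, cnt)
    if censoring is None:
        cens = np.full(n, np.inf)
    else:
        cens, _ = censoring.sample(rng, n)
    time, event = _observe(event_time, cens)
    return pd.DataFrame({"true_leaf": labels, "time_years": time, "event": event})


# --------------------------------------------------------------------------
# published-study defaults

REFERENCE_LEAF = 7  # best survival: albumin >40.6, HB >12.7, age <=66
WORST_LEAF = 5  # worst survival: albumin <=40.6, age >68, NT-proBNP >9,570

#: subgroup hazard ratios versus the reference subgroup (derivation cohort)
DEFAULT_HR_LADDER = {
    1: 3.14,
    2: 8.27,
    3: 13.12,
    4: 5.74,
    5: 20.38,
    6: 4.68,
    7: 1.0,
    8: 2.72,
}

#: survival-fraction anchors used to calibrate hazards: leaf -> {years: frac}
CALIBRATION_ANCHORS = {
    REFERENCE_LEAF: {1.0: 0.97, 6.0: 0.85},
    WORST_LEAF: {1.0: 0.48, 6.0: 0.11},
}


def default_marginals() -> tuple:
    """Marginals matching the published baseline table of the study cohort.

    Continuous variables use a normal law when the printed IQR is roughly
    symmetric around the median and a lognormal law for the right-skewed
    biomarkers; binaries use the printed prevalences.
    """
    M = MarginalSpec
    return (
        # clinical
        M.from_iqr("age", "normal", "clinical", 71, 61, 78),
        M("male", "bernoulli", "clinical", location=0.60),
        M.from_iqr("bmi", "normal", "clinical", 26, 24, 29),
        M("hypertension", "bernoulli", "clinical", location=0.51),
        M("hyperlipidemia", "bernoulli", "clinical", location=0.28),
        M("diabetes", "bernoulli", "clinical", location=0.21),
        M("coronary_artery_disease", "bernoulli", "clinical", location=0.49),
        M("atrial_fibrillation", "bernoulli", "clinical", location=0.37),
        M("copd", "bernoulli", "clinical", location=0.13),
        M("cerebrovascular_disease", "bernoulli", "clinical", location=0.19),
        M("peripheral_vascular_disease", "bernoulli", "clinical", location=0.23),
        # echocardiographic
        M.from_iqr("lv_end_diastolic_diameter", "normal", "echo", 53, 47, 60),
        M.from_iqr("left_atrial_diameter", "normal", "echo", 65, 60, 71),
        M.from_iqr("rv_end_diastolic_diameter", "normal", "echo", 36, 32, 40),
        M.from_iqr("right_atrial_diameter", "normal", "echo", 61, 56, 68),
        M("lv_dysfunction", "categorical", "echo",
          levels=(0.0, 1.0, 2.0, 3.0), probs=(0.218, 0.119, 0.165, 0.498)),
        M("reduced_rv_function", "bernoulli", "echo", location=0.44),
        M.from_iqr("pulmonary_artery_pressure", "normal", "echo", 53.6, 46.0, 64.8),
        # laboratory
        M.from_iqr("hemoglobin", "normal", "lab", 12.3, 11.0, 14.0),
        M.from_iqr("platelets", "normal", "lab", 216, 174, 273),
        M.from_iqr("wbc", "lognormal", "lab", 7.7, 6.2, 9.4),
        M.from_iqr("creatinine", "lognormal", "lab", 1.1, 0.9, 1.5),
        M.from_iqr("bun", "lognormal", "lab", 21.3, 15.5, 31.3),
        M.from_iqr("albumin", "normal", "lab", 37.9, 33.5, 41.6),
        M.from_iqr("bilirubin", "lognormal", "lab", 0.7, 0.5, 1.1),
        M.from_iqr("ast", "lognormal", "lab", 27.0, 21.0, 38.0),
        M.from_iqr("cholesterol", "normal", "lab", 151.0, 120.0, 183.0),
        M.from_iqr("nt_probnp", "lognormal", "lab", 3699.5, 1703.2, 8223.5),
    )


def default_truth_tree() -> TruthTree:
    """The published 8-subgroup partition (leaf ids = subgroup numbers).

    Routing is "value ≤ threshold goes left"; leaves appear 1..8 in
    left-to-right order, matching the published numbering.
    """
    N = TruthNode
    return TruthTree(
        root=N(
            "albumin",
            40.6,
            left=N(
                "age",
                68.0,
                left=N("bun", 24.1, left=1, right=2),
                right=N(
                    "nt_probnp",
                    9570.0,
                    left=N("albumin", 34.5, left=3, right=4),
                    right=5,
                ),
            ),
            right=N(
                "hemoglobin",
                12.7,
                left=6,
                right=N("age", 66.0, left=7, right=8),
            ),
        )
    )


def default_hazards(worst_leaf_two_piece: bool = False) -> tuple:
    """Default leaf hazards: the proportional-hazards ladder.

    The reference leaf is exponential with rate −ln(0.85)/6 (85% survival
    at 6 years); every other leaf multiplies that rate by its published
    hazard ratio. With ``worst_leaf_two_piece=True`` the worst leaf is
    instead calibrated as a two-piece exponential hitting its printed
    1-year and 6-year survival fractions (48% and 11%).
    """
    ref_rate = calibrate_exponential(CALIBRATION_ANCHORS[REFERENCE_LEAF][6.0], 6.0)
    hazards = []
    for leaf_id, hr in DEFAULT_HR_LADDER.items():
        if worst_leaf_two_piece and leaf_id == WORST_LEAF:
            a = CALIBRATION_ANCHORS[WORST_LEAF]
            r1, r2 = calibrate_piecewise(a[1.0], 1.0, a[6.0], 6.0)
            hazards.append(LeafHazard(leaf_id=leaf_id, pieces=((1.0, r1), (6.0, r2))))
        else:
            hazards.append(LeafHazard.exponential(leaf_id, ref_rate * hr))
    return tuple(hazards)


def default_generator_spec(n: int = 1317, seed: int = 0,
                           worst_leaf_two_piece: bool = False) -> GeneratorSpec:
    """GeneratorSpec calibrated to the published cohort."""
    return GeneratorSpec(
        marginals=default_marginals(),
        truth=default_truth_tree(),
        hazards=default_hazards(worst_leaf_two_piece=worst_leaf_two_piece),
        censoring=CensoringSpec(),
        n=n,
        seed=seed,
    )


# --------------------------------------------------------------------------
# I/O


def write_cohort(cohort: pd.DataFrame, path, domain_map: Optional[dict] = None):
    """Write a cohort CSV plus a sidecar ``<path>.meta.json`` of domain tags."""
    cohort.to_csv(path, index=False)
    if domain_map is not None:
        meta = {
            "domain_map": domain_map,
            "time_column": "time_years",
            "event_column": "event",
            "year_column": "inclusion_year",
            "subtype_column": "hf_subtype",
        }
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def read_cohort(path):
    """Read a cohort CSV; returns (frame, metadata-or-None)."""
    frame = pd.read_csv(path)
    meta = None
    import os

    meta_path = f"{path}.meta.json"
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
    return frame, meta
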