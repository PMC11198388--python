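"""End-to-end risk-stratification pipeline.

Orchestrates the full analysis on a patient-level cohort table:

1. stratified 70/30 derivation/validation split (stratified by HF subtype,
   per-stratum ceiling rounding);
2. univariate Cox screen and bootstrap stepwise stability selection on
   the derivation cohort, within the clinical / echo / lab domains;
3. conditional-inference survival tree grown on the derivation cohort
   using the union of retained covariates;
4. per-subgroup Kaplan-Meier landmarks and Cox hazard ratios versus the
   best-surviving subgroup, on the derivation cohort and — with the tree
   frozen — on the validation cohort;
5. a temporal-consistency check on two cohorts pooled from alternating
   inclusion years;
6. optional per-HF-subtype sub-analyses on the full cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .selection import SelectionReport, bootstrap_selection, univariate_screen
from .survival import SurvivalData, cox_hr_table, kaplan_meier, survival_at
from .tree import SplitConfig, SurvivalTree, grow_tree, predict_leaves

__all__ = [
    "AnalysisConfig",
    "SplitResult",
    "PipelineReport",
    "stratified_split",
    "temporal_split",
    "subgroup_report",
    "run_pipeline",
    "subtype_analysis",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the full pipeline (YAML-serialisable)."""

    alpha: float = 0.05
    minbucket: int = 95
    minsplit: Optional[int] = None
    bootstrap_b: int = 500
    selection_threshold: float = 0.85
    p_enter: float = 0.05
    p_remove: float = 0.10
    split_fraction: float = 0.7
    ties: str = "efron"
    landmark_years: tuple = (1.0, 6.0)
    seed: int = 0
    domain_map: Optional[dict] = None
    subtype_column: str = "hf_subtype"
    year_column: str = "inclusion_year"
    time_column: str = "time_years"
    event_column: str = "event"
    categorical: tuple = ()
    max_depth: Optional[int] = None
    subtype_minbucket: Optional[int] = None

    def split_config(self, minbucket: Optional[int] = None) -> SplitConfig:
        return SplitConfig(
            alpha=self.alpha,
            minbucket=self.minbucket if minbucket is None else minbucket,
            minsplit=self.minsplit if minbucket is None else None,
            adjustment="bonferroni",
            max_depth=self.max_depth,
            seed=self.seed,
            landmark_years=tuple(self.landmark_years),
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "landmark_years" in payload:
            payload["landmark_years"] = tuple(payload["landmark_years"])
        if "categorical" in payload:
            payload["categorical"] = tuple(payload["categorical"])
        return cls(**payload)

    def to_yaml(self, path=None) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class SplitResult:
    """Derivation/validation membership of a stratified split."""

    derivation_ids: np.ndarray  # positional indices into the cohort
    validation_ids: np.ndarray
    stratum_counts: pd.DataFrame
    fraction: float
    seed: int


def stratified_split(cohort: pd.DataFrame, fraction: float, stratum_column: str,
                     seed: int = 0) -> SplitResult:
    """Stratified random split without replacement.

    Within each stratum, ``ceil(fraction * n)`` patients are drawn into
    the derivation cohort; the remainder form the validation cohort. The
    ceiling convention reproduces a 923/394 split from strata of sizes
    331/330/656 at fraction 0.7.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    if stratum_column not in cohort.columns:
        raise ValueError(f"stratum column {stratum_column!r} not in cohort")
    rng = np.random.default_rng(seed)
    deriv, valid, rows = [], [], []
    strata = pd.unique(cohort[stratum_column])
    for s in strata:
        idx = np.flatnonzero((cohort[stratum_column] == s).to_numpy())
        if idx.size == 0:
            raise ValueError(f"empty stratum {s!r}")
        k = math.ceil(fraction * idx.size)
        perm = rng.permutation(idx.size)
        deriv.append(idx[perm[:k]])
        valid.append(idx[perm[k:]])
        rows.append({"stratum": s, "n": idx.size, "derivation": k,
                     "validation": idx.size - k})
    return SplitResult(
        derivation_ids=np.sort(np.concatenate(deriv)),
        validation_ids=np.sort(np.concatenate(valid)),
        stratum_counts=pd.DataFrame(rows),
        fraction=fraction,
        seed=seed,
    )


def temporal_split(cohort: pd.DataFrame, year_column: str = "inclusion_year"):
    """Pool patients into two cohorts by alternating inclusion year.

    Distinct years are sorted; even-indexed years go to cohort A,
    odd-indexed to cohort B. Requires at least two distinct years.
    """
    if year_column not in cohort.columns:
        raise ValueError(f"year column {year_column!r} not in cohort")
    years = np.sort(pd.unique(cohort[year_column]))
    if years.size < 2:
        raise ValueError("temporal split needs at least two distinct inclusion years")
    a_years = set(years[::2].tolist())
    mask = cohort[year_column].isin(a_years).to_numpy()
    return cohort.loc[mask], cohort.loc[~mask]


def _survival_from(cohort: pd.DataFrame, config: AnalysisConfig) -> SurvivalData:
    return SurvivalData(
        np.asarray(cohort[config.time_column], dtype=float),
        np.asarray(cohort[config.event_column], dtype=int),
    )


def subgroup_report(tree: SurvivalTree, cohort: pd.DataFrame,
                    config: AnalysisConfig,
                    reference: Optional[int] = None) -> pd.DataFrame:
    """Per-subgroup summary table: n, events, KM landmarks, HR ladder.

    Patients are routed through the (frozen) tree; the reference subgroup
    is the leaf with the highest Kaplan-Meier survival at the last
    landmark (falling back to the largest follow-up time common to all
    leaves when no landmark is reached); hazard ratios come from a Cox
    model with one-hot leaf membership against the reference. Rows are
    ordered by ascending HR. Leaves without events are flagged
    non-estimable rather than failing.
    """
    leaves = predict_leaves(tree, cohort)
    data = _survival_from(cohort, config)
    criteria = tree.leaf_criteria()
    landmarks = tuple(config.landmark_years)
    ids = np.unique(leaves)

    km_rows = {}
    for leaf in ids:
        mask = leaves == leaf
        sub = SurvivalData(data.time[mask], data.event[mask])
        km = kaplan_meier(sub)
        km_rows[leaf] = {
            "n": int(mask.sum()),
            "events": sub.n_events,
            **{f"km_{t:g}y": float(survival_at(km, t)) for t in landmarks},
            "_curve": km,
            "_max_t": float(sub.time.max()),
        }
    if reference is None:
        horizon = landmarks[-1]
        common = min(r["_max_t"] for r in km_rows.values())
        ref_t = horizon if all(r["_max_t"] >= horizon for r in km_rows.values()) else common
        reference = max(
            km_rows, key=lambda leaf: survival_at(km_rows[leaf]["_curve"], ref_t)
        )
    if len(ids) > 1:
        hr = cox_hr_table(leaves, data, reference=reference, ties=config.ties)
        hr = hr.set_index("group")
    else:
        hr = pd.DataFrame(
            {"hr": [1.0], "ci_low": [np.nan], "ci_high": [np.nan], "p": [np.nan],
             "reference": [True], "estimable": [True]},
            index=pd.Index(ids, name="group"),
        )
    rows = []
    for leaf in ids:
        r = km_rows[leaf]
        h = hr.loc[leaf]
        rows.append(
            {
                "subgroup": int(leaf),
                "criteria": criteria.get(int(leaf), ""),
                "n": r["n"],
                "events": r["events"],
                **{k: v for k, v in r.items() if k.startswith("km_")},
                "hr": float(h["hr"]),
                "ci_low": float(h["ci_low"]),
                "ci_high": float(h["ci_high"]),
                "p": float(h["p"]),
                "reference": bool(h["reference"]),
                "estimable": bool(h["estimable"]),
            }
        )
    out = pd.DataFrame(rows).sort_values("hr", na_position="last", kind="stable")
    return out.reset_index(drop=True)


@dataclass
class PipelineReport:
    """Everything the pipeline computed, plus provenance."""

    config: AnalysisConfig
    split: SplitResult
    screen: pd.DataFrame
    selection: SelectionReport
    tree: SurvivalTree
    derivation_table: pd.DataFrame
    validation_table: pd.DataFrame
    temporal_tables: tuple  # (cohort A table, cohort B table)
    n_total: int
    version: str = __version__

    def write(self, out_dir):
        """Write the report artefacts (tree.json/tree.txt + TSV tables)."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.tree.to_json(os.path.join(out_dir, "tree.json"))
        with open(os.path.join(out_dir, "tree.txt"), "w") as fh:
            fh.write(self.tree.format_text() + "\n")
        self.screen.to_csv(os.path.join(out_dir, "screen.tsv"), sep="\t", index=False)
        self.selection.to_frame().to_csv(
            os.path.join(out_dir, "selection.tsv"), sep="\t", index=False
        )
        self.derivation_table.to_csv(
            os.path.join(out_dir, "subgroups_derivation.tsv"), sep="\t", index=False
        )
        self.validation_table.to_csv(
            os.path.join(out_dir, "subgroups_validation.tsv"), sep="\t", index=False
        )
        temporal = pd.concat(
            [t.assign(temporal_cohort=name) for t, name in
             zip(self.temporal_tables, ("A", "B"))],
            ignore_index=True,
        )
        temporal.to_csv(os.path.join(out_dir, "temporal.tsv"), sep="\t", index=False)
        self.config.to_yaml(os.path.join(out_dir, "config.yaml"))
        with open(os.path.join(out_dir, "run.log"), "w") as fh:
            fh.write(
                f"survstrat {self.version}\n"
                f"n_total={self.n_total} derivation={self.split.derivation_ids.size} "
                f"validation={self.split.validation_ids.size}\n"
                f"selected covariates: {', '.join(self.selection.union)}\n"
                f"tree leaves: {self.tree.n_leaves}\n"
            )


def _validate_schema(cohort: pd.DataFrame, config: AnalysisConfig, domain_map: dict):
    problems = []
    for col in (config.time_column, config.event_column):
        if col not in cohort.columns:
            problems.append(f"missing column {col!r}")
    for var in domain_map:
        if var not in cohort.columns:
            problems.append(f"missing covariate {var!r}")
        elif not np.all(np.isfinite(np.asarray(cohort[var], dtype=float))):
            problems.append(f"covariate {var!r} has missing values (complete cases required)")
    if config.time_column in cohort.columns:
        t = np.asarray(cohort[config.time_column], dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            problems.append("follow-up times must be finite and positive")
    if problems:
        raise ValueError("cohort schema violations: " + "; ".join(problems))


def run_pipeline(cohort: pd.DataFrame, config: AnalysisConfig) -> PipelineReport:
    """Run the full derivation/validation analysis on a cohort table.

    The domain map defaults to every numeric column that is neither an
    outcome nor a bookkeeping column, which only works for cohorts written
    by the synthetic generator; real tables should set
    ``config.domain_map`` explicitly.
    """
    domain_map = config.domain_map
    if domain_map is None:
        from .synthetic import default_generator_spec

        domain_map = default_generator_spec().domain_map
    _validate_schema(cohort, config, domain_map)
    cohort = cohort.reset_index(drop=True)

    split = stratified_split(cohort, config.split_fraction,
                             config.subtype_column, seed=config.seed)
    derivation = cohort.iloc[split.derivation_ids].reset_index(drop=True)
    validation = cohort.iloc[split.validation_ids].reset_index(drop=True)
    deriv_data = _survival_from(derivation, config)

    variables = list(domain_map)
    screen = univariate_screen(derivation, variables, deriv_data, ties=config.ties)
    selection = bootstrap_selection(
        derivation, domain_map, deriv_data, b=config.bootstrap_b,
        threshold=config.selection_threshold, p_enter=config.p_enter,
        p_remove=config.p_remove, seed=config.seed, ties=config.ties,
    )
    covariates = selection.union
    if not covariates:
        # no variable cleared the stability threshold; fall back to the
        # screen's nominally significant variables so the tree stage can
        # still run (it will stop at the root if nothing is informative)
        screened = screen.loc[~screen["failed"] & (screen["p"] < config.alpha)]
        covariates = list(screened["variable"])
    if not covariates:
        covariates = variables
    categorical = tuple(c for c in config.categorical if c in covariates)
    tree = grow_tree(derivation, covariates, deriv_data,
                     config.split_config(), categorical=categorical)

    derivation_table = subgroup_report(tree, derivation, config)
    ref = int(derivation_table.loc[derivation_table["reference"], "subgroup"].iloc[0])
    validation_table = subgroup_report(tree, validation, config, reference=ref)
    coh_a, coh_b = temporal_split(cohort, config.year_column)
    temporal_tables = (
        subgroup_report(tree, coh_a, config, reference=ref),
        subgroup_report(tree, coh_b, config, reference=ref),
    )
    return PipelineReport(
        config=config,
        split=split,
        screen=screen,
        selection=selection,
        tree=tree,
        derivation_table=derivation_table,
        validation_table=validation_table,
        temporal_tables=temporal_tables,
        n_total=len(cohort),
    )


def subtype_analysis(cohort: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Selection + tree + subgroup table per HF subtype, on the full cohort.

    No internal split is performed (subtype samples are too small to
    split); the minimum leaf size is scaled to the subtype's share of the
    cohort unless ``config.subtype_minbucket`` overrides it.
    """
    domain_map = config.domain_map
    if domain_map is None:
        from .synthetic import default_generator_spec

        domain_map = default_generator_spec().domain_map
    _validate_schema(cohort, config, domain_map)
    out = {}
    n_total = len(cohort)
    for subtype in pd.unique(cohort[config.subtype_column]):
        sub = cohort.loc[cohort[config.subtype_column] == subtype].reset_index(drop=True)
        data = _survival_from(sub, config)
        if config.subtype_minbucket is not None:
            minbucket = config.subtype_minbucket
        else:
            minbucket = max(30, round(config.minbucket * len(sub) / n_total))
        selection = bootstrap_selection(
            sub, domain_map, data, b=config.bootstrap_b,
            threshold=config.selection_threshold, p_enter=config.p_enter,
            p_remove=config.p_remove, seed=config.seed, ties=config.ties,
        )
        covariates = selection.union or list(domain_map)
        categorical = tuple(c for c in config.categorical if c in covariates)
        tree = grow_tree(sub, covariates, data,
                         config.split_config(minbucket=minbucket),
                         categorical=categorical)
        out[subtype] = {
            "n": len(sub),
            "selection": selection,
            "tree": tree,
            "table": subgroup_report(tree, sub, config),
        }
    return out
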