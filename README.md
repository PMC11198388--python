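# survstrat

Survival-tree risk stratification for heart-failure cohorts with severe
secondary mitral regurgitation (sMR) — a reusable, tested Python
implementation of the full analysis workflow: univariate Cox screening,
bootstrap stepwise stability selection within variable domains,
conditional-inference survival-tree growth under a permutation-test
framework, per-subgroup Kaplan-Meier / Cox reporting, and internal plus
temporal validation. A calibrated synthetic cohort generator makes every
stage runnable and testable without access to patient data.

It is written for biostatisticians and clinical-research data scientists
who want the method as an importable library rather than a one-off script.

## The method

Patients with severe sMR across the heart-failure spectrum form a
heterogeneous risk population. The workflow stratifies them into survival
subgroups in two stages:

**Variable selection.** Within each variable domain (clinical,
echocardiographic, laboratory), forward/backward stepwise Cox models are
refitted on B = 500 bootstrap resamples of the derivation cohort; a
covariate is kept when it enters at least 85% of the resampled models.

**Tree growth.** A conditional-inference survival tree partitions the
cohort on the retained covariates. At each node the per-subject log-rank
scores

&nbsp;&nbsp;&nbsp;&nbsp;aᵢ = δᵢ − Λ̂(tᵢ)

(event indicator minus Nelson-Aalen cumulative hazard) are recomputed, and
each covariate g is tested through the linear statistic T = Σ gᵢ aᵢ
standardised by its exact permutation-null moments (the Strasser–Weber
framework):

&nbsp;&nbsp;&nbsp;&nbsp;E[T] = (Σ gᵢ) ā, &nbsp; Var[T] = n/(n−1) · V_a · (Σ gᵢ² − (Σ gᵢ)²/n).

The most significant covariate (Bonferroni-adjusted across candidates)
splits the node at the cutpoint maximising |z| of the two-sample statistic;
growth stops when the adjusted p fails α = 0.05 or a child would fall below
the minimum leaf size (95 patients by default). Each terminal subgroup is
then summarised by Kaplan-Meier survival at 1 and 6 years and a Cox hazard
ratio against the best-surviving subgroup, on the derivation cohort and —
with the tree frozen — on the validation cohort.

All estimators (Nelson-Aalen, Kaplan-Meier with Greenwood variance, Cox
partial likelihood with Efron/Breslow ties and Wald inference) are
implemented in the package and cross-checked against established survival
libraries in the test suite. See `docs/methods.md` for the full model
account, defaults, and limitations.

## Worked example

Grow a tree on a synthetic 5,000-patient cohort drawn from the calibrated
generator defaults (`examples/03_grow_survival_tree.py`):

```python
import survstrat as ss

spec = ss.default_generator_spec(n=5000, seed=0)
cohort = ss.generate_cohort(spec)
data = ss.SurvivalData(cohort["time_years"].to_numpy(), cohort["event"].to_numpy())
tree = ss.grow_tree(cohort, [m.name for m in spec.marginals], data,
                    ss.SplitConfig(alpha=0.05, minbucket=150),
                    categorical=("lv_dysfunction",))
print(tree.format_text())
```

```
albumin ≤40.5829 (p_adj=3.43e-68, n=5000)
  age ≤67.6777 (p_adj=1.72e-33, n=3336)
    bun ≤24.1296 (p_adj=4.07e-22, n=1306)
      leaf 1: n=755, events=221, S(1y)=0.93, S(6y)=0.61
    bun >24.1296
      leaf 2: n=551, events=304, S(1y)=0.80, S(6y)=0.24
  age >67.6777
    albumin ≤34.2958 (p_adj=9.97e-19, n=2030)
      leaf 3: n=851, events=619, S(1y)=0.65, S(6y)=0.09
    albumin >34.2958
      nt_probnp ≤9557.47 (p_adj=5.28e-13, n=1179)
        leaf 4: n=918, events=411, S(1y)=0.85, S(6y)=0.40
      nt_probnp >9557.47
        leaf 5: n=261, events=217, S(1y)=0.56, S(6y)=0.04
albumin >40.5829
  hemoglobin ≤12.8058 (p_adj=2e-06, n=1664)
    leaf 6: n=997, events=399, S(1y)=0.89, S(6y)=0.48
  hemoglobin >12.8058
    age ≤65.7916 (p_adj=3.1e-06, n=667)
      leaf 7: n=222, events=19, S(1y)=0.99, S(6y)=0.88
    age >65.7916
      leaf 8: n=445, events=126, S(1y)=0.92, S(6y)=0.61
```

The fitted tree rediscovers the generator's 8-subgroup truth: an albumin
split near 40.6 g/L at the root, then age / BUN / NT-proBNP on the
low-albumin side and hemoglobin / age on the high-albumin side. Each leaf
line shows its size, deaths, and Kaplan-Meier survival at the two landmark
years — leaf 7 (young, high hemoglobin, high albumin) retains 88% survival
at 6 years while leaf 5 (older, hypoalbuminaemic, very high NT-proBNP) is
down to 4%.

The other example scripts cover cohort simulation, the core estimators,
stability selection, and the end-to-end pipeline with validation tables.
A thin CLI mirrors the stages:

```bash
survstrat simulate --n 1317 --seed 7 --out cohort.csv
survstrat fit --cohort cohort.csv --out report/
survstrat validate --tree report/tree.json --cohort other.csv
```

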