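"""Covariate-adjusted group analyses of the subject feature table.

The statistical pipeline compares frail and pre-frail subjects against a
non-frail reference on a per-subject feature table:

* demographics by one-way ANOVA (continuous) and chi-square (categorical);
* WMH volumes, transformed ln(100 · V ml), by OLS adjusted for age, sex and
  intracranial volume;
* WMH shape features by OLS adjusted for age and sex (solidity transformed
  ln(100 · solidity)); secondary models add ln-volume to test volume
  independence, reporting the attenuation ratio;
* lacunar-infarct presence by logistic regression (odds-ratio scale)
  adjusted for age and sex;
* exploratory per-component models (each of the five frailty components as
  the exposure) for the features that showed group differences;
* Pearson correlation of ln-volume with gray-matter and deep-WM perfusion.

The module follows the statsmodels convention: :class:`FrailtySVDModel` is
built from a DataFrame, ``fit()`` returns :class:`FrailtySVDResults` with
the estimates, 95% intervals, p-values, per-model subject counts and a
``summary()`` table.  Confidence intervals are normal-theory Wald intervals;
no multiple-testing correction is applied (each contrast is reported at its
own two-sided p-value against the 0.05 convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import frailty as fr

logger = logging.getLogger(__name__)

SIGNIFICANCE = 0.05

FRAIL_TERM = "frail_vs_nonfrail"
PREFRAIL_TERM = "prefrail_vs_nonfrail"

#: required columns for the full pipeline
REQUIRED_COLUMNS = (
    "group",
    "age",
    "sex",
    "icv_ml",
    "vol_total_ml",
    "vol_pvconf_ml",
    "vol_deep_ml",
    "lacunar_present",
)


@dataclass
class RegressionResult:
    """One fitted contrast: coefficient (or odds ratio), Wald 95% CI,
    two-sided p, and the number of subjects used after listwise deletion."""

    term: str
    estimate: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    n: int
    outcome: str
    scale: str = "beta"  # "beta" | "odds_ratio"
    outcome_transform: str = "identity"
    flag: Optional[str] = None  # e.g. "separation"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def transform_volume(v_ml):
    """ln(100 · V) for a volume in ml; the transform used for all WMH-volume
    outcomes.  Negative volumes are an error; zero volumes return NaN and are
    excluded from volume models by listwise deletion (no epsilon offset)."""
    v = np.asarray(v_ml, float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.where(v > 0, np.log(100.0 * v), np.nan)
    return float(out) if np.isscalar(v_ml) else out


def _group_indicators(df: pd.DataFrame) -> pd.DataFrame:
    g = df["group"].astype(str)
    bad = set(g.unique()) - set(fr.GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return pd.DataFrame(
        {
            "I_frail": (g == fr.FRAIL).astype(float),
            "I_prefrail": (g == fr.PRE_FRAIL).astype(float),
        },
        index=df.index,
    )


def _design(
    df: pd.DataFrame,
    outcome: pd.Series,
    exposures: pd.DataFrame,
    covariates: Sequence[str],
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Assemble y, X with intercept; listwise deletion with count logged."""
    X = pd.concat([exposures, df[list(covariates)].astype(float)], axis=1)
    keep = outcome.notna() & X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("listwise deletion dropped %d of %d rows", n_dropped, len(df))
    y = outcome[keep].astype(float)
    X = sm.add_constant(X[keep], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"most collinear columns: {worst}"
        )
    return y, X, int(keep.sum())


def _contrast_results(
    fit, terms: dict[str, str], n: int, outcome: str, transform: str
) -> dict[str, RegressionResult]:
    ci = fit.conf_int()
    out = {}
    for col, term in terms.items():
        out[term] = RegressionResult(
            term=term,
            estimate=float(fit.params[col]),
            ci_low=float(ci.loc[col, 0]),
            ci_high=float(ci.loc[col, 1]),
            p_value=float(fit.pvalues[col]),
            n=n,
            outcome=outcome,
            outcome_transform=transform,
        )
    return out


def fit_linear(
    df: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("age", "sex"),
    transform: str = "identity",
    extra_covariates: Optional[pd.DataFrame] = None,
) -> dict[str, RegressionResult]:
    """OLS of an outcome on group indicators (non-frail reference) plus
    covariates.  ``transform`` may be ``identity`` or ``ln100`` (the WMH
    volume/solidity transform).  Contrasts present in the data are returned;
    an empty group's contrast is omitted with a warning."""
    y = df[outcome]
    if transform == "ln100":
        y = pd.Series(transform_volume(y.to_numpy()), index=df.index)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    ind = _group_indicators(df)
    exposures = ind
    if extra_covariates is not None:
        exposures = pd.concat([ind, extra_covariates], axis=1)
    terms = {}
    for col, term, grp in (
        ("I_frail", FRAIL_TERM, fr.FRAIL),
        ("I_prefrail", PREFRAIL_TERM, fr.PRE_FRAIL),
    ):
        if (df["group"] == grp).any():
            terms[col] = term
        else:
            logger.warning("group %s is empty; contrast %s omitted", grp, term)
            exposures = exposures.drop(columns=col)
    y2, X, n = _design(df, y, exposures, covariates)
    fit = sm.OLS(y2, X).fit()
    tname = "ln(100*x)" if transform == "ln100" else "identity"
    return _contrast_results(fit, terms, n, outcome, tname)


def fit_logistic(
    df: pd.DataFrame,
    outcome: str = "lacunar_present",
    covariates: Sequence[str] = ("age", "sex"),
) -> dict[str, RegressionResult]:
    """Logistic regression on the group indicators; estimates reported as
    odds ratios with Wald 95% CIs.  Complete separation is flagged and the
    interval reported as unavailable rather than a spurious number."""
    y = df[outcome].astype(float)
    if y.dropna().nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has a single class; cannot fit")
    ind = _group_indicators(df)
    terms = {
        col: term
        for col, term, grp in (
            ("I_frail", FRAIL_TERM, fr.FRAIL),
            ("I_prefrail", PREFRAIL_TERM, fr.PRE_FRAIL),
        )
        if (df["group"] == grp).any()
    }
    exposures = ind[list(terms)]
    y2, X, n = _design(df, y, exposures, covariates)
    separated = False
    try:
        fit = sm.Logit(y2, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            separated = True
    except Exception:  # PerfectSeparationError and kin
        separated = True
    out: dict[str, RegressionResult] = {}
    if separated:
        for term in terms.values():
            out[term] = RegressionResult(
                term=term, estimate=math.nan, ci_low=None, ci_high=None,
                p_value=None, n=n, outcome=outcome, scale="odds_ratio",
                flag="separation",
            )
        return out
    ci = fit.conf_int()
    big = np.abs(fit.params.drop("const")).max() > 15  # quasi-separation guard
    for col, term in terms.items():
        out[term] = RegressionResult(
            term=term,
            estimate=float(np.exp(fit.params[col])),
            ci_low=None if big else float(np.exp(ci.loc[col, 0])),
            ci_high=None if big else float(np.exp(ci.loc[col, 1])),
            p_value=float(fit.pvalues[col]),
            n=n,
            outcome=outcome,
            scale="odds_ratio",
            flag="separation" if big else None,
        )
    return out


def fit_shape_secondary(
    df: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("age", "sex"),
    transform: str = "identity",
) -> dict[str, dict]:
    """Volume-adjusted secondary model for a shape feature.

    Fits the age/sex-adjusted model and the same model with ln(100 · total
    WMH volume) added; reports both estimates and the attenuation ratio
    beta_adjusted / beta_unadjusted per contrast."""
    base = fit_linear(df, outcome, covariates, transform)
    lnvol = pd.DataFrame(
        {"ln_vol_total": transform_volume(df["vol_total_ml"].to_numpy())},
        index=df.index,
    )
    adj = fit_linear(df, outcome, covariates, transform, extra_covariates=lnvol)
    out = {}
    for term in base:
        b0, b1 = base[term].estimate, adj[term].estimate
        out[term] = {
            "unadjusted": base[term],
            "adjusted": adj[term],
            "attenuation": (b1 / b0) if b0 not in (0.0,) else math.nan,
        }
    return out


def fit_component_exploratory(
    df: pd.DataFrame,
    outcome: str,
    component: str,
    covariates: Sequence[str] = ("age", "sex"),
    transform: str = "identity",
) -> RegressionResult:
    """Linear model of a feature on one frailty component (0/1) plus
    covariates; used for features with between-group differences."""
    if component not in fr.COMPONENTS:
        raise ValueError(f"component must be one of {fr.COMPONENTS}")
    y = df[outcome]
    if transform == "ln100":
        y = pd.Series(transform_volume(y.to_numpy()), index=df.index)
    exposures = pd.DataFrame({component: df[component].astype(float)}, index=df.index)
    y2, X, n = _design(df, y, exposures, covariates)
    fit = sm.OLS(y2, X).fit()
    ci = fit.conf_int()
    return RegressionResult(
        term=component,
        estimate=float(fit.params[component]),
        ci_low=float(ci.loc[component, 0]),
        ci_high=float(ci.loc[component, 1]),
        p_value=float(fit.pvalues[component]),
        n=n,
        outcome=outcome,
        outcome_transform="ln(100*x)" if transform == "ln100" else "identity",
    )


# ---------------------------------------------------------------------------
# demographics

CONTINUOUS_DEMOGRAPHICS = ("age", "bmi")
MEDIAN_IQR_DEMOGRAPHICS = ("mmse",)
CATEGORICAL_DEMOGRAPHICS = (
    "sex",
    "depressive_symptoms",
    "obesity",
    "diabetes",
    "hypertension",
    "hyperlipidemia",
    "smoker",
    "tia_cva",
    "lacunar_present",
)


def _anova_p(groups: list[np.ndarray]) -> float:
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return math.nan
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 1.0  # identical groups: F = 0 boundary
    return float(stats.f_oneway(*groups).pvalue)


def _chi2_p(table: np.ndarray) -> tuple[float, Optional[str]]:
    table = table[:, table.sum(axis=0) > 0]
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return math.nan, "degenerate_table"
    res = stats.chi2_contingency(table, correction=False)
    flag = "zero_expected_count" if (res.expected_freq == 0).any() else None
    return float(res.pvalue), flag


def demographics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-group cohort description with omnibus tests.

    Continuous variables: mean ± sd, one-way ANOVA p.  MMSE: median (IQR),
    ANOVA p.  Categorical variables: n (%), chi-square p (flagged when a
    cell's expected count is zero).  Obesity and depressive symptoms are
    derived from BMI and HADS when not already present."""
    df = df.copy()
    if "obesity" not in df and "bmi" in df:
        df["obesity"] = (df["bmi"] >= fr.OBESITY_BMI).astype(int)
    if "depressive_symptoms" not in df and "hads_depression" in df:
        df["depressive_symptoms"] = (
            df["hads_depression"] >= fr.HADS_DEPRESSION_CUTOFF
        ).astype(int)

    groups = [g for g in (fr.FRAIL, fr.PRE_FRAIL, fr.NON_FRAIL) if (df["group"] == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    sub = {g: df[df["group"] == g] for g in groups}

    rows = []
    for var in CONTINUOUS_DEMOGRAPHICS:
        if var not in df:
            continue
        vals = [sub[g][var].to_numpy(float) for g in groups]
        row = {"variable": var, "kind": "mean_sd"}
        for g, v in zip(groups, vals):
            v = v[np.isfinite(v)]
            row[g] = f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
        row["p_value"] = _anova_p(vals)
        row["flag"] = None
        rows.append(row)
    for var in MEDIAN_IQR_DEMOGRAPHICS:
        if var not in df:
            continue
        vals = [sub[g][var].to_numpy(float) for g in groups]
        row = {"variable": var, "kind": "median_iqr"}
        for g, v in zip(groups, vals):
            q1, med, q3 = np.percentile(v[np.isfinite(v)], [25, 50, 75])
            row[g] = f"{med:.0f} ({q1:.0f}, {q3:.0f})"
        row["p_value"] = _anova_p(vals)
        row["flag"] = None
        rows.append(row)
    for var in CATEGORICAL_DEMOGRAPHICS:
        if var not in df:
            continue
        counts = np.array(
            [
                [
                    int((sub[g][var] == level).sum())
                    for level in (0, 1)
                ]
                for g in groups
            ]
        )
        row = {"variable": var, "kind": "n_pct"}
        for g, (n0, n1) in zip(groups, counts):
            total = n0 + n1
            pct = 100.0 * n1 / total if total else math.nan
            row[g] = f"{n1} ({pct:.0f}%)"
        p, flag = _chi2_p(counts)
        row["p_value"] = p
        row["flag"] = flag
        rows.append(row)
    if "asa" in df:
        levels = sorted(df["asa"].dropna().unique())
        counts = np.array(
            [[int((sub[g]["asa"] == lev).sum()) for lev in levels] for g in groups]
        )
        p, flag = _chi2_p(counts)
        rows.append(
            {
                "variable": "asa",
                "kind": "n_pct",
                **{
                    g: "/".join(str(c) for c in counts[i])
                    for i, g in enumerate(groups)
                },
                "p_value": p,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def correlate_volume_perfusion(
    df: pd.DataFrame, perfusion_col: str = "gm_cbf"
) -> tuple[float, float, int]:
    """Pearson correlation of ln(100 · total WMH volume) with a perfusion
    column; returns (r, two-sided p, n pairs)."""
    lnv = transform_volume(df["vol_total_ml"].to_numpy())
    perf = df[perfusion_col].to_numpy(float)
    keep = np.isfinite(lnv) & np.isfinite(perf)
    if keep.sum() < 3:
        raise ValueError("need >= 3 complete pairs for a correlation")
    x, y = lnv[keep], perf[keep]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the correlated variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(keep.sum())


# ---------------------------------------------------------------------------
# Model / Results

#: (column, transform, extra adjustment) per modelled outcome
VOLUME_OUTCOMES = ("vol_total_ml", "vol_pvconf_ml", "vol_deep_ml")
SHAPE_OUTCOMES = (
    ("solidity_pvconf", "ln100"),
    ("convexity_pvconf", "identity"),
    ("concavity_index_pvconf", "identity"),
    ("fractal_dimension_pvconf", "identity"),
    ("eccentricity_deep", "identity"),
    ("fractal_dimension_deep", "identity"),
)
PERFUSION_OUTCOMES = ("gm_cbf", "deepwm_cbf", "spatial_cov")
EXPLORATORY_OUTCOMES = (
    ("vol_total_ml", "ln100", True),
    ("concavity_index_pvconf", "identity", False),
    ("fractal_dimension_pvconf", "identity", False),
)


class FrailtySVDModel:
    """The full statistical pipeline as a model object.

    Parameters
    ----------
    cohort:
        Subject feature table (see :data:`frailsvd.cohort.COLUMN_DICTIONARY`).
    significance:
        Two-sided significance convention used in the summary (default 0.05).
    """

    def __init__(self, cohort: pd.DataFrame, significance: float = SIGNIFICANCE):
        missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort table is missing required columns: {missing}")
        if cohort["subject_id"].duplicated().any() if "subject_id" in cohort else False:
            raise ValueError("duplicated subject ids")
        self.cohort = cohort.reset_index(drop=True)
        self.significance = significance

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "FrailtySVDModel":
        return cls(df, **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "FrailtySVDModel":
        return cls(pd.read_csv(path), **kw)

    def fit(self) -> "FrailtySVDResults":
        df = self.cohort
        results = FrailtySVDResults(
            n_subjects=len(df), significance=self.significance
        )
        results.demographics = demographics_table(df)

        for outcome in VOLUME_OUTCOMES:
            results.volume_models[outcome] = fit_linear(
                df, outcome, covariates=("age", "sex", "icv_ml"), transform="ln100"
            )
        for outcome, tname in SHAPE_OUTCOMES:
            if outcome in df:
                results.shape_models[outcome] = fit_linear(
                    df, outcome, covariates=("age", "sex"), transform=tname
                )
        for outcome in PERFUSION_OUTCOMES:
            if outcome in df and df[outcome].notna().sum() > 4:
                results.perfusion_models[outcome] = fit_linear(
                    df, outcome, covariates=("age", "sex")
                )
        results.lacunar_models = fit_logistic(df)
        for outcome, tname in SHAPE_OUTCOMES:
            if outcome in df and outcome.endswith("_pvconf"):
                results.secondary_models[outcome] = fit_shape_secondary(
                    df, outcome, transform=tname
                )
        for outcome, tname, add_icv in EXPLORATORY_OUTCOMES:
            if outcome not in df:
                continue
            cov = ("age", "sex", "icv_ml") if add_icv else ("age", "sex")
            results.exploratory_models[outcome] = {
                comp: fit_component_exploratory(df, outcome, comp, cov, tname)
                for comp in fr.COMPONENTS
                if comp in df
            }
        for col in ("gm_cbf", "deepwm_cbf"):
            if col in df and df[col].notna().sum() >= 3:
                try:
                    results.correlations[col] = correlate_volume_perfusion(df, col)
                except ValueError:
                    pass

        # per-model exclusion bookkeeping against the input n
        for section in (
            results.volume_models,
            results.shape_models,
            results.perfusion_models,
        ):
            for outcome, contrasts in section.items():
                any_res = next(iter(contrasts.values()))
                results.exclusions[any_res.outcome] = len(df) - any_res.n
        return results


@dataclass
class FrailtySVDResults:
    """Container for every fitted table; produced by ``FrailtySVDModel.fit``."""

    n_subjects: int
    significance: float = SIGNIFICANCE
    demographics: Optional[pd.DataFrame] = None
    volume_models: dict = field(default_factory=dict)
    shape_models: dict = field(default_factory=dict)
    perfusion_models: dict = field(default_factory=dict)
    lacunar_models: dict = field(default_factory=dict)
    secondary_models: dict = field(default_factory=dict)
    exploratory_models: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)

    def _iter_results(self):
        for section, models in (
            ("volume", self.volume_models),
            ("shape", self.shape_models),
            ("perfusion", self.perfusion_models),
        ):
            for outcome, contrasts in models.items():
                for res in contrasts.values():
                    yield section, res
        for res in self.lacunar_models.values():
            yield "lacunar", res
        for outcome, contrasts in self.secondary_models.items():
            for term, d in contrasts.items():
                yield "secondary_adjusted", d["adjusted"]
        for outcome, comps in self.exploratory_models.items():
            for res in comps.values():
                yield "exploratory", res

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for section, res in self._iter_results():
            row = res.to_dict()
            row["section"] = section
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Frailty vs MRI markers of cerebral small vessel disease",
            f"subjects: {self.n_subjects}; significance convention: "
            f"two-sided p < {self.significance} (no multiplicity correction)",
            "",
        ]
        frame = self.to_frame()
        if frame.empty:
            return "\n".join(lines + ["(no fitted models)"])
        for section, part in frame.groupby("section", sort=False):
            lines.append(f"[{section}]")
            for _, r in part.iterrows():
                star = (
                    "*"
                    if r["p_value"] is not None
                    and np.isfinite(r["p_value"])
                    and r["p_value"] < self.significance
                    else " "
                )
                ci = (
                    f"({r['ci_low']:.3f}, {r['ci_high']:.3f})"
                    if r["ci_low"] is not None and pd.notna(r["ci_low"])
                    else "(CI unavailable)"
                )
                pv = (
                    f"p={r['p_value']:.3f}"
                    if r["p_value"] is not None and pd.notna(r["p_value"])
                    else "p=n/a"
                )
                lines.append(
                    f"  {r['outcome']:<28s} {r['term']:<22s} "
                    f"{r['estimate']: .3f} {ci} {pv}{star} n={r['n']}"
                )
            lines.append("")
        for col, (r, p, n) in self.correlations.items():
            lines.append(
                f"Pearson r(ln WMH volume, {col}) = {r:.3f}, p = {p:.3f}, n = {n}"
            )
        if self.exclusions:
            lines.append("")
            lines.append("rows excluded per model (missing data):")
            for outcome, n in self.exclusions.items():
                lines.append(f"  {outcome}: {n}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.demographics is not None:
            self.demographics.to_csv(outdir / "demographics.csv", index=False)
        self.to_frame().to_csv(outdir / "model_results.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")


def run_pipeline(
    cohort: pd.DataFrame | None = None,
    cohort_csv=None,
    outdir=None,
    significance: float = SIGNIFICANCE,
) -> FrailtySVDResults:
    """Orchestrate the full analysis on a cohort table and optionally save
    the report tables (deterministic for a fixed input)."""
    if cohort is None:
        if cohort_csv is None:
            raise ValueError("provide a cohort DataFrame or a cohort_csv path")
        cohort = pd.read_csv(cohort_csv)
    results = FrailtySVDModel(cohort, significance=significance).fit()
    if outdir is not None:
        results.save(outdir)
    return results
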