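"""Statistical engine: repeated-measures ANCOVA and demographic comparisons.

The primary model is a 2 (disinhibition presence) × 2 (diagnosis) × 5
(density threshold) repeated-measures ANCOVA per network metric.  Density
is a within-subject factor included only to show results are not
threshold-dependent; the between-subject tests are computed on the
per-subject mean across density levels, which is exact for between-subject
effects in a balanced repeated design with subject-constant covariates.
Factors are effects-coded and sums of squares are Type III.  Effect sizes
are partial eta squared, SS_effect / (SS_effect + SS_error).

Demographic comparisons follow the conventional cohort-table repertoire:
pooled two-sample t from summary statistics, Welch t with
Welch–Satterthwaite fractional df when variances differ, and uncorrected
Pearson chi-square for categorical variables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from msnpipe.errors import EstimabilityError, ValidationError

#: Covariates of the default model, matching the full clinical adjustment
#: set: age, sex, total intracranial volume, MRI-to-questionnaire interval,
#: dementia severity, scanner make (dummy coded against Siemens), education.
DEFAULT_COVARIATES = (
    "age",
    "sex",
    "tiv",
    "days_mri_npiq",
    "cdr_sb",
    "scanner",
    "education",
)

_CATEGORICAL_COVARIATES = {
    "sex": "C(sex, Treatment(reference='F'))",
    "scanner": "C(scanner, Treatment(reference='Siemens'))",
}


@dataclass(frozen=True)
class DesignSpec:
    """Design of the repeated-measures ANCOVA."""

    densities: tuple[float, ...] = (0.25, 0.30, 0.35, 0.40, 0.45)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    ss_type: int = 3

    def __post_init__(self) -> None:
        if self.ss_type != 3:
            raise ValidationError("only Type III sums of squares are supported")


@dataclass(frozen=True)
class AncovaResult:
    """One tested effect: F statistic, degrees of freedom, p, partial eta
    squared, and (for the factor effects) the covariate-adjusted direction."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    estimate: float | None = None  # adjusted group difference, where defined
    ss: float | None = None  # effect sum of squares (diagnostic)

    def as_dict(self) -> dict[str, object]:
        return {
            "effect": self.effect,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
            "partial_eta_sq": self.partial_eta_sq,
            "estimate": self.estimate,
        }


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0:
        raise ValueError("ss_effect must be non-negative")
    if ss_error <= 0:
        raise ValueError("ss_error must be positive")
    return ss_effect / (ss_effect + ss_error)


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Equal-variance two-sample t from summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.
    """
    _check_t_inputs(sd1, n1, sd2, n2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Unequal-variance two-sample t with Welch–Satterthwaite fractional df."""
    _check_t_inputs(sd1, n1, sd2, n2)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _check_t_inputs(sd1: float, n1: int, sd2: float, n2: int) -> None:
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")


def pearson_chi_square(table: np.ndarray | list) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square for an r × c contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all row and column margins must be positive")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


_FACTOR_TERMS = {
    "C(diagnosis, Sum)": "diagnosis",
    "C(disinhibition_present, Sum)": "disinhibition",
    "C(diagnosis, Sum):C(disinhibition_present, Sum)": "diagnosis:disinhibition",
}


def _prepare(metrics: pd.DataFrame, cohort: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    required = {"subject_id", "density", "value"}
    if not required <= set(metrics.columns):
        raise ValidationError(f"metrics table needs columns {sorted(required)}")
    densities = sorted(design.densities)
    wide = metrics.pivot_table(index="subject_id", columns="density", values="value")
    have = sorted(float(c) for c in wide.columns)
    if have != [float(d) for d in densities] or wide.isna().any().any():
        raise ValidationError(
            "unbalanced within-factor: every subject needs a value at every density "
            f"{densities}; found levels {have} with "
            f"{int(wide.isna().sum().sum())} missing cells"
        )
    response = wide.mean(axis=1).rename("mean_metric").reset_index()
    data = response.merge(cohort, on="subject_id", how="inner", validate="one_to_one")
    if len(data) != len(wide):
        raise ValidationError("metrics contain subjects absent from the cohort table")
    cov_missing = [c for c in design.covariates if c not in data.columns]
    if cov_missing:
        raise ValidationError(f"cohort table missing covariates: {cov_missing}")
    if data[list(design.covariates)].isna().any().any():
        raise ValidationError("missing covariate values")
    cells = data.groupby(["diagnosis", "disinhibition_present"], observed=True).size()
    for diag in data["diagnosis"].unique():
        for dis in (False, True):
            if (diag, dis) not in cells.index or cells.loc[(diag, dis)] == 0:
                raise EstimabilityError(
                    f"empty design cell: diagnosis={diag}, disinhibition_present={dis}"
                )
    return data


def _covariate_terms(data: pd.DataFrame, covariates: tuple[str, ...]) -> list[str]:
    terms = []
    for cov in covariates:
        if cov in _CATEGORICAL_COVARIATES:
            # Drop covariate factor levels unobserved in this cohort.
            if data[cov].nunique() < 2:
                continue
            terms.append(_CATEGORICAL_COVARIATES[cov])
        else:
            terms.append(cov)
    return terms


def _adjusted_difference(model, data: pd.DataFrame, column: str, hi, lo) -> float:
    """Covariate-adjusted marginal difference E[y | column=hi] - E[y | column=lo]."""
    d_hi = data.assign(**{column: hi})
    d_lo = data.assign(**{column: lo})
    return float(model.predict(d_hi).mean() - model.predict(d_lo).mean())


def rm_ancova(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    design: DesignSpec | None = None,
) -> list[AncovaResult]:
    """Between-subject tests of the 2 × 2 × (densities) repeated-measures ANCOVA.

    Parameters
    ----------
    metrics
        Long table with columns ``subject_id``, ``density``, ``value`` for
        one (network, metric) combination; every subject must have exactly
        one value at every design density.
    cohort
        Subject table with ``diagnosis``, ``disinhibition_present`` and the
        design covariates.
    design
        Densities, covariate list and SS type; defaults to the standard
        five-density, fully adjusted model.

    Returns results for the diagnosis and disinhibition main effects, their
    interaction, and each covariate term.
    """
    design = design or DesignSpec()
    data = _prepare(metrics, cohort, design)
    terms = list(_FACTOR_TERMS) + _covariate_terms(data, design.covariates)
    formula = "mean_metric ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    try:
        table = sm.stats.anova_lm(model, typ=design.ss_type)
    except np.linalg.LinAlgError as err:
        raise EstimabilityError(f"rank-deficient design: {err}") from err
    ss_error = float(table.loc["Residual", "sum_sq"])
    df_den = int(table.loc["Residual", "df"])
    results = []
    for term in table.index:
        if term in ("Intercept", "Residual"):
            continue
        ss = float(table.loc[term, "sum_sq"])
        res = AncovaResult(
            effect=_FACTOR_TERMS.get(term, term),
            F=float(table.loc[term, "F"]),
            df_num=int(table.loc[term, "df"]),
            df_den=df_den,
            p=float(table.loc[term, "PR(>F)"]),
            partial_eta_sq=partial_eta_squared(ss, ss_error),
            ss=ss,
        )
        if res.effect == "diagnosis":
            diags = sorted(data["diagnosis"].unique())
            res = dataclasses.replace(
                res, estimate=_adjusted_difference(model, data, "diagnosis", diags[-1], diags[0])
            )
        elif res.effect == "disinhibition":
            res = dataclasses.replace(
                res,
                estimate=_adjusted_difference(model, data, "disinhibition_present", True, False),
            )
        results.append(res)
    return results
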