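"""Cohort statistics for OCTA density outcomes.

Two model families, exposed in a statsmodels-like shape (a model object
built from a cohort table whose ``fit`` returns a results object with
estimates, 95% confidence intervals, p-values and a ``summary()``):

* :class:`BaselineDensityModel` — cross-sectional analysis of a density
  outcome at T0.  Each candidate factor is screened in a univariable
  ordinary-least-squares regression; factors reaching p < 0.1 are carried
  into a joint multivariable OLS, with the fluid-group factor always
  retained as the exposure of interest.
* :class:`TimeEffectModel` — the within-group T0 -> T1 change, estimated
  by a linear mixed model with a random intercept per eye and fixed
  effects for timepoint plus age, fibrosis and atrophy.  On a balanced
  cohort with time-invariant covariables the timepoint coefficient equals
  the mean within-eye difference, which serves as a closed-form oracle.

Reference levels follow the clinical reporting convention: healthy eyes
for the fluid group, type 1 for the neovascular subtype, aflibercept for
the anti-VEGF molecule, treatment-naive for the regimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "DegenerateDesignError",
    "UnbalancedCohortError",
    "OUTCOMES",
    "FACTORS",
    "BaselineDensityModel",
    "TimeEffectModel",
    "UnivariableResults",
    "MultivariableResults",
    "TimeEffectResults",
    "fit_univariable",
    "select_factors",
    "fit_multivariable",
    "fit_time_effect",
    "summarize_groups",
    "plot_group_time_course",
]

OUTCOMES = ("scp_mpd", "scp_mvd", "dcp_mpd", "dcp_mvd")


class DegenerateDesignError(ValueError):
    """Raised when a design matrix is constant or rank-deficient."""


class UnbalancedCohortError(ValueError):
    """Raised when a repeated-measures cohort is missing a timepoint."""


@dataclass(frozen=True)
class FactorSpec:
    column: str
    kind: str  # "categorical", "numeric" or "binary"
    reference: Optional[str] = None
    drop_levels: tuple = ()
    # factors defined only for diseased eyes cannot enter a joint model
    # with the fluid-group factor (their rows exclude the healthy
    # reference, leaving the group dummies collinear with the intercept)
    multivariable_eligible: bool = True


#: Candidate factors for the baseline screening, with reference levels.
#: ``none`` codes "not applicable" (healthy or untreated eyes) and is
#: treated as missing for the treatment-related factors.
FACTORS: Dict[str, FactorSpec] = {
    "group": FactorSpec("group", "categorical", reference="HEALTHY"),
    "age": FactorSpec("age", "numeric"),
    "sex": FactorSpec("sex", "categorical", reference="F"),
    "disease_duration": FactorSpec(
        "disease_duration", "numeric", multivariable_eligible=False
    ),
    "ivi_before": FactorSpec("ivi_before", "numeric", multivariable_eligible=False),
    "atrophy": FactorSpec("atrophy", "binary"),
    "fibrosis": FactorSpec("fibrosis", "binary"),
    "mnv_subtype": FactorSpec(
        "mnv_subtype",
        "categorical",
        reference="type1",
        drop_levels=("none",),
        multivariable_eligible=False,
    ),
    "anti_vegf": FactorSpec(
        "anti_vegf",
        "categorical",
        reference="aflibercept",
        drop_levels=("none",),
        multivariable_eligible=False,
    ),
    "regimen": FactorSpec(
        "regimen",
        "categorical",
        reference="naive",
        drop_levels=("none",),
        multivariable_eligible=False,
    ),
}


def _factor_design(df: pd.DataFrame, factor: str) -> tuple[pd.DataFrame, pd.Series]:
    """Design columns for one factor, with rows unusable for it dropped."""
    if factor not in FACTORS:
        raise KeyError(f"unknown factor {factor!r}; known: {sorted(FACTORS)}")
    spec = FACTORS[factor]
    col = df[spec.column]
    usable = col.notna()
    if spec.drop_levels:
        usable &= ~col.isin(spec.drop_levels)
    sub = df.loc[usable]
    col = sub[spec.column]
    if spec.kind == "numeric":
        if col.nunique() < 2:
            raise DegenerateDesignError(f"factor {factor!r} is constant")
        design = pd.DataFrame({factor: col.astype(float)})
    elif spec.kind == "binary":
        vals = col.astype(bool)
        if vals.nunique() < 2:
            raise DegenerateDesignError(f"factor {factor!r} is constant")
        design = pd.DataFrame({factor: vals.astype(float)})
    else:
        levels = [lv for lv in pd.unique(col) if lv != spec.reference]
        if spec.reference not in set(col) or not levels:
            raise DegenerateDesignError(
                f"factor {factor!r} needs the reference level and one other"
            )
        design = pd.DataFrame(
            {f"{factor}[{lv}]": (col == lv).astype(float) for lv in sorted(levels)}
        )
    return design, usable


def _ols(y: pd.Series, design: pd.DataFrame):
    X = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")
    return sm.OLS(np.asarray(y, float), X).fit()


def _rows_from_fit(fit, outcome: str, term_factor: dict) -> pd.DataFrame:
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for term in fit.params.index:
        if term == "const":
            continue
        rows.append(
            {
                "outcome": outcome,
                "factor": term_factor.get(term, term),
                "term": term,
                "estimate": float(fit.params[term]),
                "ci_low": float(ci.loc[term, 0]),
                "ci_high": float(ci.loc[term, 1]),
                "p": float(fit.pvalues[term]),
            }
        )
    return pd.DataFrame(rows)


def _summary_table(table: pd.DataFrame, title: str) -> str:
    disp = table.copy()
    for c in ("estimate", "ci_low", "ci_high"):
        disp[c] = disp[c].map(lambda v: f"{v:.2f}")
    disp["p"] = table["p"].map(lambda v: f"{v:.3g}")
    body = disp.to_string(index=False)
    rule = "=" * max(len(line) for line in body.splitlines())
    return f"{title}\n{rule}\n{body}\n{rule}"


class UnivariableResults:
    """Per-level estimates of a single-factor OLS at baseline."""

    def __init__(self, outcome: str, factor: str, table: pd.DataFrame, nobs: int):
        self.outcome = outcome
        self.factor = factor
        self.table = table
        self.nobs = nobs

    @property
    def min_pvalue(self) -> float:
        return float(self.table["p"].min())

    def summary(self) -> str:
        return _summary_table(
            self.table,
            f"Univariable OLS: {self.outcome} ~ {self.factor}   (n={self.nobs})",
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<UnivariableResults {self.outcome} ~ {self.factor}, n={self.nobs}>"


class MultivariableResults:
    """Joint OLS over the screened factors (fluid group always included)."""

    def __init__(
        self,
        outcome: str,
        included_factors: List[str],
        table: pd.DataFrame,
        nobs: int,
        univariable: Optional[Dict[str, UnivariableResults]] = None,
    ):
        self.outcome = outcome
        self.included_factors = included_factors
        self.table = table
        self.nobs = nobs
        self.univariable = univariable or {}

    def summary(self) -> str:
        facs = ", ".join(self.included_factors)
        return _summary_table(
            self.table,
            f"Multivariable OLS: {self.outcome} ~ {facs}   (n={self.nobs})",
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MultivariableResults {self.outcome}, "
            f"factors={self.included_factors}, n={self.nobs}>"
        )


class TimeEffectResults:
    """Adjusted T1-vs-T0 change from the random-intercept mixed model."""

    def __init__(
        self,
        outcome: str,
        group: str,
        estimate: float,
        ci_low: float,
        ci_high: float,
        p: float,
        n_eyes: int,
        covariables: Sequence[str],
    ):
        self.outcome = outcome
        self.group = group
        self.estimate = estimate
        self.ci_low = ci_low
        self.ci_high = ci_high
        self.p = p
        self.n_eyes = n_eyes
        self.covariables = tuple(covariables)

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def summary(self) -> str:
        covs = ", ".join(self.covariables) if self.covariables else "none"
        return (
            f"Mixed-model time effect on {self.outcome} ({self.group} group, "
            f"{self.n_eyes} eyes)\n"
            f"  T1 - T0 estimate : {self.estimate:.2f} "
            f"(95% CI {self.ci_low:.2f}, {self.ci_high:.2f})\n"
            f"  p-value          : {self.p:.3g}\n"
            f"  adjusted for     : {covs}\n"
            f"  random effects   : intercept per eye (REML)"
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TimeEffectResults {self.outcome} {self.group}: "
            f"{self.estimate:.2f} ({self.ci_low:.2f}, {self.ci_high:.2f})>"
        )


# ---------------------------------------------------------------------------
# models


class BaselineDensityModel:
    """Cross-sectional model of one density outcome at T0.

    Parameters
    ----------
    cohort
        Long cohort table (one row per eye and timepoint); only T0 rows
        are used.
    outcome
        One of ``scp_mpd, scp_mvd, dcp_mpd, dcp_mvd``.
    """

    def __init__(self, cohort: pd.DataFrame, outcome: str):
        if outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        self.outcome = outcome
        self.data = cohort[cohort["timepoint"] == "T0"].reset_index(drop=True)
        if len(self.data) < 3:
            raise ValueError("at least 3 baseline records are required")

    @classmethod
    def from_csv(cls, path, outcome: str) -> "BaselineDensityModel":
        return cls(pd.read_csv(path), outcome)

    def fit_univariable(self, factor: str) -> UnivariableResults:
        design, usable = _factor_design(self.data, factor)
        y = self.data.loc[usable, self.outcome]
        if len(y) < 3:
            raise DegenerateDesignError("fewer than 3 usable records")
        fit = _ols(y, design)
        table = _rows_from_fit(fit, self.outcome, {c: factor for c in design.columns})
        return UnivariableResults(self.outcome, factor, table, int(fit.nobs))

    def fit_all_univariable(
        self, factors: Optional[Iterable[str]] = None
    ) -> Dict[str, UnivariableResults]:
        out = {}
        for factor in factors if factors is not None else FACTORS:
            try:
                out[factor] = self.fit_univariable(factor)
            except DegenerateDesignError:
                continue
        return out

    def screen_factors(
        self, alpha: float = 0.1, factors: Optional[Iterable[str]] = None
    ) -> List[str]:
        uni = self.fit_all_univariable(factors)
        return select_factors(list(uni.values()), alpha=alpha)

    def fit(
        self,
        factors: Optional[Sequence[str]] = None,
        alpha: float = 0.1,
    ) -> MultivariableResults:
        """Screen factors univariably (p < alpha) and fit the joint OLS."""
        uni = self.fit_all_univariable()
        if factors is None:
            factors = [
                f
                for f in select_factors(list(uni.values()), alpha=alpha)
                if FACTORS[f].multivariable_eligible
            ]
        designs, usable = [], pd.Series(True, index=self.data.index)
        term_factor = {}
        for factor in factors:
            d, u = _factor_design(self.data, factor)
            d = d.reindex(self.data.index)
            designs.append(d)
            usable &= u
            term_factor.update({c: factor for c in d.columns})
        design = pd.concat(designs, axis=1).loc[usable]
        y = self.data.loc[usable, self.outcome]
        fit = _ols(y, design)
        table = _rows_from_fit(fit, self.outcome, term_factor)
        return MultivariableResults(
            self.outcome, list(factors), table, int(fit.nobs), uni
        )


class TimeEffectModel:
    """Random-intercept mixed model for the T0 -> T1 change in one group.

    The fixed-effect part is ``outcome ~ timepoint + covariables`` with a
    random intercept per eye, fitted by REML.  Confidence interval and
    p-value for the timepoint coefficient use a t reference distribution
    with ``n_eyes - 1`` degrees of freedom.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        outcome: str,
        group: str,
        covariables: Sequence[str] = ("age", "fibrosis", "atrophy"),
    ):
        if outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if group not in ("IRF_SRF", "SRF"):
            raise ValueError("time effects are defined for IRF_SRF or SRF")
        sub = cohort[cohort["group"] == group].copy()
        t0 = sub[sub["timepoint"] == "T0"]["eye_id"]
        t1 = sub[sub["timepoint"] == "T1"]["eye_id"]
        if (
            len(sub) == 0
            or set(t0) != set(t1)
            or t0.duplicated().any()
            or t1.duplicated().any()
        ):
            raise UnbalancedCohortError(
                "every eye must contribute exactly one T0 and one T1 record"
            )
        self.data = sub.reset_index(drop=True)
        self.outcome = outcome
        self.group = group
        self.covariables = tuple(covariables)
        self.n_eyes = t0.nunique()

    @classmethod
    def from_csv(cls, path, outcome: str, group: str, **kw) -> "TimeEffectModel":
        return cls(pd.read_csv(path), outcome, group, **kw)

    def fit(self) -> TimeEffectResults:
        df = self.data
        exog = pd.DataFrame({"const": 1.0, "time": (df["timepoint"] == "T1").astype(float)})
        for cov in self.covariables:
            col = df[cov]
            vals = col.astype(float) if col.dtype != bool else col.astype(float)
            # constant covariables carry no information within one group
            if np.nanstd(vals.to_numpy()) > 0:
                exog[cov] = vals
        endog = df[self.outcome].astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog, exog, groups=df["eye_id"])
            fit = model.fit(reml=True)
        est = float(fit.params["time"])
        se = float(fit.bse["time"])
        dof = self.n_eyes - 1
        tcrit = sps.t.ppf(0.975, dof)
        p = 2.0 * sps.t.sf(abs(est / se), dof) if se > 0 else 0.0
        return TimeEffectResults(
            self.outcome,
            self.group,
            est,
            est - tcrit * se,
            est + tcrit * se,
            min(max(p, np.finfo(float).tiny), 1.0),
            self.n_eyes,
            [c for c in exog.columns if c not in ("const", "time")],
        )


# ---------------------------------------------------------------------------
# functional wrappers (spec-level operations)


def fit_univariable(cohort: pd.DataFrame, outcome: str, factor: str) -> UnivariableResults:
    """Univariable OLS of the T0 outcome on a single factor."""
    return BaselineDensityModel(cohort, outcome).fit_univariable(factor)


def select_factors(results: List[UnivariableResults], alpha: float = 0.1) -> List[str]:
    """Factors with any level p < alpha; the fluid group is always kept."""
    chosen = ["group"]
    for res in results:
        if res.factor != "group" and res.min_pvalue < alpha:
            chosen.append(res.factor)
    return chosen


def fit_multivariable(
    cohort: pd.DataFrame, outcome: str, factors: Sequence[str]
) -> MultivariableResults:
    """Joint OLS of the T0 outcome on the given factors."""
    return BaselineDensityModel(cohort, outcome).fit(factors=factors)


def fit_time_effect(
    cohort: pd.DataFrame,
    outcome: str,
    group: str,
    covariables: Sequence[str] = ("age", "fibrosis", "atrophy"),
) -> TimeEffectResults:
    """Mixed-model T1-vs-T0 effect for one group (see TimeEffectModel)."""
    return TimeEffectModel(cohort, outcome, group, covariables).fit()


def _fmt_mean_sd(x: pd.Series) -> str:
    if len(x) == 0:
        return ""
    mean = x.mean()
    if len(x) < 2:
        return f"{mean:.1f} ± NA"
    return f"{mean:.1f} ± {x.std(ddof=1):.1f}"


def summarize_groups(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per (group, plexus, metric) and timepoint, 1 decimal."""
    rows = []
    for group in cohort["group"].unique():
        sub = cohort[cohort["group"] == group]
        for plexus in ("SCP", "DCP"):
            for metric in ("MPD", "MVD"):
                col = f"{plexus.lower()}_{metric.lower()}"
                if col not in sub:
                    continue
                entry = {"group": group, "plexus": plexus, "metric": metric}
                for tp in ("T0", "T1"):
                    x = sub.loc[sub["timepoint"] == tp, col].dropna()
                    entry[tp] = _fmt_mean_sd(x) if len(x) else "-"
                rows.append(entry)
    return pd.DataFrame(rows)


def plot_group_time_course(cohort: pd.DataFrame, outcome: str = "scp_mpd", ax=None):
    """Spaghetti plot of per-eye trajectories with group means overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xpos = {"T0": 0.0, "T1": 1.0}
    colors = {"IRF_SRF": "tab:red", "SRF": "tab:blue", "HEALTHY": "tab:green"}
    for group, sub in cohort.groupby("group"):
        for _, eye in sub.groupby("eye_id"):
            xs = [xpos[t] for t in eye["timepoint"]]
            ax.plot(xs, eye[outcome], color=colors.get(group, "gray"), alpha=0.2, lw=0.8)
        means = sub.groupby("timepoint")[outcome].mean()
        ax.plot(
            [xpos[t] for t in means.index],
            means.values,
            color=colors.get(group, "gray"),
            lw=2.5,
            marker="o",
            label=group,
        )
    ax.set_xticks([0, 1], ["T0", "T1"])
    ax.set_ylabel(outcome)
    ax.legend(frameon=False)
    return ax
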