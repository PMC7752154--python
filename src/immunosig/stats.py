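"""Association battery linking a signature to ICB response and survival.

Implements the comparisons a checkpoint-blockade biomarker study reports:
Wilcoxon rank-sum of signature scores between responders and non-responders
(BH-adjusted across the top signatures), Fisher's exact odds ratio on the
high/low x response 2x2 table (conditional-MLE OR, exact two-sided p by the
"probability <= observed" rule, exact 95% CI), a multivariate logistic model
controlling for TMB, CTL and *PD-1*/*PD-L1*/*CTLA-4* expression, Kaplan-Meier
curves with the log-rank test, and a multivariate Cox model (Efron ties)
controlling for sex, subtype/stage and TMB. All intervals are 95%. Missing
covariates are deleted listwise within each model and ``n_used`` is always
reported — never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio
import statsmodels.api as sm

from .cohort import GROUP_COLUMN, SCORE_COLUMN, StratifiedCohort
from .exceptions import ConfigurationError, SeparationError
from .ranking import bh_adjust

LOGISTIC_COVARIATES = ("tmb", "ctl", "pd1_expr", "pdl1_expr", "ctla4_expr")
COX_COVARIATES = ("sex", "subtype_or_stage", "tmb")


@dataclass
class AssociationResult:
    """One test's outcome: effect with 95% CI, p-values and bookkeeping."""

    test: str
    effect: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    p_adj: float | None = None
    covariates: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)
    note: str = ""

    def to_dict(self) -> dict:
        d = {"test": self.test, "effect": self.effect, "ci_low": self.ci_low,
             "ci_high": self.ci_high, "p": self.p, "p_adj": self.p_adj,
             "n_used": self.n_used, "covariates": ";".join(self.covariates),
             "note": self.note}
        d.update(self.extras)
        return d


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one patient group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def _bootstrap_median_ci(x: np.ndarray, rng: np.random.Generator,
                         n_boot: int = 2000) -> tuple[float, float]:
    boots = np.median(rng.choice(x, size=(n_boot, len(x)), replace=True), axis=1)
    return float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))


def compare_groups_wilcoxon(
    scores: pd.DataFrame,
    response: pd.Series,
    seed: int = 0,
) -> list[AssociationResult]:
    """Mann-Whitney comparison of each signature between response groups.

    ``scores`` is patients x signatures; ``response`` is 1 for clinical
    improvement. Two-sided tests, BH-adjusted across the signature family.
    Effect reported as the difference of group medians (improvement minus
    none), with percentile-bootstrap 95% CIs of each group median in extras.
    """
    resp = np.asarray(response).astype(int)
    if (resp == 1).sum() < 2 or (resp == 0).sum() < 2:
        raise ConfigurationError("both response groups need >= 2 patients")
    rng = np.random.default_rng(seed)
    results = []
    for sig in scores.columns:
        x = scores[sig].values[resp == 1]
        y = scores[sig].values[resp == 0]
        mw = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        ci_x = _bootstrap_median_ci(x, rng)
        ci_y = _bootstrap_median_ci(y, rng)
        results.append(AssociationResult(
            test=f"wilcoxon:{sig}",
            effect=float(np.median(x) - np.median(y)),
            ci_low=float("nan"), ci_high=float("nan"),
            p=float(mw.pvalue), n_used=len(resp),
            extras={"median_improvement": float(np.median(x)),
                    "median_no_improvement": float(np.median(y)),
                    "median_improvement_ci": ci_x,
                    "median_no_improvement_ci": ci_y,
                    "U": float(mw.statistic)},
        ))
    adj = bh_adjust(np.array([r.p for r in results]))
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def contingency_table(strat: StratifiedCohort) -> np.ndarray:
    """2x2 table [[high&improved, high&not], [low&improved, low&not]]."""
    t = strat.table
    hi = t[GROUP_COLUMN] == "high"
    resp = t["response"].astype(int) == 1
    return np.array([[int((hi & resp).sum()), int((hi & ~resp).sum())],
                     [int((~hi & resp).sum()), int((~hi & ~resp).sum())]])


def fisher_or(strat_or_table: StratifiedCohort | np.ndarray) -> AssociationResult:
    """Fisher's exact test on the high/low x response table.

    The odds ratio is the conditional maximum-likelihood estimate (the value
    of the noncentral-hypergeometric noncentrality that makes the observed
    count its conditional expectation), with an exact 95% CI; the two-sided p
    sums hypergeometric probabilities of tables no more likely than observed.
    A zero margin leaves the OR undefined: the result is flagged, with no
    silent continuity correction.
    """
    table = (strat_or_table if isinstance(strat_or_table, np.ndarray)
             else contingency_table(strat_or_table))
    table = np.asarray(table, dtype=int)
    n_used = int(table.sum())
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return AssociationResult(
            test="fisher", effect=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p=1.0, n_used=n_used,
            note="zero margin: odds ratio undefined")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    res = _cond_odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(0.95)
    note = ""
    if not np.isfinite(res.statistic) or res.statistic == 0.0:
        note = "zero cell: odds ratio estimate on the boundary"
    return AssociationResult(
        test="fisher", effect=float(res.statistic), ci_low=float(ci.low),
        ci_high=float(ci.high), p=float(p), n_used=n_used, note=note,
        extras={"table": table.tolist()})


def logistic_adjusted(
    cohort: pd.DataFrame,
    score_column: str = SCORE_COLUMN,
    covariates: Sequence[str] = LOGISTIC_COVARIATES,
) -> AssociationResult:
    """Multivariate logistic regression of response on the signature score.

    Listwise deletion on the used columns; the effect is the odds ratio per
    unit score with a Wald 95% CI, and extras carry the per-SD scaling
    (``or_per_sd``) since either convention appears in the literature.
    Constant columns raise, and perfect separation is flagged rather than
    reported as an absurd finite OR.
    """
    used = ["response", score_column, *covariates]
    missing = [c for c in used if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort lacks column(s): {', '.join(missing)}")
    df = cohort[used].dropna()
    n_used = len(df)
    y = df["response"].astype(float).values
    if df[score_column].nunique() <= 1:
        raise ConfigurationError(f"column {score_column!r} is constant; "
                                 "coefficient not estimable")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ConfigurationError(f"covariate {c!r} is constant; drop it")
    X = sm.add_constant(df[[score_column, *covariates]].astype(float))
    if y.sum() < 10 * X.shape[1] or (1 - y).sum() < 10 * X.shape[1]:
        import warnings
        warnings.warn(f"fewer than 10 events per coefficient (n={n_used})")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    beta = fit.params[score_column]
    se = fit.bse[score_column]
    if not np.isfinite(se) or se > 1e3 or abs(beta) > 20:
        raise SeparationError(
            f"perfect or quasi-separation suspected: beta={beta:.3g}, se={se:.3g}")
    sd = float(df[score_column].std(ddof=1))
    return AssociationResult(
        test="logistic", effect=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(fit.pvalues[score_column]), n_used=n_used,
        covariates=list(covariates),
        extras={"or_per_sd": float(np.exp(beta * sd)),
                "or_per_sd_ci": (float(np.exp((beta - 1.959963984540054 * se) * sd)),
                                 float(np.exp((beta + 1.959963984540054 * se) * sd))),
                "beta": float(beta)})


def km_logrank(strat: StratifiedCohort) -> tuple[list[SurvivalCurve], AssociationResult]:
    """Kaplan-Meier curves per signature group plus the two-group log-rank test."""
    t = strat.table
    groups = sorted(t[GROUP_COLUMN].unique())
    if len(groups) < 2:
        raise ConfigurationError("log-rank needs two groups")
    curves = []
    for grp in groups:
        sub = t[t[GROUP_COLUMN] == grp]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["surv_time"], sub["event"], label=grp)
        tl = kmf.event_table.index.values
        curves.append(SurvivalCurve(
            group=grp, times=tl,
            survival=kmf.survival_function_.values.ravel(),
            at_risk=kmf.event_table["at_risk"].values))
    n_events = int(t["event"].sum())
    if n_events == 0:
        result = AssociationResult(
            test="logrank", effect=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p=float("nan"), n_used=len(t),
            note="no events: log-rank undefined")
        return curves, result
    hi = t[t[GROUP_COLUMN] == "high"]
    lo = t[t[GROUP_COLUMN] == "low"]
    lr = logrank_test(hi["surv_time"], lo["surv_time"],
                      event_observed_A=hi["event"], event_observed_B=lo["event"])
    result = AssociationResult(
        test="logrank", effect=float(lr.test_statistic),
        ci_low=float("nan"), ci_high=float("nan"),
        p=float(lr.p_value), n_used=len(t),
        extras={"n_events": n_events})
    return curves, result


def cox_adjusted(
    cohort: pd.DataFrame,
    score_column: str = GROUP_COLUMN,
    covariates: Sequence[str] = COX_COVARIATES,
) -> AssociationResult:
    """Multivariate Cox proportional-hazards model (Efron tie handling).

    By default the exposure is the high/low group indicator (HR of high vs
    low); passing a numeric column instead gives a per-unit HR. Categorical
    covariates are dummy-encoded with the first level as reference; listwise
    deletion applies to the used columns. Non-convergence is raised with the
    fitter's diagnostic rather than returning a half-converged estimate.
    """
    used = ["surv_time", "event", score_column, *covariates]
    missing = [c for c in used if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort lacks column(s): {', '.join(missing)}")
    df = cohort[used].dropna().copy()
    n_used = len(df)

    if score_column == GROUP_COLUMN:
        df["_exposure"] = (df[GROUP_COLUMN] == "high").astype(float)
    else:
        df["_exposure"] = df[score_column].astype(float)
    if df["_exposure"].nunique() <= 1:
        raise ConfigurationError(f"exposure {score_column!r} is constant")

    design_cols = ["_exposure"]
    parts = [df[["surv_time", "event", "_exposure"]]]
    for c in covariates:
        col = df[c]
        if col.dtype.kind in "biufc":
            parts.append(col.astype(float).to_frame())
            design_cols.append(c)
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
            design_cols.extend(dummies.columns)
    design = pd.concat(parts, axis=1)

    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="surv_time", event_col="event")
    except ConvergenceError as exc:
        raise ConfigurationError(f"Cox model did not converge: {exc}") from exc
    hr = float(np.exp(cph.params_["_exposure"]))
    ci = cph.confidence_intervals_.loc["_exposure"]
    return AssociationResult(
        test="cox", effect=hr,
        ci_low=float(np.exp(ci.iloc[0])), ci_high=float(np.exp(ci.iloc[1])),
        p=float(cph.summary.loc["_exposure", "p"]), n_used=n_used,
        covariates=[c for c in design_cols if c != "_exposure"],
        extras={"log_hr": float(cph.params_["_exposure"])})


def results_frame(results: Sequence[AssociationResult] | Mapping[str, AssociationResult]) -> pd.DataFrame:
    """Tidy one-row-per-test frame for TSV export."""
    items = results.values() if isinstance(results, Mapping) else results
    return pd.DataFrame([r.to_dict() for r in items])
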