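"""Statistical endpoints: delta analyses, normality-gated group tests,
categorical tests, effect sizes, random-intercept mixed models, and the
a-priori power / sample-size calculations.

Conventions
-----------
* Continuous two-group comparisons are gated by a per-group Shapiro-Wilk
  test at alpha = 0.05: both groups normal -> Student's t-test, otherwise
  Mann-Whitney U.  The study hypothesis is directional (intervention >
  control), so tests default to one-sided in that direction.
* Effect sizes: Cohen's d = (m1 - m2)/pooled SD for t-based tests with
  r = sqrt(t^2/(t^2 + df)); for U tests r = |z|/sqrt(N) from the normal
  approximation of U.
* The mixed models are REML random-intercept fits; the group-by-time
  interaction coefficient is the primary intervention test.
* Power and sample size use the noncentral-t distribution of the
  two-sample t statistic, ncp = d*sqrt(n/2), df = 2n - 2; the
  normal-approximation sample size n = ceil(2 (z_{1-a/2} + z_P)^2 / d^2)
  is reported alongside the exact noncentral-t search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "MixedModelResult",
    "delta",
    "group_compare",
    "categorical_compare",
    "fisher_from_counts",
    "fit_mixed_model",
    "unified_index_long_table",
    "power_two_sample",
    "sample_size_two_sample",
    "cohens_d_from_summary",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    sided: str  # "one" | "two"
    test_name: str
    n_per_group: tuple[int, int]
    effect_d: Optional[float] = None
    effect_r: Optional[float] = None
    note: str = ""


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame  # estimate, se, p per term
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_subjects: int
    formula: str
    converged: bool = True
    singular: bool = False


def delta(
    table: pd.DataFrame,
    position: str,
    value_cols: tuple[str, ...] = ("sampen", "entropy_rate"),
    visit_col: str = "visit",
    first: str = "first",
    last: str = "last",
) -> pd.DataFrame:
    """Per-subject change (last - first) at a matching window position.

    A subject enters only with a defined value at both visits for that
    position; everyone else is excluded from that biomarker's delta (the
    pairing requirement of the delta design).
    """
    sub = table[table["position"] == position]
    out = {}
    for col in value_cols:
        piv = sub.pivot_table(index="subject", columns=visit_col,
                              values=col, aggfunc="first")
        if first not in piv.columns or last not in piv.columns:
            out[col] = pd.Series(dtype=float)
            continue
        both = piv[[first, last]].dropna()
        out[col] = both[last] - both[first]
    res = pd.DataFrame(out)
    if res.empty:
        logger.info("no subject qualifies for delta at position %r", position)
    return res


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * np.var(a, ddof=1)
                      + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / pooled)


def group_compare(
    values: np.ndarray,
    groups: np.ndarray,
    sided: str = "one",
    direction: str = "intervention_gt_control",
    intervention_label: str = "intervention",
    normality_alpha: float = 0.05,
) -> TestResult:
    """Two-group comparison with a Shapiro-Wilk-gated test choice.

    Both groups normal at ``normality_alpha`` -> t-test; otherwise
    Mann-Whitney U.  One-sided tests use the stated direction
    (intervention greater by default).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    gi = values[groups == intervention_label]
    gc = values[groups != intervention_label]
    gi, gc = gi[np.isfinite(gi)], gc[np.isfinite(gc)]
    if len(gi) < 3 or len(gc) < 3:
        raise ValueError("need at least 3 observations per group")
    if np.var(gi) == 0 and np.var(gc) == 0:
        return TestResult(np.nan, np.nan, sided, "undefined",
                          (len(gi), len(gc)),
                          note="zero variance in both groups")
    if direction == "intervention_gt_control":
        alternative = "greater" if sided == "one" else "two-sided"
    elif direction == "intervention_lt_control":
        alternative = "less" if sided == "one" else "two-sided"
    else:
        raise ValueError(f"unknown direction {direction!r}")

    normal = all(
        np.var(g) > 0 and stats.shapiro(g).pvalue > normality_alpha
        for g in (gi, gc)
    )
    n = len(gi) + len(gc)
    if normal:
        res = stats.ttest_ind(gi, gc, alternative=alternative)
        df = len(gi) + len(gc) - 2
        d = _cohens_d(gi, gc)
        r = float(np.sqrt(res.statistic ** 2 / (res.statistic ** 2 + df)))
        return TestResult(float(res.statistic), float(res.pvalue), sided,
                          "t-test", (len(gi), len(gc)), effect_d=d, effect_r=r)
    res = stats.mannwhitneyu(gi, gc, alternative=alternative)
    mu = len(gi) * len(gc) / 2.0
    sigma = np.sqrt(len(gi) * len(gc) * (n + 1) / 12.0)
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    return TestResult(float(res.statistic), float(res.pvalue), sided,
                      "mann-whitney-u", (len(gi), len(gc)),
                      effect_r=float(abs(z) / np.sqrt(n)),
                      note="r from normal approximation of U (no tie correction)")


def categorical_compare(table: np.ndarray,
                        alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test for 2x2 tables, chi-squared otherwise.

    ``alternative`` ('two-sided', 'less', 'greater') applies to the 2x2
    Fisher test only; sidedness is always explicit, never inferred.
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("empty group margin in contingency table")
    sided = "two" if alternative == "two-sided" else "one"
    n_rows = (int(table[0].sum()), int(table[1].sum()))
    if table.shape == (2, 2):
        # a saturated outcome column (everyone yes) is fine: p = 1 trivially
        res = stats.fisher_exact(table, alternative=alternative)
        return TestResult(float(res.statistic), float(res.pvalue), sided,
                          "fisher-exact", n_rows)
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("empty outcome margin in contingency table")
    if alternative != "two-sided":
        raise ValueError("chi-squared test for r x c tables is two-sided only")
    res = stats.chi2_contingency(table)
    return TestResult(float(res.statistic), float(res.pvalue), "two",
                      "chi-squared", n_rows)


def fisher_from_counts(yes_a: int, n_a: int, yes_b: int, n_b: int,
                       alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test from yes-counts of two groups.

    ``alternative='less'`` tests whether group A's yes-odds are lower than
    group B's (e.g. control practising less than intervention).
    """
    table = np.array([[yes_a, n_a - yes_a], [yes_b, n_b - yes_b]])
    return categorical_compare(table, alternative=alternative)


def unified_index_long_table(
    matrices: dict[str, pd.DataFrame],
    cohort: pd.DataFrame,
    timepoints: tuple[str, ...] = ("first_begin", "last_end"),
    covariate_names: tuple[str, ...] = ("maternal_age", "gestational_age", "bmi"),
    variance_threshold: float = 0.80,
) -> pd.DataFrame:
    """Full harmonization -> timepoint-specific PCA -> unified index chain.

    ``matrices`` maps timepoint -> raw subjects x metrics matrix.  The
    cohort table supplies group labels and covariates (gestational age is
    taken visit-specific from ga_first / ga_last).  Returns a long table
    with one row per subject x timepoint carrying the unified index, ready
    for mixed-effects modelling.  By default only the two extreme
    timepoints (first_begin, last_end) are used.
    """
    from .harmonize import harmonize_matrix
    from .structure_pca import fit_pca, unified_index

    cohort = cohort.set_index("subject") if "subject" in cohort.columns else cohort
    rows = []
    for tp in timepoints:
        if tp not in matrices:
            raise KeyError(f"timepoint {tp!r} missing from matrices")
        visit = "first" if tp.startswith("first") else "last"
        cov = pd.DataFrame({
            "maternal_age": cohort["maternal_age"],
            "gestational_age": cohort["ga_first" if visit == "first" else "ga_last"],
            "bmi": cohort["bmi"],
        })
        adj = harmonize_matrix(matrices[tp], cov,
                               covariate_names=covariate_names, timepoint=tp)
        pca = fit_pca(adj.values, timepoint=tp,
                      variance_threshold=variance_threshold)
        idx = unified_index(pca)
        for subject, val in idx.items():
            rows.append({"subject": subject, "timepoint": tp,
                         "group": cohort.loc[subject, "group"],
                         "unified_hrv_index": float(val),
                         "k_selected": pca.k_selected})
    return pd.DataFrame(rows)


def fit_mixed_model(
    data: pd.DataFrame,
    outcome: str = "unified_hrv_index",
    group_col: str = "group",
    time_col: str = "timepoint",
    subject_col: str = "subject",
    intervention_label: str = "intervention",
    baseline_time: Optional[str] = None,
    covariates: tuple[str, ...] = (),
) -> MixedModelResult:
    """REML random-intercept model: outcome ~ group * time + (1 | subject).

    Fixed effects: group (intervention vs control), time (vs the baseline
    level), and their interaction - the primary intervention test.
    ``covariates`` adds adjustment terms as a sensitivity mode.  A
    singular fit (random-intercept variance at the boundary) is flagged
    but its estimates are still returned.
    """
    import statsmodels.api as sm

    df = data.dropna(subset=[outcome]).copy()
    times = sorted(df[time_col].unique())
    if len(times) < 2:
        raise ValueError("need at least 2 timepoints")
    baseline_time = baseline_time or times[0]
    df["_group"] = (df[group_col] == intervention_label).astype(float)
    df["_time"] = (df[time_col] != baseline_time).astype(float)
    df["_gxt"] = df["_group"] * df["_time"]
    exog_cols = ["_group", "_time", "_gxt", *covariates]
    exog = sm.add_constant(df[exog_cols])
    formula = (f"{outcome} ~ group * time"
               + ("".join(f" + {c}" for c in covariates))
               + f" + (1 | {subject_col})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df[outcome], exog, groups=df[subject_col])
        fit = model.fit(reml=True)
    names = {"const": "intercept", "_group": "group", "_time": "time",
             "_gxt": "group_x_time"}
    # small-sample correction: t reference with inner-outer df instead of
    # the asymptotic normal (Wald z is anti-conservative at n ~ 28)
    n_subj = int(df[subject_col].nunique())
    n_obs = int(len(df))
    n_within = 1 + len([c for c in covariates
                        if df.groupby(subject_col)[c].nunique().max() > 1])
    df_between = max(n_subj - 2, 1)
    df_within = max(n_obs - n_subj - n_within - 1, 1)
    dof = {"const": df_between, "_group": df_between}
    tvals = fit.fe_params / fit.bse_fe
    pvals = {
        term: 2.0 * stats.t.sf(abs(tvals[term]),
                               dof.get(term, df_within))
        for term in fit.fe_params.index
    }
    fe = pd.DataFrame({
        "estimate": fit.fe_params,
        "se": fit.bse_fe,
        "p_value": pd.Series(pvals),
    })
    fe.index = [names.get(i, i) for i in fe.index]
    re_var = float(np.squeeze(fit.cov_re.to_numpy()))
    return MixedModelResult(
        fixed_effects=fe,
        random_intercept_var=re_var,
        residual_var=float(fit.scale),
        n_obs=int(len(df)),
        n_subjects=int(df[subject_col].nunique()),
        formula=formula,
        converged=bool(fit.converged),
        singular=bool(re_var < 1e-8 * max(float(fit.scale), 1e-12)),
    )


def power_two_sample(n_per_group: int, d: float, alpha: float = 0.05,
                     sided: str = "two") -> float:
    """Power of the two-sample t-test via the noncentral t distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    if d < 0:
        raise ValueError("d must be non-negative")
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    if sided == "two":
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tc, df, ncp)
                     + stats.nct.cdf(-tc, df, ncp))
    tc = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tc, df, ncp))


def sample_size_two_sample(d: float, alpha: float, power: float,
                           method: str = "normal_approx",
                           sided: str = "two") -> int:
    """Per-group n for a two-sample t-test at the target power.

    ``normal_approx``: n = ceil(2 (z_{1-a/2} + z_P)^2 / d^2);
    ``noncentral_t``: smallest n whose exact power reaches the target.
    """
    if d == 0:
        raise ValueError("d = 0 requires infinite n")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if method == "normal_approx":
        za = stats.norm.ppf(1 - alpha / 2) if sided == "two" \
            else stats.norm.ppf(1 - alpha)
        zb = stats.norm.ppf(power)
        return int(np.ceil(2.0 * (za + zb) ** 2 / d ** 2))
    if method == "noncentral_t":
        n = 2
        while power_two_sample(n, d, alpha, sided) < power:
            n += 1
            if n > 10 ** 6:
                raise RuntimeError("sample-size search did not terminate")
        return n
    raise ValueError(f"unknown method {method!r}")


def cohens_d_from_summary(mean_diff: float, sd: float) -> float:
    """Standardized mean difference from a summary difference and SD."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(mean_diff / sd)
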