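"""Cohort statistics for fat-fraction biomarker studies.

Implements the full analysis battery applied to the per-muscle fat-fraction
table: descriptive summaries (parametric and nonparametric), a Shapiro-Wilk
normality gate, Kruskal-Wallis omnibus comparison with a Tukey-HSD post hoc
on ranks, Wilcoxon signed-rank left/right pairing, the Q3 + 1.5*IQR outlier
rule, hierarchical linear regression with a sequential delta-R-squared
retention rule, two multivariate logistic models (active-vs-inactive and
pain-vs-healthy), and analytic power / sample-size calculators.

Conventions: the omnibus and logistic analyses use one row per subject
(left/right side-mean metrics); the hierarchical linear model treats the two
sides as separate observations.  All fat fractions here are percentages.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TestResult",
    "StepResult",
    "HierarchicalFit",
    "LogisticFit",
    "descriptive_table",
    "normality_gate",
    "kruskal_wallis",
    "posthoc_pairwise",
    "wilcoxon_paired",
    "outlier_flags",
    "hierarchical_linear_regression",
    "logistic_model",
    "sample_size_two_group",
    "power_delta_r2",
    "subject_level",
    "quantiles",
    "DEFAULT_ENTRY_ORDER",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    n: tuple
    effect: Optional[float] = None
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


def quantiles(values, rule: str = "linear") -> tuple[float, float, float]:
    """(Q1, median, Q3) under the configured rule.

    ``linear`` interpolates order statistics (the numpy default); ``hinges``
    uses Tukey's hinges (medians of the lower/upper halves, the median
    included in both halves for odd n).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    med = float(np.median(v))
    if rule == "linear":
        q1, q3 = (float(q) for q in np.percentile(v, [25, 75]))
    elif rule == "hinges":
        half = (v.size + 1) // 2
        q1 = float(np.median(v[:half]))
        q3 = float(np.median(v[v.size - half :]))
    else:
        raise ValueError(f"unknown quantile rule {rule!r}")
    return q1, med, q3


def _summary_row(values, rule) -> dict:
    v = np.asarray(values, dtype=float)
    q1, med, q3 = quantiles(v, rule)
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": med,
        "q1": q1,
        "q3": q3,
        "iqr": q3 - q1,
    }


def descriptive_table(
    table: pd.DataFrame,
    value: str = "ff_pct",
    group_col: str = "group",
    sex_col: Optional[str] = "sex",
    quantile_rule: str = "linear",
    healthy_pooled: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD and median (IQR) per group, split by sex plus pooled.

    When ``healthy_pooled`` is set and a ``Pain`` group exists, an extra
    "All healthy" stratum pools every non-patient subject, mirroring the
    usual cohort-table layout.
    """
    rows = []
    strata = [(g, sub) for g, sub in table.groupby(group_col, sort=False)]
    if healthy_pooled and "Pain" in set(table[group_col]):
        healthy = table[table[group_col] != "Pain"]
        if len(healthy):
            strata.append(("All healthy", healthy))
    for gname, sub in strata:
        if sub.empty:
            raise ValueError(f"empty stratum {gname!r}")
        cells = []
        if sex_col is not None:
            cells = [(str(s).capitalize(), ssub) for s, ssub in sub.groupby(sex_col)]
        cells.append(("All", sub))
        for sex_name, cell in cells:
            if cell.empty:
                continue
            rows.append(
                {"group": gname, "sex": sex_name, **_summary_row(cell[value], quantile_rule)}
            )
    return pd.DataFrame(rows)


def subject_level(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a side-level table to one row per subject (side means)."""
    if "side" not in table.columns:
        return table.copy()
    numeric = [
        c
        for c in (
            "ff_pct",
            "volume_ml",
            "lean_volume_ml",
            "normalized_volume",
            "normalized_lean_volume",
        )
        if c in table.columns
    ]
    keep = [
        c
        for c in table.columns
        if c not in numeric + ["side", "voxel_count", "undefined_count", "bulk_slices"]
    ]
    agg = {c: "mean" for c in numeric} | {c: "first" for c in keep if c != "subject_id"}
    return table.groupby("subject_id", as_index=False).agg(agg)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def normality_gate(values, name: str = "sample") -> TestResult:
    """Shapiro-Wilk normality test (valid for 3 <= n <= 5000)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {v.size}")
    w, p = sps.shapiro(v)
    return TestResult(f"shapiro_wilk({name})", float(w), float(p), (int(v.size),))


def _enumerate_assignments(n_total: int, sizes: Sequence[int]):
    """All distinct splits of indices 0..n-1 into consecutive groups of the given sizes."""

    def rec(remaining: tuple, sizes_left: tuple):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        # fix the smallest remaining index in the first group when sizes repeat?
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    yield from rec(tuple(range(n_total)), tuple(sizes))


def kruskal_wallis(groups: Sequence[Sequence[float]], exact_limit: int = 9) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p; exact for tiny n.

    For total sample sizes up to ``exact_limit`` the p-value is computed by
    full enumeration of group assignments instead of the chi-square
    approximation.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 1 for g in gs):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    pooled = np.concatenate(gs)
    if pooled.size < 3:
        raise ValueError("need >= 3 observations in total")
    sizes = tuple(int(g.size) for g in gs)
    if np.ptp(pooled) == 0:
        return TestResult(
            "kruskal_wallis", 0.0, 1.0, sizes, note="all observations identical"
        )
    h, p = sps.kruskal(*gs)
    note = None
    if pooled.size <= exact_limit:
        count = total = 0
        for assign in _enumerate_assignments(pooled.size, sizes):
            perm_groups = [pooled[list(ix)] for ix in assign]
            hp, _ = sps.kruskal(*perm_groups)
            count += hp >= h - 1e-12
            total += 1
        p = count / total
        note = f"exact permutation p over {total} assignments"
    return TestResult("kruskal_wallis", float(h), float(p), sizes, note=note)


def posthoc_pairwise(
    groups: Sequence[Sequence[float]],
    names: Optional[Sequence[str]] = None,
    scale: str = "ranks",
) -> list[TestResult]:
    """Tukey HSD over all group pairs, by default on rank-transformed data.

    Rank-based HSD is the natural follow-up to a Kruskal-Wallis omnibus; the
    raw scale is selectable with ``scale='raw'``.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    names = list(names) if names is not None else [f"g{i}" for i in range(len(gs))]
    if scale == "ranks":
        ranks = sps.rankdata(np.concatenate(gs))
        out, off = [], 0
        for g in gs:
            out.append(ranks[off : off + g.size])
            off += g.size
        data = out
    elif scale == "raw":
        data = gs
    else:
        raise ValueError(f"unknown scale {scale!r}")
    with np.errstate(invalid="ignore"):
        res = sps.tukey_hsd(*data)
    results = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        p = float(res.pvalue[i, j])
        if math.isnan(p) and res.statistic[i, j] == 0:
            p = 1.0  # zero between- and within-group variance
        results.append(
            TestResult(
                name=f"tukey_hsd[{scale}]({names[i]} vs {names[j]})",
                statistic=float(res.statistic[i, j]),
                p_value=p,
                n=(int(gs[i].size), int(gs[j].size)),
                effect=float(np.mean(gs[i]) - np.mean(gs[j])),
            )
        )
    return results


def wilcoxon_paired(
    left, right, zero_method: str = "wilcox", exact_limit: int = 25
) -> TestResult:
    """Wilcoxon signed-rank test for paired samples (e.g. left vs right FF).

    Exact null distribution for small samples without ties; normal
    approximation with continuity and tie correction otherwise.  Reports the
    median paired difference (left - right) as the effect.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1 or left.size < 1:
        raise ValueError("need equal-length 1D paired vectors")
    diffs = left - right
    effect = float(np.median(diffs))
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return TestResult(
            "wilcoxon_signed_rank", 0.0, 1.0, (int(left.size),), effect=0.0,
            note="all paired differences zero",
        )
    if nz.size <= exact_limit and zero_method == "wilcox":
        stat, p = _wilcoxon_exact(nz)
        note = "exact signed-rank enumeration"
    else:
        stat, p = sps.wilcoxon(
            left, right, zero_method=zero_method, correction=True, method="approx"
        )
        note = None
    return TestResult(
        "wilcoxon_signed_rank", float(stat), float(p), (int(left.size),),
        effect=effect, note=note,
    )


def _wilcoxon_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p, ties allowed.

    The null distribution of W+ (sum of ranks of positive differences) is
    built by dynamic programming over the 2^n sign patterns: average ranks
    are doubled to integers and the generating polynomial prod(1 + x^{2r_i})
    is expanded.  Two-sided p = min(1, 2 min(P(W+ <= w), P(W+ >= w))).
    """
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = float(ranks[diffs > 0].sum())
    doubled = np.round(2 * ranks).astype(int)
    dist = np.zeros(int(doubled.sum()) + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_obs))
    p_low = dist[: w2 + 1].sum()
    p_high = dist[w2:].sum()
    return w_obs, float(min(1.0, 2.0 * min(p_low, p_high)))


def outlier_flags(values, quantile_rule: str = "linear") -> tuple[float, np.ndarray]:
    """Upper-fence outliers: values strictly above Q3 + 1.5*IQR."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need n >= 4 for the IQR outlier rule")
    q1, _, q3 = quantiles(v, quantile_rule)
    threshold = q3 + 1.5 * (q3 - q1)
    return float(threshold), v > threshold


# ---------------------------------------------------------------------------
# Hierarchical linear regression
# ---------------------------------------------------------------------------

DEFAULT_ENTRY_ORDER = ("gender", "bmi", "age", "activity", "ohs", "side", "pain_side")

_TERMS = {
    "gender": "male",
    "bmi": "bmi",
    "age": "age_years",
    "activity": "C(group, Treatment(reference='High'))",
    "ohs": "ohs_grade_filled",
    "side": "side_right",
    "pain_side": "pain_on_side",
}


@dataclass(frozen=True)
class StepResult:
    variable: str
    coefficients: dict  # new terms at entry: name -> (coef, p)
    delta_r2: float
    cumulative_r2: float
    p_block: float
    retained: bool


@dataclass(frozen=True)
class HierarchicalFit:
    steps: list
    retained: list
    final_formula: str
    final_coefficients: pd.DataFrame
    r2_final: float
    results: object = field(repr=False)  # statsmodels results of the final model

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for term, (coef, p) in s.coefficients.items():
                rows.append(
                    {
                        "variable": s.variable,
                        "term": term,
                        "coef": coef,
                        "p_entry": p,
                        "delta_r2": s.delta_r2,
                        "cumulative_r2": s.cumulative_r2,
                        "p_block": s.p_block,
                        "retained": s.retained,
                    }
                )
        return pd.DataFrame(rows)


def _prepare_regression_frame(table: pd.DataFrame, response: str) -> pd.DataFrame:
    df = table.copy()
    if "male" not in df:
        df["male"] = (df["sex"].str.lower() == "male").astype(int)
    if "side_right" not in df:
        df["side_right"] = (df["side"].str.lower() == "right").astype(int)
    grade = df.get("ohs_grade")
    if grade is None and "ohs_score" in df:
        from .quant import ohs_grade as _grade

        grade = df["ohs_score"].map(lambda s: _grade(s) if pd.notna(s) else np.nan)
    # subjects without an OHS questionnaire sit at the Satisfactory end
    df["ohs_grade_filled"] = (grade if grade is not None else np.nan)
    df["ohs_grade_filled"] = df["ohs_grade_filled"].fillna(4).astype(float)
    pain = df.get("pain_side")
    if pain is None:
        df["pain_on_side"] = 0
    else:
        pain = pain.fillna("none").astype(str).str.lower()
        df["pain_on_side"] = (
            (pain == "both") | (pain == df["side"].astype(str).str.lower())
        ).astype(int)
    if df[response].isna().any():
        raise ValueError(f"response column {response!r} contains missing values")
    return df


def hierarchical_linear_regression(
    table: pd.DataFrame,
    entry_order: Sequence[str] = DEFAULT_ENTRY_ORDER,
    response: str = "ff_pct",
    alpha: float = ALPHA_DEFAULT,
) -> HierarchicalFit:
    """Sequential-entry OLS with the significance + R²-increase retention rule.

    Predictors enter one block at a time in ``entry_order``; a block is
    retained when its partial F test against the current model is significant
    at ``alpha`` AND the coefficient of determination strictly increases.
    Non-retained blocks are dropped before the next step, so the final model
    contains exactly the retained predictors.  Left and right side rows are
    treated as independent observations.
    """
    unknown = [v for v in entry_order if v not in _TERMS]
    if unknown:
        raise ValueError(f"unknown predictors {unknown}; choose from {sorted(_TERMS)}")
    df = _prepare_regression_frame(table, response)
    steps: list[StepResult] = []
    retained: list[str] = []
    current = smf.ols(f"{response} ~ 1", data=df).fit()
    for var in entry_order:
        terms = retained + [var]
        formula = f"{response} ~ 1 + " + " + ".join(_TERMS[t] for t in terms)
        fit = smf.ols(formula, data=df).fit()
        if fit.model.exog.shape[1] > np.linalg.matrix_rank(fit.model.exog):
            raise ValueError(f"rank-deficient design after adding {var!r}")
        delta_r2 = fit.rsquared - current.rsquared
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat, p_block, _ = fit.compare_f_test(current)
        if np.isnan(p_block) and delta_r2 > 0:
            p_block = 0.0  # saturated/noiseless fit: the block explains everything
        new_terms = [
            name for name in fit.params.index if name not in current.params.index
        ]
        coefs = {
            name: (float(fit.params[name]), float(fit.pvalues[name]))
            for name in new_terms
        }
        keep = bool(p_block < alpha and delta_r2 > 0)
        steps.append(
            StepResult(
                variable=var,
                coefficients=coefs,
                delta_r2=float(delta_r2),
                cumulative_r2=float(fit.rsquared),
                p_block=float(p_block),
                retained=keep,
            )
        )
        if keep:
            retained.append(var)
            current = fit
    final_formula = f"{response} ~ 1" + (
        " + " + " + ".join(_TERMS[t] for t in retained) if retained else ""
    )
    final = smf.ols(final_formula, data=df).fit()
    final_coefficients = pd.DataFrame(
        {"coef": final.params, "p_final": final.pvalues}
    )
    return HierarchicalFit(
        steps=steps,
        retained=retained,
        final_formula=final_formula,
        final_coefficients=final_coefficients,
        r2_final=float(final.rsquared),
        results=final,
    )


# ---------------------------------------------------------------------------
# Logistic models
# ---------------------------------------------------------------------------

DEFAULT_LOGISTIC_PREDICTORS = ("male", "bmi", "age_years", "ff_pct", "normalized_volume")


@dataclass(frozen=True)
class LogisticFit:
    outcome: str
    table: pd.DataFrame  # per predictor: odds_ratio, ci_low, ci_high, p_value
    converged: bool
    n: int
    results: object = field(repr=False)


def logistic_model(
    table: pd.DataFrame,
    outcome: str = "active_vs_not",
    predictors: Sequence[str] = DEFAULT_LOGISTIC_PREDICTORS,
) -> LogisticFit:
    """Multivariate logistic regression with Wald 95% CIs on odds ratios.

    ``active_vs_not`` codes hip-pain patients plus the low-activity group as
    the positive (inactive) class; ``pain_vs_healthy`` codes patients against
    all healthy subjects.  One row per subject (side-mean metrics) is used;
    a side-level table is collapsed automatically.
    """
    df = subject_level(table).copy()
    if "male" not in df and "sex" in df:
        df["male"] = (df["sex"].str.lower() == "male").astype(int)
    if outcome == "active_vs_not":
        y = df["group"].isin(["Pain", "Low"]).astype(int)
    elif outcome == "pain_vs_healthy":
        y = (df["group"] == "Pain").astype(int)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    missing = [p for p in predictors if p not in df.columns]
    if missing:
        raise ValueError(f"missing predictor columns {missing}")
    X = sm.add_constant(df[list(predictors)].astype(float))
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0)
    except PerfectSeparationWarning as exc:
        raise ValueError(f"complete separation detected ({exc})") from exc
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed ({exc})") from exc
    converged = bool(res.mle_retvals.get("converged", False))
    ci = res.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "odds_ratio": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p_value": res.pvalues,
        }
    ).drop(index="const")
    return LogisticFit(
        outcome=outcome, table=out, converged=converged, n=int(len(df)), results=res
    )


# ---------------------------------------------------------------------------
# Power and sample size
# ---------------------------------------------------------------------------


def sample_size_two_group(
    delta: float,
    sd: float,
    power: float = 0.8,
    alpha: float = ALPHA_DEFAULT,
    tails: int = 2,
    use_t: bool = False,
) -> int:
    """Smallest n per group for a two-sample comparison of means.

    Normal-approximation formula n = 2 ((z_{1-a/t} + z_{power}) sd / delta)^2,
    optionally refined by iterating the exact noncentral-t power until the
    requested power is reached.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    za = sps.norm.ppf(1 - alpha / tails)
    zb = sps.norm.ppf(power)
    n = max(2, math.ceil(2 * ((za + zb) * sd / delta) ** 2))
    if use_t:
        while _t_power(n, delta, sd, alpha, tails) < power:
            n += 1
        while n > 2 and _t_power(n - 1, delta, sd, alpha, tails) >= power:
            n -= 1
    return n


def _t_power(n: int, delta: float, sd: float, alpha: float, tails: int) -> float:
    df = 2 * n - 2
    nc = delta / (sd * math.sqrt(2.0 / n))
    tcrit = sps.t.ppf(1 - alpha / tails, df)
    power = sps.nct.sf(tcrit, df, nc)
    if tails == 2:
        power += sps.nct.cdf(-tcrit, df, nc)
    return float(power)


def power_delta_r2(
    delta_r2: float,
    r2_full: float,
    n: int,
    df_tested: int,
    df_model: int,
    alpha: float = ALPHA_DEFAULT,
) -> float:
    """Post-hoc power of the partial F test for an R-squared increment.

    Cohen's effect size f² = ΔR² / (1 − R²_full) with noncentrality λ = f²·n;
    the power is the upper tail of the noncentral F beyond the central-F
    critical value with (df_tested, n − df_model − 1) degrees of freedom.
    """
    if not 0 <= delta_r2 < 1 or not 0 <= r2_full < 1 or delta_r2 > r2_full + 1e-12:
        raise ValueError("need 0 <= delta_r2 <= r2_full < 1")
    if df_tested < 1 or df_model < df_tested or n <= df_model + 1:
        raise ValueError("invalid degrees of freedom")
    f2 = delta_r2 / (1.0 - r2_full)
    lam = f2 * n
    df2 = n - df_model - 1
    crit = sps.f.isf(alpha, df_tested, df2)
    if lam == 0:  # central F: power is the nominal level by definition
        return float(alpha)
    return float(sps.ncf.sf(crit, df_tested, df2, lam))
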