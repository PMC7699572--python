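"""Repeated-measures comparison machinery for airway cohorts.

The experimental design is within-subject: every subject is measured at
a baseline condition (``"00"``, sedative alone) and again 5, 10 and
15 min after an anesthetic adjunct, in two axial planes, for nine
airway measures (area/AP/TX x true-min/mean/max).  Three analysis
surfaces are provided:

* :func:`paired_compare` — baseline vs. one follow-up condition with a
  normality-gated paired t / Wilcoxon signed-rank test, 95% CI of the
  difference, per-subject percent change and Cohen's d.
* :func:`fit_lmm` — a linear mixed-effects dose-response model of the
  change from baseline with time (categorical), age and the baseline
  value as fixed effects and a per-subject random intercept; reported
  as least-squares mean change per time level.
* :func:`dunnett_compare` — many-to-one comparisons of each time level
  against baseline with Dunnett-type adjustment through the estimated
  multivariate-t distribution of the paired t statistics (used for the
  hemodynamic family, but measure-agnostic).

All functions consume plain arrays or the long-format cohort table
(``subject, plane, condition, measure, value, age``) and are fully
decoupled from the imaging stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PairedResult",
    "LmmResult",
    "DunnettResult",
    "paired_compare",
    "fit_lmm",
    "multiplicity_adjust",
    "dunnett_compare",
    "paired_results_table",
    "lmm_results_table",
]


@dataclass(frozen=True)
class PairedResult:
    measure: str
    n: int
    mean_diff: float
    ci: tuple[float, float]
    pct_change: float
    cohens_d: float
    test: str  # "paired-t" | "wilcoxon"
    p_value: float


def _hodges_lehmann_ci(diffs: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Walsh-average CI paired with the signed-rank test (normal-approx rank cutoff)."""
    n = len(diffs)
    walsh = np.sort([(diffs[i] + diffs[j]) / 2.0 for i in range(n) for j in range(i, n)])
    m = len(walsh)
    z = sps.norm.ppf(1 - alpha / 2)
    k = int(np.floor(m / 2.0 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)))
    k = max(k, 0)
    return float(walsh[k]), float(walsh[m - 1 - k])


def paired_compare(
    baseline,
    followup,
    normality_alpha: float = 0.05,
    measure: str = "",
) -> PairedResult:
    """Compare paired baseline/follow-up values for one measure.

    The within-pair differences are screened with Shapiro-Wilk at
    ``normality_alpha``; a paired t-test (with t-based 95% CI) is used
    when normality is not rejected, otherwise the Wilcoxon signed-rank
    test with a Hodges-Lehmann interval.  Cohen's d for paired data is
    ``mean(diff)/sd(diff)`` in either branch; percent change averages
    the per-subject relative changes (subjects with a zero baseline are
    excluded from that average with a logged warning).
    """
    base = np.asarray(baseline, dtype=float)
    follow = np.asarray(followup, dtype=float)
    if base.shape != follow.shape or base.ndim != 1:
        raise ValueError("baseline and followup must be equal-length 1-D vectors")
    n = len(base)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = follow - base

    nonzero_base = base != 0
    if not nonzero_base.all():
        logger.warning("%s: %d subject(s) with zero baseline excluded from percent change",
                       measure or "paired_compare", int((~nonzero_base).sum()))
    pct = (100.0 * diffs[nonzero_base] / base[nonzero_base]).mean() if nonzero_base.any() else np.nan

    if np.all(diffs == 0):
        return PairedResult(measure, n, 0.0, (0.0, 0.0), float(pct), 0.0, "paired-t", 1.0)

    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if sd_diff > 0:
        d = mean_diff / sd_diff
    else:
        d = float(np.sign(mean_diff) * np.inf)

    normal_p = sps.shapiro(diffs).pvalue if sd_diff > 0 else 0.0
    if normal_p >= normality_alpha:
        t_res = sps.ttest_rel(follow, base)
        se = sd_diff / np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
        return PairedResult(measure, n, mean_diff, ci, float(pct), float(d),
                            "paired-t", float(t_res.pvalue))
    w_res = sps.wilcoxon(diffs)
    ci = _hodges_lehmann_ci(diffs)
    return PairedResult(measure, n, mean_diff, ci, float(pct), float(d),
                        "wilcoxon", float(w_res.pvalue))


@dataclass(frozen=True)
class LmmResult:
    measure: str
    times: tuple[str, ...]
    lsm: dict  # time -> dict(estimate, ci_lo, ci_hi, p)
    fixed_effects: dict  # name -> estimate
    converged: bool
    random_effect_dropped: bool
    n_subjects: int


def _lmm_frame(cohort: pd.DataFrame, measure: str, plane: str | None) -> pd.DataFrame:
    df = cohort[cohort["measure"] == measure]
    if plane is not None:
        df = df[df["plane"] == plane]
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r} (plane {plane!r})")
    base = df[df["condition"] == "00"].set_index("subject")["value"]
    rows = []
    for _, r in df[df["condition"] != "00"].iterrows():
        if r["subject"] not in base.index:
            continue  # no baseline for this subject; unbalanced but allowed
        b = float(base.loc[r["subject"]])
        rows.append({
            "subject": r["subject"], "time": str(r["condition"]),
            "age": float(r["age"]), "baseline": b,
            "change": float(r["value"]) - b,
        })
    out = pd.DataFrame(rows)
    if out.empty or out["subject"].nunique() < 2:
        raise ValueError(f"measure {measure!r}: need >= 2 subjects with baseline + follow-up")
    return out


def fit_lmm(
    cohort: pd.DataFrame,
    measure: str,
    plane: str | None = None,
) -> LmmResult:
    """Mixed-effects dose-response model of change from baseline.

    ``change ~ 0 + C(time) + age + baseline`` with a random intercept
    per subject, fitted by REML.  The least-squares mean change at each
    time level is the model prediction at that level with age and
    baseline at their sample means; its CI and p-value use the normal
    approximation to the fixed-effect sampling distribution.  A singular
    or non-convergent random-effects fit is downgraded to an ordinary
    least-squares fit with a flag (never silently).
    """
    import statsmodels.formula.api as smf

    df = _lmm_frame(cohort, measure, plane)
    times = tuple(sorted(df["time"].unique(), key=lambda s: float(s)))
    formula = "change ~ 0 + C(time) + age + baseline"

    result, dropped, converged = None, False, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = smf.mixedlm(formula, df, groups=df["subject"])
            mr = md.fit(reml=True)
            if mr.converged and np.all(np.isfinite(mr.fe_params)) and \
                    np.all(np.isfinite(np.asarray(mr.bse_fe))):
                result = mr
                converged = bool(mr.converged)
        except Exception:
            result = None
    if result is None:
        dropped = True
        logger.warning("%s: singular mixed model, refit without random intercept", measure)
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            result = smf.ols(formula, df).fit()

    if dropped:
        names = list(result.model.exog_names)
        params = np.asarray(result.params)
        cov = np.asarray(result.cov_params())
    else:
        names = list(result.model.exog_names)
        params = np.asarray(result.fe_params)
        cov = np.asarray(result.cov_params())[:len(names), :len(names)]

    age_mean = df["age"].mean()
    base_mean = df["baseline"].mean()
    z = sps.norm.ppf(0.975)
    lsm = {}
    for t in times:
        c = np.zeros(len(names))
        label = f"C(time)[{t}]"
        if label not in names:  # pandas categorical label variant
            label = next(nm for nm in names if nm.startswith("C(time)") and f"[{t}]" in nm)
        c[names.index(label)] = 1.0
        if "age" in names:
            c[names.index("age")] = age_mean
        if "baseline" in names:
            c[names.index("baseline")] = base_mean
        est = float(c @ params)
        with np.errstate(invalid="ignore"):
            var = float(c @ cov @ c)
        se = np.sqrt(max(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = est / se if se > 0 else (np.inf * np.sign(est) if est != 0 else 0.0)
        p = float(2 * sps.norm.sf(abs(zstat))) if np.isfinite(zstat) else 0.0
        if se == 0 and est == 0:
            p = 1.0
        lsm[t] = {"estimate": est, "ci_lo": est - z * se, "ci_hi": est + z * se, "p": p}

    return LmmResult(
        measure=measure, times=times, lsm=lsm,
        fixed_effects=dict(zip(names, params.tolist())),
        converged=converged, random_effect_dropped=dropped,
        n_subjects=int(df["subject"].nunique()),
    )


def multiplicity_adjust(p_values, method: str = "bonferroni") -> np.ndarray:
    """Family-wise adjusted p-values (Bonferroni default, Holm available)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "holm": "holm"}[method]
    return multipletests(p, method=key)[1]


@dataclass(frozen=True)
class DunnettResult:
    labels: tuple[str, ...]
    mean_baseline: float
    means: np.ndarray
    mean_diffs: np.ndarray
    t_stats: np.ndarray
    df: int
    p_raw: np.ndarray
    p_adjusted: np.ndarray


def _max_abs_t_prob(c: float, corr: np.ndarray, df: int, random_state: int = 0) -> float:
    """P(max_j |T_j| <= c) for a central multivariate t with correlation ``corr``."""
    if c <= 0:
        return 0.0
    k = corr.shape[0]
    mvt = sps.multivariate_t(loc=np.zeros(k), shape=corr, df=df, allow_singular=True)
    return float(np.clip(mvt.cdf(np.full(k, c), lower_limit=np.full(k, -c),
                                 random_state=random_state), 0.0, 1.0))


def dunnett_compare(baseline, followups, labels=None, random_state: int = 0) -> DunnettResult:
    """Each time level vs. a common baseline, Dunnett-adjusted.

    ``followups`` is a (k, n) array (or list of k vectors) paired with
    the length-n baseline.  Paired t statistics are formed per level;
    the family-wise adjustment evaluates the joint multivariate-t
    distribution of the k statistics with their correlation estimated
    from the within-subject difference vectors.  With k = 1 this
    reduces exactly to the unadjusted paired t-test.
    """
    base = np.asarray(baseline, dtype=float)
    fu = np.atleast_2d(np.asarray(followups, dtype=float))
    k, n = fu.shape
    if k == 0:
        raise ValueError("need at least one follow-up level")
    if n != len(base):
        raise ValueError("followups must pair with baseline")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    labels = tuple(labels) if labels is not None else tuple(str(i + 1) for i in range(k))

    diffs = fu - base[None, :]
    means = diffs.mean(axis=1)
    sds = diffs.std(axis=1, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(sds > 0, means / (sds / np.sqrt(n)), 0.0)
    p_raw = 2 * sps.t.sf(np.abs(t_stats), df)
    p_raw = np.where(sds > 0, p_raw, 1.0)

    if k == 1:
        p_adj = p_raw.copy()
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(diffs)
        bad = ~np.isfinite(corr)
        if bad.any():  # zero-variance level: fall back to the classic 0.5
            corr = np.where(bad, 0.5, corr)
            np.fill_diagonal(corr, 1.0)
        p_adj = np.array([
            1.0 - _max_abs_t_prob(abs(t), corr, df, random_state=random_state)
            for t in t_stats
        ])
        p_adj = np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)
    return DunnettResult(labels, float(base.mean()), fu.mean(axis=1), means,
                         t_stats, df, p_raw, p_adj)


def paired_results_table(
    cohort: pd.DataFrame,
    condition: str = "15",
    baseline: str = "00",
    adjust: str = "bonferroni",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Baseline-vs-condition comparison for every (plane, measure).

    One row per measure family member with descriptive statistics,
    paired-test results and family-wise adjusted p-values — the layout
    of a study summary table.
    """
    rows = []
    for (plane, measure), grp in sorted(cohort.groupby(["plane", "measure"])):
        piv = grp.pivot_table(index="subject", columns="condition", values="value")
        if baseline not in piv.columns or condition not in piv.columns:
            continue
        piv = piv.dropna(subset=[baseline, condition])
        res = paired_compare(piv[baseline], piv[condition],
                             normality_alpha, measure=f"{plane}_{measure}")
        rows.append({
            "measure": f"{plane}_{measure}", "n": res.n,
            f"mean_{baseline}": float(piv[baseline].mean()),
            f"sd_{baseline}": float(piv[baseline].std(ddof=1)),
            f"mean_{condition}": float(piv[condition].mean()),
            f"sd_{condition}": float(piv[condition].std(ddof=1)),
            "diff": res.mean_diff, "ci_lo": res.ci[0], "ci_hi": res.ci[1],
            "pct_change": res.pct_change, "cohens_d": res.cohens_d,
            "test": res.test, "p_raw": res.p_value,
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = multiplicity_adjust(table["p_raw"].to_numpy(), adjust)
    return table


def lmm_results_table(cohort: pd.DataFrame, adjust: str = "bonferroni") -> pd.DataFrame:
    """LSM change from baseline per (plane, measure, time) with adjusted p.

    The multiplicity family is every row of the table (all measures x
    all time levels), adjusted with ``adjust``.
    """
    rows = []
    for (plane, measure) in sorted(
        cohort.groupby(["plane", "measure"]).groups.keys()
    ):
        try:
            res = fit_lmm(cohort, measure, plane=plane)
        except ValueError:
            continue
        for t in res.times:
            e = res.lsm[t]
            rows.append({
                "measure": f"{plane}_{measure}", "time": t,
                "lsm": e["estimate"], "ci_lo": e["ci_lo"], "ci_hi": e["ci_hi"],
                "p_raw": e["p"], "converged": res.converged,
                "random_effect_dropped": res.random_effect_dropped,
            })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = multiplicity_adjust(table["p_raw"].to_numpy(), adjust)
    return table
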