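"""Group statistics for lesion readouts and interobserver concordance.

The omnibus decision tree mirrors common practice in prism-style analyses
of small animal cohorts:

* every group is checked for normality (Anderson-Darling, case-3
  approximation with estimated mean and variance);
* equality of spread is checked with Bartlett's test and the
  Brown-Forsythe (median-centered Levene) test;
* all groups normal and both variance tests non-significant
  -> ordinary one-way ANOVA with Tukey's HSD post hoc;
* all normal but unequal spread -> Welch ANOVA (Brown-Forsythe ANOVA is
  recorded alongside) with Dunnett's T3 pairwise comparisons;
* any group non-normal -> Kruskal-Wallis with Bonferroni-Holm-corrected
  Mann-Whitney pairwise tests.

Two-sample contrasts route analogously: Student's t when both samples are
normal with similar variance (two-sided F-test), Welch's t for unequal
variance, Mann-Whitney otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy import integrate
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.oneway import anova_oneway

from .lesionquant import CONDITIONS, GENOTYPES

BRANCH_ANOVA = "ANOVA_TUKEY"
BRANCH_WELCH = "WELCH_BF_DUNNETT_T3"
BRANCH_KRUSKAL = "KRUSKAL_HOLM_MW"

STUDY_METRICS = (
    "lesion_density_per_mm2",
    "mean_lesion_size_um2",
    "macro_density_per_mm2",
)


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    mean_a: float = math.nan
    mean_b: float = math.nan


@dataclass
class StatDecision:
    """Full audit trail of one omnibus comparison."""

    group_names: tuple[str, ...]
    normality_p: dict[str, float]
    bartlett_p: float
    brown_forsythe_p: float
    branch: str
    omnibus_name: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult]
    alpha: float
    extra: dict = field(default_factory=dict)

    def replay_branch(self) -> str:
        """Branch implied by the recorded normality/variance outcomes."""
        return _route(
            all(p > self.alpha for p in self.normality_p.values()),
            self.bartlett_p,
            self.brown_forsythe_p,
            self.alpha,
        )


@dataclass
class ConcordanceReport:
    metrics: dict[str, dict]
    n_samples: int


def _route(all_normal: bool, bartlett_p: float, bf_p: float, alpha: float) -> str:
    if not all_normal:
        return BRANCH_KRUSKAL
    if bartlett_p <= alpha or bf_p <= alpha:
        return BRANCH_WELCH
    return BRANCH_ANOVA


def anderson_darling_normality_p(x: np.ndarray) -> float:
    """p-value of the Anderson-Darling normality test (estimated mean/var)."""
    stat, p = normal_ad(np.asarray(x, dtype=float))
    return float(p)


def _check_groups(groups: Mapping[str, Sequence[float]], min_n: int = 3) -> dict[str, np.ndarray]:
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < min_n:
            raise ValueError(f"group {name!r} has n={arr.size} < {min_n}")
        clean[name] = arr
    return clean


def f_test_variances(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test for equality of two variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples are constant; variance ratio undefined")
    f = va / vb if vb > 0 else math.inf
    dfa, dfb = a.size - 1, b.size - 1
    if math.isinf(f):
        return f, 0.0
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null when min(n) <= 8 and no ties."""
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Dunnett's T3: pairwise Welch t statistics against the studentized maximum
# modulus distribution (numerical integration over the chi distribution).
# ---------------------------------------------------------------------------

def _smm_cdf(q: float, k: int, df: float) -> float:
    """P(max_i |T_i| <= q) for k independent t variables on df degrees."""
    if q <= 0:
        return 0.0

    def integrand(u: float) -> float:
        # u = s/sigma with s^2 ~ sigma^2 * chi2_df / df
        return (2.0 * sps.norm.cdf(q * u) - 1.0) ** k * sps.chi.pdf(
            u * math.sqrt(df), df
        ) * math.sqrt(df)

    val, _err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(min(max(val, 0.0), 1.0))


def dunnett_t3(groups: Mapping[str, np.ndarray]) -> list[PairwiseResult]:
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    k = len(pairs)
    out = []
    for ga, gb in pairs:
        a, b = groups[ga], groups[gb]
        va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
        se = math.sqrt(va + vb)
        t = (a.mean() - b.mean()) / se
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_raw = 2.0 * float(sps.t.sf(abs(t), df))
        p_adj = 1.0 - _smm_cdf(abs(t), k, df)
        out.append(
            PairwiseResult(
                pair=(ga, gb), test="dunnett_t3", statistic=float(t),
                p_raw=min(p_raw, 1.0), p_adjusted=min(max(p_adj, p_raw), 1.0),
                mean_a=float(a.mean()), mean_b=float(b.mean()),
            )
        )
    return out


def choose_and_run_omnibus(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> StatDecision:
    """Run the normality/variance decision tree over >= 3 groups."""
    clean = _check_groups(groups)
    if len(clean) < 3:
        raise ValueError("omnibus comparison needs at least three groups")
    for name, arr in clean.items():
        if np.ptp(arr) == 0:
            raise ValueError(f"group {name!r} is constant; tests are undefined")

    normality_p = {n: anderson_darling_normality_p(v) for n, v in clean.items()}
    arrays = list(clean.values())
    bartlett_p = float(sps.bartlett(*arrays).pvalue)
    bf_p = float(sps.levene(*arrays, center="median").pvalue)
    all_normal = all(p > alpha for p in normality_p.values())
    branch = _route(all_normal, bartlett_p, bf_p, alpha)

    names = list(clean)
    pairs = list(itertools.combinations(names, 2))
    extra: dict = {}

    if branch == BRANCH_ANOVA:
        res = sps.f_oneway(*arrays)
        omnibus_name, stat, p = "one_way_anova", float(res.statistic), float(res.pvalue)
        tukey = sps.tukey_hsd(*arrays)
        pairwise = []
        for (ga, gb) in pairs:
            i, j = names.index(ga), names.index(gb)
            t_raw = sps.ttest_ind(clean[ga], clean[gb], equal_var=True)
            pairwise.append(
                PairwiseResult(
                    pair=(ga, gb), test="tukey_hsd",
                    statistic=float(tukey.statistic[i, j]),
                    p_raw=float(t_raw.pvalue),
                    p_adjusted=float(min(max(tukey.pvalue[i, j], t_raw.pvalue), 1.0)),
                    mean_a=float(clean[ga].mean()), mean_b=float(clean[gb].mean()),
                )
            )
    elif branch == BRANCH_WELCH:
        welch = anova_oneway(arrays, use_var="unequal", welch_correction=True)
        bf_anova = anova_oneway(arrays, use_var="bf")
        omnibus_name, stat, p = "welch_anova", float(welch.statistic), float(welch.pvalue)
        extra["brown_forsythe_anova_statistic"] = float(bf_anova.statistic)
        extra["brown_forsythe_anova_p"] = float(bf_anova.pvalue)
        pairwise = dunnett_t3(clean)
    else:
        res = sps.kruskal(*arrays)
        omnibus_name, stat, p = "kruskal_wallis", float(res.statistic), float(res.pvalue)
        raw = []
        stats_ = []
        for ga, gb in pairs:
            u, pv = mann_whitney(clean[ga], clean[gb])
            raw.append(pv)
            stats_.append(u)
        adj = multipletests(raw, method="holm")[1]
        pairwise = [
            PairwiseResult(
                pair=pr, test="mann_whitney_holm", statistic=s,
                p_raw=pv, p_adjusted=float(pa),
                mean_a=float(clean[pr[0]].mean()), mean_b=float(clean[pr[1]].mean()),
            )
            for pr, s, pv, pa in zip(pairs, stats_, raw, adj)
        ]

    return StatDecision(
        group_names=tuple(names),
        normality_p=normality_p,
        bartlett_p=bartlett_p,
        brown_forsythe_p=bf_p,
        branch=branch,
        omnibus_name=omnibus_name,
        omnibus_statistic=stat,
        omnibus_p=p,
        pairwise=pairwise,
        alpha=alpha,
        extra=extra,
    )


def pairwise_comparison(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> PairwiseResult:
    """Two-sample contrast routed by normality and an F-test on variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("all values identical in both samples; tests undefined")

    both_normal = (
        anderson_darling_normality_p(a) > alpha
        and anderson_darling_normality_p(b) > alpha
    )
    if both_normal:
        _f, p_var = f_test_variances(a, b)
        if p_var > alpha:
            res = sps.ttest_ind(a, b, equal_var=True)
            test = "student_t"
        else:
            res = sps.ttest_ind(a, b, equal_var=False)
            test = "welch_t"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = mann_whitney(a, b)
        test = "mann_whitney"
    return PairwiseResult(
        pair=("a", "b"), test=test, statistic=stat, p_raw=p, p_adjusted=p,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
    )


# ---------------------------------------------------------------------------
# interobserver concordance
# ---------------------------------------------------------------------------

def interobserver_concordance(
    readouts_e1: pd.DataFrame,
    readouts_e2: pd.DataFrame,
    metrics: Sequence[str] = STUDY_METRICS,
) -> ConcordanceReport:
    """Per-metric agreement between two investigators' readout tables."""
    ids1 = set(readouts_e1["sample_id"])
    ids2 = set(readouts_e2["sample_id"])
    if ids1 != ids2:
        raise ValueError(
            f"unmatched sample_ids: only in E1 {sorted(ids1 - ids2)}, "
            f"only in E2 {sorted(ids2 - ids1)}"
        )
    e1 = readouts_e1.set_index("sample_id").sort_index()
    e2 = readouts_e2.set_index("sample_id").sort_index()

    out: dict[str, dict] = {}
    for m in metrics:
        x = e1[m].to_numpy(dtype=float)
        y = e2[m].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        diffs = x - y
        if np.all(diffs == 0):
            r, mean_diff, p_diff = 1.0, 0.0, 1.0
            t_diff = 0.0
        else:
            r = float(sps.pearsonr(x, y).statistic)
            mean_diff = float(diffs.mean())
            tt = sps.ttest_rel(x, y)
            t_diff, p_diff = float(tt.statistic), float(tt.pvalue)
        fit = sps.linregress(x, y) if np.ptp(x) > 0 else None
        out[m] = {
            "n": int(x.size),
            "pearson_r": r,
            "slope": float(fit.slope) if fit else math.nan,
            "intercept": float(fit.intercept) if fit else math.nan,
            "mean_difference": mean_diff,
            "t_statistic": t_diff,
            "p_difference": p_diff,
            "summary_e1": _summary(x),
            "summary_e2": _summary(y),
        }
    return ConcordanceReport(metrics=out, n_samples=int(len(e1)))


def _summary(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)),
        "sem": float(sps.sem(x)) if x.size > 1 else math.nan,
        "median": float(np.median(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


# ---------------------------------------------------------------------------
# full six-group study analysis
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class StudyReport:
    """Omnibus tests per condition and within-genotype condition contrasts."""

    omnibus: dict[tuple[str, str], StatDecision]  # (metric, condition)
    contrasts: dict[tuple[str, str], PairwiseResult]  # (metric, genotype)
    alpha: float

    def posthoc_significant(self, metric: str, condition: str, g1: str, g2: str) -> bool:
        dec = self.omnibus[(metric, condition)]
        for pr in dec.pairwise:
            if set(pr.pair) == {g1, g2}:
                return pr.p_adjusted < self.alpha
        raise KeyError((g1, g2))

    def contrast_significant(self, metric: str, genotype: str) -> bool:
        return self.contrasts[(metric, genotype)].p_raw < self.alpha

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (metric, condition), dec in self.omnibus.items():
            rows.append(
                dict(metric=metric, comparison=f"genotypes|{condition}",
                     branch=dec.branch, test=dec.omnibus_name,
                     statistic=dec.omnibus_statistic, p_raw=dec.omnibus_p,
                     p_adjusted=dec.omnibus_p,
                     significant=dec.omnibus_p < self.alpha,
                     stars=significance_stars(dec.omnibus_p))
            )
            for pr in dec.pairwise:
                rows.append(
                    dict(metric=metric,
                         comparison=f"{pr.pair[0]} vs {pr.pair[1]}|{condition}",
                         branch=dec.branch, test=pr.test, statistic=pr.statistic,
                         p_raw=pr.p_raw, p_adjusted=pr.p_adjusted,
                         significant=pr.p_adjusted < self.alpha,
                         stars=significance_stars(pr.p_adjusted))
                )
        for (metric, genotype), pr in self.contrasts.items():
            rows.append(
                dict(metric=metric, comparison=f"{genotype}: no_run vs run",
                     branch="two_sample", test=pr.test, statistic=pr.statistic,
                     p_raw=pr.p_raw, p_adjusted=pr.p_adjusted,
                     significant=pr.p_raw < self.alpha,
                     stars=significance_stars(pr.p_raw))
            )
        return pd.DataFrame(rows)


def run_study_analysis(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    metrics: Sequence[str] = STUDY_METRICS,
) -> StudyReport:
    """Three-genotype omnibus within each condition + within-genotype contrasts."""
    for g in GENOTYPES:
        for c in CONDITIONS:
            sub = cohort[(cohort["genotype"] == g) & (cohort["condition"] == c)]
            if len(sub) == 0:
                raise ValueError(f"missing group: genotype={g}, condition={c}")

    omnibus: dict[tuple[str, str], StatDecision] = {}
    contrasts: dict[tuple[str, str], PairwiseResult] = {}
    for metric in metrics:
        for condition in CONDITIONS:
            groups = {
                g: cohort.loc[
                    (cohort["genotype"] == g) & (cohort["condition"] == condition),
                    metric,
                ].dropna().to_numpy()
                for g in GENOTYPES
            }
            omnibus[(metric, condition)] = choose_and_run_omnibus(groups, alpha=alpha)
        for genotype in GENOTYPES:
            sub = cohort[cohort["genotype"] == genotype]
            a = sub.loc[sub["condition"] == "no_run", metric].dropna().to_numpy()
            b = sub.loc[sub["condition"] == "run", metric].dropna().to_numpy()
            pr = pairwise_comparison(a, b, alpha=alpha)
            contrasts[(metric, genotype)] = PairwiseResult(
                pair=("no_run", "run"), test=pr.test, statistic=pr.statistic,
                p_raw=pr.p_raw, p_adjusted=pr.p_adjusted,
                mean_a=pr.mean_a, mean_b=pr.mean_b,
            )
    return StudyReport(omnibus=omnibus, contrasts=contrasts, alpha=alpha)
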