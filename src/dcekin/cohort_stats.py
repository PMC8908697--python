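"""Cohort-level statistics: risk labeling, group tests, agreement, ROC.

Implements the diagnostic-comparison battery for a two-group imaging
study: Mann-Whitney group tests with Benjamini-Hochberg FDR within
model families, Bland-Altman and Spearman agreement between models,
ROC analysis with Youden-index cutoffs and DeLong confidence intervals,
McNemar comparison of imaging classifiers against radiologist reads,
and two-reader intraclass correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger("dcekin")

__all__ = [
    "TestResult",
    "BlandAltmanResult",
    "ROCResult",
    "ICCResult",
    "classify_risk",
    "mann_whitney_u",
    "fdr_adjust",
    "wilcoxon_signed_rank",
    "bland_altman",
    "spearman",
    "roc_analysis",
    "mcnemar",
    "icc_two_reader",
    "median_ci",
    "apply_exclusions",
    "run_group_comparison",
    "ET_PARAMS",
    "DP_PARAMS",
]

# Parameter columns of the per-patient medians table, by model family.
ET_PARAMS = ("Ktrans", "Vp", "Ve", "Kep")
DP_PARAMS = ("F", "MTT", "Vp", "Ve", "PS", "E")


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    family: str | None = None
    degenerate: bool = False


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    wilcoxon_p: float
    trend_rho: float | None
    trend_p: float | None


@dataclass
class ROCResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float       # %
    specificity: float       # %
    accuracy: float          # %
    orientation: str         # ">=" positive when value >= cutoff, "<=" converse
    sens_ci: tuple[float, float] = (np.nan, np.nan)
    spec_ci: tuple[float, float] = (np.nan, np.nan)


@dataclass
class ICCResult:
    icc: float
    category: str            # poor | good | excellent


def classify_risk(subtype: str, grade: int | None, dmi: bool, csi: bool,
                  lvsi: bool, lnm: bool) -> str:
    """Dichotomous preoperative risk label from surgical pathology.

    Low risk requires endometrioid histology of grade 1-2 with none of
    deep myometrial invasion, cervical stroma invasion, lymphovascular
    space invasion, or lymph-node metastasis; everything else is high
    risk (grade-3 or non-endometrioid histology, or any positive flag).
    """
    if subtype not in ("endometrioid", "nonendometrioid"):
        raise ValueError(f"unknown subtype {subtype!r}")
    if subtype == "endometrioid":
        if grade is None or (isinstance(grade, float) and np.isnan(grade)):
            raise ValueError("endometrioid histology requires a grade (1-3)")
        grade = int(grade)
        if grade not in (1, 2, 3):
            raise ValueError(f"grade must be 1-3, got {grade}")
    if subtype == "endometrioid" and grade in (1, 2) and not any((dmi, csi, lvsi, lnm)):
        return "low"
    return "high"


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when the pooled sample is small (n <= 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Identical pooled samples short-circuit to p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=x.size * y.size / 2.0, p_raw=1.0, degenerate=True)
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue))


def fdr_adjust(p_values, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within each family.

    Sorted p-values are scaled by m/rank, enforced monotone by a
    cumulative minimum from the largest rank down, and capped at 1.
    Without family labels, one global family is assumed (logged).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if family_labels is None:
        logger.info("fdr_adjust: no family labels given; single global family")
        family_labels = ["all"] * p.size
    fam = np.asarray(family_labels)
    out = np.empty_like(p)
    for f in pd.unique(fam):
        sel = fam == f
        out[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return out


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped first; an all-zero vector is degenerate with p = 1.
    Exact when n <= 25 and tie-free, else the normal approximation with
    tie correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference vector")
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(statistic=0.0, p_raw=1.0, degenerate=True)
    ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue))


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements (difference x - y).

    Limits of agreement are bias +/- 1.96 sd (sample sd, n-1).  The
    Wilcoxon signed-rank p tests a systematic difference; trend_rho is
    the Spearman correlation of difference against pairwise mean
    (a negative trend means the second method reads relatively higher at
    larger values).  Constant differences flag the trend as undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length paired samples, n >= 3")
    d = x - y
    m = (x + y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    wp = wilcoxon_signed_rank(d).p_raw
    if np.all(d == d[0]) or np.all(m == m[0]):
        rho, pr = None, None
    else:
        rho, pr = spearman(m, d)
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                             wilcoxon_p=wp, trend_rho=rho, trend_p=pr)


def _spearman_exact_p(x, y, rho_obs: float) -> float:
    """Permutation p-value for Spearman rho at small n (full enumeration)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean())
    denom = np.sqrt((rx**2).sum())
    count = 0
    total = 0
    ry_c = ry - ry.mean()
    sy = np.sqrt((ry_c**2).sum())
    for perm in itertools.permutations(range(n)):
        r = float(rx @ ry_c[list(perm)]) / (denom * sy)
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks; (rho, two-sided p).

    Exact permutation p when n <= 8, t-approximation otherwise.
    Constant input makes rho undefined (NaN, flagged by p = NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("spearman: constant input, rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if x.size <= 8:
        p = _spearman_exact_p(x, y, rho)
    return float(rho), float(p)


# DeLong variance of the empirical AUC ------------------------------------

def _midrank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _delong_auc_var(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Empirical AUC of pos-vs-neg scores and its DeLong variance."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n           # structural components
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_analysis(values, labels, positive_class="high") -> ROCResult:
    """Empirical ROC with a Youden-index cutoff and DeLong AUC CI.

    Orientation is chosen so AUC >= 0.5: if the positive class tends to
    lower values the rule "positive when value <= cutoff" is used and
    reported as orientation "<=".  Ties at the Youden optimum are broken
    toward higher specificity.  Sensitivity/specificity/accuracy are
    percentages computed from the confusion table at the chosen cutoff;
    their Wilson 95% CIs are reported alongside.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_class).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"both classes required; positive={positive_class!r}")
    pos, neg = values[y == 1], values[y == 0]
    if np.all(values == values[0]):
        auc_raw = 0.5
    else:
        auc_raw, _ = _delong_auc_var(pos, neg)
    orientation = ">=" if auc_raw >= 0.5 else "<="
    scores = values if orientation == ">=" else -values

    auc, var = _delong_auc_var(scores[y == 1], scores[y == 0]) \
        if not np.all(values == values[0]) else (0.5, 0.25 / min(len(pos), len(neg)))
    se = np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    J = tpr - fpr
    jmax = J.max()
    # ties toward higher specificity = lower fpr
    cand = np.flatnonzero(np.isclose(J, jmax))
    best = cand[np.argmin(fpr[cand])]
    # roc_curve thresholds are on the oriented scores; map back
    cut_score = thr[best]
    if np.isinf(cut_score):
        cut_score = scores.max()
    cutoff = float(cut_score if orientation == ">=" else -cut_score)

    pred = scores >= cut_score
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(y.sum() - tp)
    fp = int((y == 0).sum() - tn)
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / y.size
    s_lo, s_hi = proportion_confint(tp, tp + fn, method="wilson")
    sp_lo, sp_hi = proportion_confint(tn, tn + fp, method="wilson")
    return ROCResult(auc=float(auc), auc_ci_low=float(ci[0]), auc_ci_high=float(ci[1]),
                     cutoff=cutoff, sensitivity=sens, specificity=spec, accuracy=acc,
                     orientation=orientation,
                     sens_ci=(100 * s_lo, 100 * s_hi), spec_ci=(100 * sp_lo, 100 * sp_hi))


def mcnemar(correct_a, correct_b) -> TestResult:
    """McNemar test on paired per-patient correctness indicators.

    Uses the discordant counts b (A correct, B wrong) and c (converse):
    exact two-sided binomial when b + c <= 25, else chi-square with
    continuity correction.  No discordance is degenerate with p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    n = b + c
    if n == 0:
        return TestResult(statistic=0.0, p_raw=1.0, degenerate=True)
    if n <= 25:
        p = stats.binomtest(min(b, c), n=n, p=0.5).pvalue
        statistic = float(min(b, c))
    else:
        statistic = (abs(b - c) - 1.0) ** 2 / n
        p = stats.chi2.sf(statistic, df=1)
    return TestResult(statistic=float(statistic), p_raw=float(min(p, 1.0)))


def icc_two_reader(reader1, reader2) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Categories follow the conventional thresholds: < 0.40 poor,
    0.40-0.75 good, > 0.75 excellent.
    """
    x = np.asarray(reader1, dtype=float)
    y = np.asarray(reader2, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired measurements with n >= 3")
    data = np.column_stack([x, y])
    n, k = data.shape
    if np.allclose(data, data.flat[0]):
        logger.warning("icc_two_reader: zero variance, ICC undefined")
        return ICCResult(icc=float("nan"), category="undefined")
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc < 0.40:
        cat = "poor"
    elif icc <= 0.75:
        cat = "good"
    else:
        cat = "excellent"
    return ICCResult(icc=float(icc), category=cat)


def median_ci(x, conf: float = 0.95) -> tuple[float, float, float]:
    """Median with a distribution-free binomial order-statistic CI.

    Returns (median, lower, upper); the interval is the widest symmetric
    pair of order statistics whose exact binomial coverage reaches
    ``conf``.  At very small n the full range is returned.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    alpha = 1.0 - conf
    # largest k with P(X < k) <= alpha/2, X ~ Bin(n, 1/2); 1-based order stats
    k = int(stats.binom.ppf(alpha / 2.0, n, 0.5))
    if stats.binom.cdf(k - 1, n, 0.5) > alpha / 2.0:
        k -= 1
    k = max(k, 0)
    lo = x[max(k - 1, 0)] if k >= 1 else x[0]
    hi = x[min(n - k, n - 1)] if k >= 1 else x[-1]
    return med, float(lo), float(hi)


def apply_exclusions(roster: pd.DataFrame,
                     reason_column: str = "exclusion_reason"
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop excluded records from a screening roster.

    Rows whose ``reason_column`` is empty/NaN are retained.  Returns the
    included table and the per-reason exclusion counts (the study-flow
    accounting).
    """
    if reason_column not in roster.columns:
        return roster.copy(), {}
    reasons = roster[reason_column].fillna("").astype(str).str.strip()
    excluded = reasons != ""
    counts = reasons[excluded].value_counts().to_dict()
    logger.info("apply_exclusions: %d of %d records excluded %s",
                int(excluded.sum()), len(roster), counts)
    return roster.loc[~excluded].copy(), counts


# --------------------------------------------------------------------------
# Full study comparison
# --------------------------------------------------------------------------

def _param_columns(cohort: pd.DataFrame) -> dict[str, list[str]]:
    families: dict[str, list[str]] = {}
    for model, names in (("et", ET_PARAMS), ("dp", DP_PARAMS)):
        cols = [f"{model}_{p}" for p in names if f"{model}_{p}" in cohort.columns]
        if cols:
            families[model] = cols
    return families


def run_group_comparison(cohort: pd.DataFrame, fdr_family: str = "model",
                         positive_class: str = "high") -> dict:
    """Low- vs high-risk comparison across every kinetic parameter.

    Blocks produced (each omitted gracefully when its inputs are absent):

    - ``group_comparison``: per-parameter medians with 95% binomial CIs
      per group, Mann-Whitney U, and BH-FDR adjusted p within each model
      family (or one global family with ``fdr_family='global'``).
    - ``agreement``: Bland-Altman + Spearman for Ve and Vp estimated by
      both models.
    - ``roc``: AUC/cutoff/sensitivity/specificity/accuracy per parameter
      and for microvessel density when present.
    - ``mcnemar``: accuracy/sensitivity/specificity comparisons of the
      best ET (Ktrans) and DP (F) classifiers against the radiologist
      reads, stratified to high-risk patients for sensitivity and
      low-risk for specificity.

    Patients missing a required median are dropped from that parameter's
    tests (logged).
    """
    if "risk" not in cohort.columns:
        raise ValueError("cohort table must carry a 'risk' column")
    risk = cohort["risk"].astype(str)
    families = _param_columns(cohort)
    report: dict = {"group_comparison": {}, "agreement": {}, "roc": {}, "mcnemar": {}}

    # --- Mann-Whitney per parameter, FDR per family ---
    rows, ps, fams = [], [], []
    for model, cols in families.items():
        for col in cols:
            v = pd.to_numeric(cohort[col], errors="coerce")
            ok = v.notna()
            if (~ok).any():
                logger.info("run_group_comparison: %d patients lack %s", int((~ok).sum()), col)
            lo = v[ok & (risk == "low")].to_numpy()
            hi = v[ok & (risk == "high")].to_numpy()
            if lo.size == 0 or hi.size == 0:
                continue
            res = mann_whitney_u(lo, hi)
            med_lo = median_ci(lo)
            med_hi = median_ci(hi)
            rows.append({
                "parameter": col, "family": model,
                "median_low": med_lo[0], "ci_low_low": med_lo[1], "ci_low_high": med_lo[2],
                "median_high": med_hi[0], "ci_high_low": med_hi[1], "ci_high_high": med_hi[2],
                "U": res.statistic, "p_raw": res.p_raw,
                "direction": "lower_in_high" if med_hi[0] < med_lo[0] else "higher_in_high",
            })
            ps.append(res.p_raw)
            fams.append(model if fdr_family == "model" else "global")
    if rows:
        adj = fdr_adjust(ps, fams)
        for r, a in zip(rows, adj):
            r["p_adjusted"] = float(a)
    report["group_comparison"] = {r["parameter"]: r for r in rows}

    # --- agreement between models for shared parameters ---
    if "et" in families and "dp" in families:
        for p in ("Ve", "Vp"):
            c_et, c_dp = f"et_{p}", f"dp_{p}"
            if c_et in cohort.columns and c_dp in cohort.columns:
                sub = cohort[[c_et, c_dp]].dropna()
                if len(sub) >= 3:
                    ba = bland_altman(sub[c_et].to_numpy(), sub[c_dp].to_numpy())
                    rho, pr = spearman(sub[c_et].to_numpy(), sub[c_dp].to_numpy())
                    report["agreement"][p] = {"bland_altman": asdict(ba),
                                              "spearman_rho": rho, "spearman_p": pr}

    # --- ROC per parameter (+ MVD) ---
    roc_cols = [c for cols in families.values() for c in cols]
    if "mvd" in cohort.columns:
        roc_cols.append("mvd")
    for col in roc_cols:
        v = pd.to_numeric(cohort[col], errors="coerce")
        ok = v.notna()
        try:
            roc = roc_analysis(v[ok].to_numpy(), risk[ok].to_numpy(), positive_class)
        except ValueError:
            continue
        report["roc"][col] = asdict(roc)

    # --- McNemar vs radiologist reads ---
    best = [c for c in ("et_Ktrans", "dp_F") if c in report["roc"]]
    readers = [c for c in ("reader_dmi", "reader_csi", "reader_lnm") if c in cohort.columns]
    y_high = (risk == "high").to_numpy()
    for col in best:
        roc = report["roc"][col]
        v = pd.to_numeric(cohort[col], errors="coerce").to_numpy()
        if roc["orientation"] == ">=":
            pred = v >= roc["cutoff"]
        else:
            pred = v <= roc["cutoff"]
        correct_dce = pred == y_high
        block = {}
        for rc in readers:
            calls = cohort[rc].astype("boolean").fillna(False).to_numpy(dtype=bool)
            correct_rd = calls == y_high
            ok = np.isfinite(v)
            block[rc] = {
                "accuracy_p": mcnemar(correct_dce[ok], correct_rd[ok]).p_raw,
                "sensitivity_p": mcnemar(correct_dce[ok & y_high],
                                         correct_rd[ok & y_high]).p_raw,
                "specificity_p": mcnemar(correct_dce[ok & ~y_high],
                                         correct_rd[ok & ~y_high]).p_raw,
                "reader_accuracy": 100.0 * correct_rd[ok].mean(),
                "reader_sensitivity": 100.0 * correct_rd[ok & y_high].mean(),
                "reader_specificity": 100.0 * correct_rd[ok & ~y_high].mean(),
            }
        report["mcnemar"][col] = block
    return report
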