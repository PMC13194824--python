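"""Diagnostic, calibration and group-comparison statistics.

AUC uses the Mann–Whitney pairwise formulation (ties count 1/2) with DeLong
structural-component variance for confidence intervals and paired AUC
comparison. Proportion CIs are exact Clopper–Pearson. Predictive values are
recomputed across a prevalence grid from Se/Sp. Calibration reports the
Brier score plus intercept/slope from logistic recalibration of the labels
on logit(score). The Jonckheere–Terpstra statistic tests monotone trend
across ordered groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DiagnosticReport",
    "CalibrationReport",
    "roc_auc",
    "delong_test",
    "choose_cutoff",
    "confusion_metrics",
    "prevalence_adjusted",
    "wilcoxon_effect",
    "bh_adjust",
    "calibration",
    "jonckheere_trend",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the V10 (per-positive) and V01 (per-negative) structural
    components, with midrank tie handling."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # pairwise with ties as 1/2 via midranks
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - r_pos) / n
    v01 = 1.0 - (ranks[m:] - r_neg) / m
    auc = v10.mean()
    return float(auc), v10, v01


def roc_auc(scores, labels, ci_level: float = 0.95) -> dict:
    """AUC with DeLong variance and normal CI (clipped to [0, 1])."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    auc, v10, v01 = _delong_components(s, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(var)
    return {
        "auc": auc,
        "var": float(var),
        "ci": (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))),
        "n_pos": m,
        "n_neg": n,
    }


def delong_test(scores_a, scores_b, labels) -> dict:
    """Paired DeLong test comparing two AUCs measured on the same samples.

    Returns the AUC difference, z and the two-sided p-value; a zero-variance
    difference with a nonzero point estimate is flagged degenerate.
    """
    y = _check_binary(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("score vectors must cover the same samples")
    auc_a, v10_a, v01_a = _delong_components(sa, y)
    auc_b, v10_b, v01_b = _delong_components(sb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return {"auc_a": auc_a, "auc_b": auc_b, "diff": diff,
                "z": 0.0 if diff == 0 else np.inf,
                "p": 1.0 if diff == 0 else 0.0,
                "degenerate": diff != 0}
    z = diff / np.sqrt(var_diff)
    return {"auc_a": auc_a, "auc_b": auc_b, "diff": diff, "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z))), "degenerate": False}


def choose_cutoff(scores, labels, target_sensitivity: float = 0.95) -> float:
    """Largest threshold t with sensitivity (score >= t => positive) at or
    above the target, computed on training out-of-fold scores.

    Candidates are the observed scores; by taking the largest feasible
    threshold, specificity is maximized by construction. A target of 0 is
    satisfied by every threshold and returns the maximum observed score.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos = np.sort(s[y == 1])[::-1]
    m = len(pos)
    best = None
    for t in np.unique(s)[::-1]:
        se = (pos >= t).sum() / m
        if se >= target_sensitivity:
            best = float(t)
            break
    if best is None:
        raise ValueError(
            f"target sensitivity {target_sensitivity} unattainable "
            f"(max achievable {(pos >= pos.min()).sum() / m:.3f})"
        )
    return best


@dataclass
class DiagnosticReport:
    cohort: str
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict = field(default_factory=dict)  # name -> (estimate, lo, hi)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "estimate": v[0], "ci_low": v[1], "ci_high": v[2]}
            for k, v in self.metrics.items()
        ]
        return pd.DataFrame(rows)


def _cp(k: int, n: int) -> tuple[float, float, float]:
    if n == 0:
        return (np.nan, np.nan, np.nan)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")  # exact Clopper-Pearson
    return (k / n, float(lo), float(hi))


def confusion_metrics(scores=None, labels=None, cutoff: float | None = None,
                      counts: tuple[int, int, int, int] | None = None,
                      cohort: str = "") -> DiagnosticReport:
    """Se/Sp/PPV/NPV/accuracy with exact 95% Clopper–Pearson CIs.

    Either supply ``scores``/``labels``/``cutoff`` (score >= cutoff predicts
    cancer) or the confusion ``counts`` (TP, FP, TN, FN) directly.
    """
    if counts is not None:
        tp, fp, tn, fn = counts
    else:
        y = _check_binary(labels)
        pred = np.asarray(scores, dtype=float) >= cutoff
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        tn = int((~pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
    metrics = {
        "sensitivity": _cp(tp, tp + fn),
        "specificity": _cp(tn, tn + fp),
        "ppv": _cp(tp, tp + fp),
        "npv": _cp(tn, tn + fn),
        "accuracy": _cp(tp + tn, tp + fp + tn + fn),
    }
    return DiagnosticReport(cohort=cohort, cutoff=cutoff if cutoff is not None else np.nan,
                            tp=tp, fp=fp, tn=tn, fn=fn, metrics=metrics)


def prevalence_adjusted(sensitivity: float, specificity: float,
                        prevalences=(0.001, 0.01, 0.1, 0.2, 0.5)) -> pd.DataFrame:
    """PPV/NPV across a prevalence grid from fixed Se/Sp (Bayes' rule)."""
    rows = []
    for pi in prevalences:
        if not 0 <= pi <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        ppv_num = sensitivity * pi
        ppv_den = ppv_num + (1 - specificity) * (1 - pi)
        npv_num = specificity * (1 - pi)
        npv_den = npv_num + (1 - sensitivity) * pi
        rows.append({
            "prevalence": pi,
            "ppv": ppv_num / ppv_den if ppv_den > 0 else np.nan,
            "npv": npv_num / npv_den if npv_den > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def wilcoxon_effect(group_a, group_b, n_boot: int = 2000, seed: int = 0) -> dict:
    """Two-sided rank-sum p, effect size r = |Z| / sqrt(N), and a percentile
    bootstrap CI for r (resampling within groups, 2,000 replicates).

    The exact null distribution is used when both groups have <= 12
    observations, else the normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")

    def _r(x, y):
        nx, ny = len(x), len(y)
        u = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
        mu = nx * ny / 2.0
        all_v = np.concatenate([x, y])
        n = nx + ny
        _, cnt = np.unique(all_v, return_counts=True)
        tie = (cnt ** 3 - cnt).sum()
        sd2 = nx * ny / 12.0 * ((n + 1) - tie / (n * (n - 1))) if n > 1 else 0.0
        if sd2 <= 0:
            return 0.0
        z = (u - mu) / np.sqrt(sd2)
        return abs(z) / np.sqrt(n)

    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        return {"p": 1.0, "r": 0.0, "ci": (0.0, 0.0)}
    method = "exact" if max(len(a), len(b)) <= 12 else "asymptotic"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method=method, use_continuity=True).pvalue)
    r = _r(a, b)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _r(rng.choice(a, len(a), replace=True),
                      rng.choice(b, len(b), replace=True))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"p": p, "r": float(r), "ci": (float(lo), float(hi))}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CalibrationReport:
    brier: float
    intercept: float
    slope: float
    bins: pd.DataFrame  # mean predicted, observed rate, n per equal-width bin
    degenerate: bool = False


def calibration(scores, labels, n_bins: int = 10) -> CalibrationReport:
    """Brier score, logistic-recalibration intercept/slope, reliability bins.

    Slope and intercept come from a logistic fit of the labels on
    logit(score) (scores clipped to [1e-6, 1 - 1e-6]); with only one class
    present the fit is undefined and flagged degenerate.
    """
    y = np.asarray(labels).astype(float)
    s = np.asarray(scores, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must be in [0, 1]")
    brier = float(np.mean((s - y) ** 2))

    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "mean_predicted": float(s[m].mean()) if m.any() else np.nan,
            "observed_rate": float(y[m].mean()) if m.any() else np.nan,
            "n": int(m.sum()),
        })
    bins = pd.DataFrame(rows)

    if len(set(y.astype(int))) < 2:
        return CalibrationReport(brier=brier, intercept=np.nan, slope=np.nan,
                                 bins=bins, degenerate=True)
    logit = np.log(np.clip(s, 1e-6, 1 - 1e-6) / (1 - np.clip(s, 1e-6, 1 - 1e-6)))
    import statsmodels.api as sm

    fit = sm.GLM(y, sm.add_constant(logit), family=sm.families.Binomial()).fit()
    return CalibrationReport(brier=brier, intercept=float(fit.params[0]),
                             slope=float(fit.params[1]), bins=bins)


def jonckheere_trend(groups, n_perm: int = 10_000, seed: int = 0,
                     method: str = "auto") -> dict:
    """Jonckheere–Terpstra test for a monotone increasing trend across
    ordered groups.

    The statistic sums, over every ordered pair of groups (i < j), the
    Mann–Whitney count of (x_i, x_j) pairs with x_j > x_i (ties 1/2).
    One-sided p (large JT = increasing trend) by seeded label permutation,
    or the normal approximation when ``method='normal'`` or total n > 200.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 ordered groups")

    def _jt(gs):
        total = 0.0
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                diff = gs[j][:, None] - gs[i][None, :]
                total += (diff > 0).sum() + 0.5 * (diff == 0).sum()
        return total

    jt = _jt(groups)
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    if method == "normal" or (method == "auto" and n > 200):
        mean = (n * n - sum(k * k for k in sizes)) / 4.0
        var = (n * n * (2 * n + 3) - sum(k * k * (2 * k + 3) for k in sizes)) / 72.0
        z = (jt - mean) / np.sqrt(var)
        p = float(stats.norm.sf(z))
    else:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(groups)
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            if _jt(parts) >= jt:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return {"statistic": float(jt), "p": float(p)}
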