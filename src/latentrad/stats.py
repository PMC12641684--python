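"""Comparison statistics for pipeline-versus-pipeline performance.

The performance comparison follows the classical nonparametric cascade: a
Shapiro-Wilk screen gates the nonparametric path, a Friedman omnibus test
looks for any global difference among the feature-extraction pipelines
across classifiers (or folds), and pairwise Wilcoxon signed-rank tests with
Bonferroni / Holm / Benjamini-Hochberg multiplicity corrections localise it.
Cohort tables are compared with chi-square tests (Yates-corrected for 2x2)
and two-sample t tests from summary statistics.  Paired AUC differences use
the DeLong covariance method.

Standard tests delegate to scipy/statsmodels; the DeLong test is implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedSample:
    """Equal-length paired measurements (pairing unit: classifier or fold)."""

    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired samples must be equal-length 1D arrays")
        if len(self.values_a) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise ValueError("paired samples must be finite")


def friedman_test(matrix) -> tuple:
    """Friedman omnibus chi-square over blocks x treatments.

    Within-block average ranks (ties mid-ranked) with the standard tie
    correction; p from the chi-square distribution with k-1 df.  Constant
    blocks everywhere give statistic 0, p = 1.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    if np.all(M == M[:, :1]):
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*[M[:, j] for j in range(M.shape[1])])
    return float(stat), float(p)


def wilcoxon_signed_rank(sample: PairedSample, mode: str = "auto") -> tuple:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties are mid-ranked.  The exact null
    distribution (enumeration over the 2^n sign assignments) is used when
    n <= 15 after zero-dropping and there are no tied ranks; otherwise the
    normal approximation with continuity correction.  All differences zero
    gives W = 0, p = 1.
    """
    d = sample.values_a - sample.values_b
    nz = d[d != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    if mode == "auto":
        ranks = sps.rankdata(np.abs(nz))
        has_ties = len(np.unique(ranks)) != len(ranks)
        method = "exact" if (len(nz) <= 15 and not has_ties) else "approx"
    else:
        method = mode
    kwargs = dict(zero_method="wilcox", alternative="two-sided")
    if method == "exact":
        res = sps.wilcoxon(d, method="exact", **kwargs)
    else:
        res = sps.wilcoxon(d, method="approx", correction=True, **kwargs)
    return float(res.statistic), float(res.pvalue)


def adjust_p(ps, method: str):
    """Multiplicity-adjusted p-values: bonferroni, holm, or bh (FDR)."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("empty p-value list")
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}[method]
    return multipletests(ps, method=key)[1]


def shapiro_wilk_screen(x) -> tuple:
    """Shapiro-Wilk normality statistic and p (gates the nonparametric path)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample is degenerate for Shapiro-Wilk")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_auc_variance(scores, labels):
    """AUCs and the DeLong covariance matrix for one or more score vectors."""
    y = np.asarray(labels).astype(int)
    order = np.argsort(-y)  # positives first
    S = np.atleast_2d(np.asarray(scores, dtype=float))[:, order]
    m = int(y.sum())
    n = len(y) - m
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    k = S.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        pos, neg = S[r, :m], S[r, m:]
        tx = _midrank(pos)
        ty = _midrank(neg)
        tz = _midrank(np.concatenate([pos, neg]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


def auc_difference_test(scores_a, scores_b, labels) -> tuple:
    """Paired AUC comparison (DeLong): returns (AUC_a - AUC_b, two-sided p)."""
    aucs, cov = _delong_auc_variance(np.vstack([scores_a, scores_b]), labels)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 0:
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return delta, min(1.0, p)


# ---------------------------------------------------------------------------
# cohort-table tests


def chi_square_test(table, correction: str = "auto") -> tuple:
    """Chi-square test of independence on a 2 x c contingency table.

    Yates continuity correction for 2x2 tables (matching the convention of
    printed cohort tables), plain Pearson otherwise.
    """
    T = np.asarray(table, dtype=float)
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    use_yates = T.shape == (2, 2) if correction == "auto" else correction == "yates"
    chi2, p, _, _ = sps.chi2_contingency(T, correction=use_yates)
    return float(chi2), float(p)


def t_test_from_summary(mean1, sd1, n1, mean2, sd2, n2,
                        equal_var: bool = True) -> tuple:
    """Two-sample t test from (mean, sd, n) summaries; Welch optional."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def cohort_table_tests(rows: dict) -> pd.DataFrame:
    """Batch cohort comparisons.

    ``rows`` maps variable name -> either a contingency table (list of
    lists) or a dict with keys mean1, sd1, n1, mean2, sd2, n2 (continuous).
    Returns a tidy frame of test type, statistic and p-value.
    """
    out = []
    for name, spec in rows.items():
        if isinstance(spec, dict):
            stat, p = t_test_from_summary(
                spec["mean1"], spec["sd1"], spec["n1"],
                spec["mean2"], spec["sd2"], spec["n2"],
                equal_var=spec.get("equal_var", True))
            out.append(dict(variable=name, test="t", statistic=stat, p=p))
        else:
            stat, p = chi_square_test(spec)
            out.append(dict(variable=name, test="chi2", statistic=stat, p=p))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# omnibus + post-hoc cascade over a result grid


def pipeline_comparison(auc_matrix: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Friedman omnibus over pipelines, then pairwise Wilcoxon + corrections.

    ``auc_matrix`` has one row per block (classifier or fold) and one column
    per pipeline.  Pairwise tests run only when the omnibus is significant
    at ``alpha``.  Returns the omnibus result and (possibly empty) pairwise
    table with bonferroni/holm/bh-adjusted p-values.
    """
    M = auc_matrix.to_numpy(dtype=float)
    chi2, p = friedman_test(M)
    result = dict(friedman_chi2=chi2, friedman_p=p, pairwise=pd.DataFrame())
    if p >= alpha:
        return result
    cols = list(auc_matrix.columns)
    pairs, raw = [], []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            _, pw = wilcoxon_signed_rank(PairedSample(M[:, i], M[:, j]))
            pairs.append((cols[i], cols[j]))
            raw.append(pw)
    table = pd.DataFrame(dict(
        pipeline_a=[a for a, _ in pairs], pipeline_b=[b for _, b in pairs],
        p_raw=raw))
    for method in ("bonferroni", "holm", "bh"):
        table[f"p_{method}"] = adjust_p(table["p_raw"].to_numpy(), method)
    result["pairwise"] = table
    return result


def write_stats_report(results: dict, path) -> None:
    """Markdown + CSV report of the omnibus and pairwise comparisons."""
    from pathlib import Path

    path = Path(path)
    lines = ["# Pipeline comparison report", ""]
    for outcome, res in results.items():
        lines.append(f"## {outcome}")
        lines.append(f"Friedman chi2 = {res['friedman_chi2']:.3f}, "
                     f"p = {res['friedman_p']:.4g}")
        pw = res["pairwise"]
        if len(pw):
            lines.append("")
            lines.append(pw.to_string(index=False))
            pw.to_csv(path.parent / f"pairwise_{outcome}.csv", index=False)
        else:
            lines.append("No significant global difference; pairwise tests skipped.")
        lines.append("")
    path.write_text("\n".join(lines))
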