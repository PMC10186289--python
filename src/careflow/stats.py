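"""Descriptive band summaries and the nonparametric testing battery.

The service data are heavily non-normal (session and missed-appointment
counts are overdispersed, scores are bounded), so group comparisons across
pre-therapy severity bands use rank-based tests: Kruskal-Wallis across all
six bands, pairwise Wilcoxon rank-sum (Mann-Whitney) with Bonferroni
correction post hoc, a chi-squared test of gender x band independence with
Bonferroni-corrected pairwise column comparisons, Shapiro-Wilk normality
screening, and Pearson (optionally Spearman) correlation.  All tests are
two-sided at alpha = 0.05; computations delegate to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .episodes import SeverityBand, band_of_score

__all__ = [
    "ALPHA",
    "TestResult",
    "summarize_by_band",
    "repeat_use_summary",
    "kruskal_wallis",
    "pairwise_wilcoxon_bonferroni",
    "chi_squared_independence",
    "pairwise_chi_squared_bonferroni",
    "shapiro_wilk",
    "pearson_r",
    "spearman_r",
]

ALPHA = 0.05

#: Combined-sample-size bound below which the rank-sum test is evaluated by
#: exact enumeration (ties permitting); larger samples use the normal
#: approximation with tie and continuity corrections.
EXACT_WILCOXON_MAX_N = 20

_SUMMARY_VARIABLES = ["age", "individual_sessions", "group_sessions",
                      "total_sessions", "cna_count", "dna_count"]


@dataclass
class TestResult:
    """One test outcome: statistic, p-value and bookkeeping."""

    test_name: str
    statistic: float
    p_value: float
    groups: tuple = ()
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "groups": list(self.groups),
            "adjustment": self.adjustment,
            **self.extra,
        }


def summarize_by_band(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-pre-band descriptive summary of an episode table.

    One row per band present (in severity order) with n, gender counts and
    percents, and min/max/mean/SD/median/IQR for age, session and
    missed-appointment counts.  SD uses the n-1 denominator and quantiles
    linear interpolation; an n = 1 band reports SD as NaN (flagged) rather
    than erroring.
    """
    if len(episodes) == 0:
        return pd.DataFrame()
    df = episodes.copy()
    if "pre_band" not in df.columns:
        df["pre_band"] = [b.value for b in band_of_score(df["pre_score"].to_numpy(float))]
    rows = []
    for band in [b.value for b in SeverityBand]:
        sub = df.loc[df["pre_band"] == band]
        if len(sub) == 0:
            continue
        n = len(sub)
        row: dict = {"band": band, "n": n, "sd_undefined": n < 2}
        for g in ("male", "female"):
            cnt = int((sub["gender"] == g).sum())
            row[f"{g}_n"] = cnt
            row[f"{g}_pct"] = 100.0 * cnt / n
        for var in _SUMMARY_VARIABLES:
            x = sub[var].to_numpy(dtype=float)
            q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
            row[f"{var}_min"] = float(x.min())
            row[f"{var}_max"] = float(x.max())
            row[f"{var}_mean"] = float(x.mean())
            row[f"{var}_sd"] = float(np.std(x, ddof=1)) if n > 1 else float("nan")
            row[f"{var}_median"] = float(np.median(x))
            row[f"{var}_iqr"] = float(q3 - q1)
        rows.append(row)
    return pd.DataFrame(rows)


def repeat_use_summary(episodes: pd.DataFrame) -> dict:
    """Client-level repeat-use breakdown.

    Counts clients by their number of episodes and reports each group's
    percentage of all clients (one decimal place in ``single_use_pct``
    style figures is left to the caller; raw fractions returned here).
    """
    per_client = episodes.groupby("client_id")["episode_index"].max()
    n_clients = len(per_client)
    counts = per_client.value_counts().sort_index()
    return {
        "n_clients": int(n_clients),
        "n_episodes": int(len(episodes)),
        "clients_by_episode_count": {int(k): int(v) for k, v in counts.items()},
        "share_by_episode_count": {
            int(k): float(v / n_clients) for k, v in counts.items()
        },
    }


def _group_arrays(values, groups) -> dict:
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups, dtype=object))
    if len(s) != len(g):
        raise ValueError("values and groups must have equal length")
    out = {label: s[g == label].to_numpy() for label in pd.unique(g)}
    if len(out) < 2:
        raise ValueError("need at least two groups to compare")
    if any(len(x) == 0 for x in out.values()):
        raise ValueError("every group must be non-empty")
    return out


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H test across groups (tie-corrected, chi-squared p)."""
    arrays = _group_arrays(values, groups)
    labels = tuple(arrays)
    if np.ptp(np.concatenate(list(arrays.values()))) == 0:
        # all observations identical: no rank variation, H = 0
        return TestResult("kruskal_wallis", 0.0, 1.0, labels,
                          extra={"df": len(labels) - 1})
    h, p = sps.kruskal(*arrays.values())
    return TestResult("kruskal_wallis", float(h), float(p), labels,
                      extra={"df": len(labels) - 1})


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    otherwise normal approximation with continuity and tie corrections."""
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "asymptotic"


def pairwise_wilcoxon_bonferroni(values, groups) -> list[TestResult]:
    """Wilcoxon rank-sum tests for every unordered group pair.

    Each result carries the raw p-value in ``extra['p_raw']`` and the
    Bonferroni-adjusted value (m = number of pairs, capped at 1) as its
    ``p_value``.
    """
    arrays = _group_arrays(values, groups)
    pairs = list(combinations(arrays, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        stat, p_raw, method = _rank_sum(arrays[a], arrays[b])
        results.append(
            TestResult(
                "wilcoxon_rank_sum",
                stat,
                min(1.0, m * p_raw),
                (a, b),
                adjustment="bonferroni",
                extra={"p_raw": p_raw, "m": m, "method": method},
            )
        )
    return results


def chi_squared_independence(table: pd.DataFrame) -> TestResult:
    """Pearson chi-squared test of independence on a contingency table.

    ``table`` is counts with rows x columns (e.g. gender x severity band);
    no continuity correction.  A zero row or column marginal is an error.
    """
    counts = np.asarray(table, dtype=float)
    if counts.sum(axis=0).min() <= 0 or counts.sum(axis=1).min() <= 0:
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    cols = tuple(table.columns) if isinstance(table, pd.DataFrame) else ()
    return TestResult("chi_squared", float(chi2), float(p), cols, extra={"df": int(dof)})


def pairwise_chi_squared_bonferroni(table: pd.DataFrame) -> list[TestResult]:
    """Bonferroni-corrected chi-squared tests for every pair of columns."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table))
    pairs = list(combinations(table.columns, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        sub = table[[a, b]]
        res = chi_squared_independence(sub)
        results.append(
            TestResult(
                "chi_squared",
                res.statistic,
                min(1.0, m * res.p_value),
                (a, b),
                adjustment="bonferroni",
                extra={"p_raw": res.p_value, "m": m, "df": res.extra["df"]},
            )
        )
    return results


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (n >= 3)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"Shapiro-Wilk needs at least 3 observations; got {len(x)}")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), float(p), extra={"n": int(len(x))})


def pearson_r(x, y) -> TestResult:
    """Sample Pearson correlation with two-sided p via the t transform."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 3:
        raise ValueError("need equal-length inputs of at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation is undefined for constant input")
    r, p = sps.pearsonr(xa, ya)
    return TestResult("pearson_r", float(r), float(p), extra={"n": int(len(xa))})


def spearman_r(x, y) -> TestResult:
    """Spearman rank correlation (offered alongside Pearson)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 3:
        raise ValueError("need equal-length inputs of at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation is undefined for constant input")
    rho, p = sps.spearmanr(xa, ya)
    return TestResult("spearman_r", float(rho), float(p), extra={"n": int(len(xa))})
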