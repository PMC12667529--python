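"""Cohort comparison machinery.

Per-sample cumulative distributions are interpolated onto a fixed grid of
101 proportion points (0, 0.01, ..., 1) by nearest-rank inversion so they
can be averaged across donors. Distribution comparisons use a two-sample
Kolmogorov-Smirnov test on matched-n subsamples drawn without replacement
from each population (default 1000), repeated over bootstrap draws and
summarized by the median statistic and median p, which removes the bias a
raw KS test has when population sizes differ. Mean comparisons use Welch's
unequal-variance t-test; relative-proportion comparisons use a one-sample t
against the no-difference mean of 1. Multiplicity is handled by
Holm-Bonferroni (per-cohort families) or plain Bonferroni (per-population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CDF_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass
class InterpolatedCDF:
    grid: np.ndarray
    values: np.ndarray
    n: int


def interpolate_cdf(values: np.ndarray, n_points: int = 101) -> InterpolatedCDF:
    """Empirical CDF inverted at a fixed proportion grid by the nearest method.

    The value at proportion p is the nearest-rank quantile, making curves
    from differently sized samples directly averageable.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to interpolate")
    grid = np.linspace(0.0, 1.0, n_points)
    out = np.quantile(values, grid, method="nearest")
    return InterpolatedCDF(grid=grid, values=out, n=values.size)


def adjust_pvalues(pvals, method: str = "holm") -> np.ndarray:
    """Family-wise correction: 'holm' (per-cohort) or 'bonferroni' (per-population)."""
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown correction {method!r}")
    return multipletests(np.asarray(pvals, dtype=float), method=method)[1]


def bootstrap_ks(pop_a: np.ndarray, pop_b: np.ndarray,
                 subsample_n: int = 1000, n_boot: int = 100,
                 seed: int | np.random.Generator = 0,
                 correction: tuple[str, int] | None = None
                 ) -> tuple[float, float]:
    """Matched-n subsampled two-sample KS test, summarized over bootstrap draws.

    Each repeat draws ``subsample_n`` values without replacement from both
    populations (the subsample size drops to the smaller population when
    necessary, logged) and applies an asymptotic two-sample KS test; the
    median statistic and median p over repeats are returned.
    ``correction=("bonferroni", m)`` multiplies the summary p by m (capped
    at 1); Holm families are corrected across tests with
    :func:`adjust_pvalues`.
    """
    a = np.asarray(pop_a, dtype=float)
    b = np.asarray(pop_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty population")
    n = min(subsample_n, a.size, b.size)
    if n < subsample_n:
        logger.info("subsample lowered to %d (population sizes %d, %d)",
                    n, a.size, b.size)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ks_stats, ps = np.empty(n_boot), np.empty(n_boot)
    for i in range(n_boot):
        sa = rng.choice(a, size=n, replace=False)
        sb = rng.choice(b, size=n, replace=False)
        res = sps.ks_2samp(sa, sb, method="asymp")
        ks_stats[i], ps[i] = res.statistic, res.pvalue
    ks, p = float(np.median(ks_stats)), float(np.median(ps))
    if correction is not None:
        method, m = correction
        if method != "bonferroni":
            raise ValueError("only plain Bonferroni is applied in-call; "
                             "use adjust_pvalues for Holm families")
        p = min(1.0, p * m)
    return ks, p


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t with Welch-Satterthwaite df, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # both groups constant
        return (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    return float(t), float(p)


def one_sample_relative_t(ratios: np.ndarray, hypothetical_mean: float = 1.0,
                          m_tests: int = 1) -> tuple[float, float]:
    """One-sample t against a no-difference ratio of 1, Bonferroni-corrected."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two ratios")
    t, p = sps.ttest_1samp(r, hypothetical_mean)
    if np.isnan(t):  # zero-variance input
        t, p = (0.0, 1.0) if np.isclose(r.mean(), hypothetical_mean) else (np.inf, 0.0)
    return float(t), min(1.0, float(p) * m_tests)


def compare_cohorts(profiles: pd.DataFrame, feature: str,
                    cohort_a: str = "CRL", cohort_b: str = "MND_TDP",
                    by: str = "region") -> pd.DataFrame:
    """Welch comparisons of a donor-profile feature between two cohorts, per panel."""
    rows = []
    for panel, sub in profiles.groupby(by):
        a = sub.loc[sub["cohort"] == cohort_a, feature].to_numpy()
        b = sub.loc[sub["cohort"] == cohort_b, feature].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        t, p = welch_t(a, b)
        rows.append({by: panel, "feature": feature, "comparison":
                     f"{cohort_a} vs {cohort_b}", "t": t, "p": p,
                     "n_a": a.size, "n_b": b.size})
    return pd.DataFrame(rows)
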