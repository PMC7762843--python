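"""Shared statistical kernel: Fisher transform, t-tests, BH-FDR, RM-ANOVA.

The repeated-measures ANOVA is a classic balanced fully-within-subject
sums-of-squares decomposition (subject as random factor, each effect tested
against its subject-by-effect interaction).  No sphericity correction is
applied; for two-level factors the question does not arise, and for the
nine-level profile factor the uncorrected F is reported as-is.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "AnovaTable",
    "fisher_z",
    "fdr_bh",
    "one_sample_t",
    "paired_t",
    "rm_anova",
]

RHO_CLIP = 1.0 - 1e-6


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    sided: str = "two"
    degenerate: bool = False

    def __post_init__(self):
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class AnovaTable:
    """Per-effect sums of squares, degrees of freedom, F and p."""

    table: pd.DataFrame  # index: effect name; columns: ss, df, ss_err, df_err, F, p

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """Fisher transformation atanh(rho), with |rho|=1 clipped to stay finite."""
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(r, -RHO_CLIP, RHO_CLIP))
    return float(out) if np.isscalar(rho) or out.ndim == 0 else out


def fdr_bh(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions at level ``q``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def one_sample_t(values: np.ndarray, popmean: float = 0.0,
                 sided: str = "two") -> TestResult:
    """One-sample t-test with n-1 df; zero-variance input is flagged."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0.0:
        stat = 0.0 if np.isclose(x.mean(), popmean) else math.inf * np.sign(
            x.mean() - popmean)
        return TestResult(stat, n - 1, 1.0 if stat == 0.0 else 0.0,
                          sided, degenerate=True)
    alternative = {"two": "two-sided", "greater": "greater",
                   "less": "less"}[sided]
    res = sps.ttest_1samp(x, popmean, alternative=alternative)
    return TestResult(float(res.statistic), n - 1, float(res.pvalue), sided)


def paired_t(a: np.ndarray, b: np.ndarray, sided: str = "two") -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal shape")
    return one_sample_t(a - b, 0.0, sided)


def _subset_term(data: np.ndarray, axes_kept: tuple[int, ...]) -> float:
    """n * sum of squared marginal means over the kept axes.

    ``data`` has one axis per factor (subject included); ``axes_kept`` are
    the axes whose levels index the marginal means.
    """
    all_axes = tuple(range(data.ndim))
    reduce_axes = tuple(ax for ax in all_axes if ax not in axes_kept)
    marg = data.mean(axis=reduce_axes) if reduce_axes else data
    n_per_cell = np.prod([data.shape[ax] for ax in reduce_axes]) if reduce_axes else 1
    return float(n_per_cell * np.sum(np.square(marg)))


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> AnovaTable:
    """Balanced fully-within-subject repeated-measures ANOVA (up to 3 factors).

    ``data`` is long-format with one row per subject x cell.  Every effect's
    sums of squares come from the standard inclusion-exclusion over marginal
    means; the error term for an effect is its interaction with subject.
    """
    if not 1 <= len(within) <= 3:
        raise ValueError("1 to 3 within-subject factors supported")
    factors = [subject] + list(within)
    levels = {f: sorted(data[f].unique(), key=str) for f in factors}
    shape = tuple(len(levels[f]) for f in factors)
    expected = int(np.prod(shape))
    if len(data) != expected:
        raise ValueError(
            f"unbalanced design: expected {expected} rows "
            f"(one per subject x cell), got {len(data)}"
        )
    # pivot into a dense [subject x factor1 x ...] array
    idx = {f: {lv: i for i, lv in enumerate(levels[f])} for f in factors}
    arr = np.full(shape, np.nan)
    for _, row in data.iterrows():
        pos = tuple(idx[f][row[f]] for f in factors)
        if not np.isnan(arr[pos]):
            raise ValueError(f"duplicate cell {pos} in design")
        arr[pos] = row[dv]
    if np.any(np.isnan(arr)):
        missing = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            "missing cell for subject "
            f"{levels[subject][missing[0]]!r} (design must be complete)"
        )

    # raw terms T_S = n_S * sum of squared marginal means, for every subset
    axes = {f: i for i, f in enumerate(factors)}
    n_subj = shape[0]

    def term(fs: tuple[str, ...]) -> float:
        return _subset_term(arr, tuple(sorted(axes[f] for f in fs)))

    def ss_effect(fs: tuple[str, ...]) -> float:
        total = 0.0
        for r in range(len(fs) + 1):
            for sub in itertools.combinations(fs, r):
                total += (-1) ** (len(fs) - len(sub)) * term(sub)
        return total

    def df_effect(fs: tuple[str, ...]) -> int:
        d = 1
        for f in fs:
            d *= len(levels[f]) - 1
        return d

    rows = {}
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            ss = ss_effect(combo)
            df = df_effect(combo)
            ss_err = ss_effect((subject,) + combo)
            df_err = df_effect((subject,) + combo)
            ms = ss / df
            ms_err = ss_err / df_err
            if ms_err > 0:
                F = ms / ms_err
                p = float(sps.f.sf(F, df, df_err))
            else:
                F, p = (0.0, 1.0) if ss == 0 else (math.inf, 0.0)
            rows[" x ".join(combo)] = {
                "ss": ss, "df": df, "ss_err": ss_err, "df_err": df_err,
                "F": F, "p": p,
            }
    table = pd.DataFrame(rows).T
    table.index.name = "effect"
    return AnovaTable(table)
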