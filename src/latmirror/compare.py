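"""Laterality categorisation and between-method agreement.

An individual is called left-lateralised when the lower bound of the 95%
CI for their LI exceeds zero, right-lateralised when the upper bound is
below zero, and bilateral when the CI includes zero.  Agreement between two
estimators over a cohort is summarised by a Spearman rank correlation with
a case-resampling bootstrap CI, a 3x3 category cross-tabulation, and the
per-method percentage categorised bilateral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantInputError, PairedLengthError

__all__ = [
    "CATEGORIES",
    "categorise",
    "spearman_with_ci",
    "AgreementReport",
    "agreement_report",
]

CATEGORIES = ("left", "bilateral", "right")


def categorise(ci_low: float, ci_high: float) -> str:
    """Assign left / bilateral / right from a 95% CI.

    ``left`` iff ci_low > 0, ``right`` iff ci_high < 0, else ``bilateral``.
    A bound exactly at zero counts as zero being included (bilateral).  The
    rule is scale-invariant under any positive rescaling of the interval.
    """
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    if ci_low > 0:
        return "left"
    if ci_high < 0:
        return "right"
    return "bilateral"


def spearman_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Spearman rho with a percentile bootstrap 95% CI.

    Pairs with a missing member are dropped pairwise.  Ties receive average
    ranks.  The bootstrap resamples cases with replacement: row ``i`` of a
    ``(n_boot, n)`` index table drawn in one ``rng.integers(0, n, (n_boot,
    n))`` call defines resample ``i`` (the documented stream contract, so a
    run is reproducible from the seed alone).  Resamples in which either
    vector is constant yield an undefined rho and are ignored by the
    percentiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairedLengthError("x and y must be 1-D and the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise PairedLengthError(f"need at least 5 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("rank correlation undefined for constant input")

    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.full(n_boot, np.nan)
    for i in range(n_boot):
        xi, yi = x[idx[i]], y[idx[i]]
        if np.all(xi == xi[0]) or np.all(yi == yi[0]):
            continue
        boots[i] = stats.spearmanr(xi, yi).statistic
    ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
    return rho, float(ci_low), float(ci_high)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between two laterality estimators over paired subjects."""

    rho: float
    rho_ci: tuple[float, float]
    n: int
    cross_tab: pd.DataFrame  # rows: method A category, cols: method B
    pct_bilateral_a: float
    pct_bilateral_b: float

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "rho_ci": list(self.rho_ci),
            "n": self.n,
            "cross_tab": {
                a: {b: int(self.cross_tab.loc[a, b]) for b in CATEGORIES}
                for a in CATEGORIES
            },
            "pct_bilateral_a": self.pct_bilateral_a,
            "pct_bilateral_b": self.pct_bilateral_b,
        }


def agreement_report(results_a, results_b, n_boot: int = 1999,
                     seed: int | None = None) -> AgreementReport:
    """Compare two per-subject result lists from different estimators.

    ``results_a`` and ``results_b`` are paired sequences of objects with
    ``estimate`` and ``category`` attributes (LiResult or GamLiFit), one
    per subject, in the same subject order.
    """
    if len(results_a) != len(results_b):
        raise PairedLengthError("result lists must be paired by subject")
    est_a = [r.estimate for r in results_a]
    est_b = [r.estimate for r in results_b]
    rho, lo, hi = spearman_with_ci(est_a, est_b, n_boot=n_boot, seed=seed)
    tab = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for a, b in zip(results_a, results_b):
        tab.loc[a.category, b.category] += 1
    n = len(results_a)
    pct_a = 100.0 * sum(r.category == "bilateral" for r in results_a) / n
    pct_b = 100.0 * sum(r.category == "bilateral" for r in results_b) / n
    return AgreementReport(
        rho=rho, rho_ci=(lo, hi), n=n, cross_tab=tab,
        pct_bilateral_a=pct_a, pct_bilateral_b=pct_b,
    )
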