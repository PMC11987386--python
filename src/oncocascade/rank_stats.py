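"""Method-comparison rank statistics over method x level metric matrices.

Implements the Friedman average-rank test with ties (within each level,
methods are ranked 1..m with average ranks on ties and the larger metric
getting the larger rank) and the Wilcoxon signed-rank test for paired
per-level differences between two methods.  Both engines are authored
here so rank sums, tie handling and p-value modes are explicit; scipy
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DomainError

__all__ = ["RankMatrix", "friedman_ranks", "wilcoxon_signed_rank"]


@dataclass
class RankMatrix:
    """Friedman analysis of a method x level metric matrix."""

    values: pd.DataFrame  # methods x levels
    ranks: pd.DataFrame  # same shape; per-level ranks, ties averaged
    rank_sums: pd.Series  # per method
    statistic: float  # tie-corrected Friedman chi-square
    pvalue: float

    @property
    def average_ranks(self) -> pd.Series:
        return self.rank_sums / self.values.shape[1]


def friedman_ranks(values: pd.DataFrame) -> RankMatrix:
    """Friedman average-rank test on a methods-by-levels metric matrix.

    Within each level (column) methods receive ranks 1..m, larger metric
    -> larger rank, ties averaged.  The chi-square statistic uses the
    standard tie correction

    .. math:: \\chi^2_F = \\frac{(m-1)\\,\\sum_j (R_j - \\bar R)^2 \\cdot m}
              {\\;\\text{total rank variance}\\;}

    computed in its sum-of-squares form, with the reference distribution
    chi-square on m-1 degrees of freedom.

    Missing cells are rejected by name.
    """
    values = pd.DataFrame(values)
    m, L = values.shape
    if m < 2 or L < 2:
        raise DomainError("Friedman test needs >= 2 methods and >= 2 levels")
    if values.isna().any().any():
        method = values.index[values.isna().any(axis=1)][0]
        level = values.columns[values.isna().any(axis=0)][0]
        raise DomainError(f"missing metric cell at (method={method!r}, level={level!r})")

    ranks = pd.DataFrame(np.column_stack([stats.rankdata(values[c]) for c in values.columns]),
                         index=values.index, columns=values.columns)
    rank_sums = ranks.sum(axis=1)

    # tie-corrected Friedman statistic
    R = rank_sums.to_numpy(dtype=float)
    stat_raw = 12.0 / (L * m * (m + 1)) * np.sum(R**2) - 3.0 * L * (m + 1)
    tie_term = 0.0
    for c in values.columns:
        _, counts = np.unique(values[c].to_numpy(), return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (L * (m**3 - m))
    if correction <= 0:
        # every level fully tied: no evidence of any difference
        statistic, pvalue = 0.0, 1.0
    else:
        statistic = stat_raw / correction
        pvalue = float(stats.chi2.sf(statistic, df=m - 1))
    return RankMatrix(values=values, ranks=ranks, rank_sums=rank_sums,
                      statistic=float(statistic), pvalue=pvalue)


def wilcoxon_signed_rank(
    differences: Sequence[float],
    zero_policy: str = "discard",
    mode: str = "exact",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    T is the smaller of the positive- and negative-sign rank sums over
    ranks of |difference| (ties averaged).  ``zero_policy="discard"``
    drops zero differences before ranking.  Two-sided p-value modes:

    - ``"exact"``: full enumeration of the 2^n sign assignments (n <= 15);
    - ``"normal-approx"``: normal approximation with tie correction and
      no continuity correction;
    - ``"auto"``: exact for n <= 15, normal approximation beyond.
    """
    d = np.asarray(differences, dtype=float)
    if zero_policy == "discard":
        d = d[d != 0]
    elif zero_policy != "keep":
        raise DomainError(f"unknown zero_policy {zero_policy!r}")
    n = d.size
    if n == 0 or not np.any(d != 0):
        raise DomainError("all differences are zero: test undefined")

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    T = min(w_plus, w_minus)

    if mode == "auto":
        mode = "exact" if n <= 15 else "normal-approx"
    if mode == "exact":
        if n > 15:
            raise DomainError("exact enumeration limited to n <= 15; use normal-approx")
        total = ranks.sum()
        # distribution of W+ over all 2^n sign assignments
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        if abs(total - 2 * T) < 1e-12:  # the two tails coincide
            p = 1.0
        else:
            lo = np.sum(sums <= T + 1e-12) / sums.size
            hi = np.sum(sums >= total - T - 1e-12) / sums.size  # symmetric tail
            p = min(1.0, lo + hi)
    elif mode == "normal-approx":
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 2.0
        sigma2 = (n * (n + 1) * (2 * n + 1) - tie_term) / 24.0
        z = (w_plus - mu) / np.sqrt(sigma2)
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise DomainError(f"unknown mode {mode!r}")
    return T, float(min(p, 1.0))
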