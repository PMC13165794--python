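"""Route-compliance statistics across a cohort.

For each parameter (speed, COPx, COPy) the distance-aligned profiles of
all participants are pairwise correlated; the squared Pearson correlation
R^2 of a pair measures how much of one participant's profile the other
explains, and — because the route is the only variable the participants
share — how strongly the route drives them.  Each participant is
summarised by the median (and IQR) of their n-1 pairwise R^2 values
("Route Compliance Index"); medians are ranked per parameter (rank 1 =
smallest), rank sums identify consistently route-driven vs individualistic
participants, and Kendall's W measures agreement of the three parameter
rankings.

Quartile convention: linear interpolation between order statistics
(numpy's default), used consistently for IQR and the low-side outlier
rule (flag if value < Q1 - 1.5 * IQR).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "R2Matrix",
    "ComplianceReport",
    "pairwise_r2",
    "participant_medians",
    "outlier_flags",
    "rank_table",
    "kendalls_w",
    "friedman_test",
    "compliance_report",
]


@dataclass(frozen=True)
class R2Matrix:
    parameter: str
    participant_ids: tuple[str, ...]
    values: np.ndarray  # n x n, symmetric, unit diagonal; NaN = undefined


@dataclass(frozen=True)
class ComplianceReport:
    participant_ids: tuple[str, ...]
    parameters: tuple[str, ...]
    medians: np.ndarray       # n x p
    iqrs: np.ndarray          # n x p
    outliers: np.ndarray      # n x p bool (low-side)
    ranks: np.ndarray         # n x p, rank 1 = smallest median
    rank_sums: np.ndarray     # n
    kendalls_w: float
    friedman_chi2: float
    friedman_p: float


def pairwise_r2(aligned_runs, parameter: str = "v") -> R2Matrix:
    """Squared Pearson correlation for every unordered pair of runs.

    Runs must share the same distance grid.  Constant profiles yield NaN
    (undefined, flagged) off-diagonal entries.
    """
    if len(aligned_runs) < 2:
        raise ValueError("need at least 2 runs")
    grids = {tuple(np.round(r.dist[[0, -1]], 9)) + (r.dist.size,) for r in aligned_runs}
    if len(grids) != 1:
        raise ValueError("runs are not on a common distance grid")
    profiles = np.array([r.values(parameter) for r in aligned_runs])
    n = profiles.shape[0]
    out = np.eye(n)
    sd = profiles.std(axis=1)
    for i, j in combinations(range(n), 2):
        if sd[i] == 0 or sd[j] == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(profiles[i], profiles[j])[0, 1]) ** 2
        out[i, j] = out[j, i] = r2
    ids = tuple(r.participant_id or str(k) for k, r in enumerate(aligned_runs))
    return R2Matrix(parameter=parameter, participant_ids=ids, values=out)


def participant_medians(matrix: R2Matrix) -> tuple[np.ndarray, np.ndarray]:
    """Median and IQR (Q3 - Q1) of each participant's n-1 off-diagonal R^2.

    NaN (undefined) entries are excluded; fewer than 2 valid values for a
    participant is an error.
    """
    m = matrix.values
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    medians = np.empty(n)
    iqrs = np.empty(n)
    for i in range(n):
        vals = np.delete(m[i], i)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            raise ValueError(f"participant {matrix.participant_ids[i]}: <2 valid R^2 values")
        medians[i] = np.median(vals)
        q1, q3 = np.percentile(vals, [25, 75])
        iqrs[i] = q3 - q1
    return medians, iqrs


def outlier_flags(medians: np.ndarray) -> np.ndarray:
    """Low-side outlier rule over the cohort medians: value < Q1 - 1.5*IQR."""
    x = np.asarray(medians, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for the quartile rule")
    q1, q3 = np.percentile(x, [25, 75])
    return x < q1 - 1.5 * (q3 - q1)


def rank_table(medians: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank medians within each parameter column (rank 1 = smallest,
    ties get average ranks) and sum ranks per participant."""
    m = np.atleast_2d(np.asarray(medians, dtype=float))
    if not np.all(np.isfinite(m)):
        raise ValueError("medians must be finite")
    ranks = np.column_stack([stats.rankdata(m[:, j]) for j in range(m.shape[1])])
    return ranks, ranks.sum(axis=1)


def kendalls_w(ranks: np.ndarray) -> tuple[float, float, float]:
    """Kendall's coefficient of concordance over m judges ranking n items.

    ``ranks`` is (n_items, m_judges); each column is one judge's ranking
    (average ranks for ties).  W = 12*S / (m^2 (n^3 - n) - m*T), with S
    the sum of squared deviations of item rank sums from their mean and T
    the tie correction.  The associated chi-square is m*(n-1)*W on n-1
    degrees of freedom.
    """
    r = np.asarray(ranks, dtype=float)
    if r.ndim != 2:
        raise ValueError("ranks must be a 2-D (items x judges) array")
    n, m = r.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 items and 2 judges")
    rank_sums = r.sum(axis=1)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    tie_term = 0.0
    for j in range(m):
        _, counts = np.unique(r[:, j], return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        raise ValueError("degenerate ranking: all items tied")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, df=n - 1))
    return float(w), float(chi2), p


def friedman_test(samples: np.ndarray) -> tuple[float, float]:
    """Friedman rank-sum test over complete blocks.

    ``samples`` is (n_blocks, k_treatments); within-block average ranks,
    tie-corrected chi-square statistic on k-1 degrees of freedom.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a complete (blocks x treatments) array, k >= 2")
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 1.0  # every block fully tied
    chi2 /= correction
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return float(chi2), p


def compliance_report(aligned_runs, parameters=("v", "copx", "copy")) -> ComplianceReport:
    """Full cohort compliance summary over the given parameters."""
    ids = tuple(r.participant_id or str(k) for k, r in enumerate(aligned_runs))
    med_cols, iqr_cols, out_cols = [], [], []
    for p in parameters:
        med, iqr = participant_medians(pairwise_r2(aligned_runs, p))
        med_cols.append(med)
        iqr_cols.append(iqr)
        out_cols.append(outlier_flags(med))
    medians = np.column_stack(med_cols)
    iqrs = np.column_stack(iqr_cols)
    outliers = np.column_stack(out_cols)
    ranks, rank_sums = rank_table(medians)
    w, chi2, p = kendalls_w(ranks)
    return ComplianceReport(
        participant_ids=ids,
        parameters=tuple(parameters),
        medians=medians,
        iqrs=iqrs,
        outliers=outliers,
        ranks=ranks,
        rank_sums=rank_sums,
        kendalls_w=w,
        friedman_chi2=chi2,
        friedman_p=p,
    )
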