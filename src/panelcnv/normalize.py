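"""Coverage normalization: fractional coverage, batch-median log2 ratios and
sex-aware X-chromosome correction.

The model: on a hybrid-capture panel, an interval's share of a sample's total
coverage reflects capture efficiency x copy number.  Capture efficiency is a
property of the bait, so dividing each sample's fractional coverage by the
per-interval median across the co-captured batch cancels it, leaving a
copy-number fold change.  On the log2 scale the diploid state is 0, a
single-copy gain is log2(3/2) ~ 0.58 and a single-copy loss is exactly -1.

The X chromosome needs one more step: depending on the sex mix of the batch,
male samples sit near a single-copy loss (or females near a gain) relative to
the batch median.  Samples are split into two groups by exact 2-medoid
clustering of per-sample X summaries and each group is re-centred on zero;
the group with the lower medoid (one X dose) is predicted male.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import BatchSizeError, DegenerateSampleError
from .io import CoverageTable, TargetInterval

logger = logging.getLogger(__name__)

#: log2 value assigned to a zero fraction at an interval whose batch median
#: is non-zero (keeps the matrix finite; such cells stay loss-eligible but
#: are excluded from boxplot statistics)
FLOOR_LOG2 = -10.0

#: minimum medoid separation (log2 units) for the sex clustering to be
#: considered informative; below this the batch is treated as single-sex
DEFAULT_MIN_MEDOID_SEPARATION = 0.3

#: fraction of highest/lowest X-interval ratios trimmed per sample before
#: computing its X summary (outlier-probe removal)
DEFAULT_X_TRIM_FRACTION = 0.1

#: minimum batch size for a representative per-interval median
MIN_BATCH_SIZE = 3


@dataclass
class Log2RatioMatrix:
    """Samples x intervals matrix of batch-median-normalized log2 ratios.

    ``masked`` flags intervals whose batch-median fraction is zero (dead
    baits); their column is NaN and excluded from all downstream statistics.
    """

    intervals: list[TargetInterval]
    samples: list[str]
    ratios: np.ndarray          # shape (n_samples, n_intervals); NaN where masked
    masked: np.ndarray          # shape (n_intervals,), bool
    floor: float = FLOOR_LOG2

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def x_columns(self) -> np.ndarray:
        """Indices of unmasked X-chromosome intervals."""
        return np.array(
            [iv.rank for iv in self.intervals if iv.is_x and not self.masked[iv.rank]],
            dtype=int,
        )

    def summary_values(self, sample_index: int) -> np.ndarray:
        """Finite, non-floor ratios for one sample (input to boxplot stats)."""
        row = self.ratios[sample_index]
        keep = np.isfinite(row) & (row != self.floor)
        return row[keep]


@dataclass
class SexClusterResult:
    """Outcome of 2-medoid clustering of per-sample X summaries."""

    assignment: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    medoid_values: tuple[float, ...] = ()
    predicted_sex: list[str] = field(default_factory=list)  # male/female/indeterminate
    shift: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    summaries: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    degenerate: bool = False
    has_x: bool = True


def fractional_coverage(cov: CoverageTable) -> np.ndarray:
    """Per-sample interval fractions: cell(s,i) = totals(s,i) / sum_i totals(s,i).

    Removes per-sample sequencing-depth differences; each row sums to 1.
    """
    sums = cov.totals.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise DegenerateSampleError(
            f"sample {cov.samples[int(zero[0])]!r} has zero total coverage"
        )
    return cov.totals / sums[:, None]


def batch_median_log2(
    fractions: np.ndarray,
    intervals: Sequence[TargetInterval],
    samples: Sequence[str],
    floor: float = FLOOR_LOG2,
) -> Log2RatioMatrix:
    """log2 of each sample's fraction over the per-interval batch median.

    Intervals with a zero batch median are masked (NaN).  A zero sample
    fraction at an unmasked interval maps to ``floor`` rather than -inf.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[0] < MIN_BATCH_SIZE:
        raise BatchSizeError(
            f"batch-median normalization needs >= {MIN_BATCH_SIZE} samples, "
            f"got {fractions.shape[0]}"
        )
    med = np.median(fractions, axis=0)
    masked = med == 0
    ratios = np.full(fractions.shape, np.nan)
    ok = ~masked
    with np.errstate(divide="ignore"):
        ratios[:, ok] = np.log2(fractions[:, ok] / med[ok])
    ratios[:, ok] = np.where(
        fractions[:, ok] == 0, floor, ratios[:, ok]
    )
    return Log2RatioMatrix(
        intervals=list(intervals),
        samples=list(samples),
        ratios=ratios,
        masked=masked,
        floor=floor,
    )


def x_summaries(log2: Log2RatioMatrix, trim_fraction: float = DEFAULT_X_TRIM_FRACTION) -> np.ndarray:
    """Per-sample median of X-interval ratios after trimming outlier probes.

    Trims the highest and lowest ``trim_fraction`` of each sample's X ratios
    (at least one value must survive; tiny panels trim nothing).
    """
    xcols = log2.x_columns()
    out = np.full(log2.n_samples, np.nan)
    for s in range(log2.n_samples):
        vals = log2.ratios[s, xcols]
        vals = np.sort(vals[np.isfinite(vals)])
        if vals.size == 0:
            continue
        k = int(trim_fraction * vals.size)
        if vals.size - 2 * k >= 1 and k > 0:
            vals = vals[k : vals.size - k]
        out[s] = np.median(vals)
    return out


def _partition_cost(values: np.ndarray, m1: float, m2: float) -> float:
    return float(np.sum(np.minimum(np.abs(values - m1), np.abs(values - m2))))


def cluster_x_samples(
    log2: Log2RatioMatrix,
    min_separation: float = DEFAULT_MIN_MEDOID_SEPARATION,
    trim_fraction: float = DEFAULT_X_TRIM_FRACTION,
) -> SexClusterResult:
    """Partition samples around two medoids of their X summaries.

    The optimization is exact: every pair of samples is evaluated as the
    medoid pair and the pair minimizing total absolute deviation to the
    nearest medoid wins (batches are small, so exhaustive search is cheap and
    oracle-testable).  If the two medoids are closer than ``min_separation``
    the batch is treated as single-sex: one cluster, all sexes indeterminate,
    and the correction shift is the global median.
    """
    n = log2.n_samples
    if n < 2:
        raise BatchSizeError("sex clustering needs >= 2 samples")
    if log2.x_columns().size == 0:
        logger.info("no X-chromosome intervals on panel; X correction skipped")
        return SexClusterResult(
            assignment=np.zeros(n, dtype=int),
            predicted_sex=["indeterminate"] * n,
            shift=np.zeros(n),
            summaries=np.full(n, np.nan),
            degenerate=True,
            has_x=False,
        )
    summ = x_summaries(log2, trim_fraction)
    best: tuple[float, int, int] | None = None
    for i, j in combinations(range(n), 2):
        cost = _partition_cost(summ, summ[i], summ[j])
        if best is None or cost < best[0] - 1e-15:
            best = (cost, i, j)
    assert best is not None
    _, i, j = best
    m_lo, m_hi = sorted((float(summ[i]), float(summ[j])))
    separation = m_hi - m_lo

    if separation < min_separation:
        global_median = float(np.median(summ))
        logger.info(
            "medoid separation %.3f < %.3f: single-sex batch, sexes indeterminate",
            separation,
            min_separation,
        )
        return SexClusterResult(
            assignment=np.zeros(n, dtype=int),
            medoid_values=(m_lo, m_hi),
            predicted_sex=["indeterminate"] * n,
            shift=np.full(n, -global_median),
            summaries=summ,
            degenerate=True,
        )

    # nearest-medoid assignment; ties go to the lower medoid (cluster 0)
    assignment = np.where(
        np.abs(summ - m_lo) <= np.abs(summ - m_hi), 0, 1
    ).astype(int)
    cluster_median = np.array(
        [float(np.median(summ[assignment == c])) for c in (0, 1)]
    )
    shift = -cluster_median[assignment]
    sex_by_cluster = {0: "male", 1: "female"}  # lower X dose = one X = male
    return SexClusterResult(
        assignment=assignment,
        medoid_values=(m_lo, m_hi),
        predicted_sex=[sex_by_cluster[int(c)] for c in assignment],
        shift=shift,
        summaries=summ,
        degenerate=False,
    )


def normalize_x(log2: Log2RatioMatrix, clusters: SexClusterResult) -> Log2RatioMatrix:
    """Re-centre each sample's X-interval ratios on its cluster median.

    Autosomal ratios are untouched.  Floor cells (zero coverage) keep the
    floor value so they remain recognizable downstream.
    """
    if not clusters.has_x:
        return log2
    xcols = log2.x_columns()
    ratios = log2.ratios.copy()
    for s in range(log2.n_samples):
        col_vals = ratios[s, xcols]
        adjust = np.isfinite(col_vals) & (col_vals != log2.floor)
        col_vals[adjust] += clusters.shift[s]
        ratios[s, xcols] = col_vals
    return Log2RatioMatrix(
        intervals=log2.intervals,
        samples=log2.samples,
        ratios=ratios,
        masked=log2.masked,
        floor=log2.floor,
    )


def normalize_batch(
    cov: CoverageTable,
    min_separation: float = DEFAULT_MIN_MEDOID_SEPARATION,
    trim_fraction: float = DEFAULT_X_TRIM_FRACTION,
) -> tuple[Log2RatioMatrix, Log2RatioMatrix, SexClusterResult]:
    """Full normalization of one batch.

    Returns (pre-X-correction matrix, corrected matrix, sex clustering).
    """
    frac = fractional_coverage(cov)
    pre = batch_median_log2(frac, cov.intervals, cov.samples)
    clusters = cluster_x_samples(pre, min_separation, trim_fraction)
    post = normalize_x(pre, clusters)
    return pre, post, clusters
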