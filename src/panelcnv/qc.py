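"""Distribution-shaped sample quality control.

Each sample's log2-ratio distribution is summarized by conventional boxplot
statistics (Tukey hinges; whiskers are the most extreme data values within
Q1/Q3 +/- a configurable multiple of the interquartile range).  A sample
fails QC when either whisker extends beyond the theoretical log2 ratio for a
single-copy gain (0.58) or loss (-1): such a distribution is too dispersed to
distinguish real single-copy events from noise.

Because the per-interval batch median is the copy-number reference, a failed
sample would skew it; the pipeline therefore removes failures and reruns the
whole normalization with the survivors, iterating until an iteration has no
failures.  A batch with fewer than the minimum number of passing samples
(default 3) is failed outright — the median of fewer samples is not a
representative diploid reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .errors import BatchSizeError, InsufficientDataError
from .io import CoverageTable, write_log2_matrix, write_qc_table
from .normalize import Log2RatioMatrix, SexClusterResult, normalize_batch

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FiveNumberSummary:
    """Boxplot statistics under a configurable IQR multiplier."""

    lower_whisker: float
    q1: float
    median: float
    q3: float
    upper_whisker: float
    iqr_multiplier: float

    def __post_init__(self) -> None:
        vals = (self.lower_whisker, self.q1, self.median, self.q3, self.upper_whisker)
        if not all(a <= b + 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError(f"five-number summary not ordered: {vals}")

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class QCVerdict:
    sample: str
    passed: bool
    reason: str = ""
    iteration: int = 1


@dataclass
class SampleQCRecord:
    """One row of the QC summary output."""

    sample: str
    summary: FiveNumberSummary
    passed: bool
    reason: str
    iteration: int
    predicted_sex: str


def _tukey_hinges(sorted_vals: np.ndarray) -> tuple[float, float, float]:
    """(Q1, median, Q3) as Tukey hinges: median of the lower/upper half,
    halves including the median element when n is odd."""
    n = sorted_vals.size
    half = (n + 1) // 2
    q1 = float(np.median(sorted_vals[:half]))
    q3 = float(np.median(sorted_vals[n - half:]))
    med = float(np.median(sorted_vals))
    return q1, med, q3


def five_number_summary(values, iqr_multiplier: float = 3.0) -> FiveNumberSummary:
    """Boxplot five-number summary of a vector of log2 ratios.

    Whiskers are actual data values: the greatest (lowest) value within
    Q3 + x*IQR (Q1 - x*IQR).  Requires at least 5 finite values and a
    multiplier >= 1 (smaller multipliers can place a fence inside the box,
    leaving no data value between hinge and fence).
    """
    if iqr_multiplier < 1:
        from .errors import ConfigError

        raise ConfigError("iqr_multiplier must be >= 1")
    vals = np.asarray(values, dtype=float)
    vals = np.sort(vals[np.isfinite(vals)])
    if vals.size < 5:
        raise InsufficientDataError(
            f"five-number summary needs >= 5 finite values, got {vals.size}"
        )
    q1, med, q3 = _tukey_hinges(vals)
    iqr = q3 - q1
    hi_fence = q3 + iqr_multiplier * iqr
    lo_fence = q1 - iqr_multiplier * iqr
    upper = float(vals[vals <= hi_fence].max())
    lower = float(vals[vals >= lo_fence].min())
    return FiveNumberSummary(
        lower_whisker=lower,
        q1=q1,
        median=med,
        q3=q3,
        upper_whisker=upper,
        iqr_multiplier=iqr_multiplier,
    )


def sample_qc(
    summary: FiveNumberSummary,
    sample: str = "",
    gain_theory: float = 0.58,
    loss_theory: float = -1.0,
    iteration: int = 1,
) -> QCVerdict:
    """Pass/fail rule: a whisker strictly beyond the theoretical single-copy
    gain (0.58) or loss (-1) ratio fails the sample.  A whisker exactly at a
    bound passes ("extends beyond" is strict)."""
    reasons = []
    if summary.upper_whisker > gain_theory:
        reasons.append(
            f"upper whisker {summary.upper_whisker:.4f} exceeds "
            f"single-copy gain bound {gain_theory:g}"
        )
    if summary.lower_whisker < loss_theory:
        reasons.append(
            f"lower whisker {summary.lower_whisker:.4f} below "
            f"single-copy loss bound {loss_theory:g}"
        )
    return QCVerdict(
        sample=sample,
        passed=not reasons,
        reason="; ".join(reasons),
        iteration=iteration,
    )


@dataclass
class BatchQCResult:
    """Outcome of the iterative QC loop."""

    status: str  # "pass" or "batch_failed"
    final_log2: Log2RatioMatrix | None
    final_pre_x: Log2RatioMatrix | None
    clusters: SexClusterResult | None
    verdicts: list[QCVerdict]
    summaries: dict[str, FiveNumberSummary]  # at each sample's final iteration
    predicted_sex: dict[str, str]
    n_iterations: int
    iteration_dirs: list[Path] = field(default_factory=list)

    @property
    def passed_samples(self) -> list[str]:
        return [v.sample for v in self.verdicts if v.passed]

    def records(self) -> list[SampleQCRecord]:
        return [
            SampleQCRecord(
                sample=v.sample,
                summary=self.summaries[v.sample],
                passed=v.passed,
                reason=v.reason,
                iteration=v.iteration,
                predicted_sex=self.predicted_sex.get(v.sample, "indeterminate"),
            )
            for v in sorted(self.verdicts, key=lambda v: v.sample)
        ]


def _write_iteration_artifacts(
    out_dir: Path,
    iteration: int,
    pre: Log2RatioMatrix,
    post: Log2RatioMatrix,
    records: list[SampleQCRecord],
    verdicts: list[QCVerdict],
    iqr_multiplier: float,
) -> Path:
    from . import viz  # deferred: matplotlib import is slow and optional here

    it_dir = out_dir / f"iteration_{iteration}"
    it_dir.mkdir(parents=True, exist_ok=True)
    write_log2_matrix(post, it_dir / "log2_matrix.tsv")
    write_qc_table(records, it_dir / "qc_summary.tsv")
    viz.plot_batch_boxplots(post, verdicts, iqr_multiplier, it_dir / "batch_boxplots")
    viz.plot_x_boxplots(pre, post, it_dir / "x_boxplots")
    return it_dir


def iterate_qc(
    cov: CoverageTable,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> BatchQCResult:
    """Run the normalize -> QC -> remove-failures loop to convergence.

    Each iteration renormalizes the survivors (the batch median changes when
    a sample is removed), corrects X dosage, summarizes every sample and
    fails those whose whiskers cross the theoretical single-copy bounds.
    The loop stops at the first iteration with zero failures, or declares the
    whole batch failed when fewer than ``min_pass_samples`` survive.

    When ``out_dir`` is given, each iteration writes its matrix, QC table and
    boxplot figures into ``iteration_k/`` subdirectories.
    """
    cfg = config or RunConfig()
    if cov.n_samples < cfg.min_pass_samples:
        raise BatchSizeError(
            f"batch has {cov.n_samples} samples; need >= {cfg.min_pass_samples}"
        )
    out_dir = Path(out_dir) if out_dir is not None else None

    survivors = list(cov.samples)
    final_verdicts: dict[str, QCVerdict] = {}
    final_summaries: dict[str, FiveNumberSummary] = {}
    predicted_sex: dict[str, str] = {}
    iteration_dirs: list[Path] = []
    iteration = 0

    while True:
        iteration += 1
        sub = cov.subset(survivors)
        pre, post, clusters = normalize_batch(
            sub, cfg.min_medoid_separation, cfg.x_trim_fraction
        )
        verdicts: list[QCVerdict] = []
        for s_idx, sample in enumerate(post.samples):
            summary = five_number_summary(
                post.summary_values(s_idx), cfg.iqr_multiplier
            )
            verdict = sample_qc(
                summary,
                sample,
                gain_theory=cfg.qc_gain_bound,
                loss_theory=cfg.qc_loss_bound,
                iteration=iteration,
            )
            verdicts.append(verdict)
            final_summaries[sample] = summary
            final_verdicts[sample] = verdict
            predicted_sex[sample] = clusters.predicted_sex[s_idx]

        if out_dir is not None:
            records = [
                SampleQCRecord(
                    sample=v.sample,
                    summary=final_summaries[v.sample],
                    passed=v.passed,
                    reason=v.reason,
                    iteration=iteration,
                    predicted_sex=predicted_sex[v.sample],
                )
                for v in sorted(verdicts, key=lambda v: v.sample)
            ]
            iteration_dirs.append(
                _write_iteration_artifacts(
                    out_dir, iteration, pre, post, records, verdicts,
                    cfg.iqr_multiplier,
                )
            )

        failed = [v.sample for v in verdicts if not v.passed]
        logger.info(
            "iteration %d: %d samples, %d failed QC%s",
            iteration, len(survivors), len(failed),
            f" ({', '.join(failed)})" if failed else "",
        )
        if not failed:
            return BatchQCResult(
                status="pass",
                final_log2=post,
                final_pre_x=pre,
                clusters=clusters,
                verdicts=list(final_verdicts.values()),
                summaries=final_summaries,
                predicted_sex=predicted_sex,
                n_iterations=iteration,
                iteration_dirs=iteration_dirs,
            )
        survivors = [s for s in survivors if s not in failed]
        if len(survivors) < cfg.min_pass_samples:
            logger.warning(
                "iteration %d: only %d samples pass QC (< %d); batch failed",
                iteration, len(survivors), cfg.min_pass_samples,
            )
            return BatchQCResult(
                status="batch_failed",
                final_log2=None,
                final_pre_x=None,
                clusters=None,
                verdicts=list(final_verdicts.values()),
                summaries=final_summaries,
                predicted_sex=predicted_sex,
                n_iterations=iteration,
                iteration_dirs=iteration_dirs,
            )
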