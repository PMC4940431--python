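"""CNV calling: dual-threshold segmentation, cohort annotation and the
droplet-digital-PCR confirmation calculator.

An interval supports a gain only when its log2 ratio exceeds BOTH the fixed
user threshold (default 0.40) and the sample's own upper boxplot whisker;
losses symmetrically must fall below both the fixed loss threshold (default
-0.55) and the lower whisker.  The whisker condition adapts calling to each
sample's dispersion: a noisy sample needs a stronger signal before an excursion
is called.  Maximal runs of consecutive same-type eligible intervals on one
chromosome become calls; masked intervals break runs.

The estimated absolute copy number is 2 * 2^median_log2 (relative to the
diploid batch reference; on the X chromosome the ratios are sex-corrected, so
the estimate is relative to the sample's own expected X dosage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, ConfigError
from .io import TargetInterval
from .qc import FiveNumberSummary

logger = logging.getLogger(__name__)


@dataclass
class CallingThresholds:
    """Fixed thresholds for calling and annotation.

    Defaults are the validated operating point: gains >= 0.40, losses
    <= -0.55 (log2), single-interval calls allowed, recurrence above 1% of
    the cohort, extreme GC outside 35-65%.
    """

    gain_log2: float = 0.40
    loss_log2: float = -0.55
    min_probes_gain: int = 1
    min_probes_loss: int = 1
    cohort_recurrence_fraction: float = 0.01
    gc_low: float = 0.35
    gc_high: float = 0.65

    def __post_init__(self) -> None:
        if not (self.gain_log2 > 0 > self.loss_log2):
            raise ConfigError("need gain_log2 > 0 > loss_log2")
        if not (0 < self.cohort_recurrence_fraction < 1):
            raise ConfigError("cohort_recurrence_fraction must be in (0, 1)")
        if min(self.min_probes_gain, self.min_probes_loss) < 1:
            raise ConfigError("min_probes must be >= 1")


@dataclass
class CNVCall:
    """One contiguous run of intervals exceeding the calling thresholds.

    ``id`` is per-sample, 1-based, assigned in genome order; the same
    identifier labels the call in the text table and on the plots.
    """

    id: int
    sample: str
    type: str  # "gain" | "loss"
    chrom: str
    first_rank: int
    last_rank: int
    start: int  # bp, start of first interval
    end: int    # bp, end of last interval
    first_label: str
    last_label: str
    n_intervals: int
    median_log2: float
    inferred_cn: float
    recurrent: bool = False
    gc_flag: bool = False

    @property
    def unique_key(self) -> tuple[str, int, int, str]:
        """Identity used for cohort recurrence: (chrom, rank span, type)."""
        return (self.chrom, self.first_rank, self.last_rank, self.type)


def _eligibility(
    ratios: np.ndarray,
    summary: FiveNumberSummary,
    thresholds: CallingThresholds,
) -> np.ndarray:
    """Per-interval state: +1 gain-eligible, -1 loss-eligible, 0 neither.

    NaN (masked) is never eligible.  Comparisons are strict, matching the QC
    convention.
    """
    gain_cut = max(thresholds.gain_log2, summary.upper_whisker)
    loss_cut = min(thresholds.loss_log2, summary.lower_whisker)
    state = np.zeros(ratios.size, dtype=int)
    finite = np.isfinite(ratios)
    state[finite & (ratios > gain_cut)] = 1
    state[finite & (ratios < loss_cut)] = -1
    return state


def segment_calls(
    sample: str,
    ratios: np.ndarray,
    intervals: Sequence[TargetInterval],
    summary: FiveNumberSummary,
    thresholds: CallingThresholds | None = None,
) -> list[CNVCall]:
    """Segment one sample's log2 vector into candidate gain/loss calls.

    Runs shorter than the type's ``min_probes`` are dropped.  Chromosome
    boundaries and masked intervals always break runs.
    """
    th = thresholds or CallingThresholds()
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size != len(intervals):
        raise AlignmentError(
            f"ratio vector length {ratios.size} != {len(intervals)} intervals"
        )
    state = _eligibility(ratios, summary, th)

    calls: list[CNVCall] = []
    run_start: int | None = None
    run_state = 0

    def flush(run_end: int) -> None:
        nonlocal run_start, run_state
        if run_start is None:
            return
        n = run_end - run_start + 1
        min_probes = th.min_probes_gain if run_state == 1 else th.min_probes_loss
        if n >= min_probes:
            member = ratios[run_start : run_end + 1]
            med = float(np.median(member))
            calls.append(
                CNVCall(
                    id=0,  # assigned after all runs collected
                    sample=sample,
                    type="gain" if run_state == 1 else "loss",
                    chrom=intervals[run_start].chrom,
                    first_rank=run_start,
                    last_rank=run_end,
                    start=intervals[run_start].start,
                    end=intervals[run_end].end,
                    first_label=intervals[run_start].label,
                    last_label=intervals[run_end].label,
                    n_intervals=n,
                    median_log2=med,
                    inferred_cn=float(2.0 * 2.0 ** med),
                )
            )
        run_start, run_state = None, 0

    for i in range(ratios.size):
        s = state[i]
        breaks = (
            run_start is not None
            and (s != run_state or intervals[i].chrom != intervals[run_start].chrom)
        )
        if breaks:
            flush(i - 1)
        if s != 0 and run_start is None:
            run_start, run_state = i, s
    flush(ratios.size - 1)

    for k, call in enumerate(calls, start=1):
        call.id = k
    return calls


def cohort_annotate(
    calls_by_case: Mapping[str, Sequence[CNVCall]],
    n_cases: int,
    thresholds: CallingThresholds | None = None,
) -> list[CNVCall]:
    """Flag recurrent calls across a cohort.

    Calls are grouped into "unique calls" by (chrom, first rank, last rank,
    type); a call is recurrent when the number of distinct cases carrying it
    exceeds ``cohort_recurrence_fraction`` of ``n_cases``.  Recurrent calls —
    likely copy-number polymorphisms or systematic capture artifacts — are
    flagged, never silently deleted.
    """
    th = thresholds or CallingThresholds()
    if n_cases < 1:
        raise ConfigError("n_cases must be >= 1")
    cases_by_key: dict[tuple, set[str]] = {}
    for case, calls in calls_by_case.items():
        for call in calls:
            cases_by_key.setdefault(call.unique_key, set()).add(case)
    out: list[CNVCall] = []
    for case in calls_by_case:
        for call in calls_by_case[case]:
            frac = len(cases_by_key[call.unique_key]) / n_cases
            call.recurrent = frac > th.cohort_recurrence_fraction
            out.append(call)
    return out


def flag_extreme_gc(
    calls: Iterable[CNVCall],
    gc_per_interval: np.ndarray | None,
    thresholds: CallingThresholds | None = None,
) -> list[CNVCall]:
    """Flag calls confined to extreme-GC intervals.

    ``gc_flag`` is set when every member interval has GC below ``gc_low`` or
    above ``gc_high`` — such baits capture inconsistently and produce small
    recurrent artifacts.  GC content is user-supplied (aligned to interval
    ranks); when absent, flags stay False.
    """
    th = thresholds or CallingThresholds()
    calls = list(calls)
    if gc_per_interval is None:
        logger.info("no GC table supplied; extreme-GC flags left unset")
        return calls
    gc = np.asarray(gc_per_interval, dtype=float)
    for call in calls:
        member = gc[call.first_rank : call.last_rank + 1]
        call.gc_flag = bool(np.all((member < th.gc_low) | (member > th.gc_high)))
    return calls


@dataclass(frozen=True)
class DdpcrResult:
    normalized_cn: float
    verdict: str  # "loss" | "neutral" | "gain"
    qc_ok: bool


def ddpcr_call(
    raw_cn: float,
    reference_ratio: float,
    rcc_scale: float = 2.0,
    loss_below: float = 1.5,
    gain_above: float = 2.5,
    qc_low: float = 0.9,
    qc_high: float = 1.2,
) -> DdpcrResult:
    """Normalize a ddPCR copy-number value and call loss/neutral/gain.

    The Reference Correction Constant is twice the copy-number ratio of the
    two reference genes (AP3B1 vs RPP30); the raw value is divided by it and
    rescaled by ``rcc_scale`` (default 2) so that a perfectly calibrated
    assay (ratio 1) is left unchanged.  Losses are normalized values < 1.5,
    gains > 2.5.  ``qc_ok`` is False when the reference ratio falls outside
    the 0.9-1.2 window, signalling possible CNV of a reference gene.
    """
    if raw_cn < 0:
        raise ConfigError("raw_cn must be >= 0")
    if reference_ratio <= 0:
        raise ConfigError("reference ratio must be positive")
    rcc = 2.0 * reference_ratio
    normalized = raw_cn / rcc * rcc_scale
    if normalized < loss_below:
        verdict = "loss"
    elif normalized > gain_above:
        verdict = "gain"
    else:
        verdict = "neutral"
    qc_ok = qc_low <= reference_ratio <= qc_high
    return DdpcrResult(normalized_cn=normalized, verdict=verdict, qc_ok=qc_ok)


def load_gc_table(path, intervals: Sequence[TargetInterval]) -> np.ndarray:
    """Read a two-column (label, GC fraction) table aligned to the panel.

    Intervals absent from the table get NaN (never flagged).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["label", "gc"], comment="#")
    by_label = dict(zip(df["label"].astype(str), df["gc"].astype(float)))
    return np.array([by_label.get(iv.label, np.nan) for iv in intervals])


def load_exclusion_list(path) -> set[str]:
    """Read interval labels (one per line) of exons known to fail NGS."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def apply_exclusion_list(calls: Iterable[CNVCall], excluded_labels: set[str]) -> list[CNVCall]:
    """Drop single-interval calls on excluded exons (pre-filter for exons
    known to fail NGS in a given lab); multi-interval calls are kept."""
    kept = [
        c for c in calls
        if not (c.n_intervals == 1 and c.first_label in excluded_labels)
    ]
    return kept
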