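"""End-to-end orchestration: load -> iterative QC -> call -> annotate ->
plot -> write, plus the machine-readable run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .calling import (
    CallingThresholds,
    CNVCall,
    apply_exclusion_list,
    cohort_annotate,
    flag_extreme_gc,
    load_exclusion_list,
    load_gc_table,
)
from .config import RunConfig
from .errors import InputError
from .io import load_batch, write_outputs
from .qc import BatchQCResult, iterate_qc
from . import viz

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_BATCH_FAILED = 3


@dataclass
class RunResult:
    exit_code: int
    status: str
    manifest: dict
    manifest_path: Path | None
    qc: BatchQCResult | None = None
    calls: list[CNVCall] | None = None


def _thresholds(cfg: RunConfig) -> CallingThresholds:
    return CallingThresholds(
        gain_log2=cfg.gain_log2,
        loss_log2=cfg.loss_log2,
        min_probes_gain=cfg.min_probes_gain,
        min_probes_loss=cfg.min_probes_loss,
        cohort_recurrence_fraction=cfg.cohort_recurrence_fraction,
        gc_low=cfg.gc_low,
        gc_high=cfg.gc_high,
    )


def run(config: RunConfig) -> RunResult:
    """Execute a full run per the configuration; never raises for batch-QC
    failure (that is a reported status with its own exit code)."""
    if config.input_dir is None or config.interval_list is None or config.output_dir is None:
        raise InputError("input_dir, interval_list and output_dir are required")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cov = load_batch(config.input_dir, config.interval_list, config.x_chrom_names)
    logger.info("loaded %d samples x %d intervals", cov.n_samples, cov.n_intervals)

    qc_result = iterate_qc(cov, config, out_dir=out_dir)
    files: list[Path] = [p for d in qc_result.iteration_dirs for p in sorted(d.iterdir())]

    thresholds = _thresholds(config)
    status = qc_result.status
    calls: list[CNVCall] = []

    if status == "pass":
        from .calling import segment_calls

        final = qc_result.final_log2
        assert final is not None
        calls_by_sample: dict[str, list[CNVCall]] = {}
        for s_idx, sample in enumerate(final.samples):
            sample_calls = segment_calls(
                sample,
                final.ratios[s_idx],
                final.intervals,
                qc_result.summaries[sample],
                thresholds,
            )
            if config.exclusion_list is not None:
                sample_calls = apply_exclusion_list(
                    sample_calls, load_exclusion_list(config.exclusion_list)
                )
            calls_by_sample[sample] = sample_calls

        calls = cohort_annotate(calls_by_sample, len(final.samples), thresholds)
        gc = (
            load_gc_table(config.gc_table, final.intervals)
            if config.gc_table is not None
            else None
        )
        calls = flag_extreme_gc(calls, gc, thresholds)
        if config.drop_recurrent:
            n0 = len(calls)
            calls = [c for c in calls if not c.recurrent]
            logger.info("dropped %d recurrent calls", n0 - len(calls))
        calls.sort(key=lambda c: (c.sample, c.first_rank))

        for s_idx, sample in enumerate(final.samples):
            sample_calls = [c for c in calls if c.sample == sample]
            files += viz.plot_sample(
                sample, final.ratios[s_idx], final.intervals, sample_calls,
                qc_result.summaries[sample], thresholds,
                out_dir / "plots" / f"{sample}_genome", scope="genome",
            )
            for chrom in sorted({c.chrom for c in sample_calls}):
                files += viz.plot_sample(
                    sample, final.ratios[s_idx], final.intervals, sample_calls,
                    qc_result.summaries[sample], thresholds,
                    out_dir / "plots" / f"{sample}_{chrom}", scope=chrom,
                )
        files += write_outputs(final, calls, qc_result.records(), out_dir)
        exit_code = EXIT_OK
    else:
        # batch failed: QC summary is still written, but no call table
        from .io import write_qc_table

        files.append(write_qc_table(qc_result.records(), out_dir / "qc_summary.tsv"))
        exit_code = EXIT_BATCH_FAILED

    manifest = {
        "tool": "panelcnv",
        "version": __version__,
        "status": status,
        "exit_code": exit_code,
        "n_iterations": qc_result.n_iterations,
        "n_samples_loaded": cov.n_samples,
        "n_samples_passed": len(qc_result.passed_samples),
        "n_calls": len(calls),
        "config": config.as_manifest_dict(),
        "files": sorted(str(p.relative_to(out_dir)) for p in files),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunResult(
        exit_code=exit_code,
        status=status,
        manifest=manifest,
        manifest_path=manifest_path,
        qc=qc_result,
        calls=calls,
    )


def merge_cohort_calls(
    call_tables: list[Path],
    out_path: Path,
    n_cases: int | None = None,
    recurrence_fraction: float = 0.01,
) -> int:
    """Merge call tables from multiple runs and recompute cohort recurrence.

    At lab scale the recurrence denominator spans many batches; this rereads
    the per-run call TSVs, regroups unique calls by (chrom, span, type) and
    rewrites the recurrent flag against the merged case count (``n_cases``
    defaults to the number of distinct samples seen).  Returns the number of
    unique recurrent calls.
    """
    import pandas as pd

    frames = [pd.read_csv(p, sep="\t") for p in call_tables]
    merged = pd.concat(frames, ignore_index=True) if frames else None
    if merged is None or merged.empty:
        raise InputError("no calls found in the supplied tables")
    cases = merged["sample"].nunique()
    denom = n_cases if n_cases is not None else cases
    key_cols = ["chrom", "span", "type"]
    counts = merged.groupby(key_cols)["sample"].nunique()
    merged["recurrent"] = [
        counts[tuple(row[k] for k in key_cols)] / denom > recurrence_fraction
        for _, row in merged.iterrows()
    ]
    merged.to_csv(out_path, sep="\t", index=False)
    return int(
        merged.loc[merged["recurrent"], key_cols].drop_duplicates().shape[0]
    )
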