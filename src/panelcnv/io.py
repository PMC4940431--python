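"""Reading and writing batch coverage data.

Input side: GATK DepthOfCoverage ``sample_interval_summary`` tables (one per
sample, one row per target interval) and a plain-text interval list.  Output
side: the tab-delimited log2-ratio matrix, CNV call table and QC summary that
make up a run's text deliverables.

Coordinates are 1-based inclusive throughout, matching GATK interval notation
``chrom:start-end``.  The sample name is taken from the ``{sample}_total_cvg``
column header, never from the filename; the filename is kept as provenance
only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DuplicateSampleError,
    FormatError,
    InputError,
)

#: chromosome names treated as the X chromosome by default
DEFAULT_X_NAMES: tuple[str, ...] = ("X", "chrX")

_TARGET_RE = re.compile(r"^\s*(?P<chrom>[^:\s]+):(?P<start>\d+)(?:-(?P<end>\d+))?\s*$")


@dataclass(frozen=True)
class TargetInterval:
    """One captured genome region (typically a single exon).

    ``rank`` is the 0-based position in genome order; downstream plotting and
    segmentation operate on rank order, not genomic scale.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    label: str
    rank: int
    is_x: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if not self.label:
            raise ValueError("interval label must be non-empty")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # GATK notation
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class CoverageTable:
    """Samples x intervals matrix of total depth-of-coverage for one batch."""

    intervals: list[TargetInterval]
    samples: list[str]
    totals: np.ndarray  # shape (n_samples, n_intervals), read-bases
    provenance: dict[str, str] = field(default_factory=dict)  # sample -> source file

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=float)
        if self.totals.shape != (len(self.samples), len(self.intervals)):
            raise ValueError(
                f"totals shape {self.totals.shape} does not match "
                f"{len(self.samples)} samples x {len(self.intervals)} intervals"
            )
        if (self.totals < 0).any():
            raise ValueError("coverage totals must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def subset(self, keep: Sequence[str]) -> "CoverageTable":
        """Return a new table restricted to ``keep`` (order preserved)."""
        idx = [self.samples.index(s) for s in keep]
        return CoverageTable(
            intervals=self.intervals,
            samples=[self.samples[i] for i in idx],
            totals=self.totals[idx, :].copy(),
            provenance={s: self.provenance.get(s, "") for s in keep},
        )


def _parse_target(text: str) -> tuple[str, int, int]:
    m = _TARGET_RE.match(text)
    if m is None:
        raise FormatError(f"malformed target {text!r}")
    chrom = m.group("chrom")
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    return chrom, start, end


def parse_interval_list(
    path: str | Path,
    x_chrom_names: Iterable[str] = DEFAULT_X_NAMES,
) -> list[TargetInterval]:
    """Read an interval list: one ``chrom:start-end<TAB>label`` per line.

    The label is optional (auto-generated as ``chrom_start`` when absent).
    Ranks are assigned in file order.  Intervals on the same chromosome must
    not overlap.
    """
    path = Path(path)
    x_names = set(x_chrom_names)
    intervals: list[TargetInterval] = []
    seen: set[tuple[str, int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            try:
                chrom, start, end = _parse_target(parts[0])
            except FormatError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from None
            if start > end:
                raise ValueError(f"{path.name}:{lineno}: start > end")
            label = parts[1].strip() if len(parts) > 1 and parts[1].strip() else (
                f"{chrom}_{start}"
            )
            key = (chrom, start, end)
            if key in seen:
                raise FormatError(f"{path.name}:{lineno}: duplicate target {parts[0]}")
            seen.add(key)
            intervals.append(
                TargetInterval(
                    chrom=chrom,
                    start=start,
                    end=end,
                    label=label,
                    rank=len(intervals),
                    is_x=chrom in x_names,
                )
            )
    _check_no_overlap(intervals, path.name)
    return intervals


def _check_no_overlap(intervals: Sequence[TargetInterval], source: str) -> None:
    by_chrom: dict[str, list[TargetInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ordered = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{source}: overlapping intervals on {chrom}: {a} and {b}"
                )


def _read_table(path: Path) -> pd.DataFrame:
    # GATK emits CSV; lab exports often re-save as TSV.  Auto-detect.
    try:
        with open(path) as fh:
            header = fh.readline()
    except (OSError, UnicodeDecodeError) as exc:
        raise InputError(f"cannot read {path.name}: {exc}") from exc
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise FormatError(f"{path.name}: cannot parse as delimited table: {exc}") from exc


def parse_interval_summary(
    path: str | Path,
    interval_list: Sequence[TargetInterval],
) -> tuple[str, np.ndarray]:
    """Parse one DepthOfCoverage interval-summary file.

    Returns the sample name (the prefix of the ``_total_cvg`` column) and the
    vector of total-coverage values aligned to ``interval_list`` order.  Rows
    may appear in any order; targets must match the interval list one-to-one
    by (chrom, start, end).
    """
    path = Path(path)
    df = _read_table(path)
    cvg_cols = [c for c in df.columns if c.endswith("_total_cvg")]
    if len(cvg_cols) != 1:
        raise FormatError(
            f"{path.name}: expected exactly one '_total_cvg' column, "
            f"found {len(cvg_cols)}"
        )
    if "Target" not in df.columns:
        raise FormatError(f"{path.name}: missing 'Target' column")
    sample = cvg_cols[0][: -len("_total_cvg")]

    values = pd.to_numeric(df[cvg_cols[0]], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        raise FormatError(
            f"{path.name}: non-numeric coverage value at row {int(bad[0])}"
        )

    by_key: dict[tuple[str, int, int], float] = {}
    for i, target in enumerate(df["Target"]):
        try:
            key = _parse_target(str(target))
        except FormatError as exc:
            raise FormatError(f"{path.name}: row {i}: {exc}") from None
        if key in by_key:
            raise AlignmentError(f"{path.name}: duplicate target {target}")
        by_key[key] = float(values.iloc[i])

    out = np.empty(len(interval_list), dtype=float)
    for iv in interval_list:
        if iv.key not in by_key:
            raise AlignmentError(
                f"{path.name}: target {iv} from interval list not found in file"
            )
        out[iv.rank] = by_key.pop(iv.key)
    if by_key:
        stray = next(iter(by_key))
        raise AlignmentError(
            f"{path.name}: target {stray[0]}:{stray[1]}-{stray[2]} "
            "not present in interval list"
        )
    return sample, out


def load_batch(
    input_dir: str | Path,
    interval_list_path: str | Path,
    x_chrom_names: Iterable[str] = DEFAULT_X_NAMES,
) -> CoverageTable:
    """Load every interval-summary file in a directory into one batch table.

    Samples are ordered lexicographically by sample name.  Any unparseable
    file in the directory is an error (it names the file); duplicate sample
    names across files are rejected.
    """
    input_dir = Path(input_dir)
    intervals = parse_interval_list(interval_list_path, x_chrom_names)
    files = sorted(p for p in input_dir.iterdir() if p.is_file() and not p.name.startswith("."))
    if not files:
        raise InputError(f"no input files found in {input_dir}")
    rows: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for f in files:
        try:
            sample, vec = parse_interval_summary(f, intervals)
        except (FormatError, AlignmentError) as exc:
            raise InputError(f"cannot parse {f.name}: {exc}") from exc
        if sample in rows:
            raise DuplicateSampleError(
                f"sample {sample!r} appears in both {provenance[sample]} and {f.name}"
            )
        rows[sample] = vec
        provenance[sample] = f.name
    samples = sorted(rows)
    totals = np.vstack([rows[s] for s in samples])
    return CoverageTable(
        intervals=intervals, samples=samples, totals=totals, provenance=provenance
    )


def _fmt(v: float) -> str:
    if not np.isfinite(v):
        return "NA"
    return f"{v:.6f}"


CALL_TABLE_COLUMNS = [
    "id",
    "sample",
    "chrom",
    "start_label",
    "end_label",
    "span",
    "type",
    "n_intervals",
    "median_log2",
    "inferred_cn",
    "recurrent",
    "gc_flag",
]

QC_TABLE_COLUMNS = [
    "sample",
    "lower_whisker",
    "q1",
    "median",
    "q3",
    "upper_whisker",
    "iqr_multiplier",
    "passed",
    "reason",
    "iteration",
    "predicted_sex",
]


def write_log2_matrix(log2, path: str | Path) -> Path:
    """Write a log2-ratio matrix: intervals as rows (genome order), samples
    as columns.  Masked intervals are written as ``NA``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Target\tlabel\t" + "\t".join(log2.samples) + "\n")
        for iv in log2.intervals:
            row = [str(iv), iv.label]
            row.extend(_fmt(log2.ratios[s, iv.rank]) for s in range(len(log2.samples)))
            fh.write("\t".join(row) + "\n")
    return path


def write_call_table(calls, path: str | Path) -> Path:
    """Write the CNV call table (header always present, one row per call)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        str(c.id),
                        c.sample,
                        c.chrom,
                        c.first_label,
                        c.last_label,
                        f"{c.chrom}:{c.start}-{c.end}",
                        c.type,
                        str(c.n_intervals),
                        _fmt(c.median_log2),
                        _fmt(c.inferred_cn),
                        str(bool(c.recurrent)),
                        str(bool(c.gc_flag)),
                    ]
                )
                + "\n"
            )
    return path


def write_qc_table(qc_records, path: str | Path) -> Path:
    """Write the per-sample QC summary (five-number summary, verdict, sex)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(QC_TABLE_COLUMNS) + "\n")
        for r in qc_records:
            s = r.summary
            fh.write(
                "\t".join(
                    [
                        r.sample,
                        _fmt(s.lower_whisker),
                        _fmt(s.q1),
                        _fmt(s.median),
                        _fmt(s.q3),
                        _fmt(s.upper_whisker),
                        f"{s.iqr_multiplier:g}",
                        str(bool(r.passed)),
                        r.reason,
                        str(r.iteration),
                        r.predicted_sex,
                    ]
                )
                + "\n"
            )
    return path


def write_outputs(log2, calls, qc_records, out_dir: str | Path) -> list[Path]:
    """Write the three text deliverables of a run; returns paths written.

    Output is deterministic: re-running on the same inputs produces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory {out_dir} is not writable: {exc}") from exc
    return [
        write_log2_matrix(log2, out_dir / "log2_matrix.tsv"),
        write_call_table(calls, out_dir / "cnv_calls.tsv"),
        write_qc_table(qc_records, out_dir / "qc_summary.tsv"),
    ]
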