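"""Static review plots.

Three figures support manual review: per-sample log2 scatter plots (whole
panel or one chromosome) with color-coded CNV segments and threshold
guidelines; before/after X-correction boxplots; and whole-batch boxplots with
QC failures marked.

Every figure is written as PNG and PDF plus a sidecar TSV holding the exact
plotted data (points, guideline positions, call markers, x-tick labels) so
the visual contract is machine-checkable without pixel comparisons.  Points
are positioned by interval rank (relative genome order), not genomic scale.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .calling import CNVCall, CallingThresholds
from .normalize import Log2RatioMatrix
from .qc import FiveNumberSummary, QCVerdict, five_number_summary

logger = logging.getLogger(__name__)

GAIN_COLOR = "red"
LOSS_COLOR = "blue"
NEUTRAL_COLOR = "black"
MARKER_COLOR = "orange"

#: theoretical single-copy gain / loss log2 ratios (light guidelines)
GAIN_THEORY = 0.58
LOSS_THEORY = -1.0

SIDECAR_COLUMNS = ["element", "name", "x_start", "x_end", "y", "color", "note"]


def _write_sidecar(rows: list[dict], path: Path) -> Path:
    with open(path, "w") as fh:
        fh.write("\t".join(SIDECAR_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(str(r.get(c, "")) for c in SIDECAR_COLUMNS) + "\n"
            )
    return path


def _save(fig, out_base: Path) -> list[Path]:
    out_base.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in ("png", "pdf"):
        p = out_base.with_suffix(f".{ext}")
        fig.savefig(p, dpi=110)
        paths.append(p)
    plt.close(fig)
    return paths


def _gene_group(label: str) -> str:
    # "TP53_Exon1" -> "TP53"; labels without "_" are their own group
    return label.rsplit("_", 1)[0] if "_" in label else label


def plot_sample(
    sample: str,
    ratios: np.ndarray,
    intervals: Sequence,
    calls: Sequence[CNVCall],
    summary: FiveNumberSummary,
    thresholds: CallingThresholds,
    out_base: str | Path,
    scope: str = "genome",
) -> list[Path]:
    """Per-sample log2 plot with guidelines and call markers.

    ``scope`` is "genome" or a chromosome name.  Guidelines: fixed thresholds
    solid black, sample whiskers dashed, theoretical +/-1-copy ratios light
    gray.  Each call is overlaid with an orange segment labeled with its id —
    the same id as in the call table.
    """
    out_base = Path(out_base)
    ratios = np.asarray(ratios, dtype=float)
    if scope == "genome":
        keep = np.arange(len(intervals))
    else:
        keep = np.array([iv.rank for iv in intervals if iv.chrom == scope], dtype=int)
    calls = [c for c in calls if scope == "genome" or c.chrom == scope]

    in_call = {}
    for c in calls:
        for r in range(c.first_rank, c.last_rank + 1):
            in_call[r] = c.type

    rows: list[dict] = []
    fig, ax = plt.subplots(figsize=(max(6, len(keep) / 60), 4))
    colors = []
    for r in keep:
        kind = in_call.get(int(r), "neutral")
        color = {"gain": GAIN_COLOR, "loss": LOSS_COLOR}.get(kind, NEUTRAL_COLOR)
        colors.append(color)
        rows.append(
            dict(element="point", name=int(r), x_start=int(r), x_end=int(r),
                 y=f"{ratios[r]:.6f}" if np.isfinite(ratios[r]) else "NA",
                 color=color, note=kind)
        )
    finite = np.isfinite(ratios[keep])
    ax.scatter(keep[finite], ratios[keep][finite],
               c=[c for c, f in zip(colors, finite) if f], s=8)

    guidelines = [
        ("gain_threshold", thresholds.gain_log2, "solid", "black"),
        ("loss_threshold", thresholds.loss_log2, "solid", "black"),
        ("upper_whisker", summary.upper_whisker, "dashed", "gray"),
        ("lower_whisker", summary.lower_whisker, "dashed", "gray"),
        ("gain_theory", GAIN_THEORY, "solid", "lightgray"),
        ("loss_theory", LOSS_THEORY, "solid", "lightgray"),
    ]
    for name, y, style, color in guidelines:
        ax.axhline(y, linestyle="dashed" if style == "dashed" else "solid",
                   color=color, linewidth=0.8)
        rows.append(dict(element="guideline", name=name, x_start="", x_end="",
                         y=f"{y:.6f}", color=color, note=style))

    marker_y = (max(np.nanmax(ratios[keep]), GAIN_THEORY) + 0.3
                if finite.any() else 1.0)
    for c in calls:
        ax.plot([c.first_rank, c.last_rank], [marker_y, marker_y],
                color=MARKER_COLOR, linewidth=3, solid_capstyle="butt")
        ax.annotate(str(c.id), ((c.first_rank + c.last_rank) / 2, marker_y),
                    textcoords="offset points", xytext=(0, 4),
                    ha="center", color=MARKER_COLOR, fontsize=8)
        rows.append(dict(element="marker", name=c.id, x_start=c.first_rank,
                         x_end=c.last_rank, y=f"{marker_y:.6f}",
                         color=MARKER_COLOR, note=c.type))

    # one x-tick under the first interval of each label group (gene)
    seen: set[str] = set()
    ticks, tick_labels = [], []
    for r in keep:
        g = _gene_group(intervals[int(r)].label)
        if g not in seen:
            seen.add(g)
            ticks.append(int(r))
            tick_labels.append(g)
            rows.append(dict(element="xtick", name=g, x_start=int(r),
                             x_end=int(r), y="", color="", note=""))
    step = max(1, len(ticks) // 40)  # avoid unreadable tick crowding
    ax.set_xticks(ticks[::step])
    ax.set_xticklabels(tick_labels[::step], rotation=90, fontsize=5)

    ax.set_ylabel("log2 ratio")
    ax.set_title(f"{sample} ({scope})")
    paths = _save(fig, out_base)
    paths.append(_write_sidecar(rows, out_base.with_suffix(".tsv")))
    return paths


def _box_stats(values: np.ndarray, iqr_multiplier: float):
    """Five-number stats for display; min/max fallback below 5 values."""
    values = values[np.isfinite(values)]
    if values.size >= 5:
        return five_number_summary(values, iqr_multiplier)
    lo, hi = float(values.min()), float(values.max())
    med = float(np.median(values))
    return FiveNumberSummary(lo, lo, med, hi, hi, iqr_multiplier)


def plot_x_boxplots(
    pre: Log2RatioMatrix,
    post: Log2RatioMatrix,
    out_base: str | Path,
    iqr_multiplier: float = 3.0,
) -> list[Path]:
    """Two-panel figure: per-sample boxplots of X-interval log2 ratios before
    and after sex-composition correction."""
    out_base = Path(out_base)
    xcols = pre.x_columns()
    if xcols.size == 0:
        logger.info("no X intervals; X boxplot skipped")
        return []
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    rows: list[dict] = []
    for ax, mat, panel in ((axes[0], pre, "pre"), (axes[1], post, "post")):
        data = []
        for s in range(mat.n_samples):
            vals = mat.ratios[s, mat.x_columns()]
            vals = vals[np.isfinite(vals) & (vals != mat.floor)]
            data.append(vals)
            st = _box_stats(vals, iqr_multiplier)
            for name, y in (("lower_whisker", st.lower_whisker), ("q1", st.q1),
                            ("median", st.median), ("q3", st.q3),
                            ("upper_whisker", st.upper_whisker)):
                rows.append(dict(element="box", name=f"{mat.samples[s]}:{name}",
                                 x_start=panel, x_end="", y=f"{y:.6f}",
                                 color="", note=panel))
        ax.boxplot(data, tick_labels=mat.samples, whis=iqr_multiplier)
        ax.axhline(0, color="lightgray", linewidth=0.8)
        ax.set_title(f"X intervals ({panel}-correction)")
        ax.tick_params(axis="x", rotation=90)
    axes[0].set_ylabel("log2 ratio")
    paths = _save(fig, out_base)
    paths.append(_write_sidecar(rows, out_base.with_suffix(".tsv")))
    return paths


def plot_batch_boxplots(
    log2: Log2RatioMatrix,
    verdicts: Sequence[QCVerdict],
    iqr_multiplier: float,
    out_base: str | Path,
    gain_theory: float = GAIN_THEORY,
    loss_theory: float = LOSS_THEORY,
) -> list[Path]:
    """One boxplot per sample over all probes, QC failures marked, with
    horizontal reference lines at the theoretical single-copy ratios."""
    out_base = Path(out_base)
    by_sample = {v.sample: v for v in verdicts}
    fig, ax = plt.subplots(figsize=(max(6, log2.n_samples), 4))
    data, rows = [], []
    for s, sample in enumerate(log2.samples):
        vals = log2.summary_values(s)
        data.append(vals)
        st = _box_stats(vals, iqr_multiplier)
        passed = by_sample[sample].passed if sample in by_sample else True
        for name, y in (("lower_whisker", st.lower_whisker), ("q1", st.q1),
                        ("median", st.median), ("q3", st.q3),
                        ("upper_whisker", st.upper_whisker)):
            rows.append(dict(element="box", name=f"{sample}:{name}",
                             x_start=s, x_end="", y=f"{y:.6f}", color="",
                             note="pass" if passed else "fail"))
    ax.boxplot(data, tick_labels=log2.samples, whis=iqr_multiplier)
    for s, sample in enumerate(log2.samples, start=1):
        if sample in by_sample and not by_sample[sample].passed:
            ax.annotate("FAIL", (s, 0), color="red", ha="center",
                        fontweight="bold")
    for name, y in (("gain_theory", gain_theory), ("loss_theory", loss_theory)):
        ax.axhline(y, color="lightgray", linewidth=0.8)
        rows.append(dict(element="guideline", name=name, x_start="", x_end="",
                         y=f"{y:.6f}", color="lightgray", note="solid"))
    ax.set_ylabel("log2 ratio")
    ax.tick_params(axis="x", rotation=90)
    paths = _save(fig, out_base)
    paths.append(_write_sidecar(rows, out_base.with_suffix(".tsv")))
    return paths
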