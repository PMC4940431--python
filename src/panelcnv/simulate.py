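"""Synthetic multiplexed-capture batches with known truth.

The generator emulates one hybrid-capture batch: a panel of exon-sized target
intervals (a small fraction on the X chromosome), per-interval capture
efficiency drawn once per batch (log-normal — bait efficiency spans well over
an order of magnitude on real panels but is shared by all co-captured
samples), per-cell multiplicative noise on the log2 scale, optional
high-dispersion samples that should fail QC, male/female X dosage, and
injected CNVs with an on-disk truth table.

Expected coverage for sample s at interval i is

    depth_mean * efficiency_i * (cn(s,i) / 2) * sex_dosage(s,i)

where sex_dosage halves X-interval coverage for males, and the observed value
is the expectation times 2**N(0, noise_sd) rounded to an integer read-base
count.  With ``noise_sd = 0`` the pipeline's log2 ratios are exactly 0 on
copy-neutral autosomes, which makes the generator an end-to-end oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io import CoverageTable, TargetInterval

#: variance-inflation factor applied to noise_sd for QC-failing samples
NOISY_SAMPLE_DISPERSION = 6.0

#: extra noise multiplier for "bad baits" (inconsistent capture)
BAD_BAIT_DISPERSION = 4.0

_EXONS_PER_GENE = 8
_INTERVAL_BP = 150
_GENE_SPACING_BP = 50_000
_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated batch.

    Defaults mirror a routine clinical capture batch: 8 samples (batches run
    7-10), a 1,016-exon panel, ~5% of targets on chrX, ~100,000 read-bases of
    total coverage per interval (≈700x over a 150 bp exon), log-normal bait
    efficiency (sd 0.5 natural-log units) and per-cell log2 noise sd 0.1.
    """

    n_samples: int = 8
    n_intervals: int = 1016
    x_fraction: float = 0.05
    sexes: Sequence[str] | None = None  # default: alternating female/male
    depth_mean: float = 100_000.0
    bait_efficiency_sd: float = 0.5
    noise_sd: float = 0.1
    bad_bait_fraction: float = 0.01
    noisy_sample_ids: Sequence[str] = field(default_factory=tuple)
    dispersion_factor: float = NOISY_SAMPLE_DISPERSION
    cnv_spec: Sequence[tuple[str, tuple[int, int], float]] = field(default_factory=tuple)
    poisson_counts: bool = False  # optional Poisson layer on read-base counts
    seed: int = 0

    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def resolved_sexes(self) -> list[str]:
        if self.sexes is not None:
            if len(self.sexes) != self.n_samples:
                raise ConfigError("sexes must have one label per sample")
            return list(self.sexes)
        return ["female" if i % 2 == 0 else "male" for i in range(self.n_samples)]


@dataclass(frozen=True)
class TruthRecord:
    sample: str
    first_rank: int
    last_rank: int
    chrom: str
    copy_number: float
    type: str  # gain | loss


@dataclass
class TruthTable:
    records: list[TruthRecord]


@dataclass
class SimulatedBatch:
    config: SimulationConfig
    coverage: CoverageTable
    truth: TruthTable
    sexes: dict[str, str]
    files: dict[str, Path] | None = None  # set when written to disk


def build_panel(n_intervals: int, x_fraction: float) -> list[TargetInterval]:
    """Deterministic panel layout: genes of 8 exons spread over the autosomes
    in genome order, X genes (labels ``XG...``) at the end."""
    n_x = int(round(n_intervals * x_fraction))
    n_auto = n_intervals - n_x
    intervals: list[TargetInterval] = []

    def add_gene_block(chrom: str, gene: str, n_exons: int, start0: int) -> int:
        pos = start0
        for e in range(n_exons):
            intervals.append(
                TargetInterval(
                    chrom=chrom,
                    start=pos,
                    end=pos + _INTERVAL_BP - 1,
                    label=f"{gene}_Exon{e + 1}",
                    rank=len(intervals),
                    is_x=chrom in ("X", "chrX"),
                )
            )
            pos += 2 * _INTERVAL_BP
        return pos + _GENE_SPACING_BP

    n_genes_auto = -(-n_auto // _EXONS_PER_GENE)  # ceil
    per_chrom = -(-n_genes_auto // len(_AUTOSOMES))
    g = 0
    remaining = n_auto
    for chrom in _AUTOSOMES:
        pos = 10_000
        for _ in range(per_chrom):
            if remaining <= 0:
                break
            n_exons = min(_EXONS_PER_GENE, remaining)
            g += 1
            pos = add_gene_block(chrom, f"GENE{g:03d}", n_exons, pos)
            remaining -= n_exons
        if remaining <= 0:
            break
    pos = 10_000
    remaining = n_x
    gx = 0
    while remaining > 0:
        n_exons = min(_EXONS_PER_GENE, remaining)
        gx += 1
        pos = add_gene_block("chrX", f"XGENE{gx:02d}", n_exons, pos)
        remaining -= n_exons
    assert len(intervals) == n_intervals
    return intervals


def simulate_batch(
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
) -> SimulatedBatch:
    """Generate one batch; optionally write interval list, per-sample
    interval-summary files and the truth table to ``out_dir``.

    Output is fully determined by ``cfg`` (including ``seed``): the same
    config written twice produces byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    intervals = build_panel(cfg.n_intervals, cfg.x_fraction)
    samples = cfg.sample_names()
    sexes = cfg.resolved_sexes()

    cn = np.full((cfg.n_samples, cfg.n_intervals), 2.0)
    truth_records: list[TruthRecord] = []
    for sample, (first, last), copy_number in cfg.cnv_spec:
        if sample not in samples:
            raise ConfigError(f"cnv_spec references unknown sample {sample!r}")
        if not (0 <= first <= last < cfg.n_intervals):
            raise ConfigError(f"cnv_spec range ({first}, {last}) outside panel")
        chroms = {intervals[r].chrom for r in range(first, last + 1)}
        if len(chroms) != 1:
            raise ConfigError("cnv_spec range must stay on one chromosome")
        s = samples.index(sample)
        cn[s, first : last + 1] = copy_number
        truth_records.append(
            TruthRecord(
                sample=sample,
                first_rank=first,
                last_rank=last,
                chrom=chroms.pop(),
                copy_number=copy_number,
                type="gain" if copy_number > 2 else "loss",
            )
        )

    efficiency = rng.lognormal(mean=0.0, sigma=cfg.bait_efficiency_sd,
                               size=cfg.n_intervals)
    n_bad = int(round(cfg.bad_bait_fraction * cfg.n_intervals))
    bad_baits = rng.choice(cfg.n_intervals, size=n_bad, replace=False) if n_bad else []
    is_x = np.array([iv.is_x for iv in intervals])
    dosage = np.ones((cfg.n_samples, cfg.n_intervals))
    for s, sex in enumerate(sexes):
        if sex == "male":
            dosage[s, is_x] = 0.5

    expected = cfg.depth_mean * efficiency[None, :] * (cn / 2.0) * dosage

    sd_cell = np.full((cfg.n_samples, cfg.n_intervals), cfg.noise_sd)
    for sample in cfg.noisy_sample_ids:
        if sample not in samples:
            raise ConfigError(f"noisy_sample_ids references unknown sample {sample!r}")
        sd_cell[samples.index(sample), :] *= cfg.dispersion_factor
    if len(bad_baits):
        sd_cell[:, np.asarray(bad_baits)] *= BAD_BAIT_DISPERSION

    # one standard normal per cell scaled by its sd, so the random stream is
    # identical whether or not any cell has zero sd
    z = rng.normal(0.0, 1.0, expected.shape)
    observed = expected * 2.0 ** (z * sd_cell)
    if cfg.poisson_counts:
        observed = rng.poisson(observed).astype(float)
    observed = np.rint(observed)

    coverage = CoverageTable(
        intervals=intervals,
        samples=samples,
        totals=observed,
        provenance={s: "simulated" for s in samples},
    )
    batch = SimulatedBatch(
        config=cfg,
        coverage=coverage,
        truth=TruthTable(records=truth_records),
        sexes=dict(zip(samples, sexes)),
    )
    if out_dir is not None:
        batch.files = write_batch(batch, Path(out_dir))
    return batch


def write_batch(batch: SimulatedBatch, out_dir: Path) -> dict[str, Path]:
    """Write the batch in the dialect the reader consumes.

    Per-sample files are GATK-style interval-summary CSVs; the truth table is
    a BED-like TSV (0-based half-open coordinates — deliberately a different
    convention from the 1-based interval list, as is usual for BED)."""
    out_dir = Path(out_dir)
    input_dir = out_dir / "coverage"
    input_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    interval_list = out_dir / "intervals.list"
    with open(interval_list, "w") as fh:
        for iv in batch.coverage.intervals:
            fh.write(f"{iv}\t{iv.label}\n")
    files["interval_list"] = interval_list

    for s, sample in enumerate(batch.coverage.samples):
        p = input_dir / f"{sample}.sample_interval_summary"
        with open(p, "w") as fh:
            fh.write(
                f"Target,total_coverage,average_coverage,"
                f"{sample}_total_cvg,{sample}_mean_cvg\n"
            )
            for iv in batch.coverage.intervals:
                total = int(batch.coverage.totals[s, iv.rank])
                mean = total / (iv.end - iv.start + 1)
                fh.write(f"{iv},{total},{mean:.2f},{total},{mean:.2f}\n")
        files[sample] = p
    files["input_dir"] = input_dir

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample\tchrom\tstart0\tend0\tfirst_rank\tlast_rank\tcopy_number\ttype\n")
        for r in batch.truth.records:
            first_iv = batch.coverage.intervals[r.first_rank]
            last_iv = batch.coverage.intervals[r.last_rank]
            fh.write(
                f"{r.sample}\t{r.chrom}\t{first_iv.start - 1}\t{last_iv.end}\t"
                f"{r.first_rank}\t{r.last_rank}\t{r.copy_number:g}\t{r.type}\n"
            )
    files["truth"] = truth_path

    sex_path = out_dir / "sexes.tsv"
    with open(sex_path, "w") as fh:
        fh.write("sample\tsex\n")
        for sample in batch.coverage.samples:
            fh.write(f"{sample}\t{batch.sexes[sample]}\n")
    files["sexes"] = sex_path
    return files


SCENARIOS = ("clean", "one_failing_sample", "mixed_sex", "single_sex",
             "recurrent_artifact")


def make_paperlike_batch(
    scenario: str,
    seed: int = 7,
    out_dir: str | Path | None = None,
) -> SimulatedBatch:
    """Canned batches exercising the pipeline's characteristic code paths.

    - ``clean``: mixed-sex batch, no CNVs; passes QC in one iteration.
    - ``one_failing_sample``: one high-dispersion sample (fails QC, batch
      converges on the second iteration).
    - ``mixed_sex``: 4 female / 4 male, a multi-exon heterozygous deletion
      and a duplication planted for end-to-end recovery checks.
    - ``single_sex``: all-female batch; sex clustering is degenerate.
    - ``recurrent_artifact``: the same single-interval loss planted in 3
      samples; annotated against a 200-case cohort it exceeds the 1%
      recurrence threshold.
    """
    base = SimulationConfig(seed=seed)
    if scenario == "clean":
        cfg = base
    elif scenario == "one_failing_sample":
        cfg = replace(base, noisy_sample_ids=("S06",))
    elif scenario == "mixed_sex":
        cfg = replace(
            base,
            sexes=["female", "female", "female", "female",
                   "male", "male", "male", "male"],
            cnv_spec=(("S03", (40, 44), 1.0), ("S07", (120, 125), 3.0)),
        )
    elif scenario == "single_sex":
        cfg = replace(base, sexes=["female"] * base.n_samples)
    elif scenario == "recurrent_artifact":
        # no bad baits here: the planted artifact is the only recurrent signal
        cfg = replace(
            base,
            bad_bait_fraction=0.0,
            cnv_spec=(("S02", (60, 60), 1.0), ("S04", (60, 60), 1.0),
                      ("S07", (60, 60), 1.0)),
        )
    else:
        raise ConfigError(
            f"unknown scenario {scenario!r}; choose from {', '.join(SCENARIOS)}"
        )
    return simulate_batch(cfg, out_dir=out_dir)
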