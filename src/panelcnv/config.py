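"""Run configuration.

A flat set of thresholds and paths; every value here is echoed verbatim into
the run manifest so a reviewer can see exactly which configuration produced a
set of calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ConfigError


@dataclass
class RunConfig:
    """All tunables for one end-to-end run.

    Defaults are the clinically validated operating point: gain/loss calling
    thresholds 0.40 / -0.55 (log2), boxplot IQR multiplier 3, QC bounds at
    the theoretical single-copy gain (0.58) and loss (-1), at least 3 passing
    samples per batch, 1% cohort recurrence, and extreme-GC bounds 35%/65%.
    """

    input_dir: Path | None = None
    interval_list: Path | None = None
    output_dir: Path | None = None

    gain_log2: float = 0.40
    loss_log2: float = -0.55
    iqr_multiplier: float = 3.0
    min_pass_samples: int = 3
    qc_gain_bound: float = 0.58
    qc_loss_bound: float = -1.0
    x_chrom_names: tuple[str, ...] = ("X", "chrX")
    min_probes_gain: int = 1
    min_probes_loss: int = 1
    cohort_recurrence_fraction: float = 0.01
    gc_low: float = 0.35
    gc_high: float = 0.65
    min_medoid_separation: float = 0.3
    x_trim_fraction: float = 0.1
    exclusion_list: Path | None = None
    gc_table: Path | None = None
    drop_recurrent: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.gain_log2 > 0 > self.loss_log2):
            raise ConfigError("need gain_log2 > 0 > loss_log2")
        if not (0 < self.cohort_recurrence_fraction < 1):
            raise ConfigError("cohort_recurrence_fraction must be in (0, 1)")
        if self.iqr_multiplier < 1:
            raise ConfigError("iqr_multiplier must be >= 1")
        if self.min_pass_samples < 1:
            raise ConfigError("min_pass_samples must be >= 1")
        for attr in ("input_dir", "interval_list", "output_dir",
                     "exclusion_list", "gc_table"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, Path(v))

    def as_manifest_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
            elif isinstance(v, tuple):
                d[k] = list(v)
        return d
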