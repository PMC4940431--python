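import numpy as np
import pytest

from panelcnv.io import TargetInterval
from panelcnv.simulate import SimulationConfig, make_paperlike_batch, simulate_batch


def make_intervals(n, chrom="chr1", x_from=None):
    """n non-overlapping intervals on one chromosome (or chrX from x_from)."""
    out = []
    for i in range(n):
        c = "chrX" if x_from is not None and i >= x_from else chrom
        out.append(
            TargetInterval(
                chrom=c, start=1000 + 500 * i, end=1200 + 500 * i,
                label=f"G{i // 4}_Exon{i % 4 + 1}", rank=i, is_x=c == "chrX",
            )
        )
    return out


@pytest.fixture(scope="session")
def clean_batch():
    return make_paperlike_batch("clean")


@pytest.fixture(scope="session")
def mixed_batch():
    return make_paperlike_batch("mixed_sex")


@pytest.fixture(scope="session")
def failing_batch():
    return make_paperlike_batch("one_failing_sample")


@pytest.fixture(scope="session")
def small_noiseless_batch():
    """Single-sex, noise-free batch: every log2 ratio is exactly 0."""
    cfg = SimulationConfig(
        n_samples=4, n_intervals=64, noise_sd=0.0, bad_bait_fraction=0.0,
        sexes=["female"] * 4, seed=11,
    )
    return simulate_batch(cfg)
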