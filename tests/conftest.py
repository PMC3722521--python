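import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_copy_fixture():
    """Synthetic genome with one engineered paralogue pair (interior Δ=20)."""
    from prtdesign.synthetic import (
        SegmentCopy,
        SegmentFamily,
        SyntheticSpec,
        generate,
    )

    spec = SyntheticSpec(
        seed=7,
        chrom_lengths={"chr1": 60_000, "chr2": 60_000},
        families=(
            SegmentFamily(
                "dupA",
                copies=(
                    SegmentCopy("chr1", 30_000, 0),
                    SegmentCopy("chr2", 45_000, 20),
                ),
            ),
        ),
    )
    return generate(spec)
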