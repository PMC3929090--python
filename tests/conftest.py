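import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cnvpipe import (
    DELETION,
    GenomicInterval,
    RiskLocusSpec,
    StratumSpec,
    SyntheticCohortSpec,
)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced two-chromosome cohort spec used across integration tests.

    Discovery sample sizes follow the emulated study design (6882 cases,
    11255 controls); genome size, gene count and background rate are scaled
    down so a single cohort generates in well under a second.
    """
    return SyntheticCohortSpec(
        seed=1,
        strata=(StratumSpec("discovery", 6882, 11255, 5000),),
        chrom_lengths=(("chr1", 30_000_000), ("chr2", 30_000_000)),
        n_genes=300,
        background_rate=0.2,
        risk_loci=(
            RiskLocusSpec(
                GenomicInterval("chr1", 10_000_000, 10_400_000),
                DELETION,
                control_freq=0.005,
                odds_ratio=5.0,
                recurrent=True,
                label="planted-del",
            ),
        ),
    )
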