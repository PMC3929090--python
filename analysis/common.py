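"""Shared demonstration cohort for the numbered analysis scripts.

A two-stratum, two-chromosome cohort with two planted risk loci: a
recurrent multi-gene deletion (the classic LCR-flanked configuration) and a
non-recurrent single-locus duplication with jittered breakpoints.  Sizes
are scaled so every script runs in seconds; the package accepts the full
eight-stratum design (``cnvpipe.DEFAULT_STRATA``) the same way.
"""

from pathlib import Path

from cnvpipe import (
    DELETION,
    DUPLICATION,
    GenomicInterval,
    RiskLocusSpec,
    StratumSpec,
    SyntheticCohortSpec,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

DEL_LOCUS = RiskLocusSpec(
    GenomicInterval("chr1", 10_000_000, 10_500_000), DELETION,
    control_freq=0.003, odds_ratio=4.0, recurrent=True, label="recurrent-del",
)
DUP_LOCUS = RiskLocusSpec(
    GenomicInterval("chr2", 20_000_000, 20_250_000), DUPLICATION,
    control_freq=0.004, odds_ratio=3.0, recurrent=False, breakpoint_sd=40_000,
    label="jittered-dup",
)

DEMO_SPEC = SyntheticCohortSpec(
    seed=11,
    strata=(
        StratumSpec("discovery", 3000, 4500, 5000),
        StratumSpec("replication", 2000, 2000, 4000),
    ),
    chrom_lengths=(("chr1", 30_000_000), ("chr2", 30_000_000)),
    n_genes=300,
    background_rate=0.3,
    risk_loci=(DEL_LOCUS, DUP_LOCUS),
)
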