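"""Synthetic multi-stratum case/control CNV cohorts.

Generates everything downstream stages consume — sample tables with QC
metrics, PennCNV-style calls, gene and low-copy-repeat tracks, per-stratum
probe maps, and LRR matrices — with the statistical structure the analysis
assumes: Poisson background CNVs with log-normal sizes placed uniformly on
a miniature genome, plus risk loci where carrier status is Bernoulli with
the control frequency in controls and the odds-transformed frequency in
cases, so the planted odds ratio equals the analysis estimand.

Default stratum sizes follow the eight-dataset design of the study being
emulated (one discovery set of 6882/11255, seven replication sets totalling
14568/15274); trio-derived replication data are modeled as a case/control
stratum of matched size, which is how the association stage consumes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .association import collapse_regions, screen_and_replicate
from .intervals import GenomicInterval
from .io_formats import (
    DELETION,
    DUPLICATION,
    CNVCall,
    GeneModel,
    SampleQC,
    SampleRecord,
)
from .power import case_frequency
from .qc import (
    FilterConfig,
    exclude_outlier_samples,
    filter_by_locus_frequency,
    filter_calls,
    join_calls_by_sample,
)
from .zscore import LRRMatrix


@dataclass(frozen=True)
class StratumSpec:
    label: str
    n_cases: int
    n_controls: int
    probe_spacing: int = 5_000  # bp between probes on this stratum's array

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls == 0:
            raise ValueError(f"stratum {self.label}: invalid sizes")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")


#: the eight-dataset design: discovery plus seven replication strata
DEFAULT_STRATA: tuple[StratumSpec, ...] = (
    StratumSpec("discovery", 6882, 11255, 5000),
    StratumSpec("MGS-EA", 2215, 2556, 4000),
    StratumSpec("MGS-AA", 977, 881, 4000),
    StratumSpec("ISC", 3045, 3185, 4000),
    StratumSpec("BG-trios", 662, 662, 4000),
    StratumSpec("Irish", 1377, 992, 4000),
    StratumSpec("Swedish", 4655, 6038, 4500),
    StratumSpec("AA-GPC", 1637, 960, 3000),
)


@dataclass(frozen=True)
class RiskLocusSpec:
    """A planted susceptibility locus."""

    interval: GenomicInterval
    copy_type: str
    control_freq: float
    odds_ratio: float
    recurrent: bool = True
    breakpoint_sd: int = 50_000  # jitter SD for non-recurrent loci
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.control_freq <= 0.01:
            raise ValueError("control_freq must be in (0, 0.01]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if self.copy_type not in (DELETION, DUPLICATION):
            raise ValueError(f"unknown copy type {self.copy_type!r}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.interval}:{self.copy_type}")

    @property
    def case_freq(self) -> float:
        return case_frequency(self.control_freq, self.odds_ratio)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for one cohort; the seed is mandatory."""

    seed: int
    strata: tuple[StratumSpec, ...] = DEFAULT_STRATA
    chrom_lengths: tuple[tuple[str, int], ...] = tuple(
        (f"chr{i}", 50_000_000) for i in range(1, 6)
    )
    n_genes: int = 2000
    gene_length: int = 20_000
    exons_per_gene: int = 8
    exon_length: int = 200
    background_rate: float = 0.5       # mean rare CNVs per person (Poisson)
    size_log_median: float = math.log(100_000)  # log-normal call sizes
    size_log_sd: float = 1.0
    min_call_bp: int = 5_000
    max_call_bp: int = 5_000_000
    lcr_fraction: float = 0.05          # genome fraction covered by LCR track
    lcr_mean_bp: int = 100_000
    qc_outlier_fraction: float = 0.002  # samples with grossly inflated LRR noise
    artifact_call_rate: float = 30.0    # mean small artifact calls per person
                                        # (feeds the cnv_count QC metric only)
    risk_loci: tuple[RiskLocusSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.background_rate < 0:
            raise ValueError("invalid spec")
        genome = dict(self.chrom_lengths)
        for locus in self.risk_loci:
            L = genome.get(locus.interval.chrom)
            if L is None or locus.interval.end > L:
                raise ValueError(f"risk locus {locus.label} outside simulated genome")

    @property
    def genome_bp(self) -> int:
        return sum(L for _, L in self.chrom_lengths)


@dataclass
class CohortData:
    samples: list[SampleRecord]
    calls: list[CNVCall]
    genes: list[GeneModel]
    lcr: list[GenomicInterval]
    probes: dict[str, dict[str, np.ndarray]]  # stratum -> chrom -> positions
    spec: SyntheticCohortSpec


def _make_genes(spec: SyntheticCohortSpec) -> list[GeneModel]:
    """Evenly spaced genes, exon count/length from the spec, deterministic."""
    genome = spec.genome_bp
    genes: list[GeneModel] = []
    gid = 0
    for chrom, L in spec.chrom_lengths:
        n = round(spec.n_genes * L / genome)
        if n == 0:
            continue
        pitch = L // (n + 1)
        for i in range(n):
            start = (i + 1) * pitch
            end = start + spec.gene_length - 1
            step = (spec.gene_length - spec.exon_length) // max(1, spec.exons_per_gene - 1)
            exons = tuple(
                GenomicInterval(chrom, start + k * step, start + k * step + spec.exon_length - 1)
                for k in range(spec.exons_per_gene)
            )
            genes.append(GeneModel(f"G{gid:05d}", GenomicInterval(chrom, start, end), exons))
            gid += 1
    return genes


def _make_lcr(spec: SyntheticCohortSpec, rng: np.random.Generator) -> list[GenomicInterval]:
    """Random LCR segments covering ~lcr_fraction of the genome.

    Segments are kept clear of planted risk loci: recurrent CNVs are flanked
    by LCRs, not buried in them, and the LCR-overlap filter must not censor
    the planted signal.
    """
    out: list[GenomicInterval] = []
    n_target = int(spec.lcr_fraction * spec.genome_bp / spec.lcr_mean_bp)
    chroms = [c for c, _ in spec.chrom_lengths]
    lengths = np.array([L for _, L in spec.chrom_lengths], dtype=float)
    probs = lengths / lengths.sum()
    attempts = 0
    while len(out) < n_target and attempts < 20 * n_target:
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        L = int(lengths[ci])
        size = max(10_000, int(rng.exponential(spec.lcr_mean_bp)))
        if size >= L:
            continue
        start = int(rng.integers(1, L - size + 1))
        iv = GenomicInterval(chroms[ci], start, start + size - 1)
        if any(iv.overlaps(r.interval) for r in spec.risk_loci):
            continue
        out.append(iv)
    return out


def _probe_grid(spec: SyntheticCohortSpec) -> dict[str, dict[str, np.ndarray]]:
    grids: dict[str, dict[str, np.ndarray]] = {}
    for st in spec.strata:
        offset = st.probe_spacing // 2
        grids[st.label] = {
            chrom: np.arange(offset, L + 1, st.probe_spacing, dtype=np.int64)
            for chrom, L in spec.chrom_lengths
        }
    return grids


def _n_probes_in(grid: np.ndarray, start: int, end: int) -> int:
    lo = np.searchsorted(grid, start, side="left")
    hi = np.searchsorted(grid, end, side="right")
    return max(1, int(hi - lo))


def generate_cohort(spec: SyntheticCohortSpec) -> CohortData:
    """Draw one cohort: samples + QC metrics, calls, gene/LCR tracks, probes."""
    rng = np.random.default_rng(spec.seed)
    genes = _make_genes(spec)
    lcr = _make_lcr(spec, rng)
    probes = _probe_grid(spec)

    chroms = [c for c, _ in spec.chrom_lengths]
    chrom_len = dict(spec.chrom_lengths)
    lengths = np.array([chrom_len[c] for c in chroms], dtype=float)
    chrom_probs = lengths / lengths.sum()

    samples: list[SampleRecord] = []
    calls: list[CNVCall] = []
    call_count: dict[str, int] = {}

    for st in spec.strata:
        grid = probes[st.label]
        n_tot = st.n_cases + st.n_controls
        ids = [
            f"{st.label}-{'case' if i < st.n_cases else 'ctrl'}-{i:05d}"
            for i in range(n_tot)
        ]
        is_case = np.arange(n_tot) < st.n_cases

        # background CNVs
        n_bg = rng.poisson(spec.background_rate, n_tot)
        owners = np.repeat(np.arange(n_tot), n_bg)
        T = len(owners)
        bg_chrom = rng.choice(len(chroms), size=T, p=chrom_probs)
        bg_size = np.exp(rng.normal(spec.size_log_median, spec.size_log_sd, T))
        bg_size = np.clip(bg_size, spec.min_call_bp, spec.max_call_bp).astype(np.int64)
        bg_is_del = rng.random(T) < 0.5
        bg_extreme = rng.random(T) < 0.1  # homozygous del / double dup
        for k in range(T):
            chrom = chroms[bg_chrom[k]]
            L = chrom_len[chrom]
            size = int(min(bg_size[k], L - 2))
            start = int(rng.integers(1, L - size + 1))
            iv = GenomicInterval(chrom, start, start + size - 1)
            cn = (0 if bg_extreme[k] else 1) if bg_is_del[k] else (4 if bg_extreme[k] else 3)
            sid = ids[owners[k]]
            calls.append(CNVCall(sid, iv, cn, _n_probes_in(grid[chrom], iv.start, iv.end)))
            call_count[sid] = call_count.get(sid, 0) + 1

        # risk-locus carriers
        for locus in spec.risk_loci:
            p = np.where(is_case, locus.case_freq, locus.control_freq)
            carrier = rng.random(n_tot) < p
            L = chrom_len[locus.interval.chrom]
            for i in np.nonzero(carrier)[0]:
                if locus.recurrent:
                    iv = locus.interval
                else:
                    jit = rng.normal(0, locus.breakpoint_sd, 2)
                    start = max(1, int(locus.interval.start + jit[0]))
                    end = min(L, int(locus.interval.end + jit[1]))
                    if end - start + 1 < spec.min_call_bp:
                        end = min(L, start + spec.min_call_bp - 1)
                    iv = GenomicInterval(locus.interval.chrom, start, end)
                cn = 1 if locus.copy_type == DELETION else 3
                sid = ids[i]
                calls.append(
                    CNVCall(sid, iv, cn, _n_probes_in(grid[iv.chrom], iv.start, iv.end))
                )
                call_count[sid] = call_count.get(sid, 0) + 1

        # QC metrics; a small fraction of samples are genuine array failures.
        # The cnv_count metric mirrors the *raw* segmentation output: tens of
        # small artifact calls per person on top of the rare calls modeled
        # explicitly, so the metric has spread and its outlier tail marks
        # noisy arrays rather than every rare-CNV carrier.
        lrr_sd = np.maximum(0.02, rng.normal(0.12, 0.02, n_tot))
        baf_drift = np.abs(rng.normal(0.002, 0.001, n_tot))
        wave = rng.normal(0.0, 0.015, n_tot)
        artifact = rng.poisson(spec.artifact_call_rate, n_tot)
        bad = rng.random(n_tot) < spec.qc_outlier_fraction
        lrr_sd[bad] *= 3.0
        artifact[bad] *= 4
        for i in range(n_tot):
            samples.append(
                SampleRecord(
                    sample_id=ids[i],
                    phenotype="case" if is_case[i] else "control",
                    stratum=st.label,
                    qc_metrics=SampleQC(
                        lrr_sd=float(lrr_sd[i]),
                        baf_drift=float(baf_drift[i]),
                        wave_factor=float(wave[i]),
                        cnv_count=int(artifact[i]) + call_count.get(ids[i], 0),
                    ),
                )
            )

    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.sample_id))
    return CohortData(samples, calls, genes, lcr, probes, spec)


def generate_lrr(
    calls: Sequence[CNVCall],
    samples: Sequence[SampleRecord],
    positions: dict[str, np.ndarray],
    noise_sd: float = 0.15,
    del_shift: float = -0.45,
    dup_shift: float = 0.30,
    seed: int = 0,
) -> LRRMatrix:
    """Gaussian LRR noise with carrier in-call probes shifted by type.

    ``positions`` maps chromosome -> sorted probe coordinates (restrict to a
    region of interest to keep the matrix small).  Defaults put a
    heterozygous deletion |shift|/noise_sd = 3 population SDs below zero.
    """
    if not (del_shift < 0 < dup_shift):
        raise ValueError("need del_shift < 0 < dup_shift")
    rng = np.random.default_rng(seed)
    sample_ids = [s.sample_id for s in samples]
    col = {sid: i for i, sid in enumerate(sample_ids)}
    values = {
        chrom: rng.normal(0.0, noise_sd, (len(pos), len(sample_ids)))
        for chrom, pos in positions.items()
    }
    for c in calls:
        j = col.get(c.sample_id)
        pos = positions.get(c.interval.chrom)
        if j is None or pos is None:
            continue
        lo = np.searchsorted(pos, c.interval.start, side="left")
        hi = np.searchsorted(pos, c.interval.end, side="right")
        if hi > lo:
            values[c.interval.chrom][lo:hi, j] += (
                del_shift if c.copy_type == DELETION else dup_shift
            )
    return LRRMatrix(positions=dict(positions), values=values, sample_ids=sample_ids)


def end_to_end_recovery(
    spec: SyntheticCohortSpec,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    config: FilterConfig = FilterConfig(),
    apply_frequency_filter: bool = False,
) -> dict:
    """Generate a cohort, clean it, run the association scan, score recovery.

    Stages: sample-outlier QC -> per-sample call joining -> size/probe/LCR/
    density filters -> (optionally the >1% locus-frequency exclusion) ->
    gene screening with replication and region collapse.  The frequency
    filter defaults off here: it targets common polymorphisms, and a planted
    locus whose pooled carrier frequency is pushed past 1% by a large odds
    ratio would be censored by design rather than missed by the test — the
    full pipeline (:mod:`cnvpipe.pipeline`) always applies it.

    Returns a report with per-locus detection (a significant gene of the
    right type overlapping the locus, discovery p < alpha), the estimated
    pooled OR and its log, and stage-by-stage counts.
    """
    if seed is not None:
        spec = replace(spec, seed=seed)
    cohort = generate_cohort(spec)

    kept_samples, excluded = exclude_outlier_samples(cohort.samples)
    kept_ids = {s.sample_id for s in kept_samples}
    calls = [c for c in cohort.calls if c.sample_id in kept_ids]
    n_raw = len(calls)
    calls = join_calls_by_sample(calls, config.join_gap_fraction)
    n_joined = len(calls)
    calls, removed = filter_calls(calls, cohort.lcr, config)
    n_filtered = len(calls)
    if apply_frequency_filter:
        calls, _ = filter_by_locus_frequency(calls, kept_samples, config)
    n_final = len(calls)

    discovery = spec.strata[0].label
    results = screen_and_replicate(
        cohort.genes, calls, kept_samples, discovery_stratum=discovery, alpha=alpha
    )
    regions = collapse_regions(results, cohort.genes, calls)

    loci_report = []
    for locus in spec.risk_loci:
        overlapping = [
            r
            for r in results
            if r.copy_type == locus.copy_type
            and any(
                locus.interval.overlaps(g.interval)
                for g in cohort.genes
                if g.gene_id == r.gene_id
            )
        ]
        if overlapping:
            best = min(overlapping, key=lambda r: r.p_discovery)
            loci_report.append(
                {
                    "label": locus.label,
                    "detected": best.p_discovery < alpha,
                    "p_discovery": best.p_discovery,
                    "p_combined": best.p_combined,
                    "or": best.pooled_or,
                    "ln_or": math.log(best.pooled_or) if best.pooled_or else None,
                    "gene": best.gene_id,
                }
            )
        else:
            loci_report.append(
                {
                    "label": locus.label,
                    "detected": False,
                    "p_discovery": None,
                    "p_combined": None,
                    "or": None,
                    "ln_or": None,
                    "gene": None,
                }
            )

    return {
        "loci": loci_report,
        "n_samples_kept": len(kept_samples),
        "n_samples_excluded": len(excluded),
        "n_calls_raw": n_raw,
        "n_calls_joined": n_joined,
        "n_calls_filtered": n_filtered,
        "n_calls_final": n_final,
        "n_significant_genes": len(results),
        "n_regions": len(regions),
        "results": results,
        "regions": regions,
    }
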