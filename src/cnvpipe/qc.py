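"""Sample-level QC exclusion, adjacent-call joining, and call-level filters.

The cleaning cascade applied to raw array CNV calls before any association
testing:

1. samples that are outliers on any of four array-quality metrics are dropped;
2. adjacent same-type calls in one sample are joined when the gap between
   them is under half their combined length (artifact of segmentation
   splitting one event in two);
3. calls are dropped when too short (<10 kb), supported by too few probes
   (<10), mostly inside low-copy repeats (>50% of length), or too sparsely
   probed (<1 probe per 20 kb);
4. common CNV loci (>1% frequency across all samples pooled) are dropped —
   the analysis targets rare variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval, total_overlap_bp
from .io_formats import DELETION, CNVCall, SampleQC, SampleRecord


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the call-level filter cascade (defaults = study protocol)."""

    min_length_bp: int = 10_000
    min_probes: int = 10
    max_lcr_overlap_fraction: float = 0.5
    min_probe_density: float = 1 / 20_000  # probes per bp
    max_locus_frequency: float = 0.01
    join_gap_fraction: float = 0.5
    locus_overlap_fraction: float = 0.5  # reciprocal-coverage fraction for frequency counting

    def __post_init__(self) -> None:
        for name in (
            "max_lcr_overlap_fraction",
            "max_locus_frequency",
            "join_gap_fraction",
            "locus_overlap_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("min_length_bp", "min_probes", "min_probe_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Sample outlier exclusion
# ---------------------------------------------------------------------------

def _metric_value(qc: SampleQC, metric: str) -> float:
    v = getattr(qc, metric)
    # the wave factor is signed; quality degrades with magnitude either way
    return abs(v) if metric == "wave_factor" else float(v)


def exclude_outlier_samples(
    samples: Sequence[SampleRecord],
    fixed_thresholds: Optional[Mapping[str, float]] = None,
    iqr_multiplier: float = 3.0,
) -> tuple[list[SampleRecord], list[tuple[SampleRecord, list[str]]]]:
    """Drop samples that are an outlier on *any one* QC metric.

    Default rule, applied within each stratum separately: a sample is an
    outlier on a metric when its value exceeds ``median + iqr_multiplier*IQR``
    of that metric (strictly; the wave factor is tested on absolute value).
    ``fixed_thresholds`` (metric name -> absolute upper bound) replaces the
    adaptive rule for the named metrics.

    Returns ``(kept, excluded)`` where each excluded entry carries the list
    of violated metric names.
    """
    for s in samples:
        if s.qc_metrics is None:
            raise ValueError(f"sample {s.sample_id} has no QC metrics")
        for metric in SampleQC.METRICS:
            if getattr(s.qc_metrics, metric) is None:
                raise ValueError(f"sample {s.sample_id} missing metric {metric}")

    fixed = dict(fixed_thresholds or {})
    # adaptive bounds per (stratum, metric)
    bounds: dict[tuple[str, str], float] = {}
    strata = {s.stratum for s in samples}
    for stratum in strata:
        members = [s for s in samples if s.stratum == stratum]
        for metric in SampleQC.METRICS:
            if metric in fixed:
                continue
            vals = np.array([_metric_value(s.qc_metrics, metric) for s in members])
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            bounds[(stratum, metric)] = med + iqr_multiplier * (q3 - q1)

    kept, excluded = [], []
    for s in samples:
        violated = []
        for metric in SampleQC.METRICS:
            bound = fixed.get(metric, bounds.get((s.stratum, metric)))
            if _metric_value(s.qc_metrics, metric) > bound:
                violated.append(metric)
        if violated:
            excluded.append((s, violated))
        else:
            kept.append(s)
    return kept, excluded


# ---------------------------------------------------------------------------
# Adjacent-call joining
# ---------------------------------------------------------------------------

def _merge_pair(a: CNVCall, b: CNVCall) -> CNVCall:
    # span the two calls; probes add; keep the more extreme copy number so a
    # homozygous segment inside a het deletion stays a deletion call
    cn = min(a.copy_number, b.copy_number) if a.copy_type == DELETION else max(
        a.copy_number, b.copy_number
    )
    return CNVCall(
        sample_id=a.sample_id,
        interval=GenomicInterval(
            a.interval.chrom,
            min(a.interval.start, b.interval.start),
            max(a.interval.end, b.interval.end),
        ),
        copy_number=cn,
        n_probes=a.n_probes + b.n_probes,
    )


def join_adjacent_calls(
    calls: Sequence[CNVCall], join_gap_fraction: float = 0.5
) -> list[CNVCall]:
    """Join one sample's fragmented calls separated by small gaps.

    Two consecutive same-chromosome, same-type calls A, B (coordinate order)
    merge when ``gap < join_gap_fraction * (length(A) + length(B))`` with
    ``gap = start(B) - end(A) - 1``; the scan repeats to a fixpoint so chains
    collapse.  Strict inequality: a gap exactly at the threshold stays split.
    """
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"join_adjacent_calls got calls from {len(sample_ids)} samples")
    groups: dict[tuple[str, str], list[CNVCall]] = {}
    for c in calls:
        groups.setdefault((c.interval.chrom, c.copy_type), []).append(c)

    out: list[CNVCall] = []
    for group in groups.values():
        cur = sorted(group, key=lambda c: (c.interval.start, c.interval.end))
        changed = True
        while changed:
            changed = False
            nxt: list[CNVCall] = [cur[0]]
            for b in cur[1:]:
                a = nxt[-1]
                gap = b.interval.start - a.interval.end - 1
                if gap < join_gap_fraction * (a.length + b.length):
                    nxt[-1] = _merge_pair(a, b)
                    changed = True
                else:
                    nxt.append(b)
            cur = nxt
        out.extend(cur)
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return out


def join_calls_by_sample(
    calls: Iterable[CNVCall], join_gap_fraction: float = 0.5
) -> list[CNVCall]:
    """Apply :func:`join_adjacent_calls` to each sample's calls."""
    by_sample: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    out: list[CNVCall] = []
    for sample_calls in by_sample.values():
        out.extend(join_adjacent_calls(sample_calls, join_gap_fraction))
    return out


# ---------------------------------------------------------------------------
# Call-level filters
# ---------------------------------------------------------------------------

#: fixed order in which removal reasons are checked and labeled
REASON_ORDER = ("min_length", "min_probes", "lcr_overlap", "probe_density")


def filter_calls(
    calls: Sequence[CNVCall],
    lcr_track: Sequence[GenomicInterval] = (),
    config: FilterConfig = FilterConfig(),
) -> tuple[list[CNVCall], list[tuple[CNVCall, str]]]:
    """Apply the size / probe / LCR / density filters.

    A call is removed iff its length is below ``min_length_bp``, it has fewer
    than ``min_probes`` probes, more than ``max_lcr_overlap_fraction`` of its
    bases lie in low-copy repeats (strictly more), or its probe density is
    below ``min_probe_density``.  Each removed call is labeled with the first
    triggering reason in the fixed order ``REASON_ORDER``.
    """
    lcr_trees: dict[str, IntervalTree] = {}
    from .intervals import merge_intervals

    for iv in merge_intervals(lcr_track) if lcr_track else []:
        lcr_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1)

    kept: list[CNVCall] = []
    removed: list[tuple[CNVCall, str]] = []
    for c in calls:
        reason = None
        if c.length < config.min_length_bp:
            reason = "min_length"
        elif c.n_probes < config.min_probes:
            reason = "min_probes"
        else:
            tree = lcr_trees.get(c.interval.chrom)
            if tree is not None:
                ov = sum(
                    min(hit.end - 1, c.interval.end) - max(hit.begin, c.interval.start) + 1
                    for hit in tree.overlap(c.interval.start, c.interval.end + 1)
                )
                if ov / c.length > config.max_lcr_overlap_fraction:
                    reason = "lcr_overlap"
            if reason is None and c.n_probes / c.length < config.min_probe_density:
                reason = "probe_density"
        if reason is None:
            kept.append(c)
        else:
            removed.append((c, reason))
    return kept, removed


def filter_by_locus_frequency(
    calls: Sequence[CNVCall],
    samples: Sequence[SampleRecord] | int,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[CNVCall], list[CNVCall]]:
    """Drop calls at loci seen in more than ``max_locus_frequency`` of samples.

    All strata are pooled.  A call's locus frequency is the fraction of
    distinct samples carrying a same-type call that covers at least
    ``config.locus_overlap_fraction`` (default 50%) of *this* call's length
    — one-directional overlap, PLINK ``--cnv-freq-method2``-style counting.
    """
    n_samples = samples if isinstance(samples, int) else len(samples)
    if n_samples == 0:
        raise ValueError("zero samples")

    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, c in enumerate(calls):
        trees.setdefault((c.interval.chrom, c.copy_type), IntervalTree()).addi(
            c.interval.start, c.interval.end + 1, idx
        )

    kept, removed = [], []
    for c in calls:
        tree = trees[(c.interval.chrom, c.copy_type)]
        need = config.locus_overlap_fraction * c.length
        carriers = set()
        for hit in tree.overlap(c.interval.start, c.interval.end + 1):
            other = calls[hit.data]
            if other.interval.overlap_bp(c.interval) >= need:
                carriers.add(other.sample_id)
        if len(carriers) / n_samples > config.max_locus_frequency:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed
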