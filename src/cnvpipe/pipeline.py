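"""End-to-end orchestration: simulate -> QC -> validate -> associate -> burden.

``run_pipeline`` executes every stage in order on a synthetic cohort (or on
calls/samples supplied by the caller), writes per-stage TSVs plus a
Table-1-style combined report, and keeps a machine-readable run log with
counts at every filter step.  Stage outputs are pure functions of
(inputs, config, seed); re-running with the same config reproduces every
file byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .association import RegionResult, collapse_regions, screen_and_replicate
from .burden import burden_decomposition
from .intervals import GenomicInterval
from .io_formats import (
    CNVCall,
    SampleRecord,
    write_penncnv_calls,
    write_sample_table,
)
from .qc import (
    FilterConfig,
    exclude_outlier_samples,
    filter_by_locus_frequency,
    filter_calls,
    join_calls_by_sample,
)
from .simulate import CohortData, SyntheticCohortSpec, generate_cohort, generate_lrr
from .zscore import validate_calls


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    out_dir: str | Path
    spec: Optional[SyntheticCohortSpec] = None  # simulate when given
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    excluded_loci: Sequence[GenomicInterval] = ()   # known loci masked before screening
    manual_removals: Sequence[GenomicInterval] = () # post-inspection region removals
    validate_lrr: bool = False   # run median-Z validation on significant regions
    burden_mode: str = "rate"


def _assoc_frame(results, regions: list[RegionResult]) -> pd.DataFrame:
    region_of = {}
    for reg in regions:
        for gid in reg.member_genes:
            region_of[(gid, reg.representative.copy_type)] = reg.label
    rows = []
    for r in results:
        disc, repl = r.discovery_table, list(r.replication_tables.values())
        rows.append(
            {
                "gene": r.gene_id,
                "region": region_of.get((r.gene_id, r.copy_type), ""),
                "type": r.copy_type,
                "disc_case": disc.a,
                "disc_control": disc.c,
                "repl_case": sum(t.a for t in repl),
                "repl_control": sum(t.c for t in repl),
                "p_discovery": r.p_discovery,
                "p_replication": r.p_replication,
                "p_cmh": r.p_combined,
                "odds_ratio": r.pooled_or if r.pooled_or is not None else float("nan"),
                "ci_low": r.or_ci95[0] if r.or_ci95 else float("nan"),
                "ci_high": r.or_ci95[1] if r.or_ci95 else float("nan"),
                "case_pct": r.case_pct,
                "control_pct": r.control_pct,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    cohort: Optional[CohortData] = None,
) -> Path:
    """Run all stages; returns the report directory.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "alpha": config.alpha}

    stage = "simulate"
    try:
        if cohort is None:
            if config.spec is None:
                raise ValueError("need either a cohort or a SyntheticCohortSpec")
            cohort = generate_cohort(config.spec)
        write_sample_table(cohort.samples, out / "samples_raw.tsv")
        write_penncnv_calls(cohort.calls, out / "calls_raw.txt")
        log["n_samples_raw"] = len(cohort.samples)
        log["n_calls_raw"] = len(cohort.calls)

        stage = "qc"
        fc = config.filter_config
        kept_samples, excluded = exclude_outlier_samples(cohort.samples)
        kept_ids = {s.sample_id for s in kept_samples}
        calls = [c for c in cohort.calls if c.sample_id in kept_ids]
        calls = join_calls_by_sample(calls, fc.join_gap_fraction)
        log["n_samples_kept"] = len(kept_samples)
        log["n_samples_excluded"] = len(excluded)
        log["n_calls_joined"] = len(calls)
        calls, removed = filter_calls(calls, cohort.lcr, fc)
        reasons: dict[str, int] = {}
        for _, reason in removed:
            reasons[reason] = reasons.get(reason, 0) + 1
        log["n_removed_by_reason"] = reasons
        calls, freq_removed = filter_by_locus_frequency(calls, kept_samples, fc)
        log["n_removed_frequency"] = len(freq_removed)
        log["n_calls_final"] = len(calls)
        write_sample_table(kept_samples, out / "samples_qc.tsv")
        write_penncnv_calls(calls, out / "calls_qc.txt")

        stage = "association"
        discovery = kept_samples[0].stratum if cohort.spec is None else cohort.spec.strata[0].label
        masked = list(config.excluded_loci) + list(config.manual_removals)
        results = screen_and_replicate(
            cohort.genes, calls, kept_samples,
            discovery_stratum=discovery, alpha=config.alpha, excluded_loci=masked,
        )
        regions = collapse_regions(results, cohort.genes, calls)
        log["n_significant_genes"] = len(results)
        log["n_regions"] = len(regions)
        frame = _assoc_frame(results, regions)
        frame.to_csv(out / "association.tsv", sep="\t", index=False)

        stage = "validate"
        if config.validate_lrr and results:
            # score calls inside significant regions against synthetic LRR
            sig_genes = {r.gene_id for r in results}
            spans = [g.interval for g in cohort.genes if g.gene_id in sig_genes]
            sig_calls = [
                c for c in calls if any(c.interval.overlaps(s) for s in spans)
            ]
            if sig_calls:
                chroms = {c.interval.chrom for c in sig_calls}
                grid = cohort.probes[discovery]
                positions = {ch: grid[ch] for ch in chroms if ch in grid}
                carriers = {c.sample_id for c in sig_calls}
                subset = [s for s in kept_samples if s.sample_id in carriers]
                # pad with non-carriers: the reference panel must be large
                # enough that carriers barely contaminate per-probe mean/SD
                pad = [s for s in kept_samples if s.sample_id not in carriers][:2000]
                panel = subset + pad
                lrr = generate_lrr(sig_calls, panel, positions, seed=config.seed)
                zres = validate_calls(sig_calls, lrr)
                pd.DataFrame(
                    {
                        "sample": [z.call.sample_id for z in zres],
                        "interval": [str(z.call.interval) for z in zres],
                        "type": [z.call.copy_type for z in zres],
                        "median_z": [z.median_z for z in zres],
                        "n_probes": [z.n_probes_used for z in zres],
                        "status": [z.status for z in zres],
                    }
                ).to_csv(out / "zscores.tsv", sep="\t", index=False)
                log["n_validated"] = sum(1 for z in zres if z.validated)
                log["n_untestable"] = sum(1 for z in zres if z.validated is None)

        stage = "burden"
        implicated = list(config.excluded_loci)
        for reg in regions:
            rep = reg.representative
            spans = [g.interval for g in cohort.genes if g.gene_id in reg.member_genes]
            if spans:
                implicated.append(
                    GenomicInterval(
                        spans[0].chrom,
                        min(s.start for s in spans),
                        max(s.end for s in spans),
                    )
                )
        decomp = burden_decomposition(
            calls, kept_samples, implicated,
            n_perm=config.n_perm, seed=config.seed, mode=config.burden_mode,
        )
        rows = []
        for (sc, ct), cell in decomp.items():
            before, after = cell["before"], cell["after"]
            rows.append(
                {
                    "size_class": sc,
                    "type": ct,
                    "excess_before": before.excess,
                    "excess_after": after.excess,
                    "attributable_excess": cell["attributable_excess"],
                    "p_perm_before": before.p_perm,
                    "p_perm_after": after.p_perm,
                }
            )
        pd.DataFrame(rows).to_csv(out / "burden.tsv", sep="\t", index=False)

        stage = "report"
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return out
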