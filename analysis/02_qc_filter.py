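"""Clean the raw calls: sample-outlier exclusion, adjacent-call joining,
size/probe/LCR/density filters, and the >1% locus-frequency exclusion.

Reads the files 01 wrote, so the whole cascade runs off disk formats."""

from common import RESULTS

from cnvpipe import (
    FilterConfig,
    exclude_outlier_samples,
    filter_by_locus_frequency,
    filter_calls,
    join_calls_by_sample,
    read_bed_intervals,
    read_penncnv_calls,
    read_sample_table,
    write_penncnv_calls,
    write_sample_table,
)

cohort_dir = RESULTS / "cohort"
samples = read_sample_table(cohort_dir / "samples.tsv")
calls = read_penncnv_calls(cohort_dir / "calls.txt")
lcr = [iv for iv, _ in read_bed_intervals(cohort_dir / "lcr.bed")]
config = FilterConfig()

kept_samples, excluded = exclude_outlier_samples(samples)
print(f"sample QC: kept {len(kept_samples)}, excluded {len(excluded)} "
      f"(outlier on any of 4 array metrics)")

kept_ids = {s.sample_id for s in kept_samples}
calls = [c for c in calls if c.sample_id in kept_ids]
n0 = len(calls)
calls = join_calls_by_sample(calls, config.join_gap_fraction)
print(f"joining: {n0} -> {len(calls)} calls (gap < 50% of combined length)")

calls, removed = filter_calls(calls, lcr, config)
reasons = {}
for _, r in removed:
    reasons[r] = reasons.get(r, 0) + 1
print(f"filters: removed {len(removed)} calls by reason {reasons}")

calls, freq_removed = filter_by_locus_frequency(calls, kept_samples, config)
print(f"frequency: removed {len(freq_removed)} calls at loci >1% in all samples")
print(f"final: {len(calls)} calls pass QC")

write_sample_table(kept_samples, RESULTS / "samples_qc.tsv")
write_penncnv_calls(calls, RESULTS / "calls_qc.txt")
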