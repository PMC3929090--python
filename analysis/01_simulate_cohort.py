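"""Generate the demonstration cohort and write it in the pipeline's input
formats (PennCNV calls, sample TSV, gene/LCR BED tracks)."""

from common import DEMO_SPEC, RESULTS

from cnvpipe import generate_cohort, write_bed_intervals, write_penncnv_calls, write_sample_table

out = RESULTS / "cohort"
out.mkdir(parents=True, exist_ok=True)

cohort = generate_cohort(DEMO_SPEC)
write_sample_table(cohort.samples, out / "samples.tsv")
write_penncnv_calls(cohort.calls, out / "calls.txt")
write_bed_intervals(
    [(ex, g.gene_id) for g in cohort.genes for ex in g.exons], out / "genes.bed"
)
write_bed_intervals([(iv, None) for iv in cohort.lcr], out / "lcr.bed")

n_case = sum(1 for s in cohort.samples if s.is_case)
print(f"cohort: {n_case} cases / {len(cohort.samples) - n_case} controls "
      f"in {len({s.stratum for s in cohort.samples})} strata")
print(f"calls: {len(cohort.calls)} raw CNV calls "
      f"({sum(c.copy_type == 'deletion' for c in cohort.calls)} deletions)")
print(f"planted loci: {[l.label for l in DEMO_SPEC.risk_loci]}")
print(f"written to {out}")
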