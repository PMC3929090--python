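# Methods

## The statistical design

The pipeline targets the standard two-stage rare-CNV association design.
A *discovery* case/control stratum is scanned gene by gene: for each gene
and each CNV type (deletions and duplications strictly separate), the
carrier count — samples with at least one call of that type overlapping at
least one exon base — forms a 2×2 table against phenotype, tested with a
two-sided Fisher exact test. Genes with p < α (default 0.05) *and* case
enrichment advance. In the *replication* strata the hypothesis is now
directional, so the test is a one-sided (upper-tail) Fisher exact on the
replication strata pooled into one 2×2. The combined evidence over all
strata is a Cochran–Mantel–Haenszel chi-square (1 df, no continuity
correction), stratified by dataset so that between-dataset frequency
differences (platform, ancestry) cannot masquerade as association. With
only a discovery stratum present, the combined p-value degenerates to the
discovery p.

Effect sizes are *pooled* (collapsed) odds ratios rather than CMH common
odds ratios: all strata are summed into one table and OR = ad/bc. The 95%
CI is Woolf's interval on the log scale with z = 1.96 (the conventional
rounded quantile, which is what the classic tools of this literature use),
with the Haldane–Anscombe correction — 0.5 added to *every* cell — applied
only when some cell is zero. When there are no control carriers the OR
itself is undefined and reported as NA while the Haldane CI is still
given; when there are no carriers at all, both are undefined. This exact
recipe was locked in only after verifying, by direct arithmetic on pooled
2×2 tables, that it reproduces the full set of reference OR/CI values the
package's acceptance suite asserts (including the zero-cell cases).

Multiple-testing correction is deliberately *not* applied to outputs — the
design reports nominal p-values and treats replication as the guard — but
`bonferroni_threshold` provides the genome-wide reference line
α/(20,000 genes × 2 types) = 1.25×10⁻⁶.

Genes disrupted by the same call in at least one sample are collapsed into
regions (connected components of the sharing graph, per CNV type), because
a recurrent multi-gene CNV yields one signal, not several independent
ones. Each region is reported through its member with the smallest
combined p-value. Known loci and regions removed after manual inspection
enter as an exclusion list of intervals masked before screening; nothing
about that step is automated.

## QC cascade

Cleaning happens in a fixed order, each rule taken with strict
inequalities:

1. **Sample outliers.** A sample is dropped when any one of its four array
   metrics (LRR SD, BAF drift, |wave factor|, calls per person) exceeds
   `median + 3·IQR` of that metric within its stratum. The multiplier and
   per-metric fixed thresholds are configurable; the adaptive rule is the
   package's choice of a reasonable "outlier" operationalization, and with
   identical metric values nothing is excluded (IQR = 0 excludes only
   strictly greater values).
2. **Joining.** Segmentation tends to split one event into fragments. Two
   consecutive same-chromosome, same-type calls of one sample merge when
   the gap between them (start(B) − end(A) − 1) is under half the *sum of
   their lengths*; the scan repeats until nothing changes, so chains
   collapse. The sum-of-lengths reading (rather than merged-span) keeps
   the rule symmetric; merged probes add; the more extreme copy number is
   kept. Equivalence of the coordinate-order scan with an
   arbitrary-order pairwise-merge fixpoint is property-tested against a
   brute-force oracle.
3. **Call filters**, labeled by first triggering reason in the fixed order
   length → probes → LCR → density: <10 kb, <10 probes, >50% of bases in
   low-copy repeats, <1 probe/20 kb.
4. **Locus frequency.** Pooling all strata, a call is dropped when
   same-type calls covering ≥50% of *its* length are carried by >1% of
   samples (one-directional overlap counting, in the style of PLINK's
   `--cnv-freq-method2`; both the fraction and threshold are
   configurable).

## Median Z-score validation

Each probe's LRR is standardized to mean 0, SD 1 across samples (sample
SD, ddof = 1; constant rows go to zero with a warning). A call's score is
the carrier's *median* Z over in-call probes (even counts: mean of the two
central values); deletions validate at median Z ≤ −2, duplications at
≥ +2, and calls with fewer than 3 in-call probes are *untestable* rather
than failed. All thresholds are parameters. The reference mean/SD
includes the carrier by default — stable for large cohorts — with a
closed-form leave-one-out mode for small panels. A practical caveat the
tests exercise explicitly: if carriers of one recurrent locus exceed a few
percent of the panel, they contaminate the per-probe reference (mean
pulled toward the shift, SD inflated) and sensitivity drops; validation
panels should therefore be dominated by non-carriers, which is how the
pipeline stage builds them.

## Burden

The burden statistic is the *excess*: mean CNV count per case minus per
control, ×100 (a carrier-proportion mode is provided as the "x% excess"
phrasing is compatible with either; the count mode is the default).
Calls are stratified by size (>500 kb, 500 kb–1 Mb, >1 Mb — strict lower
bounds, inclusive upper) and type. Significance is one-sided permutation:
phenotype labels are shuffled within stratum, p = (1 + #{permuted ≥
observed}) / (n_perm + 1); the +1 correction avoids zero p-values and
makes the test valid but slightly conservative on coarse grids (visible
when counts are sparse and heavily tied; with denser counts the null
rejection rate sits at nominal level, which the suite measures).
Per-stratum count vectors are sorted before shuffling so the p-value is
exactly invariant to sample ordering at a fixed seed. Decomposition
re-runs every cell after dropping calls overlapping implicated loci by
≥1 bp (whole-call removal, not trimming); the excess is additive over any
partition of calls, so before − after is the excess attributable to those
loci.

## Power

A locus is parameterized by its control carrier proportion q and odds
ratio; the case proportion is the odds transform OR·q/(1−q+OR·q), which
makes the planted generative OR identical to the analysis estimand.
`analytic_power` defaults to exact enumeration of Fisher's test over the
joint binomial distribution of carrier counts (deterministic, truncated at
negligible tail mass). The familiar non-central chi-square two-proportion
approximation is provided as `method="chi2"` and is used for curve tracing
(root finding), but it is *not* the default because at the rare
frequencies this field cares about (q ~ 10⁻⁴–10⁻³) it misses the exact
Fisher power by up to ~0.1 in either direction — far beyond the precision
the frontier is quoted at. A seeded binomial/Fisher simulation mode is
the independent cross-check; exact enumeration agrees with it to Monte
Carlo error, which the acceptance suite asserts at ±0.03. The 80%-power
frontier is found by bisection on log OR (power is monotone in OR).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the emulated study's sample sizes by default: eight strata (one discovery
of 6882 cases / 11,255 controls; seven replication strata totalling
14,568 / 15,274, with the trio-derived dataset modeled as a case/control
stratum of matched size, which is how the association stage consumes it).
Per sample, background CNVs are Poisson (default mean 0.5 per person,
the order of large rare calls surviving QC in real array data), placed
uniformly with log-normal sizes (median 100 kb, log-SD 1, clipped to
5 kb–5 Mb), half deletions (10% homozygous) and half duplications. Risk
loci draw carrier status Bernoulli(q) in controls and Bernoulli(odds
transform) in cases; recurrent loci reuse fixed breakpoints, non-recurrent
loci jitter both breakpoints with Gaussian SD (default 50 kb). Probe
counts come from each stratum's regular probe grid (default spacing
4–5 kb, the order of a genome-wide consensus probe set). QC metrics are
drawn from plausible array distributions, with a small fraction (0.2%) of
genuine array failures; the calls-per-person metric includes a Poisson(30)
count of small artifact calls not otherwise modeled, because the raw
segmentation output a QC metric sees is dominated by such calls — without
them the metric would be degenerate (median and IQR both ~0) and the
outlier rule would excise every rare-CNV carrier. The default genome is a
miniature (5 × 50 Mb, 2000 evenly spaced genes of 20 kb with 8 exons of
200 bp), so end-to-end runs take seconds; everything scales up by spec.

What the generator does *not* emulate: LD and NAHR sequence context, real
gene-density and size distributions, platform batch effects beyond
per-stratum probe spacing, B-allele frequencies, and call-boundary error.
Passing tests therefore demonstrate the statistical machinery — detection,
calibration, effect-size recovery, filter behavior — under the assumed
model, not robustness to array artifacts beyond those modeled.

### The recovery harness and the frequency filter

`end_to_end_recovery` runs generation → sample QC → joining → call filters
→ association → region collapse and scores each planted locus (detected =
an overlapping significant gene of the right type with discovery
p < 0.05). The >1% locus-frequency exclusion is a switch that defaults
off in this harness (it always runs in the full pipeline): its job is
removing common polymorphisms, and a planted locus whose *pooled* carrier
frequency is pushed past 1% by a large odds ratio (q = 0.005 at OR = 5
reaches ~1.2% pooled) would be censored by design — a real interaction
worth knowing about when interpreting near-threshold loci in any pipeline
of this family, and distinct from the association stage's detection
ability, which is what the harness measures.

## Problem sizes and numerical choices

Integration and acceptance tests run the discovery sample sizes
(6882/11,255) on a reduced genome (2 × 30 Mb, 300 genes, background rate
0.2) so that a hundred end-to-end replicates complete in about a minute;
detection probability at the tested effect sizes depends on carrier counts,
not genome size. Tolerances: Fisher vs exact rational enumeration at
1e-12; CMH vs the direct formula at 1e-9 relative; permutation vs
exhaustive enumeration within twice the Monte Carlo SE; power enumeration
truncates binomial tails at 1e-10 total mass. Coordinates are 1-based
inclusive everywhere internally (length = end − start + 1); BED converts
at the boundary. Ties in region reporting break by (combined p, discovery
p, gene id) for reproducibility; all generation and permutation is
`numpy.random.default_rng` seeded, and identical seeds give byte-identical
outputs.

## Known limitations

* The CMH common OR is not computed; effect sizes are pooled ORs, which
  can differ under strong between-stratum frequency heterogeneity
  (Simpson-type effects). The stratified *test* guards inference; the
  pooled OR matches how results are conventionally tabulated.
* The replication Fisher pools strata; a per-stratum one-sided
  combination (e.g. Fisher's method) is not offered.
* Validation operates on simulated LRR only; there is no BAF-based check
  and no mosaicism handling.
* The outlier rule's exact form (median + 3·IQR per stratum) is a
  defensible default, not a community standard; fixed thresholds can be
  supplied where a study protocol prescribes them.
* Trio data are modeled as case/control strata; transmission-based
  analysis is out of scope.
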