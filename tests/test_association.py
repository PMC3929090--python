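"""Gene-based enrichment statistics: Fisher, CMH, pooled OR, screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvpipe import (
    CNVCall,
    ContingencyTable,
    GeneModel,
    GenomicInterval,
    SampleRecord,
    bonferroni_threshold,
    carrier_percentages,
    cmh_statistic,
    cmh_test,
    collapse_regions,
    count_exonic_carriers,
    fisher_one_sided,
    fisher_two_sided,
    pooled_or_ci,
    screen_and_replicate,
)
from cnvpipe.io_formats import DELETION, DUPLICATION

from oracles import cmh_direct, fisher_enumeration, pearson_chi2_2x2


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            # discovery 16p12.1 deletion: 13/6882 cases vs 6/11255 controls
            ((13, 6869, 6, 11249), 0.0084),
            # European-ancestry-restricted: 13/6307 vs 5/10676
            ((13, 6294, 5, 10671), 0.0029),
        ],
    )
    def test_two_sided_reproduces_published_values(self, table, expected):
        assert fisher_two_sided(ContingencyTable(*table)) == pytest.approx(
            expected, rel=5e-2
        )

    def test_one_sided_reproduces_published_replication_value(self):
        # 20 case vs 9 control carriers in the pooled replication sample
        t = ContingencyTable.from_carriers(20, 14_568, 9, 15_274)
        assert fisher_one_sided(t) == pytest.approx(0.023, rel=5e-2)

    def test_symmetric_table_p_one(self):
        assert fisher_two_sided(ContingencyTable(5, 95, 5, 95)) == pytest.approx(1.0)

    def test_no_carriers_one_sided_p_one(self):
        assert fisher_one_sided(ContingencyTable(0, 100, 0, 100)) == pytest.approx(1.0)

    @given(
        st.integers(0, 60), st.integers(0, 140), st.integers(0, 60), st.integers(0, 140)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_exact_enumeration(self, a, b, c, d):
        # margins <= 200; oracle enumerates rational hypergeometric mass
        if a + b == 0 or c + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_enumeration(a, b, c, d, "two-sided"), abs=1e-12
        )
        assert fisher_one_sided(t) == pytest.approx(
            fisher_enumeration(a, b, c, d, "one-sided"), abs=1e-12
        )

    def test_one_sided_below_two_sided_when_enriched(self):
        t = ContingencyTable(12, 88, 3, 97)
        assert fisher_one_sided(t) <= fisher_two_sided(t)


class TestCMH:
    def test_single_stratum_equals_direct_formula(self):
        t = (13, 6869, 6, 11249)
        stat, p = cmh_statistic([ContingencyTable(*t)])
        want_stat, want_p = cmh_direct([t])
        assert stat == pytest.approx(want_stat, rel=1e-10)
        assert p == pytest.approx(want_p, rel=1e-10)
        # the single-stratum CMH statistic is (n-1)/n times Pearson's chi2
        n = sum(t)
        assert stat == pytest.approx((n - 1) / n * pearson_chi2_2x2(*t), rel=1e-10)

    def test_multi_stratum_matches_direct_formula(self):
        tables = [(9, 6873, 0, 11255), (5, 14563, 2, 15272), (3, 997, 1, 999)]
        stat, p = cmh_statistic([ContingencyTable(*t) for t in tables])
        want_stat, want_p = cmh_direct(tables)
        assert stat == pytest.approx(want_stat, rel=1e-9)
        assert p == pytest.approx(want_p, rel=1e-9)

    def test_null_strata_give_statistic_near_zero(self):
        t = ContingencyTable(5, 95, 5, 95)
        stat, p = cmh_statistic([t, t])
        assert stat == pytest.approx(0, abs=1e-9)
        assert p == pytest.approx(1, abs=1e-9)

    def test_all_degenerate_strata_flagged_undefined(self):
        t = ContingencyTable(0, 100, 0, 100)
        assert math.isnan(cmh_test([t, t]))

    def test_degenerate_strata_contribute_nothing(self):
        live = [(13, 6869, 6, 11249), (20, 14548, 9, 15265)]
        dead = ContingencyTable(0, 50, 0, 50)
        with_dead = [ContingencyTable(*t) for t in live] + [dead]
        without = [ContingencyTable(*t) for t in live]
        assert cmh_test(with_dead) == pytest.approx(cmh_test(without), rel=1e-12)

    def test_power_against_common_or_three(self):
        # 8 strata, true common OR 3 at 0.5% control carrier frequency,
        # n=5000/5000 per stratum: the median p over replicates is well
        # under 0.05
        rng = np.random.default_rng(11)
        q = 0.005
        p1 = 3 * q / (1 - q + 3 * q)
        pvals = []
        for _ in range(200):
            tables = []
            for _ in range(8):
                a = rng.binomial(5000, p1)
                c = rng.binomial(5000, q)
                tables.append(ContingencyTable.from_carriers(a, 5000, c, 5000))
            pvals.append(cmh_test(tables))
        assert np.median(pvals) < 0.05


class TestPooledOrCi:
    # pooled 2x2 counts from the combined discovery+replication carrier
    # totals, against the published OR (95% CI) values
    @pytest.mark.parametrize(
        "carriers,published",
        [
            ((33, 15), (2.72, 1.48, 5.02)),    # 16p12.1 deletion
            ((14, 2), (8.66, 1.97, 38.12)),    # 1p36.33 duplication
            ((10, 2), (6.19, 1.36, 28.24)),    # SLC1A1 deletion
            ((69, 50), (1.71, 1.19, 2.46)),    # CGNL1 duplication
            ((74, 64), (1.43, 1.02, 2.00)),    # AQP12A/KIF1A duplication
            ((7, 1), (8.66, 1.07, 70.39)),     # ELOVL6 duplication
            ((9, 1), (11.14, 1.41, 87.90)),    # IRGM region deletion
        ],
    )
    def test_reproduces_published_or_and_ci(self, carriers, published):
        a, c = carriers
        t = ContingencyTable.from_carriers(a, 21_450, c, 26_529)
        orr, ci = pooled_or_ci([t])
        want_or, want_lo, want_hi = published
        assert orr == pytest.approx(want_or, abs=0.005)
        assert ci[0] == pytest.approx(want_lo, abs=0.005)
        assert ci[1] == pytest.approx(want_hi, abs=0.005)

    @pytest.mark.parametrize(
        "carriers,published_ci",
        [
            ((7, 0), (1.06, 324.96)),  # GLIS3: no control carriers
            ((5, 0), (0.75, 246.1)),   # GALR1
        ],
    )
    def test_zero_control_carriers_undefined_or_haldane_ci(self, carriers, published_ci):
        a, c = carriers
        t = ContingencyTable.from_carriers(a, 21_450, c, 26_529)
        orr, ci = pooled_or_ci([t])
        assert orr is None
        assert ci[0] == pytest.approx(published_ci[0], abs=0.005)
        assert ci[1] == pytest.approx(published_ci[1], abs=0.05)

    def test_balanced_table_or_one(self):
        orr, _ = pooled_or_ci([ContingencyTable(10, 90, 10, 90)])
        assert orr == pytest.approx(1.0)

    def test_no_carriers_at_all_undefined(self):
        assert pooled_or_ci([ContingencyTable(0, 10, 0, 10)]) == (None, None)

    def test_invariant_to_stratum_partition(self):
        pooledt = ContingencyTable(33, 21_417, 15, 26_514)
        parts = [
            ContingencyTable(13, 6_869, 6, 11_249),
            ContingencyTable(20, 14_548, 9, 15_265),
        ]
        assert pooled_or_ci([pooledt]) == pooled_or_ci(parts)

    def test_ci_width_shrinks_as_cells_grow(self):
        t1 = ContingencyTable(10, 90, 5, 95)
        t2 = ContingencyTable(20, 180, 10, 190)  # same OR, doubled counts
        _, ci1 = pooled_or_ci([t1])
        _, ci2 = pooled_or_ci([t2])
        assert math.log(ci2[1] / ci2[0]) < math.log(ci1[1] / ci1[0])


class TestCarrierPercentages:
    @pytest.mark.parametrize(
        "carriers,expected",
        [
            ((33, 15), (0.15, 0.057)),  # 16p12.1 combined
            ((69, 50), (0.32, 0.19)),   # CGNL1 combined
            ((0, 0), (0.0, 0.0)),
        ],
    )
    def test_published_percentages(self, carriers, expected):
        a, c = carriers
        t = ContingencyTable.from_carriers(a, 21_450, c, 26_529)
        case_pct, ctrl_pct = carrier_percentages([t])
        assert case_pct == pytest.approx(expected[0], abs=0.005)
        assert ctrl_pct == pytest.approx(expected[1], abs=0.005)


class TestBonferroni:
    @pytest.mark.parametrize(
        "args,expected",
        [((20_000, 2, 0.05), 1.25e-6), ((1, 1, 0.05), 0.05), ((10, 2, 0.05), 2.5e-3)],
    )
    def test_threshold(self, args, expected):
        assert bonferroni_threshold(*args) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# Carrier counting and the screening design
# ---------------------------------------------------------------------------

def _gene(gene_id, chrom, start, end, exon_spans):
    return GeneModel(
        gene_id,
        GenomicInterval(chrom, start, end),
        tuple(GenomicInterval(chrom, s, e) for s, e in exon_spans),
    )


def _del(sample, chrom, start, end):
    return CNVCall(sample, GenomicInterval(chrom, start, end), 1, 50)


class TestCountExonicCarriers:
    gene = _gene("G", "chr1", 1000, 9000, [(1000, 1200), (4000, 4200), (8800, 9000)])

    def _samples(self):
        return [
            SampleRecord("A", "case", "d"),
            SampleRecord("B", "case", "d"),
            SampleRecord("C", "control", "d"),
        ]

    def test_two_hits_in_one_sample_count_once(self):
        calls = [_del("A", "chr1", 900, 1100), _del("A", "chr1", 3900, 4100)]
        t = count_exonic_carriers(self.gene, calls, self._samples(), DELETION, "d")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 1)

    def test_intron_only_call_is_not_a_carrier(self):
        calls = [_del("A", "chr1", 2000, 3500)]  # between exons 1 and 2
        t = count_exonic_carriers(self.gene, calls, self._samples(), DELETION, "d")
        assert t.a == 0

    def test_single_base_exon_overlap_counts(self):
        calls = [_del("C", "chr1", 500, 1000)]  # touches exon 1's first base
        t = count_exonic_carriers(self.gene, calls, self._samples(), DELETION, "d")
        assert (t.a, t.c) == (0, 1)

    def test_type_and_stratum_respected(self):
        dup = CNVCall("A", GenomicInterval("chr1", 900, 1100), 3, 50)
        other = _del("X", "chr1", 900, 1100)  # not in the sample table
        t = count_exonic_carriers(self.gene, [dup, other], self._samples(), DELETION, "d")
        assert t.a == 0 and t.c == 0


class TestScreenAndReplicate:
    def _world(self):
        genes = [
            _gene("RISK", "chr1", 10_000, 30_000, [(10_000, 10_500), (29_000, 30_000)]),
            _gene("NULL", "chr2", 10_000, 30_000, [(10_000, 10_500)]),
            _gene("KNOWN", "chr3", 10_000, 30_000, [(10_000, 10_500)]),
        ]
        samples = [SampleRecord(f"D{i}", "case" if i < 500 else "control", "discovery") for i in range(1500)]
        samples += [SampleRecord(f"R{i}", "case" if i < 500 else "control", "repl") for i in range(1000)]
        calls = [_del(f"D{i}", "chr1", 9_000, 31_000) for i in range(20)]  # 4% of cases
        calls += [_del("D1400", "chr1", 9_000, 31_000)]  # 1 control carrier
        calls += [_del(f"R{i}", "chr1", 9_000, 31_000) for i in range(10)]
        calls += [_del(f"D{i}", "chr3", 9_000, 31_000) for i in range(30)]  # in KNOWN
        return genes, samples, calls

    def test_enriched_gene_advances_with_all_three_pvalues(self):
        genes, samples, calls = self._world()
        results = screen_and_replicate(genes, calls, samples, "discovery")
        (r,) = [x for x in results if x.gene_id == "RISK"]
        assert r.copy_type == DELETION
        assert r.p_discovery < 0.05
        assert r.p_replication is not None and r.p_combined is not None
        assert r.discovery_table.a == 20 and r.discovery_table.c == 1
        assert r.replication_tables["repl"].a == 10

    def test_gene_inside_excluded_locus_is_masked(self):
        genes, samples, calls = self._world()
        results = screen_and_replicate(
            genes, calls, samples, "discovery",
            excluded_loci=[GenomicInterval("chr3", 1, 1_000_000)],
        )
        assert all(r.gene_id != "KNOWN" for r in results)

    def test_gene_without_carriers_screened_out(self):
        genes, samples, calls = self._world()
        results = screen_and_replicate(genes, calls, samples, "discovery")
        assert all(r.gene_id != "NULL" for r in results)

    def test_control_enriched_gene_does_not_advance(self):
        genes, samples, _ = self._world()
        calls = [_del(f"D{i}", "chr1", 9_000, 31_000) for i in range(600, 660)]
        results = screen_and_replicate(genes, calls, samples, "discovery")
        assert results == []

    def test_type_one_error_conservative_under_null(self):
        # 10,000 simulated null genes: equal carrier rates in both arms;
        # the fraction reaching p < 0.05 stays at or below 0.05
        rng = np.random.default_rng(42)
        n1, n0, f = 3000, 4000, 0.004
        a = rng.binomial(n1, f, 10_000)
        c = rng.binomial(n0, f, 10_000)
        hits = sum(
            fisher_two_sided(ContingencyTable.from_carriers(int(ai), n1, int(ci), n0)) < 0.05
            for ai, ci in zip(a, c)
        )
        assert hits / 10_000 <= 0.05


class TestCollapseRegions:
    def _results_for(self, genes, calls, samples):
        return screen_and_replicate(genes, calls, samples, "discovery")

    def test_contiguous_duplication_forms_single_region(self):
        # five adjacent genes all hit by the same duplications
        genes = [
            _gene(f"G{k}", "chr1", 10_000 + 5_000 * k, 13_000 + 5_000 * k,
                  [(10_000 + 5_000 * k, 11_000 + 5_000 * k)])
            for k in range(5)
        ]
        samples = [
            SampleRecord(f"D{i}", "case" if i < 1000 else "control", "discovery")
            for i in range(3000)
        ]
        calls = [
            CNVCall(f"D{i}", GenomicInterval("chr1", 9_000, 40_000), 3, 60)
            for i in range(15)
        ]
        results = self._results_for(genes, calls, samples)
        assert len(results) == 5
        regions = collapse_regions(results, genes, calls)
        assert len(regions) == 1
        assert sorted(regions[0].member_genes) == [f"G{k}" for k in range(5)]

    def test_different_chromosomes_stay_separate(self):
        genes = [
            _gene("A", "chr1", 10_000, 12_000, [(10_000, 11_000)]),
            _gene("B", "chr2", 10_000, 12_000, [(10_000, 11_000)]),
        ]
        samples = [
            SampleRecord(f"D{i}", "case" if i < 1000 else "control", "discovery")
            for i in range(3000)
        ]
        calls = [_del(f"D{i}", "chr1", 9_000, 13_000) for i in range(10)]
        calls += [_del(f"D{i}", "chr2", 9_000, 13_000) for i in range(10)]
        results = self._results_for(genes, calls, samples)
        regions = collapse_regions(results, genes, calls)
        assert len(regions) == 2

    def test_shared_call_chain_is_transitively_closed(self):
        # A-B share one deletion, B-C share another: one region {A,B,C}
        genes = [
            _gene("A", "chr1", 10_000, 12_000, [(10_000, 11_000)]),
            _gene("B", "chr1", 20_000, 22_000, [(20_000, 21_000)]),
            _gene("C", "chr1", 30_000, 32_000, [(30_000, 31_000)]),
        ]
        samples = [
            SampleRecord(f"D{i}", "case" if i < 1000 else "control", "discovery")
            for i in range(3000)
        ]
        calls = [_del(f"D{i}", "chr1", 9_000, 23_000) for i in range(10)]   # A+B
        calls += [_del(f"D{i}", "chr1", 19_000, 33_000) for i in range(10, 20)]  # B+C
        results = self._results_for(genes, calls, samples)
        assert len(results) == 3
        regions = collapse_regions(results, genes, calls)
        assert len(regions) == 1
        assert sorted(regions[0].member_genes) == ["A", "B", "C"]
        # best gene is B: hit by all 20 calls
        assert regions[0].best_gene == "B"
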