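"""Gene-based case-control enrichment of exonic CNVs.

The discovery/replication design: every gene is tested for exon-disrupting
deletions and (separately) duplications in the discovery stratum with a
two-sided Fisher exact test; nominally significant, case-enriched genes
advance to a one-sided Fisher test on the pooled replication strata and a
Cochran-Mantel-Haenszel (CMH) chi-square over all strata.  Effect sizes are
pooled odds ratios with Woolf confidence intervals (Haldane-Anscombe +0.5
correction when a cell is zero).  Genes hit by the same CNV in some sample
collapse into regions reported by their strongest member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from .intervals import GenomicInterval
from .io_formats import DELETION, DUPLICATION, CNVCall, GeneModel, SampleRecord


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier/non-carrier 2x2 counts: a,b = cases, c,d = controls."""

    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def case_rate(self) -> float:
        return self.a / self.n_cases if self.n_cases else 0.0

    @property
    def control_rate(self) -> float:
        return self.c / self.n_controls if self.n_controls else 0.0

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_carriers(cls, case_carriers: int, n_cases: int, control_carriers: int, n_controls: int) -> "ContingencyTable":
        return cls(case_carriers, n_cases - case_carriers, control_carriers, n_controls - control_carriers)

    @staticmethod
    def pool(tables: Iterable["ContingencyTable"]) -> "ContingencyTable":
        a = b = c = d = 0
        for t in tables:
            a, b, c, d = a + t.a, b + t.b, c + t.c, d + t.d
        return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# Elementary tests and effect sizes
# ---------------------------------------------------------------------------

def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: mass of all tables (fixed margins) whose
    point hypergeometric probability is <= the observed table's."""
    if t.n_cases == 0 or t.n_controls == 0:
        raise ValueError("empty margin")
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def fisher_one_sided(t: ContingencyTable) -> float:
    """Upper-tail Fisher exact p for carrier enrichment in cases."""
    if t.n_cases == 0 or t.n_controls == 0:
        raise ValueError("empty margin")
    return float(stats.fisher_exact(t.as_array(), alternative="greater")[1])


def _degenerate(t: ContingencyTable) -> bool:
    """A stratum with an empty margin has zero hypergeometric variance."""
    n = t.a + t.b + t.c + t.d
    return (
        n <= 1
        or t.a + t.c == 0  # no carriers at all
        or t.b + t.d == 0
        or t.n_cases == 0
        or t.n_controls == 0
    )


def cmh_statistic(tables: Sequence[ContingencyTable]) -> tuple[float, float]:
    """CMH chi-square (1 df, no continuity correction) and p over strata.

    Degenerate strata (zero carrier-count variance) contribute nothing.
    Returns ``(nan, nan)`` when every stratum is degenerate.
    """
    usable = [t for t in tables if not _degenerate(t)]
    if not usable:
        return float("nan"), float("nan")
    tbl = np.array([t.as_array() for t in usable])  # k x 2 x 2
    st = StratifiedTable(np.transpose(tbl, (1, 2, 0)))
    res = st.test_null_odds(correction=False)
    return float(res.statistic), float(res.pvalue)


def cmh_test(tables: Sequence[ContingencyTable]) -> float:
    """CMH p-value across stratified 2x2 tables (nan when undefined)."""
    return cmh_statistic(tables)[1]


def pooled_or_ci(
    tables: Sequence[ContingencyTable], z: float = 1.96
) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    """Pooled (collapsed) odds ratio with a Woolf 95% CI.

    All strata are summed into one 2x2.  OR = ad/bc on the raw pooled
    counts, reported as undefined (None) when there are no control carriers
    (c = 0).  The CI uses ``exp(ln OR* +- z*sqrt(1/a*+1/b*+1/c*+1/d*))``
    where z defaults to the conventional 1.96 and the starred counts have 0.5 added to *every* cell iff any cell is
    zero (Haldane-Anscombe), else the raw counts.  With both a = 0 and
    c = 0 the CI is undefined too.
    """
    if not tables:
        raise ValueError("no tables")
    p = ContingencyTable.pool(tables)
    if p.a == 0 and p.c == 0:
        return None, None
    orr = (p.a * p.d) / (p.b * p.c) if p.c > 0 and p.b > 0 else None
    cells = [p.a, p.b, p.c, p.d]
    if min(cells) == 0:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    lor = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(lor - z * se), math.exp(lor + z * se))
    return orr, ci


def carrier_percentages(tables: Sequence[ContingencyTable]) -> tuple[float, float]:
    """Pooled carrier percentages: (100*sum(a)/sum(a+b), 100*sum(c)/sum(c+d))."""
    p = ContingencyTable.pool(tables)
    return 100.0 * p.case_rate, 100.0 * p.control_rate


def bonferroni_threshold(n_genes: int = 20_000, n_types: int = 2, alpha: float = 0.05) -> float:
    """Genome-wide reference threshold: alpha / (genes x CNV types tested)."""
    if n_genes < 1 or n_types < 1 or not 0 < alpha < 1:
        raise ValueError("n_genes, n_types must be positive; alpha in (0,1)")
    return alpha / (n_genes * n_types)


# ---------------------------------------------------------------------------
# Carrier counting
# ---------------------------------------------------------------------------

def _exon_tree(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes):
        for ex in g.exons:
            trees.setdefault(ex.chrom, IntervalTree()).addi(ex.start, ex.end + 1, gi)
    return trees


def genes_hit_by_call(
    call: CNVCall, genes: Sequence[GeneModel], trees: Optional[dict[str, IntervalTree]] = None
) -> set[int]:
    """Indices of genes with >= 1 exon base overlapped by the call."""
    trees = trees if trees is not None else _exon_tree(genes)
    tree = trees.get(call.interval.chrom)
    if tree is None:
        return set()
    return {hit.data for hit in tree.overlap(call.interval.start, call.interval.end + 1)}


def exonic_carriers_by_gene(
    genes: Sequence[GeneModel], calls: Sequence[CNVCall]
) -> dict[tuple[str, str], set[str]]:
    """Map (gene_id, copy_type) -> set of carrier sample ids.

    A sample is a carrier of a gene for a CNV type iff it has >= 1 call of
    that type overlapping >= 1 base of >= 1 exon; multiple qualifying calls
    still count the sample once (sets dedupe).
    """
    trees = _exon_tree(genes)
    carriers: dict[tuple[str, str], set[str]] = {}
    for call in calls:
        for gi in genes_hit_by_call(call, genes, trees):
            carriers.setdefault((genes[gi].gene_id, call.copy_type), set()).add(call.sample_id)
    return carriers


def count_exonic_carriers(
    gene: GeneModel,
    calls: Sequence[CNVCall],
    samples: Sequence[SampleRecord],
    copy_type: str,
    stratum: str,
) -> ContingencyTable:
    """Carrier/non-carrier 2x2 for one gene, one CNV type, one stratum."""
    if copy_type not in (DELETION, DUPLICATION):
        raise ValueError(f"unknown copy type {copy_type!r}")
    members = [s for s in samples if s.stratum == stratum]
    member_ids = {s.sample_id for s in members}
    carrier_ids = exonic_carriers_by_gene([gene], calls).get((gene.gene_id, copy_type), set())
    carrier_ids &= member_ids
    a = sum(1 for s in members if s.is_case and s.sample_id in carrier_ids)
    c = sum(1 for s in members if not s.is_case and s.sample_id in carrier_ids)
    n_cases = sum(1 for s in members if s.is_case)
    n_controls = len(members) - n_cases
    return ContingencyTable.from_carriers(a, n_cases, c, n_controls)


# ---------------------------------------------------------------------------
# Screen -> replicate -> combine
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    gene_id: str
    copy_type: str
    discovery_table: ContingencyTable
    replication_tables: dict[str, ContingencyTable]
    p_discovery: float
    p_replication: Optional[float]
    p_combined: Optional[float]
    pooled_or: Optional[float]
    or_ci95: Optional[tuple[float, float]]
    case_pct: float
    control_pct: float

    @property
    def all_tables(self) -> list[ContingencyTable]:
        return [self.discovery_table, *self.replication_tables.values()]


@dataclass
class RegionResult:
    label: str
    member_genes: list[str]
    best_gene: str
    representative: AssociationResult


def screen_and_replicate(
    genes: Sequence[GeneModel],
    calls: Sequence[CNVCall],
    samples: Sequence[SampleRecord],
    discovery_stratum: str = "discovery",
    alpha: float = 0.05,
    excluded_loci: Sequence[GenomicInterval] = (),
) -> list[AssociationResult]:
    """Run the full gene-wise two-stage analysis.

    Genes whose transcript span overlaps any excluded locus are masked
    before screening (known loci are tested elsewhere, and post-hoc manual
    removals enter through the same list).  Per gene x CNV type, a
    discovery two-sided Fisher test screens; genes with p < alpha *and*
    case enrichment advance to the one-sided replication Fisher (all
    replication strata pooled into one 2x2) and the CMH over all strata.
    Only advanced genes are returned, each with pooled OR/CI/percentages
    over all strata.
    """
    masked = []
    for g in genes:
        if any(g.interval.overlaps(x) for x in excluded_loci):
            continue
        masked.append(g)

    strata = sorted({s.stratum for s in samples})
    if discovery_stratum not in strata:
        raise ValueError(f"discovery stratum {discovery_stratum!r} not present")
    repl_strata = [x for x in strata if x != discovery_stratum]

    # sample bookkeeping per stratum
    by_stratum: dict[str, list[SampleRecord]] = {x: [] for x in strata}
    for s in samples:
        by_stratum[s.stratum].append(s)
    stratum_of = {s.sample_id: s.stratum for s in samples}
    is_case = {s.sample_id: s.is_case for s in samples}
    n_case = {x: sum(1 for s in by_stratum[x] if s.is_case) for x in strata}
    n_ctrl = {x: len(by_stratum[x]) - n_case[x] for x in strata}

    carriers = exonic_carriers_by_gene(masked, calls)

    results: list[AssociationResult] = []
    for g in masked:
        for copy_type in (DELETION, DUPLICATION):
            carrier_ids = carriers.get((g.gene_id, copy_type), set())
            if not carrier_ids:
                continue  # p = 1, screened out
            # per-stratum tables
            a_by = {x: 0 for x in strata}
            c_by = {x: 0 for x in strata}
            for sid in carrier_ids:
                x = stratum_of.get(sid)
                if x is None:
                    continue
                if is_case[sid]:
                    a_by[x] += 1
                else:
                    c_by[x] += 1
            disc = ContingencyTable.from_carriers(
                a_by[discovery_stratum], n_case[discovery_stratum],
                c_by[discovery_stratum], n_ctrl[discovery_stratum],
            )
            if disc.a == 0 and disc.c == 0:
                continue
            p_disc = fisher_two_sided(disc)
            if p_disc >= alpha or disc.case_rate <= disc.control_rate:
                continue
            repl_tables = {
                x: ContingencyTable.from_carriers(a_by[x], n_case[x], c_by[x], n_ctrl[x])
                for x in repl_strata
            }
            all_tables = [disc, *repl_tables.values()]
            p_repl = (
                fisher_one_sided(ContingencyTable.pool(repl_tables.values()))
                if repl_tables
                else None
            )
            p_comb = cmh_test(all_tables) if repl_tables else p_disc
            orr, ci = pooled_or_ci(all_tables)
            case_pct, ctrl_pct = carrier_percentages(all_tables)
            results.append(
                AssociationResult(
                    gene_id=g.gene_id,
                    copy_type=copy_type,
                    discovery_table=disc,
                    replication_tables=repl_tables,
                    p_discovery=p_disc,
                    p_replication=p_repl,
                    p_combined=p_comb,
                    pooled_or=orr,
                    or_ci95=ci,
                    case_pct=case_pct,
                    control_pct=ctrl_pct,
                )
            )
    results.sort(key=lambda r: (r.p_combined if r.p_combined is not None else 1.0, r.gene_id))
    return results


def collapse_regions(
    results: Sequence[AssociationResult],
    genes: Sequence[GeneModel],
    calls: Sequence[CNVCall],
) -> list[RegionResult]:
    """Group significant genes into regions connected by shared CNVs.

    Two genes (same CNV type) are linked when at least one call disrupts
    exons of both; connected components of that graph are regions.  Each
    region is reported through its member with the smallest combined p
    (ties: smallest discovery p, then gene id).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    out: list[RegionResult] = []
    for copy_type in (DELETION, DUPLICATION):
        sub = [r for r in results if r.copy_type == copy_type]
        if not sub:
            continue
        members = [gene_by_id[r.gene_id] for r in sub]
        trees = _exon_tree(members)
        graph = nx.Graph()
        graph.add_nodes_from(r.gene_id for r in sub)
        for call in calls:
            if call.copy_type != copy_type:
                continue
            hit = genes_hit_by_call(call, members, trees)
            hit_ids = [members[i].gene_id for i in hit]
            for u, v in zip(hit_ids, hit_ids[1:]):
                graph.add_edge(u, v)
        res_by_id = {r.gene_id: r for r in sub}

        def sort_key(gid: str):
            r = res_by_id[gid]
            pc = r.p_combined if r.p_combined is not None and not math.isnan(r.p_combined) else 1.0
            return (pc, r.p_discovery, gid)

        for comp in nx.connected_components(graph):
            best = min(comp, key=sort_key)
            g = gene_by_id[best]
            spans = [gene_by_id[m].interval for m in comp]
            label = (
                f"{g.interval.chrom}:"
                f"{min(s.start for s in spans)}-{max(s.end for s in spans)}"
                f":{copy_type}"
            )
            out.append(
                RegionResult(
                    label=label,
                    member_genes=sorted(comp),
                    best_gene=best,
                    representative=res_by_id[best],
                )
            )
    out.sort(key=lambda r: (r.representative.p_combined
                            if r.representative.p_combined is not None else 1.0, r.label))
    return out
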