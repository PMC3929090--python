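"""Readers and writers for the text formats the pipeline touches.

Supported dialects:

* PennCNV raw-call lines (read/write), 1-based inclusive coordinates;
* BED3/BED4 (read/write), converted between 0-based half-open (on disk) and
  the package's 1-based inclusive convention;
* PLINK ``.cnv`` / ``.fam`` companions (write/read) for burden analysis;
* a sample table TSV (``sample_id  phenotype  stratum`` plus optional QC
  metric columns);
* a log-R-ratio (LRR) matrix TSV for in-silico validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, merge_intervals, normalize_chrom

DELETION = "deletion"
DUPLICATION = "duplication"


class ParseError(ValueError):
    """A malformed record in an input file; carries the offending line number."""


def copy_type_of(copy_number: int) -> str:
    if copy_number < 0:
        raise ValueError(f"negative copy number {copy_number}")
    if copy_number == 2:
        raise ValueError("copy number 2 is copy-neutral, not a CNV")
    return DELETION if copy_number < 2 else DUPLICATION


@dataclass(frozen=True)
class CNVCall:
    """One called copy-number segment in one sample."""

    sample_id: str
    interval: GenomicInterval
    copy_number: int
    n_probes: int

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError(f"n_probes must be >= 1, got {self.n_probes}")
        copy_type_of(self.copy_number)  # validates

    @property
    def copy_type(self) -> str:
        return copy_type_of(self.copy_number)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneModel:
    """A gene: transcript span plus merged, sorted exons."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        merged = tuple(merge_intervals(self.exons))
        for ex in merged:
            if not self.interval.contains(ex):
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex} outside transcript span {self.interval}"
                )
        object.__setattr__(self, "exons", merged)


@dataclass(frozen=True)
class SampleQC:
    """Per-sample array-quality metrics used for outlier exclusion."""

    lrr_sd: float
    baf_drift: float
    wave_factor: float
    cnv_count: int

    METRICS = ("lrr_sd", "baf_drift", "wave_factor", "cnv_count")


@dataclass
class SampleRecord:
    sample_id: str
    phenotype: str  # "case" | "control"
    stratum: str
    qc_metrics: Optional[SampleQC] = None

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control"):
            raise ValueError(f"phenotype must be case/control, got {self.phenotype!r}")

    @property
    def is_case(self) -> bool:
        return self.phenotype == "case"


# ---------------------------------------------------------------------------
# PennCNV raw-call dialect
# ---------------------------------------------------------------------------

_PENNCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>[\d,]+)-(?P<end>[\d,]+)"
    r"\s+numsnp=(?P<numsnp>[\d,]+)"
    r"\s+length=(?P<length>[\d,]+)"
    r"\s+state(?P<state>\d+),cn=(?P<cn>\d+)"
    r"\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
)


def read_penncnv_calls(path: str | Path) -> list[CNVCall]:
    """Read a PennCNV raw-call file, one :class:`CNVCall` per line.

    Lines look like::

        chr16:21950000-22430000 numsnp=120 length=480,001 state2,cn=1 S1 startsnp=rs1 endsnp=rs2

    ``cn`` below 2 becomes a deletion, above 2 a duplication; ``cn=2`` is a
    rejected record (copy-neutral segments are not CNVs).
    """
    calls: list[CNVCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = _PENNCNV_RE.match(line)
            if m is None:
                raise ParseError(f"{path}:{lineno}: malformed PennCNV line: {line!r}")
            cn = int(m["cn"])
            if cn == 2:
                raise ParseError(
                    f"{path}:{lineno}: cn=2 record is copy-neutral and not a CNV"
                )
            interval = GenomicInterval(
                m["chrom"],
                int(m["start"].replace(",", "")),
                int(m["end"].replace(",", "")),
            )
            calls.append(
                CNVCall(
                    sample_id=m["sample"],
                    interval=interval,
                    copy_number=cn,
                    n_probes=int(m["numsnp"].replace(",", "")),
                )
            )
    return calls


def write_penncnv_calls(calls: Iterable[CNVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            state = {0: 1, 1: 2, 3: 5, 4: 6}.get(c.copy_number, 2 if c.copy_number < 2 else 5)
            fh.write(
                f"{c.interval} numsnp={c.n_probes} length={c.length} "
                f"state{state},cn={c.copy_number} {c.sample_id}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed_intervals(
    path: str | Path,
) -> list[tuple[GenomicInterval, Optional[str]]]:
    """Read BED3/BED4 rows as (interval, name-or-None) pairs.

    BED is 0-based half-open on disk; rows convert to 1-based inclusive:
    ``(start_bed + 1, end_bed)``.
    """
    out: list[tuple[GenomicInterval, Optional[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED row needs >= 3 columns")
            chrom, start_bed, end_bed = parts[0], int(parts[1]), int(parts[2])
            if end_bed <= start_bed:
                raise ParseError(
                    f"{path}:{lineno}: BED end ({end_bed}) <= start ({start_bed})"
                )
            name = parts[3] if len(parts) > 3 else None
            out.append((GenomicInterval(chrom, start_bed + 1, end_bed), name))
    return out


def write_bed_intervals(
    records: Iterable[tuple[GenomicInterval, Optional[str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            cols = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if name is not None:
                cols.append(name)
            fh.write("\t".join(cols) + "\n")


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read an exon-level BED4 (name = gene id) into gene models.

    All rows sharing a name become that gene's exons; the transcript span is
    their envelope.  Overlapping exon rows are merged (GeneModel invariant).
    """
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for iv, name in read_bed_intervals(path):
        if name is None:
            raise ParseError(f"{path}: gene BED rows need a name column")
        exons_by_gene.setdefault(name, []).append(iv)
    genes = []
    for gene_id, exons in exons_by_gene.items():
        chroms = {e.chrom for e in exons}
        if len(chroms) != 1:
            raise ParseError(f"gene {gene_id} has exons on multiple chromosomes")
        span = GenomicInterval(
            exons[0].chrom, min(e.start for e in exons), max(e.end for e in exons)
        )
        genes.append(GeneModel(gene_id, span, tuple(exons)))
    return genes


# ---------------------------------------------------------------------------
# PLINK .cnv / .fam
# ---------------------------------------------------------------------------

def write_plink_cnv(
    calls: Sequence[CNVCall],
    samples: Sequence[SampleRecord],
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write PLINK ``.cnv`` (FID IID CHR BP1 BP2 TYPE SCORE SITES) and ``.fam``.

    TYPE is the integer copy number (0/1 deletions, 3+ duplications), the
    PLINK CNV coding.  Every call's sample must appear in ``samples``.
    """
    known = {s.sample_id for s in samples}
    for c in calls:
        if c.sample_id not in known:
            raise ValueError(f"call sample {c.sample_id!r} missing from sample table")
    prefix = Path(prefix)
    cnv_path = prefix.with_suffix(".cnv")
    fam_path = prefix.with_suffix(".fam")
    with open(cnv_path, "w") as fh:
        fh.write("FID\tIID\tCHR\tBP1\tBP2\tTYPE\tSCORE\tSITES\n")
        for c in calls:
            chrom = c.interval.chrom.removeprefix("chr")
            fh.write(
                f"{c.sample_id}\t{c.sample_id}\t{chrom}\t{c.interval.start}\t"
                f"{c.interval.end}\t{c.copy_number}\t0\t{c.n_probes}\n"
            )
    with open(fam_path, "w") as fh:
        for s in samples:
            phe = 2 if s.is_case else 1
            fh.write(f"{s.sample_id}\t{s.sample_id}\t0\t0\t0\t{phe}\n")
    return cnv_path, fam_path


def read_plink_cnv(cnv_path: str | Path) -> list[CNVCall]:
    df = pd.read_csv(cnv_path, sep="\t")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            CNVCall(
                sample_id=str(row.IID),
                interval=GenomicInterval(str(row.CHR), int(row.BP1), int(row.BP2)),
                copy_number=int(row.TYPE),
                n_probes=int(row.SITES),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

_QC_COLS = ["lrr_sd", "baf_drift", "wave_factor", "cnv_count"]


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read a TSV with columns ``sample_id phenotype stratum`` (+ QC metrics)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "phenotype", "stratum"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: sample table needs columns {sorted(required)}")
    has_qc = all(c in df.columns for c in _QC_COLS)
    records = []
    for row in df.itertuples(index=False):
        qc = None
        if has_qc:
            qc = SampleQC(
                lrr_sd=float(row.lrr_sd),
                baf_drift=float(row.baf_drift),
                wave_factor=float(row.wave_factor),
                cnv_count=int(row.cnv_count),
            )
        records.append(
            SampleRecord(str(row.sample_id), str(row.phenotype), str(row.stratum), qc)
        )
    return records


def write_sample_table(samples: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    with_qc = any(s.qc_metrics is not None for s in samples)
    for s in samples:
        row = {"sample_id": s.sample_id, "phenotype": s.phenotype, "stratum": s.stratum}
        if with_qc:
            if s.qc_metrics is None:
                raise ValueError(f"sample {s.sample_id} missing QC metrics")
            row.update(
                lrr_sd=s.qc_metrics.lrr_sd,
                baf_drift=s.qc_metrics.baf_drift,
                wave_factor=s.qc_metrics.wave_factor,
                cnv_count=s.qc_metrics.cnv_count,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
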