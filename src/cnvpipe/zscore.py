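"""In-silico CNV validation by the median Z-score outlier method.

Array log-R ratios (LRR) measure total signal intensity per probe: depressed
in deletions, elevated in duplications.  To confirm a called CNV without
re-running segmentation, each probe's LRR is standardized across all samples
and the carrier's *median* Z over the probes inside the call is compared
with an outlier threshold: a real heterozygous deletion pulls the carrier
several population SDs below zero at every in-call probe, so its median Z is
strongly negative; a spurious call hovers near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import DELETION, DUPLICATION, CNVCall


@dataclass
class LRRMatrix:
    """Per-chromosome probe positions plus a probes x samples value matrix.

    ``positions[chrom]`` is a sorted 1-D array of probe coordinates and
    ``values[chrom]`` the matching (n_probes, n_samples) LRR block; columns
    align with ``sample_ids``.
    """

    positions: Mapping[str, np.ndarray]
    values: Mapping[str, np.ndarray]
    sample_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self._col = {sid: i for i, sid in enumerate(self.sample_ids)}
        for chrom, pos in self.positions.items():
            vals = self.values[chrom]
            if vals.shape != (len(pos), len(self.sample_ids)):
                raise ValueError(
                    f"{chrom}: values shape {vals.shape} != "
                    f"({len(pos)}, {len(self.sample_ids)})"
                )
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"{chrom}: probe positions not sorted")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> int:
        try:
            return self._col[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in LRR matrix") from None

    def probes_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of probes within [start, end] on ``chrom`` (may be empty)."""
        pos = self.positions.get(chrom)
        if pos is None:
            return np.array([], dtype=int)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return np.arange(lo, hi)


@dataclass(frozen=True)
class ZScoreResult:
    call: CNVCall
    median_z: Optional[float]
    n_probes_used: int
    validated: Optional[bool]  # None = untestable (too few in-call probes)

    @property
    def status(self) -> str:
        if self.validated is None:
            return "untestable"
        return "validated" if self.validated else "not_validated"


def probe_zscores(lrr: LRRMatrix) -> LRRMatrix:
    """Standardize every probe row to mean 0, SD 1 across samples.

    Sample SD (ddof=1).  Constant rows have no scale and become all-zero
    (with a warning); they carry no copy-number information.  Fewer than 2
    samples is an error; fewer than 10 draws a stability warning.
    """
    n = lrr.n_samples
    if n < 2:
        raise ValueError("probe standardization needs >= 2 samples")
    if n < 10:
        warnings.warn(f"only {n} samples: per-probe SD estimates are unstable")
    z_values = {}
    n_constant = 0
    for chrom, vals in lrr.values.items():
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=1, keepdims=True)
        const = (sd == 0).ravel()
        n_constant += int(const.sum())
        safe_sd = np.where(sd == 0, 1.0, sd)
        z = (vals - mu) / safe_sd
        z[const, :] = 0.0
        z_values[chrom] = z
    if n_constant:
        warnings.warn(f"{n_constant} constant probe rows standardized to zero")
    return LRRMatrix(positions=dict(lrr.positions), values=z_values, sample_ids=lrr.sample_ids)


def validate_call(
    call: CNVCall,
    z: LRRMatrix,
    min_probes: int = 3,
    z_del: float = 2.0,
    z_dup: float = 2.0,
) -> ZScoreResult:
    """Score one call against a standardized LRR matrix.

    ``median_z`` is the median of the carrier sample's Z-scores over probes
    inside the call (even count: mean of the two central values, numpy's
    convention).  The call validates when ``median_z <= -z_del`` for a
    deletion or ``median_z >= +z_dup`` for a duplication.  With fewer than
    ``min_probes`` in-call probes the call is *untestable*, not failed.
    """
    idx = z.probes_in(call.interval.chrom, call.interval.start, call.interval.end)
    if len(idx) < min_probes:
        return ZScoreResult(call, None, len(idx), None)
    col = z.column(call.sample_id)
    med = float(np.median(z.values[call.interval.chrom][idx, col]))
    if call.copy_type == DELETION:
        ok = med <= -z_del
    else:
        ok = med >= z_dup
    return ZScoreResult(call, med, len(idx), ok)


def _loo_zscores_for_column(vals: np.ndarray, col: int) -> np.ndarray:
    """Column ``col``'s Z-scores with itself left out of each probe's mean/SD."""
    n = vals.shape[1]
    if n < 3:
        raise ValueError("leave-one-out standardization needs >= 3 samples")
    x = vals[:, col]
    s1 = vals.sum(axis=1)
    s2 = (vals**2).sum(axis=1)
    mu = (s1 - x) / (n - 1)
    var = (s2 - x**2 - (n - 1) * mu**2) / (n - 2)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zcol = np.where(sd > 0, (x - mu) / sd, 0.0)
    return zcol


def validate_calls(
    calls: Sequence[CNVCall],
    lrr: LRRMatrix,
    min_probes: int = 3,
    z_del: float = 2.0,
    z_dup: float = 2.0,
    leave_one_out: bool = False,
) -> list[ZScoreResult]:
    """Validate many calls against a *raw* LRR matrix.

    Standardizes once (or per-carrier with the carrier left out of the
    reference mean/SD when ``leave_one_out`` is set — removes the carrier's
    own pull on the reference, which matters only for small cohorts).
    """
    if not leave_one_out:
        z = probe_zscores(lrr)
        return [validate_call(c, z, min_probes, z_del, z_dup) for c in calls]

    results = []
    for call in calls:
        chrom = call.interval.chrom
        idx = lrr.probes_in(chrom, call.interval.start, call.interval.end)
        if len(idx) < min_probes:
            results.append(ZScoreResult(call, None, len(idx), None))
            continue
        col = lrr.column(call.sample_id)
        zcol = _loo_zscores_for_column(lrr.values[chrom][idx, :], col)
        med = float(np.median(zcol))
        ok = med <= -z_del if call.copy_type == DELETION else med >= z_dup
        results.append(ZScoreResult(call, med, len(idx), ok))
    return results
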