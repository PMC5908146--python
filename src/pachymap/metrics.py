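"""Chromosome-level quantities: arm lengths and ratios, Levan centromere
classes, chromatin compaction (Mb/μm), marker placement arithmetic, the
chromomere census, and region-wise condensation dynamics.

Compaction is defined as the estimated DNA content of a region (Mb) divided
by its physical length (μm). Arm ratio is long/short using the *designated*
arms, so a ratio below 1 is possible (a designated short arm can be
physically longer); Levan classes are assigned from the ratio, taking the
reciprocal when it is below 1. All values are kept at full precision
internally and rounded half-up to two decimals only for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np

from .io import ChromosomeRecord
from .profiles import ChromomereSegment
from .simulate import StageSeries

log = logging.getLogger("pachymap")

#: Levan (1964) arm-ratio boundaries: m ≤ 1.7 < sm ≤ 3.0 < st ≤ 7.0 < t
LEVAN_BOUNDS = (1.7, 3.0, 7.0)


class MetricsError(ValueError):
    pass


def round_report(x: float, ndigits: int = 2) -> float:
    """Half-up rounding used only at report time."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ArmMetrics:
    short_um: float
    long_um: float
    total_um: float
    arm_ratio: float
    levan_class: str
    compaction_total: Optional[float] = None
    compaction_short: Optional[float] = None
    compaction_long: Optional[float] = None


@dataclass
class RegionDynamics:
    region_labels: list[str]
    stage_lengths_um: np.ndarray  # (n_stages, n_regions)
    percent_reduction: np.ndarray  # per region


@dataclass
class ChromosomeSummary:
    chrom_id: Optional[int]
    metrics: ArmMetrics
    n_chromomeres: int
    n_short: int
    n_long: int
    n_condensed: int


# --------------------------------------------------------------------------
# arms and classification


def arm_lengths(
    total_um: float,
    centromere_um: float,
    designation: Optional[str] = None,
) -> tuple[float, float]:
    """Split at the centromere; (short, long) by length, unless a linkage-map
    ``designation`` ("first"/"last" part is short) overrides it."""
    if not 0 < centromere_um < total_um:
        raise MetricsError("centromere outside chromosome")
    first, last = centromere_um, total_um - centromere_um
    if designation == "first_short":
        return first, last
    if designation == "last_short":
        return last, first
    if designation is not None:
        raise MetricsError(f"unknown designation {designation!r}")
    return (first, last) if first <= last else (last, first)


def arm_ratio(short_um: float, long_um: float) -> float:
    """Long/short of the designated arms (may be < 1 for chromosomes whose
    designated short arm is physically longer)."""
    if short_um <= 0:
        raise MetricsError("short arm length must be positive")
    return long_um / short_um


def levan_class(ratio: float) -> str:
    """Levan centromere class from the arm ratio (reciprocal if ratio < 1)."""
    if ratio <= 0:
        raise MetricsError("arm ratio must be positive")
    r = ratio if ratio >= 1 else 1.0 / ratio
    m, sm, st = LEVAN_BOUNDS
    if r <= m:
        return "m"
    if r <= sm:
        return "sm"
    if r <= st:
        return "st"
    return "t"


def compaction(nt_mb: float, length_um: float) -> float:
    """DNA content divided by physical length (Mb/μm)."""
    if length_um <= 0:
        raise MetricsError("length must be positive")
    return nt_mb / length_um


# --------------------------------------------------------------------------
# marker placement


def marker_um(percent_pos: float, total_um: float) -> float:
    """Percent-of-length (from the short-arm terminus) to μm."""
    return percent_pos / 100.0 * total_um


def marker_percent(um_pos: float, total_um: float) -> float:
    if total_um <= 0:
        raise MetricsError("total length must be positive")
    return um_pos / total_um * 100.0


@dataclass
class PlacementCheck:
    name: str
    chrom_arm: str
    computed_um: float
    printed_um: float
    deviation_um: float
    consistent: bool


def check_marker_placements(
    markers, chromosomes: Sequence[ChromosomeRecord], tol_um: float = 0.02,
) -> list[PlacementCheck]:
    """Recompute each marker's μm position from its percent position and the
    chromosome length; rows deviating beyond ``tol_um`` are flagged (not
    forced) as internally inconsistent."""
    totals = {r.chrom_id: r.total_len_um.mean for r in chromosomes}
    out = []
    for m in markers:
        if m.chrom_id is None or m.percent_pos is None or m.um_pos is None:
            continue
        um = marker_um(m.percent_pos.mean, totals[m.chrom_id])
        dev = um - m.um_pos
        out.append(PlacementCheck(
            name=m.name,
            chrom_arm=f"{m.chrom_id}{m.arm}",
            computed_um=um,
            printed_um=m.um_pos,
            deviation_um=dev,
            consistent=abs(dev) <= tol_um,
        ))
    return out


@dataclass
class CompactionCheck:
    chrom_id: int
    cell: str  # total | short | long
    computed: float
    printed: float
    deviation: float
    consistent: bool


def check_table_closure(
    chromosomes: Sequence[ChromosomeRecord], tol: float = 0.005,
) -> list[CompactionCheck]:
    """Recompute all 36 compaction cells from the tabulated means; cells that
    cannot be reproduced within ``tol`` from the rounded inputs are flagged."""
    out = []
    for r in chromosomes:
        cells = {
            "total": (r.nt_total_mb, r.total_len_um.mean, r.compaction_total),
            "short": (r.nt_short_mb, r.short_len_um.mean, r.compaction_short),
            "long": (r.nt_long_mb, r.long_len_um.mean, r.compaction_long),
        }
        for cell, (nt, um, printed) in cells.items():
            c = compaction(nt, um)
            out.append(CompactionCheck(
                chrom_id=r.chrom_id, cell=cell, computed=c, printed=printed,
                deviation=c - printed, consistent=abs(c - printed) <= tol,
            ))
    return out


# --------------------------------------------------------------------------
# condensation dynamics


def condensation_dynamics(series: StageSeries) -> RegionDynamics:
    """Per-region percent length reduction from the stage where the region is
    longest to the stage where it is shortest."""
    lm = series.landmarks
    lengths = np.diff(np.concatenate([np.zeros((lm.shape[0], 1)), lm], axis=1),
                      axis=1)
    longest = lengths.max(axis=0)
    shortest = lengths.min(axis=0)
    reduction = (longest - shortest) / longest * 100.0
    return RegionDynamics(
        region_labels=list(series.region_labels),
        stage_lengths_um=lengths,
        percent_reduction=reduction,
    )


# --------------------------------------------------------------------------
# per-chromosome summary


def summarize_chromosome(
    segments: Sequence[ChromomereSegment],
    centromere_um: float,
    record: Optional[ChromosomeRecord] = None,
    total_um: Optional[float] = None,
    designation: Optional[str] = None,
) -> ChromosomeSummary:
    """Bundle the chromomere census with whole-chromosome metrics.

    The census equals the segment count (the centromeric merge rule is
    already encoded in the segments); the centromeric chromomere counts with
    the long arm (index +1).
    """
    if record is not None and total_um is None:
        total_um = record.total_len_um.mean
    if total_um is None:
        raise MetricsError("need a chromosome record or a total length")
    short, long_ = arm_lengths(total_um, centromere_um, designation)
    ratio = arm_ratio(short, long_)
    metrics = ArmMetrics(
        short_um=short, long_um=long_, total_um=total_um,
        arm_ratio=ratio, levan_class=levan_class(ratio),
    )
    if record is not None:
        metrics.compaction_total = compaction(record.nt_total_mb, total_um)
        metrics.compaction_short = compaction(record.nt_short_mb, short)
        metrics.compaction_long = compaction(record.nt_long_mb, long_)
    n_short = sum(1 for s in segments if (s.index or 0) < 0)
    n_long = sum(1 for s in segments if (s.index or 0) > 0)
    return ChromosomeSummary(
        chrom_id=record.chrom_id if record is not None else None,
        metrics=metrics,
        n_chromomeres=len(segments),
        n_short=n_short,
        n_long=n_long,
        n_condensed=sum(1 for s in segments if s.condensed),
    )
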