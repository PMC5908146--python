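"""Readers and writers for the package's table and image formats.

Tables are UTF-8 TSV with a header row; cells printed as ``mean±sd`` in the
source tables are kept as a single cell and split on ``±`` at parse time.
Absent numeric cells are empty strings on disk and ``None`` in memory, never 0.
Multi-channel images are plain TIFF with a JSON description carrying the
μm/pixel calibration and channel labels.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

log = logging.getLogger("pachymap")


class ParseError(ValueError):
    """A table cell could not be parsed; message names row and column."""


class ValidationError(ValueError):
    """Parsed records violate a structural invariant."""


class FormatError(ValueError):
    """A file is not in the expected on-disk format."""


# --------------------------------------------------------------------------
# value types


@dataclass(frozen=True)
class MeanSD:
    """A mean with its standard deviation, as printed ``mean±sd``."""

    mean: float
    sd: Optional[float] = None

    def __format__(self, spec: str) -> str:
        if self.sd is None:
            return format(self.mean, spec)
        return f"{format(self.mean, spec)}±{format(self.sd, spec)}"


@dataclass(frozen=True)
class ChromosomeRecord:
    """One row of the pachytene karyotype table (dimensions in μm, DNA in Mb)."""

    chrom_id: int
    total_len_um: MeanSD
    short_len_um: MeanSD
    long_len_um: MeanSD
    arm_ratio: MeanSD
    n_chromomeres: int
    nt_total_mb: float
    nt_short_mb: float
    nt_long_mb: float
    nt_arm_ratio: float
    compaction_total: float
    compaction_short: float
    compaction_long: float
    pachytene_rank: int
    somatic_rank: int


@dataclass(frozen=True)
class MarkerRecord:
    """A FISH landmark with its genetic, physical and cytological positions.

    ``percent_pos`` and ``um_pos`` are measured from the short-arm terminus.
    ``approx`` records a ``~`` prefix on the printed percent position.
    The pericentromeric clone has no arm assignment (``chrom_id``/``arm`` None).
    """

    name: str
    chrom_id: Optional[int]
    arm: Optional[str]  # "S" | "L"
    markers: str = ""
    genetic_cm: Optional[float] = None
    physical_mb: Optional[float] = None
    percent_pos: Optional[MeanSD] = None
    um_pos: Optional[float] = None
    approx: bool = False


@dataclass
class MultiChannelImage:
    """Pixel data indexed ``[channel, row, col]`` with μm/pixel calibration."""

    pixels: np.ndarray
    um_per_px: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValidationError("image must be [channel, row, col]")
        if self.um_per_px <= 0:
            raise ValidationError("um_per_px must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.pixels.shape[0])]
        if len(self.channel_labels) != self.pixels.shape[0]:
            raise ValidationError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return int(self.pixels.shape[0])

    def channel(self, index_or_label) -> np.ndarray:
        if isinstance(index_or_label, str):
            index_or_label = self.channel_labels.index(index_or_label)
        return self.pixels[index_or_label]


# --------------------------------------------------------------------------
# TSV parsing helpers

_PM_RE = re.compile(r"^(~?)\s*([-+0-9.eE]+)\s*(?:±\s*([-+0-9.eE]+))?$")


def parse_pm_cell(cell: str, *, row: str = "?", column: str = "?"):
    """Parse a ``mean±sd`` cell; returns (MeanSD, approx_flag)."""
    m = _PM_RE.match(cell.strip())
    if not m:
        raise ParseError(f"malformed ±-cell {cell!r} at row {row}, column {column}")
    approx = m.group(1) == "~"
    try:
        mean = float(m.group(2))
        sd = float(m.group(3)) if m.group(3) is not None else None
    except ValueError as exc:
        raise ParseError(
            f"malformed ±-cell {cell!r} at row {row}, column {column}"
        ) from exc
    return MeanSD(mean, sd), approx


def _opt_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    return float(cell) if cell else None


def _read_tsv(path) -> tuple[list[str], list[list[str]]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise ParseError(f"{path}: empty file, no records")
    header = lines[0].split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    if not rows:
        raise ParseError(f"{path}: no records")
    return header, rows


# --------------------------------------------------------------------------
# chromosome table (karyotype dimensions)

_T2_COLUMNS = [
    "chrom_id", "total_len_um", "short_len_um", "long_len_um", "arm_ratio",
    "n_chromomeres", "nt_total_mb", "nt_short_mb", "nt_long_mb",
    "nt_arm_ratio", "compaction_total", "compaction_short", "compaction_long",
    "pachytene_rank", "somatic_rank",
]


def read_chromosome_table(path) -> list[ChromosomeRecord]:
    """Read the pachytene karyotype table; enforces per-row consistency."""
    header, rows = _read_tsv(path)
    if header != _T2_COLUMNS:
        raise ParseError(f"{path}: unexpected header {header}")
    records: list[ChromosomeRecord] = []
    for cells in rows:
        if len(cells) != len(header):
            raise ParseError(f"{path}: row {cells[:1]} has {len(cells)} cells")
        row_id = cells[0]
        pm = {
            name: parse_pm_cell(cells[i], row=row_id, column=name)[0]
            for i, name in ((1, "total_len_um"), (2, "short_len_um"),
                            (3, "long_len_um"), (4, "arm_ratio"))
        }
        rec = ChromosomeRecord(
            chrom_id=int(cells[0]),
            total_len_um=pm["total_len_um"],
            short_len_um=pm["short_len_um"],
            long_len_um=pm["long_len_um"],
            arm_ratio=pm["arm_ratio"],
            n_chromomeres=int(cells[5]),
            nt_total_mb=float(cells[6]),
            nt_short_mb=float(cells[7]),
            nt_long_mb=float(cells[8]),
            nt_arm_ratio=float(cells[9]),
            compaction_total=float(cells[10]),
            compaction_short=float(cells[11]),
            compaction_long=float(cells[12]),
            pachytene_rank=int(cells[13]),
            somatic_rank=int(cells[14]),
        )
        records.append(rec)
    ids = [r.chrom_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate chrom_id in chromosome table")
    for r in records:
        _validate_chromosome_record(r)
    log.info("read_chromosome_table: %d records from %s", len(records), path)
    return records


def _validate_chromosome_record(r: ChromosomeRecord) -> None:
    if not 1 <= r.chrom_id <= 12:
        raise ValidationError(f"chrom_id {r.chrom_id} outside 1-12")
    sd = r.total_len_um.sd or 0.0
    gap = abs(r.short_len_um.mean + r.long_len_um.mean - r.total_len_um.mean)
    if gap > 2 * max(sd, 0.01):
        raise ValidationError(
            f"chrom {r.chrom_id}: arm sum deviates from total by {gap:.3f} μm"
        )
    if r.nt_short_mb + r.nt_long_mb > r.nt_total_mb + 0.05:
        raise ValidationError(f"chrom {r.chrom_id}: nucleotide arm sum exceeds total")


def write_chromosome_table(records: Sequence[ChromosomeRecord], path) -> None:
    """Serialize in the canonical dialect (round-trips byte-identically)."""
    lines = ["\t".join(_T2_COLUMNS)]
    for r in records:
        lines.append("\t".join([
            str(r.chrom_id),
            f"{r.total_len_um:.2f}", f"{r.short_len_um:.2f}",
            f"{r.long_len_um:.2f}", f"{r.arm_ratio:.2f}",
            str(r.n_chromomeres),
            f"{r.nt_total_mb:.2f}", f"{r.nt_short_mb:.2f}", f"{r.nt_long_mb:.2f}",
            f"{r.nt_arm_ratio:.2f}",
            f"{r.compaction_total:.2f}", f"{r.compaction_short:.2f}",
            f"{r.compaction_long:.2f}",
            str(r.pachytene_rank), str(r.somatic_rank),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# marker table (FISH landmarks)

_T1_COLUMNS = [
    "chrom_arm", "name", "markers", "genetic_cm", "physical_mb",
    "percent_pos", "um_pos",
]
_ARM_RE = re.compile(r"^(\d+)([SL])$")
PERICENTROMERE = "pericent"


def read_marker_table(path) -> list[MarkerRecord]:
    """Read the FISH landmark table (12 arm markers + pericentromeric clone)."""
    header, rows = _read_tsv(path)
    if header != _T1_COLUMNS:
        raise ParseError(f"{path}: unexpected header {header}")
    records: list[MarkerRecord] = []
    for cells in rows:
        if len(cells) != len(header):
            raise ParseError(f"{path}: row {cells[:1]} has {len(cells)} cells")
        chrom_arm = cells[0].strip()
        if chrom_arm == PERICENTROMERE:
            chrom_id, arm = None, None
        else:
            m = _ARM_RE.match(chrom_arm)
            if not m:
                raise ValidationError(f"unknown arm code {chrom_arm!r}")
            chrom_id, arm = int(m.group(1)), m.group(2)
        pct_cell = cells[5].strip()
        if pct_cell:
            percent, approx = parse_pm_cell(pct_cell, row=chrom_arm,
                                            column="percent_pos")
            if not 0.0 <= percent.mean <= 100.0:
                raise ValidationError(
                    f"{chrom_arm}: percent position {percent.mean} outside [0, 100]"
                )
        else:
            percent, approx = None, False
        records.append(MarkerRecord(
            name=cells[1].strip(),
            chrom_id=chrom_id,
            arm=arm,
            markers=cells[2].strip(),
            genetic_cm=_opt_float(cells[3]),
            physical_mb=_opt_float(cells[4]),
            percent_pos=percent,
            um_pos=_opt_float(cells[6]),
            approx=approx,
        ))
    log.info("read_marker_table: %d records from %s", len(records), path)
    return records


def write_marker_table(records: Sequence[MarkerRecord], path) -> None:
    lines = ["\t".join(_T1_COLUMNS)]
    for r in records:
        if r.chrom_id is None:
            chrom_arm = PERICENTROMERE
        else:
            chrom_arm = f"{r.chrom_id}{r.arm}"
        pct = ""
        if r.percent_pos is not None:
            pct = ("~" if r.approx else "") + f"{r.percent_pos:.2f}"
        lines.append("\t".join([
            chrom_arm, r.name, r.markers,
            "" if r.genetic_cm is None else f"{r.genetic_cm:.1f}",
            "" if r.physical_mb is None else f"{r.physical_mb:.1f}",
            pct,
            "" if r.um_pos is None else f"{r.um_pos:.2f}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("pachymap.data") / name)


def load_chromosome_records() -> list[ChromosomeRecord]:
    """The packaged 12-chromosome karyotype fixture."""
    return read_chromosome_table(_data_path("table2.tsv"))


def load_marker_records() -> list[MarkerRecord]:
    """The packaged 13-row FISH landmark fixture."""
    return read_marker_table(_data_path("table1.tsv"))


def packaged_fixture_path(name: str) -> Path:
    """Path of a packaged data file (tables, synthetic arm columns, schema)."""
    return _data_path(name)


# --------------------------------------------------------------------------
# TIFF images


def write_image(img: MultiChannelImage, path) -> None:
    """Write a multi-channel TIFF; calibration goes in the JSON description."""
    meta = {"um_per_px": img.um_per_px, "channel_labels": img.channel_labels}
    kwargs = {"planarconfig": "separate"} if img.n_channels > 1 else {}
    tifffile.imwrite(path, img.pixels, description=json.dumps(meta),
                     photometric="minisblack", **kwargs)


def read_image(path) -> MultiChannelImage:
    """Read a TIFF written by :func:`write_image` (bit-exact round trip)."""
    try:
        with tifffile.TiffFile(path) as tif:
            pixels = tif.asarray()
            desc = tif.pages[0].description or "{}"
    except (tifffile.TiffFileError, FileNotFoundError, OSError, ValueError,
            IndexError, KeyError) as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return MultiChannelImage(
        pixels=pixels,
        um_per_px=float(meta.get("um_per_px", 1.0)),
        channel_labels=list(meta.get("channel_labels", [])),
    )


def configure_logging(level: int = logging.INFO) -> None:
    """Route pipeline logs to standard error with a stage-friendly format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
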