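"""Unification of the four rice chromosome maps on a relative-length scale
and arm-wise regression against nucleotide length.

Each map is a per-arm column (24 arms keyed by chromosome and arm). Arms are
compared to nucleotide length by ordinary least squares; the intercept is
tested against zero with a two-sided t-test and, when the null is not
rejected, the line is refit through the origin (one fewer degree of
freedom). 95% confidence and prediction bands come from the adopted model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .io import ChromosomeRecord, packaged_fixture_path

log = logging.getLogger("pachymap")

ArmKey = tuple[int, str]

MAP_KINDS = ("nucleotide_mb", "linkage_cm", "pachytene_um", "somatic_um",
             "repeat_count", "gene_count")


class IntegrationError(ValueError):
    pass


@dataclass
class MapColumn:
    """One map's per-arm values. ``excluded`` marks arms to drop from fits
    (e.g. a NOR-bearing arm whose tabulated length covers a different extent
    than its nucleotide count)."""

    kind: str
    values: dict[ArmKey, float]
    units: str = ""
    excluded: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise IntegrationError(f"unknown map kind {self.kind!r}")
        for k, v in self.values.items():
            if v < 0:
                raise IntegrationError(f"negative value for arm {k}")

    def arms(self) -> list[ArmKey]:
        return sorted(self.values)


@dataclass
class RegressionFit:
    """OLS fit of a map column against nucleotide length.

    ``through_origin`` is True when the zero-intercept null was not rejected
    and the adopted model has no intercept term. Confidence and prediction
    bands are evaluated on demand from the stored model.
    """

    slope: float
    slope_se: float
    intercept: Optional[float]
    intercept_se: Optional[float]
    intercept_p: float
    r_squared: float
    n: int
    alpha: float
    through_origin: bool
    _results: object = field(repr=False, default=None)

    def bands(self, x: np.ndarray):
        """(fit, ci_lo, ci_hi, pi_lo, pi_hi) at the given x values."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        X = x[:, None] if self.through_origin else sm.add_constant(x, has_constant="add")
        pred = self._results.get_prediction(X)
        frame = pred.summary_frame(alpha=self.alpha)
        return (frame["mean"].to_numpy(),
                frame["mean_ci_lower"].to_numpy(), frame["mean_ci_upper"].to_numpy(),
                frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy())

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.through_origin:
            return self.slope * x
        return self.intercept + self.slope * x


# --------------------------------------------------------------------------
# relative lengths (map unification scale)


def relative_lengths(column: MapColumn) -> dict[int, tuple[float, float]]:
    """Per-chromosome (short%, long%) of that chromosome's own total."""
    out: dict[int, tuple[float, float]] = {}
    chroms = sorted({c for c, _ in column.values})
    for c in chroms:
        short = column.values.get((c, "S"))
        long_ = column.values.get((c, "L"))
        if short is None or long_ is None:
            raise IntegrationError(f"chromosome {c}: missing arm value")
        total = short + long_
        if total <= 0:
            raise IntegrationError(f"chromosome {c}: zero total")
        out[c] = (short / total * 100.0, long_ / total * 100.0)
    return out


# --------------------------------------------------------------------------
# regression


def fit_arm_regression(
    x: MapColumn, y: MapColumn, alpha: float = 0.05,
) -> RegressionFit:
    """OLS of y on x over the arms present (and not excluded) in both.

    Fits with an intercept, t-tests the intercept against zero at ``alpha``,
    and refits through the origin when the null is not rejected.
    """
    arms = [a for a in x.arms()
            if a in y.values and a not in x.excluded and a not in y.excluded]
    if len(arms) < 3:
        raise IntegrationError("need at least 3 paired arms")
    xv = np.array([x.values[a] for a in arms])
    yv = np.array([y.values[a] for a in arms])
    if np.allclose(xv.std(), 0):
        raise IntegrationError("zero variance in x")
    full = sm.OLS(yv, sm.add_constant(xv)).fit()
    intercept_p = float(full.pvalues[0])
    if intercept_p < alpha:
        fit = RegressionFit(
            slope=float(full.params[1]), slope_se=float(full.bse[1]),
            intercept=float(full.params[0]), intercept_se=float(full.bse[0]),
            intercept_p=intercept_p, r_squared=float(full.rsquared),
            n=len(arms), alpha=alpha, through_origin=False, _results=full,
        )
    else:
        origin = sm.OLS(yv, xv[:, None]).fit()
        fit = RegressionFit(
            slope=float(origin.params[0]), slope_se=float(origin.bse[0]),
            intercept=None, intercept_se=None,
            intercept_p=intercept_p, r_squared=float(origin.rsquared),
            n=len(arms), alpha=alpha, through_origin=True, _results=origin,
        )
    log.info("fit_arm_regression: %s~%s n=%d intercept_p=%.4f origin=%s "
             "slope=%.4f", y.kind, x.kind, len(arms), intercept_p,
             fit.through_origin, fit.slope)
    return fit


def within_pi(fit: RegressionFit, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """True per point iff y lies inside the 95% prediction band at its x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    _, _, _, lo, hi = fit.bands(x)
    return (y >= lo) & (y <= hi)


def compaction_range(
    length_col: MapColumn, nt_col: MapColumn,
) -> tuple[float, float, ArmKey, ArmKey]:
    """Per-arm length/DNA quotients (μm/Mb): (min, max, argmin arm, argmax arm)."""
    arms = [a for a in length_col.arms() if a in nt_col.values]
    ratios = {a: length_col.values[a] / nt_col.values[a] for a in arms
              if nt_col.values[a] > 0}
    lo = min(ratios, key=ratios.get)
    hi = max(ratios, key=ratios.get)
    return ratios[lo], ratios[hi], lo, hi


# --------------------------------------------------------------------------
# packaged columns


def nucleotide_column(records: Sequence[ChromosomeRecord]) -> MapColumn:
    vals = {}
    for r in records:
        vals[(r.chrom_id, "S")] = r.nt_short_mb
        vals[(r.chrom_id, "L")] = r.nt_long_mb
    return MapColumn("nucleotide_mb", vals, units="Mb")


def pachytene_column(records: Sequence[ChromosomeRecord]) -> MapColumn:
    vals = {}
    for r in records:
        vals[(r.chrom_id, "S")] = r.short_len_um.mean
        vals[(r.chrom_id, "L")] = r.long_len_um.mean
    return MapColumn("pachytene_um", vals, units="μm")


def load_synthetic_columns() -> dict[str, MapColumn]:
    """The clearly-labelled synthetic stand-in columns (linkage, somatic,
    repeat counts, gene counts); see the fixture header for provenance."""
    path = Path(packaged_fixture_path("arms_synthetic.tsv"))
    rows = [ln.split("\t") for ln in path.read_text(encoding="utf-8").splitlines()
            if ln and not ln.startswith("#")]
    header, data = rows[0], rows[1:]
    cols = {name: {} for name in header[1:]}
    for cells in data:
        chrom_arm = cells[0]
        key = (int(chrom_arm[:-1]), chrom_arm[-1])
        for name, cell in zip(header[1:], cells[1:]):
            cols[name][key] = float(cell)
    return {
        "linkage_cm": MapColumn("linkage_cm", cols["linkage_cm"], units="cM"),
        "somatic_um": MapColumn("somatic_um", cols["somatic_um"], units="μm"),
        "repeat_count": MapColumn("repeat_count", cols["repeat_count"], units="count"),
        "gene_count": MapColumn("gene_count", cols["gene_count"], units="count"),
    }


# --------------------------------------------------------------------------
# rendering


def render_maps(
    columns: dict[str, MapColumn],
    markers=None,
    centromeres: Optional[dict[int, float]] = None,
    out_path=None,
):
    """Side-by-side bar rendering of the map columns, scaled so the length
    ratios among chromosomes follow the pachytene column; centromere gaps
    and marker ticks included. Deterministic SVG for fixed input."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    required = ("nucleotide_mb", "pachytene_um")
    for kind in required:
        if kind not in columns:
            raise IntegrationError(f"missing column {kind!r}")
    plt.rcParams["svg.hashsalt"] = "pachymap"
    order = [k for k in ("nucleotide_mb", "linkage_cm", "pachytene_um",
                         "somatic_um") if k in columns]
    pachy = columns["pachytene_um"]
    chroms = sorted({c for c, _ in pachy.values})
    totals = {c: pachy.values[(c, "S")] + pachy.values[(c, "L")] for c in chroms}

    fig, ax = plt.subplots(figsize=(12, 5))
    width = 0.16
    for ci, c in enumerate(chroms):
        target = totals[c]
        for mi, kind in enumerate(order):
            col = columns[kind]
            s = col.values.get((c, "S"), 0.0)
            l = col.values.get((c, "L"), 0.0)
            if s + l == 0:
                continue
            scale = target / (s + l)  # adjust ratios to the pachytene column
            x0 = ci + (mi - len(order) / 2) * width
            ax.bar(x0, s * scale, width=width * 0.85, bottom=0,
                   color="#777777", edgecolor="black", linewidth=0.3)
            ax.bar(x0, l * scale, width=width * 0.85, bottom=s * scale + 0.6,
                   color="#bbbbbb", edgecolor="black", linewidth=0.3)
        if markers:
            for m in markers:
                if m.chrom_id == c and m.percent_pos is not None:
                    yy = m.percent_pos.mean / 100.0 * target
                    ax.plot([ci - 0.45, ci - 0.35], [yy, yy], color="tab:green",
                            linewidth=1.0)
    ax.set_xticks(range(len(chroms)))
    ax.set_xticklabels([str(c) for c in chroms])
    ax.set_xlabel("chromosome")
    ax.set_ylabel("scaled length (pachytene μm)")
    ax.invert_yaxis()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, format="svg", metadata={"Date": None})
        plt.close(fig)
        return Path(out_path)
    return fig
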