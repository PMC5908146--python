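"""Synthetic pachytene chromosome generator with ground truth.

Emulates the structures the downstream analysis assumes: a curved chromosome
axis carrying a string of Gaussian chromomere bumps on a baseline, a
centromeric constriction (intensity dip), heterochromatic blocks (amplified
bumps), per-channel FISH spots at known axial positions, and CCD-style
camera noise (additive Gaussian, optional Poisson). Every generator returns
its input specification verbatim as ground truth, and all randomness flows
through an explicit seed, so fixed spec + seed reproduces output
bit-identically.

The per-chromosome fixtures encode the published karyotype: total length and
centromere position from the packaged dimension table, and one bump per
chromomere plus a pair flanking the centromere, so that detection followed
by the centromeric merge rule recovers the published chromomere count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import MultiChannelImage, load_chromosome_records
from .profiles import AxialProfile

log = logging.getLogger("pachymap")

#: μm per pixel of the synthetic camera (repo convention, not a published value)
DEFAULT_UM_PER_PX = 0.1
#: axial sampling step of 1-D profiles (μm)
PROFILE_STEP_UM = 0.1
#: radial Gaussian sigma of the chromosome tube (μm)
TUBE_SIGMA_UM = 0.35
#: default chromomere bump parameters
BUMP_SIGMA_UM = 0.15
BUMP_AMPLITUDE = 100.0
BASELINE = 50.0
#: amplitude multiplier inside heterochromatic blocks
HET_MULTIPLIER = 2.0
#: centromeric constriction dip (fraction of baseline removed, Gaussian sigma)
CENTROMERE_DIP = 0.7
CENTROMERE_DIP_SIGMA_UM = 0.4
#: offset of the two centromere-flanking bumps (μm, inside the merge window)
CENTRO_FLANK_UM = 0.5


class SpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Full description of one synthetic chromosome.

    ``axis`` is ``{"kind": "line"|"arc"|"sinusoid"|"polyline", ...}``;
    axial positions are μm from the short-arm terminus (curve start).
    ``fish_spots`` maps channel label -> list of (position_um, amplitude).
    ``het_blocks`` are (start_um, end_um, amplitude_multiplier).
    """

    length_um: float
    chromomere_positions_um: list[float] = field(default_factory=list)
    chromomere_sigma_um: float = BUMP_SIGMA_UM
    chromomere_amplitudes: Optional[list[float]] = None
    centromere_um: Optional[float] = None
    het_blocks: list[tuple[float, float, float]] = field(default_factory=list)
    fish_spots: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    background: float = BASELINE
    background_gradient: float = 0.0
    noise_sd: float = 0.0
    poisson: bool = False
    seed: int = 0
    axis: dict = field(default_factory=lambda: {"kind": "line"})
    um_per_px: float = DEFAULT_UM_PER_PX
    chrom_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise SpecError("length_um must be positive")
        for p in self.chromomere_positions_um:
            if not 0 <= p <= self.length_um:
                raise SpecError(f"chromomere position {p} outside [0, length]")
        if self.centromere_um is not None and not (
                0 < self.centromere_um < self.length_um):
            raise SpecError("centromere outside the chromosome")
        for spots in self.fish_spots.values():
            for p, _amp in spots:
                if not 0 <= p <= self.length_um:
                    raise SpecError(f"FISH spot at {p} outside [0, length]")
        amps = self.amplitudes
        if any(a <= self.background for a in amps):
            raise SpecError("chromomere amplitudes must exceed the background")

    @property
    def amplitudes(self) -> list[float]:
        if self.chromomere_amplitudes is not None:
            if len(self.chromomere_amplitudes) != len(self.chromomere_positions_um):
                raise SpecError("one amplitude per chromomere required")
            return list(self.chromomere_amplitudes)
        return [BUMP_AMPLITUDE] * len(self.chromomere_positions_um)

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# axial intensity model (shared by profile and image renderers)


def axial_intensity(spec: SyntheticSpec, s: np.ndarray) -> np.ndarray:
    """Noise-free axial intensity: baseline (dipped at the centromere) plus
    chromomere Gaussians scaled by heterochromatin multipliers."""
    s = np.asarray(s, dtype=float)
    base = spec.background + spec.background_gradient * s
    if spec.centromere_um is not None:
        dip = CENTROMERE_DIP * np.exp(
            -0.5 * ((s - spec.centromere_um) / CENTROMERE_DIP_SIGMA_UM) ** 2)
        base = base * (1.0 - dip)
    out = base.copy()
    for pos, amp in zip(spec.chromomere_positions_um, spec.amplitudes):
        mult = 1.0
        for lo, hi, m in spec.het_blocks:
            if lo <= pos <= hi:
                mult = m
                break
        out += amp * mult * np.exp(-0.5 * ((s - pos) / spec.chromomere_sigma_um) ** 2)
    return out


def _apply_noise(arr: np.ndarray, spec: SyntheticSpec,
                 rng: np.random.Generator) -> np.ndarray:
    out = arr
    if spec.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# --------------------------------------------------------------------------
# 1-D profiles


def make_profile(
    spec: SyntheticSpec, seed: Optional[int] = None, label: str = "counterstain",
) -> tuple[AxialProfile, SyntheticSpec]:
    """1-D shortcut of :func:`make_image` (no geometry); returns ground truth."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(spec.length_um / PROFILE_STEP_UM))
    positions = (np.arange(n) + 0.5) * PROFILE_STEP_UM
    intens = _apply_noise(axial_intensity(spec, positions), spec, rng)
    return AxialProfile(positions, intens, label=label), spec


# --------------------------------------------------------------------------
# axis geometry


def axis_polyline(spec: SyntheticSpec, step_um: float = 0.02) -> np.ndarray:
    """Dense (x, y) polyline in μm, uniformly sampled in arc length, with
    total arc length equal to ``spec.length_um``."""
    kind = spec.axis.get("kind", "line")
    L = spec.length_um
    if kind == "line":
        t = np.arange(0.0, L + step_um / 2, step_um)
        pts = np.stack([t, np.zeros_like(t)], axis=1)
    elif kind == "arc":
        R = float(spec.axis["radius_um"])
        theta = np.arange(0.0, L / R + step_um / (2 * R), step_um / R)
        pts = np.stack([R * np.sin(theta), R * (1 - np.cos(theta))], axis=1)
    elif kind == "sinusoid":
        A = float(spec.axis.get("amplitude_um", 3.0))
        lam = float(spec.axis.get("period_um", 15.0))
        # arc-length reparameterization of y = A sin(2πx/λ)
        x = np.linspace(0.0, 3 * L, 60000)
        y = A * np.sin(2 * np.pi * x / lam)
        seg = np.hypot(np.diff(x), np.diff(y))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        if arc[-1] < L:
            raise SpecError("sinusoid domain too short for requested length")
        t = np.arange(0.0, L + step_um / 2, step_um)
        pts = np.stack([np.interp(t, arc, x), np.interp(t, arc, y)], axis=1)
    elif kind == "polyline":
        raw = np.asarray(spec.axis["points_um"], dtype=float)
        seg = np.hypot(*np.diff(raw, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        if arc[-1] <= 0:
            raise SpecError("degenerate polyline")
        scale = L / arc[-1]
        arc = arc * scale
        t = np.arange(0.0, L + step_um / 2, step_um)
        pts = np.stack([np.interp(t, arc, raw[:, 0] * scale),
                        np.interp(t, arc, raw[:, 1] * scale)], axis=1)
    else:
        raise SpecError(f"unknown axis kind {kind!r}")
    _check_no_self_intersection(pts, step_um)
    return pts


def _check_no_self_intersection(pts: np.ndarray, step_um: float) -> None:
    """Straightening is ill-posed if distant arc positions come closer than
    a tube diameter."""
    min_clear = 2.5 * TUBE_SIGMA_UM
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=min_clear, output_type="ndarray")
    if pairs.size == 0:
        return
    arc_sep = np.abs(pairs[:, 0] - pairs[:, 1]) * step_um
    if np.any(arc_sep > 4.0 * min_clear):
        raise SpecError("axis approaches itself: straightening ill-posed")


# --------------------------------------------------------------------------
# image rendering


def make_image(
    spec: SyntheticSpec, seed: Optional[int] = None,
) -> tuple[MultiChannelImage, SyntheticSpec]:
    """Render the multi-channel image of one synthetic chromosome.

    Channel 0 (counterstain) is a tube of Gaussian cross-section whose axial
    intensity follows :func:`axial_intensity`; FISH/antibody channels render
    2-D Gaussian spots at their mapped axis coordinates. Noise is applied
    last, independently per channel.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    px = spec.um_per_px
    pts = axis_polyline(spec)
    margin = 4 * TUBE_SIGMA_UM + 1.0
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    n_cols = int(math.ceil((hi[0] - lo[0]) / px))
    n_rows = int(math.ceil((hi[1] - lo[1]) / px))

    # pixel centers in μm
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    px_xy = np.stack([lo[0] + (cols + 0.5) * px, lo[1] + (rows + 0.5) * px],
                     axis=-1).reshape(-1, 2)
    tree = cKDTree(pts)
    dist, idx = tree.query(px_xy)
    s_of_px = idx * 0.02  # axis sampling step of axis_polyline
    radial = np.exp(-0.5 * (dist / TUBE_SIGMA_UM) ** 2)
    near = dist <= 4 * TUBE_SIGMA_UM

    channels = []
    labels = ["counterstain"]
    counter = np.zeros(n_rows * n_cols)
    counter[near] = axial_intensity(spec, s_of_px[near]) * radial[near]
    channels.append(counter.reshape(n_rows, n_cols))

    spot_sigma = spec.axis.get("spot_sigma_um", 0.3)
    for label, spots in spec.fish_spots.items():
        ch = np.zeros(n_rows * n_cols)
        for s_pos, amp in spots:
            center = pts[int(round(s_pos / 0.02))]
            d2 = ((px_xy - center) ** 2).sum(axis=1)
            ch += amp * np.exp(-0.5 * d2 / spot_sigma ** 2)
        channels.append(ch.reshape(n_rows, n_cols))
        labels.append(label)

    out = np.stack(channels)
    out = np.stack([_apply_noise(c, spec, rng) for c in out])
    log.info("make_image: %s, %d channels, %dx%d px", spec.axis.get("kind"),
             out.shape[0], n_rows, n_cols)
    return MultiChannelImage(out, um_per_px=px, channel_labels=labels), spec


# --------------------------------------------------------------------------
# per-chromosome fixtures (published karyotype layout)


def chromosome_layout(chrom_id: int, noise_sd: float = 0.0,
                      seed: int = 0) -> SyntheticSpec:
    """Synthetic layout for one of the 12 chromosomes.

    Plants ``n+1`` chromomere bumps for a published count of ``n``: two bumps
    flank the centromere inside the merge window (they are counted as the
    single centromeric chromomere) and the remaining ``n−1`` are spaced
    evenly along the arms in proportion to arm length. Heterochromatic
    blocks follow the qualitative per-chromosome descriptions (entire short
    arm of chromosomes 4 and 10, pericentromeric blocks elsewhere).
    """
    recs = {r.chrom_id: r for r in load_chromosome_records()}
    if chrom_id not in recs:
        raise SpecError(f"unknown chromosome {chrom_id}")
    r = recs[chrom_id]
    L = r.total_len_um.mean
    c = r.short_len_um.mean
    n = r.n_chromomeres
    n_short = max(1, round((n - 1) * c / L))
    n_long = (n - 1) - n_short
    short_pos = np.linspace(0.5, c - 1.5, n_short)
    long_pos = np.linspace(c + 1.5, L - 0.5, n_long)
    positions = (list(short_pos)
                 + [c - CENTRO_FLANK_UM, c + CENTRO_FLANK_UM]
                 + list(long_pos))
    return SyntheticSpec(
        length_um=L,
        chromomere_positions_um=sorted(float(p) for p in positions),
        centromere_um=float(c),
        het_blocks=_het_blocks(chrom_id, L, c),
        noise_sd=noise_sd,
        seed=seed,
        chrom_id=chrom_id,
    )


def _het_blocks(chrom_id: int, L: float, c: float) -> list[tuple[float, float, float]]:
    m = HET_MULTIPLIER
    peri = lambda a, b: (max(0.0, a), min(L, b), m)
    table = {
        1: [], 2: [], 3: [],                       # large chromosomes: none
        4: [peri(0.0, c), peri(c, c + 4.0)],       # whole short arm + long peri
        5: [peri(c - 2.0, c + 2.0)],
        6: [peri(c - 2.0, c + 2.0)],
        7: [peri(c - 2.0, c + 2.0)],
        8: [peri(c - 2.0, c + 2.0)],
        9: [peri(c, c + 3.0)],
        10: [peri(0.0, c), peri(c, c + 3.0)],      # whole short arm + long peri
        11: [peri(c, c + 4.0)],                    # large block on long arm
        12: [peri(c - 3.0, c)],                    # short-arm pericentromeric
    }
    return table[chrom_id]


def published_chromomere_count(chrom_id: int) -> int:
    return {r.chrom_id: r.n_chromomeres for r in load_chromosome_records()}[chrom_id]


# --------------------------------------------------------------------------
# stage series (condensation dynamics)


@dataclass
class StageSeries:
    """Per-stage landmark positions (μm); landmark k is the cumulative end of
    region k, with region I starting at the short-arm terminus (0)."""

    landmarks: np.ndarray  # (n_stages, n_regions)
    stage_labels: list[str]
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[0] < 2:
            raise SpecError("need >= 2 stages of landmarks")
        if np.any(np.diff(self.landmarks, axis=1) <= 0):
            raise SpecError("landmarks must be strictly increasing within a stage")


ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]


def make_stage_series(
    contractions: Sequence[float],
    base_lengths: Sequence[float],
    n_stages: int = 6,
    seed: int = 0,
    jitter_sd: float = 0.0,
) -> StageSeries:
    """Region lengths shrink linearly across stages from ``base`` down to
    ``base × (1 − contraction)``; landmark positions are cumulative sums."""
    contractions = np.asarray(contractions, dtype=float)
    base = np.asarray(base_lengths, dtype=float)
    if contractions.shape != base.shape:
        raise SpecError("one contraction per region required")
    if np.any(base <= 0):
        raise SpecError("base lengths must be positive")
    if np.any((contractions < 0) | (contractions >= 1)):
        raise SpecError("contractions must lie in [0, 1)")
    if n_stages < 2:
        raise SpecError("need >= 2 stages")
    rng = np.random.default_rng(seed)
    frac = np.linspace(0.0, 1.0, n_stages)[:, None]
    lengths = base[None, :] * (1.0 - contractions[None, :] * frac)
    if jitter_sd > 0:
        lengths = np.clip(lengths + rng.normal(0, jitter_sd, lengths.shape),
                          1e-3, None)
    landmarks = np.cumsum(lengths, axis=1)
    return StageSeries(
        landmarks=landmarks,
        stage_labels=[f"stage{k + 1}" for k in range(n_stages)],
        region_labels=ROMAN[:base.size],
    )


# --------------------------------------------------------------------------
# dual-channel (counterstain + antibody) profiles


def make_dual_profile(
    n_peaks: int,
    matched_indices: Sequence[int],
    offset_um: float = 0.1,
    seed: int = 0,
    length_um: float = 20.07,
    antibody_label: str = "H3K9me2",
) -> tuple[AxialProfile, AxialProfile]:
    """Counterstain profile with ``n_peaks`` chromomere bumps and an antibody
    profile with a coincident peak (within ``offset_um``) at every index in
    ``matched_indices`` and no peak near the others."""
    matched = sorted(set(int(i) for i in matched_indices))
    if any(i < 0 or i >= n_peaks for i in matched):
        raise SpecError("matched index outside range")
    positions = np.linspace(0.6, length_um - 0.6, n_peaks)
    spacing = float(np.min(np.diff(positions))) if n_peaks > 1 else length_um
    if spacing <= 3 * offset_um:
        raise SpecError("peaks too close for the requested offset separation")
    rng = np.random.default_rng(seed)
    counter_spec = SyntheticSpec(
        length_um=length_um,
        chromomere_positions_um=list(map(float, positions)),
        seed=seed,
    )
    counter, _ = make_profile(counter_spec, seed=seed)
    anti_pos = positions[matched] + rng.uniform(-offset_um, offset_um,
                                               size=len(matched))
    anti_spec = SyntheticSpec(
        length_um=length_um,
        chromomere_positions_um=list(map(float, np.clip(anti_pos, 0, length_um))),
        chromomere_sigma_um=counter_spec.chromomere_sigma_um,
        chromomere_amplitudes=[80.0] * len(matched),
        background=30.0,
        seed=seed + 1,
    )
    antibody, _ = make_profile(anti_spec, seed=seed + 1, label=antibody_label)
    return counter, antibody


def chromosome11_dual_fixture(seed: int = 0) -> tuple[AxialProfile, AxialProfile]:
    """The immunostaining demo condition: 19 chromomeres on chromosome 11
    (7 short-arm + 12 long-arm) of which 16 carry an H3K9me2 peak."""
    unmatched = {2, 8, 14}
    matched = [i for i in range(19) if i not in unmatched]
    return make_dual_profile(19, matched, offset_um=0.1, seed=seed,
                             length_um=20.07)
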