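"""Axial intensity profiles and chromomere segmentation.

A pachytene chromosome appears as a string of bead-like chromomeres whose
DAPI/PI fluorescence rises above the local baseline. Because chromomere size
and brightness vary strongly along a chromosome, segmentation is *relative*:
a local maximum becomes a chromomere peak only if its prominence exceeds a
fraction of the local baseline (running median within a window). Boundaries
between adjacent chromomeres sit at the deepest intervening minimum. The two
chromomeres immediately flanking the centromere are counted as a single
centromeric chromomere, and chromomeres are indexed outward from it
(negative on the short arm, positive on the long arm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, peak_prominences

log = logging.getLogger("pachymap")

#: default running-median window for the local baseline (μm)
DEFAULT_WINDOW_UM = 2.0
#: default relative prominence threshold (fraction of local baseline)
DEFAULT_PROMINENCE_REL = 0.15
#: default half-width of the pericentromeric merge window (μm)
DEFAULT_MERGE_WINDOW_UM = 1.0
#: default Gaussian pre-smoothing of the profile (μm); 0 disables
DEFAULT_SMOOTH_SIGMA_UM = 0.15
#: heterochromatin call threshold in global-SD units
DEFAULT_K_SD = 0.5


class ProfileError(ValueError):
    pass


@dataclass
class AxialProfile:
    """Intensity trace along the chromosome axis.

    Positions are μm from the short-arm terminus, uniformly spaced;
    intensities are arbitrary fluorescence units, non-negative.
    """

    positions: np.ndarray
    intensities: np.ndarray
    label: str = "counterstain"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ProfileError("positions and intensities must have equal length")
        if self.positions.size < 2:
            raise ProfileError("profile needs at least two samples")
        steps = np.diff(self.positions)
        if np.any(steps <= 0):
            raise ProfileError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ProfileError("positions must be uniformly spaced")

    @property
    def step_um(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def length_um(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class ChromomereSegment:
    """One chromomere: boundaries, peak, intensity and classification."""

    start_um: float
    end_um: float
    peak_um: float
    peak_intensity: float
    mean_intensity: float
    condensed: Optional[bool] = None
    index: Optional[int] = None


@dataclass
class Graygram:
    """Quantile-quantized gray levels along the axis (higher = darker ink =
    brighter fluorescence)."""

    positions: np.ndarray
    levels: np.ndarray
    n_levels: int


@dataclass
class MatchResult:
    n_matched: int
    pairs: list[tuple[float, float]]
    peaks_a: np.ndarray = field(default_factory=lambda: np.array([]))
    peaks_b: np.ndarray = field(default_factory=lambda: np.array([]))


# --------------------------------------------------------------------------
# profile extraction from straightened images


def axial_profile(straightened, channel=0, aggregation: str = "mean") -> AxialProfile:
    """Aggregate a straightened image column-wise into an axial trace.

    The modal off-axis level (estimated from the outermost rows) is
    subtracted and the result floored at zero.
    """
    img = straightened.channel(channel)
    if img.size == 0:
        raise ProfileError("empty image")
    if aggregation not in ("mean", "max"):
        raise ProfileError(f"unknown aggregation {aggregation!r}")
    n_rows = img.shape[0]
    edge = max(1, n_rows // 8)
    off_axis = np.concatenate([img[:edge].ravel(), img[-edge:].ravel()])
    background = float(np.median(off_axis))
    agg = img.mean(axis=0) if aggregation == "mean" else img.max(axis=0)
    intens = np.clip(agg - background, 0.0, None)
    step = straightened.axial_um_per_col
    positions = (np.arange(img.shape[1]) + 0.5) * step
    label = straightened.channel_labels[channel] if isinstance(channel, int) else channel
    log.info("axial_profile: channel=%s aggregation=%s background=%.2f",
             channel, aggregation, background)
    return AxialProfile(positions, intens, label=str(label))


# --------------------------------------------------------------------------
# peak detection core


def _local_baseline(intensities: np.ndarray, idx: int, half: int) -> float:
    lo = max(0, idx - half)
    hi = min(intensities.size, idx + half + 1)
    return float(np.median(intensities[lo:hi]))


def find_profile_peaks(
    profile: AxialProfile,
    window_um: float = DEFAULT_WINDOW_UM,
    min_prominence_rel: float = DEFAULT_PROMINENCE_REL,
    smooth_sigma_um: float = DEFAULT_SMOOTH_SIGMA_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak indices and smoothed trace under the relative-prominence rule.

    A strict local maximum is kept iff its topological prominence exceeds
    ``min_prominence_rel`` times the local baseline (median within
    ±window_um). All thresholds are relative, so the result is invariant
    under a global intensity rescaling.
    """
    step = profile.step_um
    y = profile.intensities
    if smooth_sigma_um > 0:
        y = gaussian_filter1d(y, sigma=smooth_sigma_um / step, mode="nearest")
    candidates, _ = find_peaks(y)
    if candidates.size == 0:
        return np.array([], dtype=int), y
    prom = peak_prominences(y, candidates)[0]
    half = int(round(window_um / step))
    floor = 1e-3 * float(y.max()) if y.max() > 0 else 0.0
    keep = []
    for idx, p in zip(candidates, prom):
        base = max(_local_baseline(y, int(idx), half), floor)
        if p > min_prominence_rel * base:
            keep.append(int(idx))
    return np.asarray(keep, dtype=int), y


def _boundary_between(y: np.ndarray, i: int, j: int) -> int:
    """Index of the deepest minimum in (i, j); ties broken toward midpoint."""
    inner = y[i + 1:j]
    lows = np.flatnonzero(inner == inner.min()) + i + 1
    mid = (i + j) / 2.0
    return int(lows[np.argmin(np.abs(lows - mid))])


def detect_chromomeres(
    profile: AxialProfile,
    window_um: float = DEFAULT_WINDOW_UM,
    min_prominence_rel: float = DEFAULT_PROMINENCE_REL,
    centromere_um: Optional[float] = None,
    merge_window_um: float = DEFAULT_MERGE_WINDOW_UM,
    smooth_sigma_um: float = DEFAULT_SMOOTH_SIGMA_UM,
) -> list[ChromomereSegment]:
    """Segment a profile into chromomeres.

    Returns ordered, non-overlapping segments. When ``centromere_um`` is
    given, the two peaks immediately flanking it (each within
    ``merge_window_um``) are merged into a single centromeric chromomere and
    indices are assigned outward from it: −1, −2, … toward the short-arm
    terminus and +1 (the centromeric chromomere), +2, … toward the long-arm
    terminus. A flat profile yields an empty list.
    """
    if profile.length_um <= window_um:
        raise ProfileError("profile shorter than the baseline window")
    log.info(
        "detect_chromomeres: window=%.2f rel=%.2f merge=%.2f smooth=%.2f "
        "centromere=%s", window_um, min_prominence_rel, merge_window_um,
        smooth_sigma_um, centromere_um)
    peaks, y = find_profile_peaks(
        profile, window_um, min_prominence_rel, smooth_sigma_um)
    if peaks.size == 0:
        return []
    pos = profile.positions
    raw = profile.intensities

    bounds = [0]
    for i, j in zip(peaks[:-1], peaks[1:]):
        bounds.append(_boundary_between(y, int(i), int(j)))
    bounds.append(len(pos) - 1)

    segments: list[ChromomereSegment] = []
    for k, pk in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 1]
        segments.append(ChromomereSegment(
            start_um=float(pos[lo]),
            end_um=float(pos[hi]),
            peak_um=float(pos[pk]),
            peak_intensity=float(raw[pk]),
            mean_intensity=float(raw[lo:hi + 1].mean()),
        ))

    if centromere_um is not None:
        segments = _merge_centromeric(segments, centromere_um, merge_window_um)
        segments = assign_indices(segments, centromere_um)
    else:
        for n, seg in enumerate(segments, start=1):
            seg.index = n
    return segments


def _merge_centromeric(
    segments: list[ChromomereSegment], centromere_um: float, merge_window_um: float
) -> list[ChromomereSegment]:
    left = [k for k, s in enumerate(segments)
            if centromere_um - merge_window_um <= s.peak_um < centromere_um]
    right = [k for k, s in enumerate(segments)
             if centromere_um < s.peak_um <= centromere_um + merge_window_um]
    if not left or not right:
        return segments
    i, j = left[-1], right[0]  # the two immediately flanking peaks
    a, b = segments[i], segments[j]
    top = a if a.peak_intensity >= b.peak_intensity else b
    merged = ChromomereSegment(
        start_um=a.start_um,
        end_um=b.end_um,
        peak_um=top.peak_um,
        peak_intensity=top.peak_intensity,
        mean_intensity=(a.mean_intensity * (a.end_um - a.start_um)
                        + b.mean_intensity * (b.end_um - b.start_um))
                       / max(b.end_um - a.start_um, 1e-12),
    )
    return segments[:i] + [merged] + segments[j + 1:]


def assign_indices(
    segments: list[ChromomereSegment], centromere_um: float
) -> list[ChromomereSegment]:
    """Number chromomeres outward from the centromeric chromomere (= +1)."""
    if not segments:
        return segments
    # centromeric segment: the one containing the centromere, else nearest peak
    containing = [k for k, s in enumerate(segments)
                  if s.start_um <= centromere_um <= s.end_um]
    if containing:
        c = containing[0]
    else:
        c = int(np.argmin([abs(s.peak_um - centromere_um) for s in segments]))
    for k, seg in enumerate(segments):
        seg.index = (k - c + 1) if k >= c else (k - c)
    return segments


# --------------------------------------------------------------------------
# condensation classes, centromere, graygram, dual-channel matching


def classify_condensation(
    profile: AxialProfile,
    segments: Sequence[ChromomereSegment],
    k_sd: float = DEFAULT_K_SD,
) -> list[ChromomereSegment]:
    """Flag condensed (heterochromatic) chromomeres.

    A segment is condensed iff its mean intensity exceeds the
    chromosome-wide mean by more than ``k_sd`` standard deviations, both
    taken across the chromosome's segment means (so the call compares
    chromomeres with chromomeres, not with the sub-chromomere intensity
    texture). The rule is invariant under global rescaling; with all
    segment intensities equal, nothing is condensed for k_sd > 0.
    """
    if not segments:
        return []
    means = np.array([s.mean_intensity for s in segments], dtype=float)
    mu = float(means.mean())
    sd = float(means.std())
    threshold = mu + k_sd * sd
    log.info("classify_condensation: k_sd=%.2f threshold=%.3f", k_sd, threshold)
    return [replace(s, condensed=bool(s.mean_intensity > threshold))
            for s in segments]


def heterochromatic_blocks(
    segments: Sequence[ChromomereSegment],
) -> list[tuple[float, float]]:
    """Contiguous runs of condensed segments, as (start_um, end_um) blocks."""
    blocks: list[tuple[float, float]] = []
    run: Optional[list[float]] = None
    for s in segments:
        if s.condensed:
            if run is None:
                run = [s.start_um, s.end_um]
            else:
                run[1] = s.end_um
        elif run is not None:
            blocks.append((run[0], run[1]))
            run = None
    if run is not None:
        blocks.append((run[0], run[1]))
    return blocks


def locate_centromere(
    straightened,
    method: str = "constriction",
    fish_channel: str = "pericent",
    margin_frac: float = 0.10,
) -> float:
    """Centromere position (μm) on a straightened chromosome.

    ``fish``: the peak of the pericentromeric-repeat channel.
    ``constriction``: the deepest interior minimum of the counterstain
    profile, excluding a margin at both ends.
    """
    if method == "fish":
        if fish_channel not in straightened.channel_labels:
            raise ProfileError(f"FISH channel {fish_channel!r} absent")
        prof = axial_profile(straightened, fish_channel, aggregation="max")
        return float(prof.positions[int(np.argmax(prof.intensities))])
    if method != "constriction":
        raise ProfileError(f"unknown method {method!r}")
    prof = axial_profile(straightened, 0, aggregation="mean")
    return centromere_from_profile(prof, margin_frac)


def centromere_from_profile(
    profile: AxialProfile,
    margin_frac: float = 0.10,
    erosion_um: float = 0.7,
    smooth_sigma_um: float = 0.2,
) -> float:
    """Constriction call on a bare axial profile: deepest interior minimum
    of the baseline envelope.

    Chromomere bumps (including the pair flanking the centromere) are first
    removed with a grey erosion wider than a bump, leaving the baseline,
    whose deepest minimum away from the margins is the primary constriction.
    """
    from scipy.ndimage import median_filter, minimum_filter1d

    step = profile.step_um
    # grey erosion removes chromomere bumps (wider than a bump), leaving the
    # baseline envelope; the median filter then suppresses the noise-driven
    # extreme minima the erosion picks up
    y = minimum_filter1d(profile.intensities,
                         size=max(3, int(round(erosion_um / step))),
                         mode="nearest")
    y = median_filter(y, size=max(3, int(round(1.0 / step))), mode="nearest")
    if smooth_sigma_um > 0:
        y = gaussian_filter1d(y, sigma=smooth_sigma_um / step, mode="nearest")
    n = y.size
    lo = int(round(margin_frac * n))
    hi = n - lo
    inner = y[lo:hi]
    return float(profile.positions[lo + int(np.argmin(inner))])


def render_graygram(profile: AxialProfile, n_levels: int = 8) -> Graygram:
    """Quantile-bin intensities into gray levels (monotone in intensity)."""
    if n_levels < 1:
        raise ProfileError("n_levels must be >= 1")
    x = profile.intensities
    # minimum rank = number of strictly smaller samples, so ties share a level
    base = np.searchsorted(np.sort(x), x, side="left")
    levels = np.minimum((base * n_levels) // x.size, n_levels - 1)
    return Graygram(profile.positions.copy(), levels.astype(int), n_levels)


def match_peaks(
    a: AxialProfile,
    b: AxialProfile,
    tol_um: float,
    window_um: float = DEFAULT_WINDOW_UM,
    min_prominence_rel: float = DEFAULT_PROMINENCE_REL,
    smooth_sigma_um: float = DEFAULT_SMOOTH_SIGMA_UM,
) -> MatchResult:
    """Greedy nearest-neighbour pairing of peak lists from two channels.

    A pair counts iff the positional offset is at most ``tol_um``; each peak
    is used at most once. Used to ask how many counterstain chromomere peaks
    have a coincident antibody (e.g. H3K9me2) peak.
    """
    ia, _ = find_profile_peaks(a, window_um, min_prominence_rel, smooth_sigma_um)
    ib, _ = find_profile_peaks(b, window_um, min_prominence_rel, smooth_sigma_um)
    pa = a.positions[ia]
    pb = b.positions[ib]
    cand = sorted(
        ((abs(x - ybm), i, j) for i, x in enumerate(pa)
         for j, ybm in enumerate(pb) if abs(x - ybm) <= tol_um))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[float, float]] = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((float(pa[i]), float(pb[j])))
    log.info("match_peaks: %d/%d vs %d peaks matched at tol=%.2f μm",
             len(pairs), pa.size, pb.size, tol_um)
    return MatchResult(len(pairs), pairs, pa, pb)
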