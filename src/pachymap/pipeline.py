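"""End-to-end pipeline: simulate (or ingest) → straighten → profile →
metrics → integrate, with a single seed, a parameter echo, and a JSON run
report that is byte-identical for identical config + seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .axis import extract_axis, orient, segment_foreground, straighten
from .integration import (compaction_range, fit_arm_regression,
                          load_synthetic_columns, nucleotide_column,
                          pachytene_column, relative_lengths, within_pi)
from .io import (load_chromosome_records, load_marker_records,
                 packaged_fixture_path, write_image)
from .metrics import (check_marker_placements, check_table_closure,
                      condensation_dynamics, levan_class, round_report,
                      summarize_chromosome)
from .profiles import (axial_profile, centromere_from_profile,
                       classify_condensation, detect_chromomeres,
                       heterochromatic_blocks, locate_centromere, match_peaks,
                       render_graygram)
from .simulate import (SyntheticSpec, chromosome11_dual_fixture,
                       chromosome_layout, make_image, make_profile,
                       make_stage_series)

log = logging.getLogger("pachymap")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline parameters; every field is echoed into the run report."""

    seed: int = 0
    out_dir: str = "results"
    image_chromosome: int = 9
    half_width_um: float = 1.2
    window_um: float = 2.0
    min_prominence_rel: float = 0.15
    merge_window_um: float = 1.0
    smooth_sigma_um: float = 0.15
    k_sd: float = 0.5
    aggregation: str = "mean"
    n_levels: int = 8
    alpha: float = 0.05
    profile_noise_sd: float = 10.0
    image_noise_sd: float = 5.0
    # demo stage-series condition: five regions (I = short arm, II–V on the
    # long arm); region III condenses most, region IV least
    stage_contractions: tuple = (0.40, 0.45, 0.656, 0.158, 0.30)
    stage_base_lengths: tuple = (4.87, 6.5, 5.5, 5.0, 4.6)
    n_stages: int = 6

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        for key in ("stage_contractions", "stage_base_lengths"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        mapping = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(mapping, dict):
            raise ConfigError("config must be a key: value mapping")
        return cls.from_mapping(mapping)


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derived per-stage streams from the single run seed (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


# --------------------------------------------------------------------------
# stages


def _stage_image(cfg: RunConfig, seed: int, out_dir: Path) -> dict:
    """Simulate one curved chromosome image, straighten it, and read its
    centromere back by both methods."""
    base = chromosome_layout(cfg.image_chromosome)
    spec = SyntheticSpec(
        length_um=base.length_um,
        chromomere_positions_um=base.chromomere_positions_um,
        centromere_um=base.centromere_um,
        het_blocks=base.het_blocks,
        fish_spots={"pericent": [(base.centromere_um, 150.0)]},
        noise_sd=cfg.image_noise_sd,
        seed=seed,
        axis={"kind": "sinusoid", "amplitude_um": 2.5, "period_um": 14.0},
        chrom_id=base.chrom_id,
    )
    img, truth = make_image(spec)
    write_image(img, out_dir / "demo_chromosome.tif")
    mask = segment_foreground(img, 0)
    path = extract_axis(mask, img.um_per_px, intensity=img.channel(0))
    st = straighten(img, path, half_width_um=cfg.half_width_um)
    cen_fish = locate_centromere(st, "fish")
    st = orient(st, centromere_um=cen_fish)
    cen_fish = locate_centromere(st, "fish")
    cen_con = locate_centromere(st, "constriction")
    return {
        "chromosome": cfg.image_chromosome,
        "true_length_um": round_report(truth.length_um),
        "straightened_length_um": round_report(st.length_um),
        "true_centromere_um": round_report(truth.centromere_um),
        "centromere_fish_um": round_report(cen_fish),
        "centromere_constriction_um": round_report(cen_con),
    }


def _stage_census(cfg: RunConfig, seed: int) -> dict:
    """Profile + chromomere census for all 12 chromosome fixtures."""
    records = {r.chrom_id: r for r in load_chromosome_records()}
    seeds = _stage_seeds(seed, 12)
    out = {}
    for chrom_id in range(1, 13):
        spec = chromosome_layout(chrom_id, noise_sd=cfg.profile_noise_sd,
                                 seed=seeds[chrom_id - 1])
        profile, truth = make_profile(spec)
        segs = detect_chromomeres(
            profile, window_um=cfg.window_um,
            min_prominence_rel=cfg.min_prominence_rel,
            centromere_um=truth.centromere_um,
            merge_window_um=cfg.merge_window_um,
            smooth_sigma_um=cfg.smooth_sigma_um)
        segs = classify_condensation(profile, segs, k_sd=cfg.k_sd)
        gray = render_graygram(profile, n_levels=cfg.n_levels)
        summary = summarize_chromosome(segs, truth.centromere_um,
                                       record=records[chrom_id])
        out[str(chrom_id)] = {
            "census": summary.n_chromomeres,
            "published": records[chrom_id].n_chromomeres,
            "n_short": summary.n_short,
            "n_long": summary.n_long,
            "n_condensed": summary.n_condensed,
            "het_blocks_um": [[round_report(a), round_report(b)]
                              for a, b in heterochromatic_blocks(segs)],
            "gray_levels_used": int(np.unique(gray.levels).size),
        }
    return out


def _stage_metrics(cfg: RunConfig) -> dict:
    records = load_chromosome_records()
    markers = load_marker_records()
    closure = check_table_closure(records)
    placements = check_marker_placements(markers, records)
    return {
        "levan": {str(r.chrom_id): levan_class(r.arm_ratio.mean) for r in records},
        "compaction_cells_consistent": sum(c.consistent for c in closure),
        "compaction_cells_total": len(closure),
        "compaction_flagged": [
            {"chrom": c.chrom_id, "cell": c.cell,
             "computed": round_report(c.computed, 4), "printed": c.printed}
            for c in closure if not c.consistent],
        "placements_consistent": sum(p.consistent for p in placements),
        "placements_total": len(placements),
        "placements_flagged": [
            {"name": p.name, "arm": p.chrom_arm,
             "computed_um": round_report(p.computed_um, 3),
             "printed_um": p.printed_um}
            for p in placements if not p.consistent],
    }


def _stage_integrate(cfg: RunConfig) -> dict:
    records = load_chromosome_records()
    nt = nucleotide_column(records)
    pachy = pachytene_column(records)
    columns = {"pachytene_um": pachy, **load_synthetic_columns()}
    out = {}
    for kind, col in columns.items():
        fit = fit_arm_regression(nt, col, alpha=cfg.alpha)
        arms = [a for a in nt.arms() if a in col.values]
        x = np.array([nt.values[a] for a in arms])
        y = np.array([col.values[a] for a in arms])
        out[kind] = {
            "slope": round_report(fit.slope, 4),
            "intercept": None if fit.through_origin else round_report(fit.intercept, 4),
            "intercept_p": round_report(fit.intercept_p, 4),
            "through_origin": fit.through_origin,
            "r_squared": round_report(fit.r_squared, 4),
            "n": fit.n,
            "n_inside_pi95": int(within_pi(fit, x, y).sum()),
        }
    lo, hi, lo_arm, hi_arm = compaction_range(pachy, nt)
    out["pachytene_um_per_mb"] = {
        "min": round_report(lo), "max": round_report(hi),
        "min_arm": f"{lo_arm[0]}{lo_arm[1]}", "max_arm": f"{hi_arm[0]}{hi_arm[1]}",
    }
    rel = relative_lengths(pachy)
    out["relative_lengths_pct"] = {
        str(c): [round_report(s), round_report(l)] for c, (s, l) in rel.items()}
    return out


def _stage_dynamics(cfg: RunConfig, seed: int) -> dict:
    series = make_stage_series(cfg.stage_contractions, cfg.stage_base_lengths,
                               n_stages=cfg.n_stages, seed=seed)
    dyn = condensation_dynamics(series)
    return {
        "regions": dyn.region_labels,
        "percent_reduction": [round_report(v) for v in dyn.percent_reduction],
    }


def _stage_immuno(cfg: RunConfig, seed: int) -> dict:
    counter, antibody = chromosome11_dual_fixture(seed=seed)
    res = match_peaks(counter, antibody, tol_um=0.3,
                      window_um=cfg.window_um,
                      min_prominence_rel=cfg.min_prominence_rel,
                      smooth_sigma_um=cfg.smooth_sigma_um)
    return {
        "counterstain_peaks": int(res.peaks_a.size),
        "antibody_peaks": int(res.peaks_b.size),
        "matched": res.n_matched,
    }


# --------------------------------------------------------------------------
# driver


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Run every stage and return (and write) the JSON-serializable report."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 4)
    report = {"version": __version__, "parameters": asdict(config)}
    stages = [
        ("image", lambda: _stage_image(config, seeds[0], out)),
        ("census", lambda: _stage_census(config, seeds[1])),
        ("metrics", lambda: _stage_metrics(config)),
        ("integration", lambda: _stage_integrate(config)),
        ("dynamics", lambda: _stage_dynamics(config, seeds[2])),
        ("immunostaining", lambda: _stage_immuno(config, seeds[3])),
    ]
    for name, fn in stages:
        log.info("pipeline stage %s: parameters %s", name, asdict(config))
        try:
            report[name] = fn()
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed with parameters "
                f"{asdict(config)}: {exc}") from exc
    validate_report(report)
    text = json.dumps(report, sort_keys=True, indent=2)
    (out / "report.json").write_text(text + "\n", encoding="utf-8")
    return report


# --------------------------------------------------------------------------
# minimal schema validation (packaged schema, JSON-schema subset)


def validate_report(report: dict) -> None:
    schema = json.loads(
        Path(packaged_fixture_path("report_schema.json")).read_text("utf-8"))
    _check_schema(report, schema, "report")


_TYPES = {"object": dict, "array": list, "string": str, "boolean": bool,
          "integer": int, "number": (int, float)}


def _check_schema(value, schema: dict, where: str) -> None:
    typ = schema.get("type")
    if typ is not None:
        ok = isinstance(value, _TYPES[typ])
        if typ == "boolean":
            ok = isinstance(value, bool)
        if typ == "integer":
            ok = isinstance(value, int) and not isinstance(value, bool)
        if not ok and not (value is None and schema.get("nullable")):
            raise ConfigError(f"{where}: expected {typ}, got {type(value).__name__}")
    for key in schema.get("required", []):
        if key not in value:
            raise ConfigError(f"{where}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in value:
            _check_schema(value[key], sub, f"{where}.{key}")
    if "items" in schema and isinstance(value, list):
        for i, item in enumerate(value):
            _check_schema(item, schema["items"], f"{where}[{i}]")
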