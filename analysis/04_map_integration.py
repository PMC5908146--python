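#!/usr/bin/env python
"""Unify the four per-arm map columns on the relative-length scale, regress
each against nucleotide length (zero-intercept test, 95% CI/PI), and render
the side-by-side map figure."""

import json
from pathlib import Path

import numpy as np

from pachymap.integration import (compaction_range, fit_arm_regression,
                                  load_synthetic_columns, nucleotide_column,
                                  pachytene_column, relative_lengths,
                                  render_maps, within_pi)
from pachymap.io import load_chromosome_records, load_marker_records
from pachymap.metrics import round_report

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    records = load_chromosome_records()
    nt = nucleotide_column(records)
    pachy = pachytene_column(records)
    columns = {"pachytene_um": pachy, **load_synthetic_columns()}

    payload = {}
    for kind, col in columns.items():
        fit = fit_arm_regression(nt, col)
        arms = [a for a in nt.arms() if a in col.values]
        x = np.array([nt.values[a] for a in arms])
        y = np.array([col.values[a] for a in arms])
        inside = int(within_pi(fit, x, y).sum())
        payload[kind] = {
            "slope": round_report(fit.slope, 4),
            "intercept": (None if fit.through_origin
                          else round_report(fit.intercept, 3)),
            "intercept_p": round_report(fit.intercept_p, 4),
            "through_origin": fit.through_origin,
            "r_squared": round_report(fit.r_squared, 4),
            "arms_inside_pi95": inside,
            "n": fit.n,
        }
        verdict = ("through origin (intercept=0 not rejected)"
                   if fit.through_origin else
                   f"nonzero intercept (p={fit.intercept_p:.4f})")
        print(f"{kind:13s} vs nucleotide: slope {fit.slope:.3f}, {verdict}, "
              f"{inside}/{fit.n} arms inside 95% PI")

    lo, hi, lo_arm, hi_arm = compaction_range(pachy, nt)
    payload["pachytene_um_per_mb_range"] = {
        "min": round_report(lo), "max": round_report(hi),
        "min_arm": f"{lo_arm[0]}{lo_arm[1]}", "max_arm": f"{hi_arm[0]}{hi_arm[1]}"}
    print(f"pachytene per-arm compaction spans {lo:.2f}–{hi:.2f} μm/Mb "
          f"(most compact {lo_arm[0]}{lo_arm[1]}, least {hi_arm[0]}{hi_arm[1]})")

    payload["relative_lengths_pct"] = {
        str(c): [round_report(s), round_report(l)]
        for c, (s, l) in relative_lengths(pachy).items()}

    (OUT / "map_integration.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    render_maps({"nucleotide_mb": nt, **columns},
                markers=load_marker_records(), out_path=OUT / "maps.svg")
    print(f"wrote {OUT / 'map_integration.json'} and {OUT / 'maps.svg'}")


if __name__ == "__main__":
    main()
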