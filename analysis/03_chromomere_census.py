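#!/usr/bin/env python
"""Chromomere census on the 12 packaged chromosome fixtures: exact counts
at zero noise and the recovery rate over 20 seeds at SNR 10, with
heterochromatic-block calls from the condensation classifier."""

import csv
from pathlib import Path

from pachymap.metrics import summarize_chromosome
from pachymap.io import load_chromosome_records
from pachymap.profiles import classify_condensation, detect_chromomeres
from pachymap.simulate import chromosome_layout, make_profile

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    records = {r.chrom_id: r for r in load_chromosome_records()}
    rows = []
    for cid in range(1, 13):
        spec = chromosome_layout(cid)
        prof, truth = make_profile(spec)
        segs = detect_chromomeres(prof, centromere_um=truth.centromere_um)
        segs = classify_condensation(prof, segs)
        summary = summarize_chromosome(segs, truth.centromere_um,
                                       record=records[cid])
        hits = 0
        for seed in range(20):
            noisy, t = make_profile(chromosome_layout(cid, noise_sd=10.0,
                                                      seed=seed))
            n = len(detect_chromomeres(noisy, centromere_um=t.centromere_um))
            hits += n == records[cid].n_chromomeres
        rows.append([cid, records[cid].n_chromomeres, summary.n_chromomeres,
                     summary.n_short, summary.n_long, summary.n_condensed,
                     hits / 20])
    with (OUT / "chromomere_census.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "published", "census_zero_noise", "n_short",
                    "n_long", "n_condensed", "snr10_recovery_rate"])
        w.writerows(rows)
    exact = sum(r[1] == r[2] for r in rows)
    worst = min(r[6] for r in rows)
    print(f"zero-noise census exact for {exact}/12 chromosomes; "
          f"worst SNR-10 recovery rate {worst:.0%} (20 seeds each)")
    print("counts:", " ".join(str(r[2]) for r in rows))


if __name__ == "__main__":
    main()
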