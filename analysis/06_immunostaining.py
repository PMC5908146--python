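#!/usr/bin/env python
"""Dual-channel peak coincidence: the chromosome-11 fixture plants 19
counterstain chromomeres (7 short-arm + 12 long-arm) of which 16 carry an
antibody (H3K9me2) peak; greedy matching at 0.3 μm recovers the planted
coincidence set."""

import json
from pathlib import Path

from pachymap.metrics import round_report
from pachymap.profiles import match_peaks
from pachymap.simulate import chromosome11_dual_fixture

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 0) -> None:
    counter, antibody = chromosome11_dual_fixture(seed=seed)
    res = match_peaks(counter, antibody, tol_um=0.3)
    payload = {
        "counterstain_peaks": int(res.peaks_a.size),
        "antibody_peaks": int(res.peaks_b.size),
        "matched": res.n_matched,
        "pairs_um": [[round_report(a), round_report(b)] for a, b in res.pairs],
    }
    (OUT / "immunostaining.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"{res.n_matched} of {res.peaks_a.size} counterstain chromomere "
          f"peaks have a coincident antibody peak within 0.3 μm")


if __name__ == "__main__":
    main()
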