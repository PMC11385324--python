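#!/usr/bin/env python
"""Footprint region densities and the ISR readthrough ratio.

Simulates Poisson footprint coverage over the human-like fixture (CDS rate
100/nt, ISR rate theta*100, distal background 1/nt), computes region
densities and the isr/cds readthrough ratio, and runs the ISR-vs-distal
enrichment permutation test.  Writes results/footprint_signal.json.
"""

import dataclasses
import json
from pathlib import Path

from scrkit.ribosignal import readthrough_enrichment_test, region_densities
from scrkit.seqcore import find_isr
from scrkit.synthdata import SimConfig, make_fixture, simulate_footprints

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    t = make_fixture("hominini_like")
    isr = find_isr(t)
    results = {}
    for label, theta in [("readthrough", 0.2), ("no_readthrough", 0.0)]:
        cfg = SimConfig(seed=SEED, theta=theta, lambda_cds=100.0, distal_lambda=1.0)
        profile = simulate_footprints(t, isr, cfg)
        signal = region_densities(profile, t, isr)
        pv = readthrough_enrichment_test(profile, t, isr, n_perm=999, seed=SEED)
        entry = dataclasses.asdict(signal)
        entry["enrichment_p"] = pv
        entry["true_theta"] = theta
        results[label] = entry
        print(
            f"{label}: cds={signal.cds_density:.2f}/nt isr={signal.isr_density:.2f}/nt "
            f"distal={signal.distal_density:.2f}/nt ratio={signal.ratio:.3f} "
            f"perm_p={pv:.4g}"
        )
    OUT.mkdir(exist_ok=True)
    with open(OUT / "footprint_signal.json", "w") as fh:
        json.dump(results, fh, indent=2)
    print(
        "\nWith readthrough the ISR density sits far above the distal 3'UTR "
        "background (small permutation p); without it the ISR is "
        "indistinguishable from background."
    )


if __name__ == "__main__":
    main()
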