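#!/usr/bin/env python
"""Cross-species ISR comparison: indel calling and frame classification.

Aligns the ancestral-like 3'UTR against the derived (insertion-carrying)
fixture to recover the single-base insertion, classifies extension lengths
across a simulated ortholog family, and renders a conservation mosaic of the
extension peptides.  Writes results/frame_comparison.tsv and
results/indel_calls.tsv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from scrkit.orthoevo import (
    compare_orthologs,
    conservation_profile,
    detect_insertions,
    render_conservation,
)
from scrkit.synthdata import OrthologSet, make_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    anc = make_fixture("ancestral_like")
    hom = make_fixture("hominini_like")
    mouse = make_fixture("mouse_like")

    calls = detect_insertions(anc.utr3, hom.utr3)
    OUT.mkdir(exist_ok=True)
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        OUT / "indel_calls.tsv", sep="\t", index=False
    )
    call = calls[0]
    print(
        f"indel call: {call.kind} of '{call.bases}' at offset {call.pos} after "
        "the canonical stop (1-based, in the insertion-carrying sequence)"
    )

    family = OrthologSet(
        taxa=["hominini_like", "ancestral_like", "mouse_like"],
        utr3_by_taxon={t.id: t.utr3 for t in (hom, anc, mouse)},
        reference_taxon="hominini_like",
    )
    frames = compare_orthologs(family, threshold_aa=28)
    frame_tbl = pd.DataFrame([dataclasses.asdict(f) for f in frames])
    frame_tbl.to_csv(OUT / "frame_comparison.tsv", sep="\t", index=False)
    print("\n" + frame_tbl.drop(columns="extension_seq").to_string(index=False))

    width = min(len(f.extension_seq) for f in frames)
    rows = [f.extension_seq[:width] for f in frames]
    prof = conservation_profile(rows)
    print("\nextension conservation (truncated to shortest):")
    print(render_conservation(rows, prof))
    print(f"conserved fraction: {prof.conserved_fraction:.2f}")
    print(
        "\nThe single-base insertion moves the first in-frame stop: the "
        "insertion-carrying UTR encodes a 28-aa decoded extension, the "
        "others stop short (<=19 aa)."
    )


if __name__ == "__main__":
    main()
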