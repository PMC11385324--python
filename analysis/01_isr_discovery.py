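#!/usr/bin/env python
"""ISR discovery and extension translation on the named transcript fixtures.

Scans each fixture's 3'UTR for the first downstream in-frame stop, reports
the inter-stop-codon region (length, span including the downstream stop) and
the decoded C-terminal extension, and writes results/isr_scan.tsv.
"""

from pathlib import Path

import pandas as pd

from scrkit.seqcore import find_isr, translate_extension
from scrkit.synthdata import FIXTURE_NAMES, make_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for name in FIXTURE_NAMES:
        t = make_fixture(name)
        isr = find_isr(t)
        ext = translate_extension(isr, "decode_as_X")
        rows.append(
            {
                "transcript_id": t.id,
                "start_offset": isr.start_offset,
                "length_nt": isr.length_nt,
                "downstream_stop": isr.downstream_stop or "open_ended",
                "span_nt": isr.span_nt,
                "ext_len_aa": ext.length_aa,
                "extension_aa": ext.residues,
            }
        )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "isr_scan.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    hom = frame.set_index("transcript_id").loc["hominini_like"]
    print(
        f"\nhominini_like: {hom.length_nt}-nt ISR ({hom.span_nt} nt with its "
        f"downstream stop) -> {hom.ext_len_aa}-aa decoded extension; the "
        "mouse_like 51-nt ISR reaches only 18 aa."
    )


if __name__ == "__main__":
    main()
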