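"""Independent oracles shared by module and acceptance tests.

These deliberately avoid the code paths they check: the codon table is an
explicit 64-entry lookup, the stop scan enumerates codon windows naively,
and the alignment score oracle enumerates every global alignment path.
"""

from __future__ import annotations

from typing import Optional

_BASES = "TCAG"
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
#: Independent 64-entry standard-code lookup (TCAG ordering).
CODON_TABLE = {
    a + b + c: _AA_ORDER[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(seq: str) -> str:
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def oracle_first_stop(utr: str) -> Optional[int]:
    """0-based nt index of the first in-frame stop codon, scanning windows."""
    for i in range(0, len(utr) - 2, 3):
        if CODON_TABLE[utr[i : i + 3]] == "*":
            return i
    return None


def oracle_align_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Best global alignment score by exhaustive path enumeration (tiny inputs)."""

    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)
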