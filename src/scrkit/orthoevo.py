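"""Cross-species ISR comparison: pairwise alignment, indel calling, frame classification.

A single-base insertion in the proximal 3'UTR shifts the readthrough frame
and can move the first downstream in-frame stop, lengthening or truncating
the extension encoded by the ISR.  This module aligns orthologous 3'UTRs
with a Needleman-Wunsch global aligner (linear gap penalty, deterministic
leftmost gap placement), calls insertions relative to a reference, classifies
each taxon's extension length, and profiles per-column conservation of the
extension peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ConfigError, ShapeError
from .seqcore import scan_utr, translate_extension


@dataclass(frozen=True)
class ScoringScheme:
    """Linear-gap alignment scores; defaults suit near-identical proximal UTRs."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass(frozen=True)
class OrthologSet:
    taxa: Sequence[str]
    utr3_by_taxon: Mapping[str, str]
    reference_taxon: str

    def __post_init__(self) -> None:
        if self.reference_taxon not in self.taxa:
            raise ConfigError(f"reference taxon {self.reference_taxon!r} not in taxa")


@dataclass(frozen=True)
class IndelCall:
    """One insertion/deletion call; ``pos`` is 1-based in the non-reference
    (alternate) sequence's own coordinates, counting from the first base after
    the canonical stop.  For deletions ``pos`` is the alternate-coordinate
    position the deleted bases would occupy.  Leftmost placement within
    homopolymer runs is canonical; ``run_span`` records the equivalent span."""

    kind: str  # "insertion" | "deletion"
    pos: int
    bases: str
    run_span: tuple[int, int] = (0, 0)

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class FrameComparison:
    taxon: str
    isr_len_nt: int
    ext_len_aa: int
    extension_seq: str
    category: str  # long_extension | short_extension | open_ended


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column residue frequencies; a column is conserved when every row
    shows the same single non-gap residue."""

    columns: Sequence[tuple[int, dict, bool]] = field(default_factory=tuple)

    @property
    def conserved_fraction(self) -> float:
        if not self.columns:
            return 0.0
        return sum(1 for _, _, c in self.columns if c) / len(self.columns)


def global_align(
    a: str, b: str, scoring: ScoringScheme = ScoringScheme()
) -> tuple[str, str, float]:
    """Optimal global alignment (Needleman-Wunsch, linear gaps).

    Ties are broken deterministically and gap columns are slid as far left as
    the score allows (gaps in ``b`` first, then in ``a``), so equal-scoring
    placements within repeats resolve to the leftmost.
    """
    if not a or not b:
        raise ConfigError("global_align requires non-empty sequences")
    n, m = len(a), len(b)
    gap = scoring.gap
    prev = [j * gap for j in range(m + 1)]
    trace = []  # trace[i][j] in {0: diag, 1: up (gap in b), 2: left (gap in a)}
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur = [i * gap] + [0.0] * m
        row = [1] + [0] * m
        for j in range(1, m + 1):
            d = prev[j - 1] + (scoring.match if ai == b[j - 1] else scoring.mismatch)
            u = prev[j] + gap
            l = cur[j - 1] + gap
            # preference: diagonal, then gap in b, then gap in a
            if d >= u and d >= l:
                cur[j], row[j] = d, 0
            elif u >= l:
                cur[j], row[j] = u, 1
            else:
                cur[j], row[j] = l, 2
        trace.append(row)
        prev = cur
    score = prev[m]
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        move = trace[i - 1][j] if i > 0 else 2
        if j == 0:
            move = 1
        if move == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif move == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aln_a = "".join(reversed(out_a))
    aln_b = "".join(reversed(out_b))
    aln_b, aln_a = _push_gaps_left(aln_b, aln_a, scoring)
    aln_a, aln_b = _push_gaps_left(aln_a, aln_b, scoring)
    return aln_a, aln_b, score


def _push_gaps_left(gapped: str, other: str, scoring: ScoringScheme) -> tuple[str, str]:
    """Slide each maximal gap run in ``gapped`` leftward, one column at a
    time and as a unit, while the move preserves the alignment score
    (canonical leftmost placement within repeats)."""
    g = list(gapped)
    o = list(other)

    def colscore(x: str, y: str) -> float:
        if x == "-" or y == "-":
            return scoring.gap
        return scoring.match if x == y else scoring.mismatch

    changed = True
    while changed:
        changed = False
        j = 0
        while j < len(g):
            if g[j] != "-":
                j += 1
                continue
            j0 = j
            while j < len(g) and g[j] == "-":
                j += 1
            j1 = j - 1  # run = [j0, j1]
            # shifting the run left moves the char at j0-1 to column j1
            if j0 > 0 and g[j0 - 1] != "-" and o[j0 - 1] != "-" and o[j1] != "-":
                ch = g[j0 - 1]
                if colscore(ch, o[j1]) >= colscore(ch, o[j0 - 1]):
                    g[j0 - 1 : j1 + 1] = ["-"] * (j1 - j0 + 1) + [ch]
                    changed = True
    return "".join(g), "".join(o)


def detect_insertions(ref_utr: str, alt_utr: str, scoring: ScoringScheme = ScoringScheme()) -> list[IndelCall]:
    """Call indels in ``alt_utr`` relative to ``ref_utr``.

    Gap columns in the reference row become insertions in the alternate
    sequence (adjacent columns merged into one call); gap columns in the
    alternate row become deletions.  Positions are 1-based in alternate
    coordinates.  ``run_span`` marks the homopolymer run containing the call
    site, within which placement is ambiguous.
    """
    aln_ref, aln_alt, _ = global_align(ref_utr, alt_utr, scoring)
    calls: list[IndelCall] = []
    alt_pos = 0  # bases of alt consumed
    col = 0
    L = len(aln_ref)
    while col < L:
        if aln_ref[col] == "-":
            start_alt = alt_pos + 1
            bases = []
            while col < L and aln_ref[col] == "-":
                bases.append(aln_alt[col])
                alt_pos += 1
                col += 1
            calls.append(
                IndelCall("insertion", start_alt, "".join(bases),
                          run_span=_homopolymer_run(alt_utr, start_alt))
            )
        elif aln_alt[col] == "-":
            bases = []
            while col < L and aln_alt[col] == "-":
                bases.append(aln_ref[col])
                col += 1
            calls.append(
                IndelCall("deletion", alt_pos + 1, "".join(bases),
                          run_span=_homopolymer_run(alt_utr, min(alt_pos + 1, len(alt_utr))))
            )
        else:
            alt_pos += 1
            col += 1
    return calls


def _homopolymer_run(seq: str, pos: int) -> tuple[int, int]:
    """1-based inclusive span of the homopolymer run containing ``pos``."""
    if not seq:
        return (0, 0)
    i = min(max(pos, 1), len(seq)) - 1
    base = seq[i]
    lo = i
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = i
    while hi + 1 < len(seq) and seq[hi + 1] == base:
        hi += 1
    return (lo + 1, hi + 1)


def compare_orthologs(s: OrthologSet, threshold_aa: int = 28) -> list[FrameComparison]:
    """Classify each taxon's readthrough extension (stop decoded as X).

    ``long_extension`` when the decoded extension reaches ``threshold_aa``
    residues; ``short_extension`` below it; ``open_ended`` when the 3'UTR
    holds no downstream in-frame stop.  Output order follows input taxa.
    """
    out = []
    for taxon in s.taxa:
        isr = scan_utr(s.utr3_by_taxon[taxon], taxon)
        ext = translate_extension(isr, "decode_as_X")
        if isr.open_ended:
            cat = "open_ended"
        elif ext.length_aa >= threshold_aa:
            cat = "long_extension"
        else:
            cat = "short_extension"
        out.append(
            FrameComparison(taxon, isr.length_nt, ext.length_aa, ext.residues, cat)
        )
    return out


def star_align(reference: str, others: Sequence[str], scoring: ScoringScheme = ScoringScheme()) -> list[str]:
    """Project pairwise alignments onto reference coordinates (star alignment).

    Each row is the other sequence written in reference columns: positions
    deleted relative to the reference show ``-``; insertions relative to the
    reference are dropped.  Adequate for per-column conservation display on
    near-identical families; not a full MSA.
    """
    rows = [reference]
    for seq in others:
        aln_ref, aln_other, _ = global_align(reference, seq, scoring)
        rows.append("".join(o for r, o in zip(aln_ref, aln_other) if r != "-"))
    return rows


def conservation_profile(peptides: Sequence[str]) -> ConservationProfile:
    """Per-column conservation over equal-length aligned amino-acid strings."""
    if not peptides:
        return ConservationProfile()
    L = len(peptides[0])
    if any(len(p) != L for p in peptides):
        raise ShapeError("aligned peptides must have equal lengths")
    cols = []
    for i in range(L):
        residues = [p[i] for p in peptides]
        non_gap = [r for r in residues if r != "-"]
        freq: dict[str, float] = {}
        for r in non_gap:
            freq[r] = freq.get(r, 0.0) + 1.0
        total = sum(freq.values())
        if total:
            freq = {r: c / total for r, c in freq.items()}
        conserved = len(non_gap) == len(residues) and len(set(non_gap)) == 1
        cols.append((i + 1, freq, conserved))
    return ConservationProfile(columns=tuple(cols))


def render_conservation(rows: Sequence[str], profile: Optional[ConservationProfile] = None) -> str:
    """Text mosaic: aligned rows plus a ``*`` line under conserved columns."""
    if profile is None:
        profile = conservation_profile(rows)
    marks = "".join("*" if c else " " for _, _, c in profile.columns)
    return "\n".join([*rows, marks])
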