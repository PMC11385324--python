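"""Transcript model, inter-stop-codon-region (ISR) discovery and extension translation.

A transcript carries a CDS whose final codon is the canonical stop, plus a
3'UTR.  Stop-codon readthrough (SCR) continues translation past the canonical
stop in the same frame until the next in-frame stop; the 3'UTR segment between
the two stops (exclusive of both) is the inter-stop-codon region (ISR).  This
module finds the ISR, translates the resulting C-terminal extension under a
configurable stop-decoding policy, and assembles readthrough reporter
constructs (CDS fragment - stop - ISR - linker - reporter) in a single frame.

Coordinates are 1-based and inclusive throughout; offset 1 is the first
nucleotide after the canonical stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .errors import AlphabetError, FrameError, PolicyError, StructureError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_NT = frozenset("ACGT")


@dataclass(frozen=True)
class Transcript:
    """A transcript: CDS (including its stop codon) plus 3'UTR.

    The CDS keeps its terminal stop codon so the transcript itself is the
    single source of truth for the canonical stop identity.
    """

    id: str
    cds: str
    utr3: str = ""

    @property
    def stop_codon(self) -> str:
        return self.cds[-3:]

    def __post_init__(self) -> None:
        _validate_transcript(self.cds, self.utr3)


@dataclass(frozen=True)
class IsrRecord:
    """The inter-stop-codon region of one transcript.

    ``start_offset`` is always 1 (first base after the canonical stop);
    ``span_nt`` adds the downstream stop codon to ``length_nt`` when one
    exists.  An ISR with no downstream in-frame stop within complete codons
    is *open-ended*: ``downstream_stop`` is None and ``length_nt`` is the
    largest multiple of 3 that fits in the 3'UTR.
    """

    transcript_id: str
    length_nt: int
    seq: str
    downstream_stop: Optional[str] = None
    start_offset: int = 1

    @property
    def open_ended(self) -> bool:
        return self.downstream_stop is None

    @property
    def span_nt(self) -> int:
        return self.length_nt + (0 if self.open_ended else 3)


@dataclass(frozen=True)
class ExtensionPeptide:
    """Amino-acid extension appended by readthrough.

    ``stop_residue`` is the residue decoded at the canonical stop position
    (prepended to the ISR-encoded residues), or None when the policy excludes
    the stop.
    """

    residues: str
    stop_residue: Optional[str]

    @property
    def length_aa(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReporterConstruct:
    """An in-frame readthrough reporter assembly."""

    name: str
    parts: Sequence[tuple[str, str]] = field(default_factory=tuple)

    @property
    def full_seq(self) -> str:
        return "".join(seq for _, seq in self.parts)

    def part_start(self, label: str) -> int:
        """1-based start of the first part with this label in ``full_seq``."""
        offset = 0
        for name, seq in self.parts:
            if name == label:
                return offset + 1
            offset += len(seq)
        raise KeyError(label)


def normalize_sequence(raw: str, *, what: str = "sequence") -> str:
    """Uppercase, map U->T and validate the A/C/G/T alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _NT
    if bad:
        raise AlphabetError(
            f"{what} contains non-nucleotide characters: {sorted(bad)!r}"
        )
    return seq


def _validate_transcript(cds: str, utr3: str) -> None:
    if not cds:
        raise StructureError("CDS must be non-empty")
    if set(cds) - _NT or set(utr3) - _NT:
        raise AlphabetError("transcript sequences must be normalized A/C/G/T")
    if len(cds) % 3 != 0:
        raise StructureError(f"CDS length {len(cds)} not divisible by 3")
    if cds[-3:] not in STOP_CODONS:
        raise StructureError(f"CDS does not end in a stop codon (got {cds[-3:]!r})")


def normalize_transcript(raw_cds: str, raw_utr3: str, id: str) -> Transcript:
    """Build a validated :class:`Transcript` from raw sequence strings."""
    cds = normalize_sequence(raw_cds, what=f"CDS of {id!r}")
    utr3 = normalize_sequence(raw_utr3, what=f"3'UTR of {id!r}") if raw_utr3 else ""
    return Transcript(id=id, cds=cds, utr3=utr3)


def scan_utr(utr3: str, transcript_id: str = "") -> IsrRecord:
    """Scan a 3'UTR codon-by-codon in the frame continuing from the stop.

    Returns the region before the first in-frame stop codon; open-ended if
    no stop occurs within complete codons (empty UTRs included).
    """
    for i in range(0, len(utr3) - 2, 3):
        codon = utr3[i : i + 3]
        if codon in STOP_CODONS:
            return IsrRecord(
                transcript_id=transcript_id,
                length_nt=i,
                seq=utr3[:i],
                downstream_stop=codon,
            )
    n = 3 * (len(utr3) // 3)
    return IsrRecord(transcript_id=transcript_id, length_nt=n, seq=utr3[:n])


def find_isr(t: Transcript) -> IsrRecord:
    """Locate the ISR of a transcript in the canonical reading frame."""
    return scan_utr(t.utr3, t.id)


def translate_codons(seq: str, *, allow_stop: bool = False) -> str:
    """Translate a frame-complete DNA string with the standard nuclear code.

    Stop codons render as ``*`` only when ``allow_stop`` is set; otherwise an
    in-frame stop raises :class:`FrameError`.
    """
    if len(seq) % 3 != 0:
        raise FrameError(f"sequence length {len(seq)} not divisible by 3")
    aa = str(Seq(seq).translate())
    if not allow_stop and "*" in aa:
        raise FrameError("in-frame stop codon in sequence (allow_stop not set)")
    return aa


def translate_extension(
    isr: IsrRecord,
    stop_policy: str = "exclude",
) -> ExtensionPeptide:
    """Translate the readthrough extension encoded by an ISR.

    ``stop_policy`` is one of:

    - ``"exclude"`` — ISR residues only (the canonical stop contributes no
      residue);
    - ``"decode_as_X"`` — prepend ``X`` for the decoded stop (the identity of
      the near-cognate insertion is not modelled);
    - ``"decode_as:<aa>"`` — prepend a specific one-letter residue, e.g.
      ``"decode_as:Q"``.
    """
    body = translate_codons(isr.seq)
    if stop_policy == "exclude":
        return ExtensionPeptide(residues=body, stop_residue=None)
    if stop_policy == "decode_as_X":
        residue = "X"
    elif stop_policy.startswith("decode_as:"):
        residue = stop_policy.split(":", 1)[1]
        if len(residue) != 1 or residue not in AMINO_ACIDS:
            raise PolicyError(f"invalid decoded residue {residue!r}")
    else:
        raise PolicyError(f"unknown stop policy {stop_policy!r}")
    return ExtensionPeptide(residues=residue + body, stop_residue=residue)


def assemble_reporter(
    cds_fragment: str,
    stop: Optional[str],
    isr: str,
    linker: str,
    reporter_cds: str,
    mode: str = "readthrough_test",
) -> ReporterConstruct:
    """Assemble an SCR reporter in one reading frame.

    Part order is ``cds_fragment . [stop] . [isr] . linker . reporter`` with
    the reporter's initiator ATG removed, so the reporter is produced only by
    readthrough of the upstream stop.  ``no_stop_control`` omits the stop
    (constitutive reporter expression, the 100% anchor); ``no_isr_control``
    omits the ISR (background readthrough).
    """
    if mode not in {"readthrough_test", "no_stop_control", "no_isr_control"}:
        raise PolicyError(f"unknown reporter mode {mode!r}")
    if not reporter_cds.startswith("ATG"):
        raise StructureError("reporter CDS must start with ATG (removed on assembly)")
    parts: list[tuple[str, str]] = [("cds_fragment", cds_fragment)]
    if mode != "no_stop_control":
        if stop is None or stop not in STOP_CODONS:
            raise StructureError(f"mode {mode!r} requires a stop codon, got {stop!r}")
        parts.append(("stop", stop))
    if mode != "no_isr_control":
        parts.append(("isr", isr))
    parts.append(("linker", linker))
    parts.append(("reporter", reporter_cds[3:]))
    offset = 0
    for label, seq in parts:
        if len(seq) % 3 != 0:
            raise FrameError(
                f"part {label!r} (len {len(seq)}) breaks the reading frame"
            )
        offset += len(seq)
    return ReporterConstruct(name=mode, parts=tuple(parts))
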