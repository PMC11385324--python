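"""Readthrough proteoform database, in-silico tryptic digestion and peptide matching.

At a readthrough event the stop codon is decoded by a near-cognate tRNA, so
the extended proteoform may carry any of the 20 standard amino acids at the
stop position.  The database built here therefore holds 20 readthrough
variants (one per substitution) plus the canonical proteoform, and scored
peptide identifications (e.g. a MaxQuant peptides table) are matched against
it by exact substring search, classified by how they overlap the ISR-encoded
extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO

from .errors import StructureError
from .seqcore import AMINO_ACIDS, Transcript, find_isr, translate_codons

CANONICAL = "canonical"


@dataclass(frozen=True)
class Proteoform:
    """One protein isoform: canonical, or readthrough with a specific stop decoding.

    ``extension_start`` is the 1-based residue index of the decoded-stop
    residue; the canonical form ends at ``extension_start - 1``.
    """

    base_id: str
    substituted_aa: str  # one-letter code, or "canonical"
    sequence: str
    extension_start: int

    @property
    def header(self) -> str:
        tag = CANONICAL if self.substituted_aa == CANONICAL else f"rt_{self.substituted_aa}"
        return f"{self.base_id}|{tag}"


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    score: float
    source: str = ""


@dataclass(frozen=True)
class PeptideMatch:
    """A peptide located on the proteoform database.

    ``overlap_class`` summarises the best hit: ``extension_internal`` (fully
    within the decoded extension), ``junction_spanning`` (straddles the
    substituted residue), ``canonical_only`` or ``no_hit``.
    ``unique_in_reference`` stays None until checked against a reference
    proteome.
    """

    peptide: PeptideRecord
    proteoform_hits: Sequence[tuple[str, str, int, int]] = field(default_factory=tuple)
    overlap_class: str = "no_hit"
    unique_in_reference: Optional[bool] = None


def build_readthrough_db(t: Transcript, base_id: Optional[str] = None) -> list[Proteoform]:
    """Build the 20-substitution readthrough database plus the canonical form.

    Readthrough sequence = CDS translation + substituted residue + ISR
    translation.  Requires a closed ISR (a downstream in-frame stop).
    """
    isr = find_isr(t)
    if isr.open_ended:
        raise StructureError(
            f"transcript {t.id!r} has an open-ended ISR; readthrough product undefined"
        )
    base_id = base_id or t.id
    canonical_aa = translate_codons(t.cds[:-3])
    ext_aa = translate_codons(isr.seq)
    ext_start = len(canonical_aa) + 1
    db = [
        Proteoform(base_id, aa, canonical_aa + aa + ext_aa, ext_start)
        for aa in AMINO_ACIDS
    ]
    db.append(Proteoform(base_id, CANONICAL, canonical_aa, ext_start))
    return db


def tryptic_digest(
    p: Union[Proteoform, str], missed_cleavages: int = 0
) -> list[tuple[str, int, int]]:
    """Tryptic peptides with 1-based inclusive coordinates.

    Cleaves C-terminal of K or R except before P; emits every peptide with at
    most ``missed_cleavages`` internal cleavage sites.
    """
    seq = p.sequence if isinstance(p, Proteoform) else p
    if not seq:
        return []
    # boundaries[i] is a 0-based index where a fragment starts
    boundaries = [0]
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR" and seq[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(seq))
    out = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            out.append((seq[start:end], start + 1, end))
    return out


def filter_by_score(
    records: Iterable[PeptideRecord], threshold: float = 70.0
) -> list[PeptideRecord]:
    """Keep peptides with score strictly greater than the threshold."""
    return [r for r in records if r.score > threshold]


_CLASS_RANK = {"no_hit": 0, "canonical_only": 1, "junction_spanning": 2, "extension_internal": 3}


def map_to_isr_region(
    pep: PeptideRecord,
    db: Sequence[Proteoform],
    *,
    collapse_il: bool = False,
) -> PeptideMatch:
    """Locate a peptide on every proteoform and classify its extension overlap.

    Exact substring search (every occurrence); with ``collapse_il`` isoleucine
    and leucine are treated as equivalent.  The reported class is the
    strongest across hits: a hit starting at or after ``extension_start`` is
    ``extension_internal``; one straddling it is ``junction_spanning``.
    """
    fold = (lambda s: s.replace("I", "L")) if collapse_il else (lambda s: s)
    query = fold(pep.sequence)
    hits: list[tuple[str, str, int, int]] = []
    best = "no_hit"
    for pf in db:
        hay = fold(pf.sequence)
        start = hay.find(query)
        while start != -1:
            s1, e1 = start + 1, start + len(query)  # 1-based inclusive
            hits.append((pf.base_id, pf.substituted_aa, s1, e1))
            if pf.substituted_aa == CANONICAL or e1 < pf.extension_start:
                cls = "canonical_only"
            elif s1 >= pf.extension_start:
                cls = "extension_internal"
            else:
                cls = "junction_spanning"
            if _CLASS_RANK[cls] > _CLASS_RANK[best]:
                best = cls
            start = hay.find(query, start + 1)
    return PeptideMatch(peptide=pep, proteoform_hits=tuple(hits), overlap_class=best)


def check_uniqueness(
    pep: PeptideRecord, reference_proteome: Union[str, PathLike]
) -> bool:
    """True iff the peptide occurs in no entry of the reference proteome FASTA."""
    for rec in SeqIO.parse(str(reference_proteome), "fasta"):
        if pep.sequence in str(rec.seq).upper():
            return False
    return True


def write_db_fasta(db: Sequence[Proteoform], path: Union[str, PathLike]) -> None:
    """Write the proteoform database as FASTA (headers ``{base_id}|rt_{aa}``)."""
    with open(path, "w") as fh:
        for pf in db:
            fh.write(f">{pf.header}\n{pf.sequence}\n")
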