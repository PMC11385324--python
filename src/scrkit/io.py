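"""File I/O: transcript FASTA conventions, peptide/reporter/coverage TSVs.

Transcripts can be stored two ways (both read and written here):

1. two-record convention — each transcript contributes records ``{id}|cds``
   and ``{id}|utr3`` (the utr3 record may be omitted when empty);
2. single-record + sidecar — one record per transcript holding cds+utr3,
   with a TSV sidecar of columns ``id``, ``cds_len`` giving the boundary.
"""

from __future__ import annotations

from os import PathLike
from typing import Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataError
from .orthoevo import OrthologSet
from .proteoform import PeptideRecord
from .ribosignal import FootprintProfile
from .seqcore import Transcript, normalize_transcript

PathArg = Union[str, PathLike]


def read_transcripts(
    fasta: PathArg, boundary_tsv: PathArg | None = None
) -> list[Transcript]:
    """Read transcripts from FASTA (two-record or single-record+sidecar)."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    if boundary_tsv is not None:
        table = pd.read_csv(boundary_tsv, sep="\t")
        if not {"id", "cds_len"} <= set(table.columns):
            raise DataError("boundary sidecar needs columns 'id' and 'cds_len'")
        out = []
        for row in table.itertuples():
            seq = records[str(row.id)]
            n = int(row.cds_len)
            out.append(normalize_transcript(seq[:n], seq[n:], str(row.id)))
        return out
    ids = []
    for rid in records:
        if rid.endswith("|cds"):
            ids.append(rid[: -len("|cds")])
    if not ids:
        raise DataError(
            "no '|cds' records found; for single-record FASTA pass boundary_tsv"
        )
    return [
        normalize_transcript(records[f"{tid}|cds"], records.get(f"{tid}|utr3", ""), tid)
        for tid in ids
    ]


def write_transcripts(transcripts: Sequence[Transcript], fasta: PathArg) -> None:
    """Write transcripts in the two-record convention."""
    with open(fasta, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}|cds\n{t.cds}\n")
            if t.utr3:
                fh.write(f">{t.id}|utr3\n{t.utr3}\n")


def read_ortholog_set(fasta: PathArg, reference_taxon: str) -> OrthologSet:
    """Read an ortholog 3'UTR family (record id = taxon id)."""
    utrs = {}
    taxa = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        taxa.append(rec.id)
        utrs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return OrthologSet(taxa=taxa, utr3_by_taxon=utrs, reference_taxon=reference_taxon)


def write_ortholog_set(s: OrthologSet, fasta: PathArg) -> None:
    with open(fasta, "w") as fh:
        for taxon in s.taxa:
            fh.write(f">{taxon}\n{s.utr3_by_taxon[taxon]}\n")


def read_peptide_table(tsv: PathArg) -> list[PeptideRecord]:
    """Scored peptide TSV: required columns ``sequence`` and ``score``
    (extra columns, e.g. the rest of a MaxQuant peptides table, ignored)."""
    table = pd.read_csv(tsv, sep="\t")
    cols = {c.lower(): c for c in table.columns}
    if "sequence" not in cols or "score" not in cols:
        raise DataError("peptide table needs 'sequence' and 'score' columns")
    return [
        PeptideRecord(str(row[cols["sequence"]]).upper(), float(row[cols["score"]]))
        for _, row in table.iterrows()
    ]


def write_peptide_table(records: Sequence[PeptideRecord], tsv: PathArg) -> None:
    pd.DataFrame(
        [{"sequence": r.sequence, "score": r.score, "source": r.source} for r in records]
    ).to_csv(tsv, sep="\t", index=False)


def read_luciferase_table(tsv: PathArg) -> pd.DataFrame:
    """Reporter replicate TSV: construct, replicate, fluc, rluc."""
    table = pd.read_csv(tsv, sep="\t")
    missing = {"construct", "fluc", "rluc"} - set(table.columns)
    if missing:
        raise DataError(f"luciferase table missing columns {sorted(missing)}")
    return table


def read_coverage(tsv: PathArg, transcript_id: str, length: int) -> FootprintProfile:
    """Transcript-relative coverage TSV (transcript_id, pos, count; 1-based).

    Positions absent from the table count zero; the profile is materialised
    to the full transcript length.
    """
    table = pd.read_csv(tsv, sep="\t")
    missing = {"transcript_id", "pos", "count"} - set(table.columns)
    if missing:
        raise DataError(f"coverage table missing columns {sorted(missing)}")
    sub = table[table["transcript_id"] == transcript_id]
    counts = np.zeros(length, dtype=int)
    pos = sub["pos"].to_numpy(dtype=int)
    if len(pos) and (pos.min() < 1 or pos.max() > length):
        raise DataError("coverage positions outside transcript bounds")
    counts[pos - 1] = sub["count"].to_numpy(dtype=int)
    return FootprintProfile(transcript_id=transcript_id, counts=counts)


def write_coverage(p: FootprintProfile, tsv: PathArg) -> None:
    pd.DataFrame(
        {
            "transcript_id": p.transcript_id,
            "pos": range(1, len(p.counts) + 1),
            "count": p.counts,
        }
    ).to_csv(tsv, sep="\t", index=False)
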