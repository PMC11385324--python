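"""Region-density readthrough signal from transcript-relative footprint coverage.

Ribosome footprints between the canonical stop and the next in-frame stop are
direct evidence of readthrough.  Given per-nucleotide footprint counts over
cds+utr3, this module computes mean densities over the CDS, the ISR and the
distal 3'UTR (both stop codons excluded from every region), a readthrough
ratio isr/cds, and a permutation test for ISR-over-distal enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError, ShapeError, StructureError
from .seqcore import IsrRecord, Transcript


@dataclass(frozen=True)
class FootprintProfile:
    """Per-nucleotide footprint counts, 1-based over cds+utr3."""

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 1:
            raise ShapeError("counts must be one-dimensional")
        if np.any(counts < 0):
            raise ShapeError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ReadthroughSignal:
    """Mean densities (counts/nt) per region and the readthrough ratio.

    ``ratio`` (isr/cds) is None when the CDS density is zero;
    ``distal_density`` and ``isr_vs_distal_enrichment`` are None when there
    is no distal region (or its density is zero, for the enrichment).
    """

    cds_density: float
    isr_density: float
    distal_density: Optional[float]
    ratio: Optional[float]
    isr_vs_distal_enrichment: Optional[float]


def _regions(t: Transcript, isr: IsrRecord) -> tuple[slice, slice, slice]:
    """0-based slices for (CDS minus stop, ISR, distal beyond downstream stop)."""
    if isr.open_ended:
        raise StructureError("region densities require a closed ISR")
    cds_end = len(t.cds)
    return (
        slice(0, cds_end - 3),
        slice(cds_end, cds_end + isr.length_nt),
        slice(cds_end + isr.span_nt, cds_end + len(t.utr3)),
    )


def region_densities(
    p: FootprintProfile, t: Transcript, isr: IsrRecord
) -> ReadthroughSignal:
    """Mean footprint density over CDS, ISR and distal 3'UTR regions."""
    expected = len(t.cds) + len(t.utr3)
    if len(p.counts) != expected:
        raise ShapeError(
            f"profile length {len(p.counts)} != transcript length {expected}"
        )
    cds_sl, isr_sl, distal_sl = _regions(t, isr)
    cds_density = float(np.mean(p.counts[cds_sl]))
    isr_density = float(np.mean(p.counts[isr_sl])) if isr.length_nt else 0.0
    distal = p.counts[distal_sl]
    distal_density = float(np.mean(distal)) if distal.size else None
    ratio = isr_density / cds_density if cds_density > 0 else None
    enrichment = (
        isr_density / distal_density
        if distal_density is not None and distal_density > 0
        else None
    )
    return ReadthroughSignal(cds_density, isr_density, distal_density, ratio, enrichment)


def readthrough_enrichment_test(
    p: FootprintProfile,
    t: Transcript,
    isr: IsrRecord,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for ISR density exceeding distal density.

    Per-nucleotide counts across the combined 3'UTR positions (ISR + distal,
    stops excluded) are shuffled ``n_perm`` times; the statistic is the
    density difference isr - distal, and p = (1 + #{perm >= observed}) /
    (1 + n_perm).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be at least 1")
    expected = len(t.cds) + len(t.utr3)
    if len(p.counts) != expected:
        raise ShapeError("profile length does not match transcript")
    _, isr_sl, distal_sl = _regions(t, isr)
    isr_counts = p.counts[isr_sl]
    distal_counts = p.counts[distal_sl]
    if isr_counts.size == 0 or distal_counts.size == 0:
        raise StructureError("enrichment test needs non-empty ISR and distal regions")
    observed = float(np.mean(isr_counts) - np.mean(distal_counts))
    combined = np.concatenate([isr_counts, distal_counts])
    k = isr_counts.size
    rng = np.random.default_rng(seed)
    # one shuffled matrix: rows are permutations of the combined counts
    perm = rng.permuted(np.tile(combined, (n_perm, 1)), axis=1)
    stat = perm[:, :k].mean(axis=1) - perm[:, k:].mean(axis=1)
    return float((1 + np.sum(stat >= observed)) / (1 + n_perm))
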