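"""Seeded generators and named fixtures for every input the pipeline consumes.

All sequence fixtures here are synthetic constructions: the study-scale
parameters (an 81-nt human-like ISR spanning 84 nt with its downstream stop,
a 51-nt rodent-like ISR, a single 'T' inserted at position 53 after the
canonical stop, readthrough fractions of 0.17 and 0.34, a >70 peptide score
threshold anchored at 143.37) are real reported quantities, but the literal
nucleotide sequences are generated in-repo, deterministically, because no
machine-readable sequence is distributed with them.

Generators draw from ``numpy.random.default_rng(cfg.seed)`` and are
bit-reproducible under a fixed (seed, config) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .orthoevo import OrthologSet
from .proteoform import PeptideRecord, Proteoform, tryptic_digest
from .ribosignal import FootprintProfile
from .seqcore import STOP_CODONS, IsrRecord, Transcript

#: Sense codons of the standard nuclear code (all 64 minus the three stops).
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study-scale conditions.

    theta is the true readthrough fraction (0.17 in-cell, 0.34 in vitro for
    the human ISR); noise_cv the lognormal coefficient of variation of the
    reporter channels; lambda_cds the mean footprint count per CDS
    nucleotide, with ISR rate theta*lambda_cds and a distal background rate.
    """

    seed: int = 0
    cds_len_nt: int = 93  # includes the terminal stop codon
    isr_len_nt: int = 81
    insertion_offset: Optional[int] = 53
    theta: float = 0.17
    noise_cv: float = 0.10
    n_replicates: int = 3
    lambda_cds: float = 100.0
    distal_lambda: float = 1.0
    n_taxa: int = 22
    sub_rate: float = 0.02
    distal_len_nt: int = 45

    def __post_init__(self) -> None:
        if self.cds_len_nt < 6 or self.cds_len_nt % 3:
            raise ConfigError("cds_len_nt must be a multiple of 3, at least 6")
        if self.isr_len_nt < 0 or self.isr_len_nt % 3:
            raise ConfigError("isr_len_nt must be a non-negative multiple of 3")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigError("theta must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be at least 1")
        if self.lambda_cds <= 0 or self.distal_lambda < 0:
            raise ConfigError("footprint rates must be positive (distal >= 0)")
        if not 0.0 <= self.sub_rate < 1.0:
            raise ConfigError("sub_rate must lie in [0, 1)")


# --------------------------------------------------------------------------
# named fixtures (deterministic, no RNG)
#
# The human-like fixture encodes a 27-residue ISR peptide whose first 23
# residues are the experimentally anchored VTGYVKSFNVVLKSKGLLITDSR context
# (antibody epitope VTGYVKSFNVVLKSKGL; tryptic evidence peptide GLLITDSR).
# Codons 18-20 are pinned (CTA ATA ACA) so that deleting the single 'T' at
# UTR offset 53 — the middle base of codon 18 — shifts the frame onto a TAA
# spanning what were offsets 56-58, restoring a short-extension structure,
# while the insertion site itself sits in no homopolymer run (the leftmost-
# placement indel call is unambiguous at 53).

_PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

#: ISR-encoded extension of the human-like fixture (27 aa).
HOMININI_EXT_AA = "VTGYVKSFNVVLKSKGLLITDSREASA"
#: ISR-encoded extension of the rodent-like fixture (17 aa).
MOUSE_EXT_AA = HOMININI_EXT_AA[:17]
#: Canonical protein of all fixtures (30 aa, M-initiated).
FIXTURE_CDS_AA = "MSLENQARTVDGHWYFCPKISEAVNQDTGK"

_HOMININI_CODON_OVERRIDES = {18: "CTA", 19: "ATA", 20: "ACA"}
_FIXTURE_CANONICAL_STOP = "TGA"  # the leaky stop class (UGA > UAG/UAA)
_FIXTURE_DOWNSTREAM_STOP = "TAA"
_FIXTURE_DISTAL = "CCAGGCTTCAAGAGCAGAGGAAGCCTGAGC"  # 30 nt

FIXTURE_NAMES = ("hominini_like", "mouse_like", "ancestral_like")


def _encode(aa_seq: str, overrides: Optional[dict[int, str]] = None) -> str:
    codons = []
    for i, aa in enumerate(aa_seq, start=1):
        codon = (overrides or {}).get(i, _PREFERRED_CODON[aa])
        codons.append(codon)
    return "".join(codons)


def _fixture_cds() -> str:
    return _encode(FIXTURE_CDS_AA) + _FIXTURE_CANONICAL_STOP


def make_fixture(name: str) -> Transcript:
    """Deterministic named transcript fixtures.

    ``hominini_like``: 81-nt ISR (84-nt span), 'T' at UTR offset 53.
    ``ancestral_like``: the same UTR with offset-53 base deleted (frame
    shifts onto an earlier stop; short extension).
    ``mouse_like``: 51-nt ISR.
    """
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    cds = _fixture_cds()
    if name == "mouse_like":
        utr = _encode(MOUSE_EXT_AA) + _FIXTURE_DOWNSTREAM_STOP + _FIXTURE_DISTAL
        return Transcript(id=name, cds=cds, utr3=utr)
    hom_utr = (
        _encode(HOMININI_EXT_AA, _HOMININI_CODON_OVERRIDES)
        + _FIXTURE_DOWNSTREAM_STOP
        + _FIXTURE_DISTAL
    )
    if name == "hominini_like":
        return Transcript(id=name, cds=cds, utr3=hom_utr)
    # ancestral_like: delete the inserted base at offset 53 (1-based)
    anc_utr = hom_utr[:52] + hom_utr[53:]
    return Transcript(id=name, cds=cds, utr3=anc_utr)


def make_fixture_pair() -> tuple[Transcript, Transcript]:
    """(ancestral_like, hominini_like) — the insertion-calling pair."""
    return make_fixture("ancestral_like"), make_fixture("hominini_like")


# --------------------------------------------------------------------------
# seeded generators


def _random_sense_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(SENSE_CODONS, size=n)) if n else ""


def _random_utr(rng: np.random.Generator, cfg: SimConfig) -> str:
    """ISR of sense codons, a random downstream stop, then a distal tail."""
    isr = _random_sense_codons(rng, cfg.isr_len_nt // 3)
    stop = rng.choice(sorted(STOP_CODONS))
    distal = "".join(rng.choice(list("ACGT"), size=cfg.distal_len_nt))
    return isr + stop + distal


def make_transcript(cfg: SimConfig) -> Transcript:
    """Random transcript whose first in-frame 3'UTR stop begins at offset
    isr_len_nt + 1 (sense codons sampled uniformly from the 61)."""
    rng = np.random.default_rng(cfg.seed)
    n_sense = cfg.cds_len_nt // 3 - 1
    cds = _random_sense_codons(rng, n_sense) + "TAA"
    return Transcript(id=f"sim_seed{cfg.seed}", cds=cds, utr3=_random_utr(rng, cfg))


def simulate_luciferase(cfg: SimConfig, constructs: Sequence[str] = ("no_stop", "test_isr")) -> pd.DataFrame:
    """Dual-luciferase replicate table at true readthrough fraction theta.

    Per replicate: rluc ~ lognormal (CV = noise_cv); fluc(no_stop) =
    k*rluc*eps; fluc(test_isr) = theta*k*rluc*eps', with eps mean-1
    lognormal multiplicative noise at noise_cv.  Returns a tidy frame with
    columns construct, replicate, fluc, rluc.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    k = 1000.0  # arbitrary instrument scale; cancels in all ratios

    def eps(n: int) -> np.ndarray:
        if sigma == 0:
            return np.ones(n)
        return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n)

    rows = []
    for construct in constructs:
        frac = {"no_stop": 1.0, "test_isr": cfg.theta}.get(construct, 0.0)
        rluc = 50.0 * eps(cfg.n_replicates)
        fluc = frac * k * rluc * eps(cfg.n_replicates)
        for r in range(cfg.n_replicates):
            rows.append(
                {"construct": construct, "replicate": r + 1,
                 "fluc": float(fluc[r]), "rluc": float(rluc[r])}
            )
    return pd.DataFrame(rows)


def make_ortholog_set(
    cfg: SimConfig, insertion_taxa: Optional[Sequence[str]] = None
) -> OrthologSet:
    """Ortholog 3'UTR family: i.i.d. substitutions at sub_rate off a common
    ancestor (downstream-stop positions protected), with a designated subset
    of taxa carrying a single-base 'T' insertion at insertion_offset.

    By default the first two taxa (including the reference) carry the
    insertion, mirroring a Hominini-restricted event.
    """
    if cfg.n_taxa < 2:
        raise ConfigError("n_taxa must be at least 2")
    rng = np.random.default_rng(cfg.seed)
    base = _random_utr(rng, cfg)
    stop_span = range(cfg.isr_len_nt, cfg.isr_len_nt + 3)  # 0-based, protected
    taxa = [f"taxon_{i + 1:02d}" for i in range(cfg.n_taxa)]
    if insertion_taxa is None:
        insertion_taxa = taxa[:2] if cfg.insertion_offset is not None else []
    bases = "ACGT"
    utrs = {}
    for taxon in taxa:
        seq = list(base)
        if cfg.sub_rate > 0:
            hits = np.nonzero(rng.random(len(seq)) < cfg.sub_rate)[0]
            for i in hits:
                if i in stop_span:
                    continue
                alternatives = [b for b in bases if b != seq[i]]
                seq[i] = alternatives[rng.integers(len(alternatives))]
        utr = "".join(seq)
        if taxon in insertion_taxa and cfg.insertion_offset is not None:
            off = cfg.insertion_offset
            utr = utr[: off - 1] + "T" + utr[off - 1 :]
        utrs[taxon] = utr
    return OrthologSet(taxa=taxa, utr3_by_taxon=utrs, reference_taxon=taxa[0])


def simulate_peptides(
    db: Sequence[Proteoform],
    cfg: SimConfig,
    n_decoys: int = 20,
    min_len: int = 7,
) -> list[PeptideRecord]:
    """Scored peptide table: true ISR tryptic peptides at high scores plus
    shuffled decoys at low scores.

    True peptides are the tryptic peptides (length >= min_len) lying fully
    within the ISR-encoded extension of a readthrough proteoform, scored
    ~Normal(140, 20) truncated > 0; decoys are letter-shuffles of the true
    peptides, scored ~Normal(50, 15) truncated > 0.
    """
    if not db:
        raise ConfigError("empty proteoform database")
    rng = np.random.default_rng(cfg.seed)
    rt = next(pf for pf in db if pf.substituted_aa != "canonical")
    true_peps = [
        pep
        for pep, start, _ in tryptic_digest(rt, 0)
        if start > rt.extension_start and len(pep) >= min_len
    ]
    records = []
    for pep in true_peps:
        score = max(float(rng.normal(140.0, 20.0)), 1e-6)
        records.append(PeptideRecord(pep, score, source="true_isr"))
    for _ in range(n_decoys):
        if not true_peps:
            break
        template = true_peps[rng.integers(len(true_peps))]
        shuffled = template
        while shuffled == template:
            shuffled = "".join(rng.permutation(list(template)))
        score = max(float(rng.normal(50.0, 15.0)), 1e-6)
        records.append(PeptideRecord(shuffled, score, source="decoy"))
    return records


def simulate_footprints(
    t: Transcript, isr: IsrRecord, cfg: SimConfig
) -> FootprintProfile:
    """Poisson footprint counts: rate lambda_cds over the CDS, theta*lambda
    over the ISR, distal_lambda beyond the downstream stop."""
    rng = np.random.default_rng(cfg.seed)
    n = len(t.cds) + len(t.utr3)
    rates = np.full(n, cfg.distal_lambda, dtype=float)
    rates[: len(t.cds)] = cfg.lambda_cds
    isr_start = len(t.cds)
    rates[isr_start : isr_start + isr.length_nt] = cfg.theta * cfg.lambda_cds
    counts = rng.poisson(rates)
    return FootprintProfile(transcript_id=t.id, counts=counts)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
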