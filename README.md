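# scrkit

Analysis toolkit for **stop-codon readthrough (SCR)** — the translational
recoding event in which a ribosome decodes a stop codon as a sense codon and
continues in frame into the 3′UTR until the next in-frame stop. The segment
between the canonical stop and that downstream stop (exclusive of both) is
the **inter-stop-codon region (ISR)**; it encodes the C-terminal extension of
the readthrough proteoform. In *FEM1B*-style readthrough the extension acts
as a degron, making the extended isoform highly unstable — so the ISR is
simultaneously the *cis*-signal for readthrough and the encoder of the
product's fate.

`scrkit` is aimed at researchers quantifying readthrough events: it covers
ISR discovery, proteogenomic evidence for the extended proteoform, the
evolutionary frame analysis of ortholog 3′UTRs, reporter-based efficiency
estimation, and ribosome-footprint signals — with seeded synthetic-data
generators so every stage runs end to end without external downloads.

## What it computes

- **ISR discovery** (`scrkit.seqcore`): scan the 3′UTR codon-by-codon in the
  frame continuing from the canonical stop; report the region before the
  first in-frame stop (its span adds the downstream stop: an 81-nt ISR spans
  84 nt). Extensions are translated under a configurable stop-decoding
  policy: an 81-nt ISR encodes 27 aa, or 28 aa with the decoded stop residue.
- **Readthrough proteoform database** (`scrkit.proteoform`): because the
  identity of the near-cognate residue inserted at the stop is unknown, the
  database holds 20 variants (stop → each standard amino acid) plus the
  canonical form. Scored peptide tables (e.g. MaxQuant `peptides.txt`) are
  filtered at score > 70 and matched by exact substring search, classified
  as `extension_internal`, `junction_spanning`, `canonical_only` or `no_hit`,
  with optional uniqueness checks against a reference proteome FASTA.
- **Ortholog frame comparison** (`scrkit.orthoevo`): Needleman–Wunsch global
  alignment (match +1, mismatch −1, gap −2; leftmost gap placement) of
  orthologous 3′UTRs, single-base insertion calling in the derived sequence's
  coordinates, per-taxon extension-length classification (≥ 28 aa = long),
  and per-column conservation profiles.
- **Reporter efficiency** (`scrkit.reporterquant`): per-replicate FLuc/RLuc
  ratios with the no-stop construct anchored at 100%:
  `%SCR = 100 · mean(FLuc/RLuc)_test / mean(FLuc/RLuc)_no-stop`,
  plus background-subtracted and ratio-of-means variants, GFP/DsRed
  stability ratios, 2^−ΔΔCt, MTT fold proliferation, calliper tumour volume,
  densitometry normalisation and Student/Welch/paired t statistics.
- **Footprint signal** (`scrkit.ribosignal`): mean footprint densities over
  CDS, ISR and distal 3′UTR (stop codons excluded), the readthrough ratio
  ISR/CDS, and a permutation test for ISR-over-distal enrichment.
- **Synthetic data** (`scrkit.synthdata`): seeded generators for every input
  plus pinned fixtures — `hominini_like` (81-nt ISR with a 'T' at offset 53),
  `ancestral_like` (that base deleted; frame restored to a short extension)
  and `mouse_like` (51-nt ISR → 18-aa extension).

## Worked example

```python
from scrkit import *

t = make_fixture("hominini_like")
isr = find_isr(t)
print(isr.length_nt, isr.span_nt)              # 81 84
ext = translate_extension(isr, "decode_as_X")
print(ext.length_aa, ext.residues)             # 28 XVTGYVKSFNVVLKSKGLLITDSREASA

db = build_readthrough_db(t)                   # 20 variants + canonical
m = map_to_isr_region(PeptideRecord("GLLITDSR", 143.37), db)
print(m.overlap_class)                         # extension_internal

anc = make_fixture("ancestral_like")
print(detect_insertions(anc.utr3, t.utr3))
# [IndelCall(kind='insertion', pos=53, bases='T', run_span=(53, 53))]

table = simulate_luciferase(SimConfig(seed=0, theta=0.17))
print(round(scr_efficiency(table).pct, 2))     # 16.04
```

The 81-nt ISR spans 84 nt with its downstream stop and encodes a 28-residue
decoded extension; the tryptic peptide GLLITDSR falls entirely inside that
extension (and in no canonical sequence), which is the proteogenomic
signature of readthrough. The ancestral/derived UTR pair differs by a single
'T' inserted 53 nt after the canonical stop — the frameshift that lengthens
the extension from 18–19 aa to 28 aa. A simulated triplicate dual-luciferase
assay at a true readthrough fraction of 0.17 recovers ≈ 16–17%.

The numbered drivers under `analysis/` run each stage and write tables under
`results/`:

```bash
python analysis/01_isr_discovery.py        # ISR scan of the fixtures
python analysis/02_proteoform_matching.py  # DB + peptide matching
python analysis/03_ortholog_comparison.py  # indel call + frame classes
python analysis/04_reporter_efficiency.py  # %SCR estimates
python analysis/05_footprint_signal.py     # region densities + perm test
```

A `scrkit` console command exposes the same steps on files
(`isr-scan`, `proteoform-db`, `match-peptides`, `ortho-compare`, `scr-eff`,
`ribo-scan`, `simulate`); see `scrkit --help`.

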