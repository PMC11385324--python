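# Methods

## Model and coordinate conventions

A transcript is a CDS whose final codon is the canonical stop, plus a 3′UTR.
Readthrough is modelled purely as frame continuation: the ribosome decodes
the stop as some sense residue and translates on, in the same frame, until
the first downstream in-frame stop. The inter-stop-codon region (ISR) is the
3′UTR segment between the two stops, exclusive of both; its *span* adds the
downstream stop codon (81-nt ISR → 84-nt span). All coordinates are 1-based
and inclusive, with offset 1 the first nucleotide after the canonical stop.
A 3′UTR with no in-frame stop within complete codons yields an *open-ended*
ISR — reported with a flag, never an error — whose length is the largest
multiple of 3 that fits.

Translation uses the standard nuclear code (via Biopython); selenocysteine
recoding and non-standard codes are out of scope. Because the identity of
the near-cognate residue inserted at the stop is not determined by sequence
alone, the decoded stop residue defaults to `X` and is configurable
(`decode_as:<aa>`); the readthrough proteoform database instead enumerates
all 20 possibilities, which is what a proteomic search needs.

## Proteoform database and peptide matching

The database is canonical translation + substituted residue + ISR
translation, one entry per standard amino acid plus the canonical form, and
requires a closed ISR. Digestion is tryptic — cleave C-terminal of K/R
except before P — because the evidence peptides of interest are tryptic;
missed cleavages 0–2 are emitted with 1-based coordinates. Matching is exact
substring search (no mass or spectrum model): a peptide wholly at or beyond
the substituted position is `extension_internal`; one straddling it is
`junction_spanning` and can hit only the variant whose substituted residue
it contains. The score filter is a strict `score > threshold` (default 70)
on a generic search-engine score column; no FDR modelling. Isoleucine and
leucine are distinct by default, with an I=L-collapsed mode behind a flag,
off, since collapsing discards the distinction the database encodes.
Uniqueness checking is substring search over a reference proteome FASTA;
genome-wide six-frame search is out of scope.

## Alignment and indel calling

Pairwise global alignment is Needleman–Wunsch with linear gap penalty
(defaults match +1, mismatch −1, gap −2 — adequate for proximal-UTR-scale,
near-identical inputs; affine gaps are not implemented). Determinism is
enforced twice: traceback prefers diagonal, then gap-in-second-sequence;
then every maximal gap run is slid leftward while the score is preserved, so
equal-scoring placements inside repeats always resolve to the leftmost
column. Insertion calls report the 1-based position of the first inserted
base in the insertion-carrying sequence's own coordinates, with the
homopolymer run containing the site recorded as metadata (`run_span`),
since within a run the position is conventional rather than observable.
Multi-sequence conservation display uses a star alignment to the reference
(insertions relative to the reference dropped), not a full MSA — sufficient
for per-column conservation on near-identical families. A column is
conserved iff every row carries the same single non-gap residue.

## Reporter efficiency

The estimator is mean-of-per-replicate-ratios:
`%SCR = 100 · mean(FLuc/RLuc | test) / mean(FLuc/RLuc | no-stop)`,
because per-replicate normalisation is what the dual-reporter design buys;
a ratio-of-channel-means variant is provided since either reading of the
published percentages is defensible. Background subtraction (of a
no-ISR/nonspecific construct's mean ratio, from numerator and denominator)
is available but off by default: the dual-luciferase percentage is defined
only by the no-stop 100% anchor, while background mode suits
fluorescence-reporter assays where a no-ISR construct measures background
signal. A negative background-corrected numerator clips to 0 with a
warning. With multiplicative lognormal noise the estimator carries a small
positive bias of order CV²/n (≈ 0.3% relative at CV 0.10, n = 3) from the
reciprocal of the reference mean — negligible against replicate scatter.
t statistics go through scipy (`ttest_ind`/`ttest_rel`); Welch's df uses
Welch–Satterthwaite; identical paired samples return t = 0, p = 1 rather
than 0/0. No multiple-testing correction is applied.

## Footprint signal

Input is transcript-relative per-nucleotide counts (TSV), not genome BAM.
Densities are means over CDS (minus its stop), ISR (between the stops) and
distal 3′UTR (beyond the downstream stop); both stop codons are excluded
from every region because termination-site peaks would bias all three. The
readthrough ratio is ISR density / CDS density, undefined (absent, no
pseudocount) when the CDS density is zero. The enrichment test permutes
per-nucleotide counts across the combined ISR+distal positions, statistic
= density difference, p = (1 + #{perm ≥ obs}) / (1 + n_perm) — exchangeable
under the null of a single 3′UTR rate, slightly conservative on discrete
counts.

## Synthetic data: what it emulates, and what it does not

Generators produce transcripts (CDS of uniform sense codons ending TAA; 3′UTR
whose first in-frame stop begins exactly at `isr_len_nt + 1`, followed by a
distal tail), ortholog families (i.i.d. substitutions off a common ancestor
with downstream-stop positions protected, plus a designated insertion-carrier
subset), dual-luciferase tables (RLuc lognormal; FLuc = θ·k·RLuc·ε with ε a
mean-1 lognormal at the configured CV), scored peptide tables (true ISR
tryptic peptides ≥ 7 aa at Normal(140, 20), letter-shuffled decoys at
Normal(50, 15) — the score scale anchored to a known true positive at 143.37
against a > 70 threshold), and Poisson footprint profiles (rates λ over CDS,
θλ over ISR, a background rate beyond). Uniform sense-codon sampling is the
null composition model; it does not emulate codon-usage bias, UTR base
composition, reporter cross-talk, peptide detectability, or ribo-seq
read-length/periodicity structure. Passing tests therefore demonstrate
estimator correctness under the stated noise models, not robustness to the
full messiness of real data.

Default `SimConfig` values are the study-scale conditions: 81-nt ISR,
insertion offset 53, θ = 0.17 (0.34 for the in-vitro-like condition),
CV = 0.10, n = 3 replicates, footprint rate 100/nt with background 1/nt,
22 taxa at substitution rate 0.02. The 93-nt fixture CDS and 45-nt default
distal tail are desk-scale choices: long enough to give stable CDS densities
and non-trivial tryptic maps, small enough that every stage runs in
milliseconds.

## Fixture construction

The named fixtures are deterministic (no RNG): the literal sequences behind
the published lengths are not machine-readable, so the fixtures realise the
published *parameters* — 81/84 nt, 51 nt, offset 53 — around the
experimentally anchored extension peptide. The `hominini_like` ISR encodes
27 residues whose first 23 are VTGYVKSFNVVLKSKGLLITDSR (antibody epitope +
tryptic evidence peptide), padded with EASA; codons 18–20 are pinned to
CTA·ATA·ACA so that deleting the single 'T' at offset 53 (codon 18's middle
base) shifts the frame onto a TAA at former offsets 56–58.

One geometric constraint forced a design choice here: had the ancestral
first stop sat exactly one codon after the shared 51-nt prefix (giving an
18-aa ancestral extension), its first base would occupy offset 52 and be
'T' — adjacent to the inserted 'T' — and under leftmost gap placement the
indel call would land at 52, not 53. The `ancestral_like` fixture therefore
stops one codon later (54-nt ISR, 19-aa decoded extension, still short of
the 28-aa class boundary), keeping the insertion site free of any repeat
context so the position-53 call is unambiguous. The 18-aa short-extension
case is carried by `mouse_like` (51-nt ISR). The fixture canonical stop is
TGA (the leakiest stop class); the generator default is TAA, which is
immaterial to frame arithmetic.

## Numerical and testing choices

Problem sizes in the default suite: 10³ random UTRs against a naive
codon-window oracle; alignment scores against exhaustive path enumeration
(≤ 7 nt) and an independent DP implementation (≤ 12 nt); 200 planted-insertion
recovery trials on 120-nt UTRs (≥ 95% exact, discrepancies confined to
repeat contexts); 10⁴ null simulations for the t-test type-I error; 500
seeded assays per θ for estimator consistency; 300 exchangeable-null runs
for the permutation-test level. Seeds are fixed in the tests; the
acceptance script derives all child seeds (< 2³¹) from its `--seed` via
`numpy.random.SeedSequence`. The stochastic efficiency targets are reported
as the mean over 100 simulated triplicate experiments to make the recovered
value stable in a single run without altering the per-experiment design
(n = 3, CV 0.10).

## Known limitations

No genome-coordinate lifting, splice isoforms, or non-standard codes; no
spectrum-level proteomics (identifications are consumed, not produced); no
affine gaps, tree inference or dN/dS; no P-site offsetting or read-length
handling for footprints; two-sample t-tests only (no ANOVA or survival
analysis). The footprint readthrough ratio is a density proxy, not a
calibrated efficiency: it equals θ only under the generator's uniform-rate
assumptions.
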