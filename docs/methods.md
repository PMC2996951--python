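# Methods

This note documents the models, rules and numerical choices behind
`trna_anchor`, and what the synthetic corpus does and does not emulate.

## Coordinates, records and tokens

All intervals are 0-based half-open internally; GenBank's 1-based inclusive
convention is converted at the I/O boundary. Origin-spanning features on
circular genomes are rejected with a clear error: the analysis only ever
inspects a short linear window upstream of the target gene, and supporting
wrapped intervals would complicate every downstream operation for no
benefit at this locus. Gene names are normalized through a data-driven
synonym table (`data/synonyms.tsv`, replaceable by the user) because
GenBank naming is inconsistent (`COX1`/`CO1`/`COI`, `tRNA-Trp`/`trnW`);
normalization is idempotent and unknown names pass through untouched.

## Arrangement survey and anchor choice

The upstream arrangement of a genome is the ordered list of genes whose
strand-aware 3' end falls within a window (default 200 bp) upstream of the
target start, signed by orientation relative to the target. Reverse-strand
targets are handled by reverse-complementing the whole record first, so a
single forward-strand code path serves both cases. The 3' end is used for
the inclusion and distance rules because a primer sits in the anchor's 3'
portion: that edge bounds the non-barcode overhead in the amplicon.

Anchor candidates are ranked lexicographically — presence fraction, then
forward-orientation fraction, then median distance (ascending), then token —
rather than by a weighted score. The ordering is reproducible and matches
how one would qualitatively choose a stable anchor; the weights of a scalar
score would be arbitrary. A candidate is eligible when its modal
orientation is forward and its median distance does not exceed
`max_anchor_distance_bp` (default 200 bp, the distance bound the trnW
geometry implies: two 60–68 bp tRNAs plus short gaps). When no candidate is
eligible the ranking is empty and a warning is emitted.

## Alignment and homogeneity grouping

Anchor tRNAs are short (20–100 nt) and near-equal length, a regime where a
center-star multiple alignment is accurate and dependency-free: the center
is the sequence minimizing summed pairwise edit distance (distances via
edlib), every other sequence is Needleman–Wunsch-aligned to the center
(unit costs, traceback preferring substitution over indels so equal-length
inputs stay gap-free), and alignments merge under "once a gap, always a
gap". Pre-aligned FASTA is accepted as an alternative input path.

Groups are formed by complete-linkage agglomerative clustering: repeatedly
merge the pair of clusters whose minimum pairwise identity is highest, while
that minimum stays at or above the threshold (default 0.75); ties break on
the lowest member index, making the partition independent of input order.
Pairwise identity over the column window (default: the central 19 columns)
is computed on the two rows' **ungapped** subsequences within the window as
`1 − d/ℓ` (d = edit distance, ℓ = the longer subsequence). This was a
deliberate choice over column-wise identity: center-star gap placement for
equally good alignments is essentially arbitrary, and column-wise identity
lets that arbitrariness fragment genuinely homogeneous groups. The
edit-distance form is invariant to gap placement; with it, worst-case
within-group identity for uniform expansions of the two anchor consensi
(0.79–0.84 over 19 columns) clears the 0.75 threshold deterministically,
while the groups' fixed inter-group differences keep complete linkage from
ever merging them. The 0.75 default reflects that bound; the original
grouping was done by eye, so the threshold and window are both parameters.

## Degenerate consensus and primer construction

Per alignment column (gaps excluded) every symbol contributes weight
`1/|base set|` to each base it can stand for (N counts ¼ toward each base);
bases with relative frequency ≥ `min_freq` form the column's IUPAC code.
`min_freq` defaults to 0.05 — a base seen in fewer than 5 % of members is
treated as noise; at 0 the consensus/expansion round trip is exact. If the
cutoff would empty a column's set, the maximal-frequency bases are kept so
a code always exists.

Primer construction exposes the decisions a designer actually makes:

* `resolution_map` (1-based positions → single base) replaces a degenerate
  code with one member base. Such resolutions are not algorithmically
  derivable — they trade coverage against degeneracy and synthesis cost —
  so they are explicit, validated inputs rather than hidden heuristics.
* `prefer_3prime_GC` ends the core at the rightmost G/C/S position when one
  exists, since a G or C 3' terminus primes more efficiently.
* `three_prime_extension` appends extra 3' bases, covering designs that
  extend one base past the conserved block.
* Tails (e.g. the M13 sequencing tail) ride along 5' and never participate
  in template matching.

Degeneracy is the product of per-position set sizes (verified against
brute-force expansion in tests). Tm is the Wallace rule 2(A+T)+4(G+C)
evaluated over the min-GC and max-GC expansions of the core — a quick
operator sanity check, not a thermodynamic model. The universal barcode
primers themselves (LepF1/LepR1, LCO1490/HCO2198) are configuration inputs,
never baked into the package.

## In-silico PCR

Matching is symmetric IUPAC set-intersection per position (template N
matches everything); only the core participates. The amplification call
operationalizes the empirically observed failure pattern — failures occur
when more than three bases are substituted, usually with substitutions near
the 3' end — as one deterministic score: a 3'-terminal mismatch fails
outright; otherwise mismatches inside the 10-nt 3' window count double and
the primer fails when the weighted score exceeds 3. All three constants
live in `Thresholds` and are overridable. The rule is monotone: adding a
mismatch can never turn a failure into a success. Amplicon lengths are
reported with both primer footprints included and tails excluded, matching
how sequenced amplicon lengths are reported. Scanning is a naive
vectorized sweep — entirely adequate at tRNA/COI scale.

## Barcode QC

**Trimming** is ORF-anchored rather than tRNA-model-based (no covariance
model is in scope, and the ORF contract is directly testable). Candidate
start positions are codon offsets in the first `trim_band_bp[1] + 30`
(= 230) bases whose downstream stop-free run reaches ≥ 150 nt; scanning
5'→3', the first candidate whose initiation call is not `uncertain` wins.
The 5'-most-acceptable rule is applied across frames (rather than fixing
the frame with the longest open run first): the non-canonical context rule
already defers to nearby canonical starts, and position-first scanning
makes recovery on clean reads deterministic instead of depending on how
long the off-frame stop-free runs happen to be.

**Initiation calls**: first codon in {ATA, ATT, ATC, ATG} → `ATN`; TTG and
GTG likewise canonical. TCG (or CCG) and CGA are accepted only when the
in-frame codon immediately 5' is TAA/TAG and no canonical initiator occurs
within `initiator_scan_window_bp` (30 bp) downstream of that stop; the
window is measured from the first base after the stop codon (the codon
boundary reading is ambiguous in prose; this choice is documented and
tested). Quadruplet starts (ATAA/TTAA/TTAG/ATTA) are annotated on request
but never asserted as calls — the evidence for them is weaker than for
TCG/CGA. `uncertain` arises only when no rule applies.

**Translation** uses NCBI genetic code table 5 (AGA/AGG = Ser, TGA = Trp,
ATA = Met), with degenerate codons resolved by expansion (agreeing
expansions give the amino acid, disagreeing give X) and the trailing
partial codon dropped.

**NUMT screening** flags internal stops, frameshift-sized (length not
divisible by 3) interior gaps in a nucleotide alignment against a reference
coding sequence, and reads below `barcode_min_len_bp`. The 500 bp default
is the community convention for formal barcode status; compliant records
in practice run ~512–711 bp, and the value is configurable.

**Indel detection** globally aligns the query protein to a same-gene
reference (match +1, mismatch −1, gap −2, free end gaps on the right so 3'
truncation is not an event; a 10⁻⁶ epsilon on gap opening makes one
contiguous run beat an equal-cost split, keeping events contiguous).
Deletions are reported at the 1-based reference position of the first
missing residue, counted from the initiation codon; insertions
symmetrically at the reference position following the insertion point.
Alignment identity below 50 % over paired columns raises — that is a wrong
gene or frame, not an indel call.

## Synthetic corpus

The generator emulates the surveyed locus structure: per genome, an
upstream pad, tRNA genes of 60–68 bp in one of the observed arrangements
(`W,-C,-Y` dominant; defaults give 120 of 126 genomes an anchored trnW,
split 92/28 between the two anchor groups by exact largest-remainder
counts under a seeded permutation), intergenic gaps of 0–20 bp, and a COI
gene of 230 codons built by back-translating a fixed reference protein
with uniform synonymous codon choice. Initiator classes default to the
observed mix (58 ATN : 14 TTG : 1 GTG : 21 TCG : 1 CCG : 17 CGA);
non-canonical initiators get an in-frame TAA/TAG planted directly 5'.
Reads are a 70–200 bp tRNA-derived filler plus the 5' COI segment, total
length 730–870 bp. Everything is a pure function of `(seed, index)`.

Deliberate constructions worth knowing about:

* The anchor block sits at a fixed offset (20 nt) inside trnW, so analyses
  can slice a common window from extracted gene sequences before alignment;
  real tRNAs would need the conserved block located by alignment or a tRNA
  model.
* Back-translation avoids codons that double as canonical initiators within
  protein positions 2–10, keeping the 30-bp scan window clean for the
  non-canonical rule — mirroring the real sequences in which TCG/CGA calls
  were plausible.
* Codons at residues 9–17 and 222–230 are pinned to fixed synonymous
  choices so all genomes share synthetic stand-ins for the standard
  forward/reverse primer binding sites (`STANDARD_FWD_SITE`,
  `STANDARD_REV_SITE`); configured substitutions are planted on the forward
  site for failure-profiling experiments.
* `reject_confounders` (off by default) redraws upstream sequence until no
  spurious acceptable initiator with a ≥150 nt open run precedes the
  planted start. Clean-read recovery rates are measured under this option;
  without it, random filler mimics the genuinely ambiguous reads real
  projects discard.

What the corpus does **not** emulate: realistic base composition or codon
usage, substitution-model evolution along a phylogeny, sequencing error,
chromatogram quality, heteroplasmy, or true NUMTs with their own flanking
context. Passing tests therefore demonstrate correctness of the operations
on structurally faithful inputs, not field performance on real trace data.

## Problem sizes

The default verification workloads — a 126-genome survey corpus, a
120-sequence alignment/clustering, 1,000 QC reads, 200 consensus round
trips, exhaustive 225-pair and expansion-union oracles — were chosen to
exercise every code path at the study's stated proportions while keeping
the whole suite around half a minute on one CPU.
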