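# Methods

This note documents the models, parameter choices and numerical conventions
behind splintstore, and what the simulations do and do not establish about
real sequencing runs.

## Word codec

Text is restricted to 7-bit ASCII; each character code is one symbol of
GF(2⁷). The field is generated by the primitive polynomial x⁷+x³+1, pinned
so that payloads are bit-exactly reproducible across runs and machines (any
primitive degree-7 polynomial gives an information-equivalent code). The
Reed–Solomon code is systematic and shortened: k message symbols plus 2
parity symbols, k + 2 ≤ 127. Two parity symbols give minimum distance 3 and
correct any single symbol error — one character, 7 bits. Decoding uses
syndromes, Berlekamp–Massey, Chien search and Forney's formula; after
correction the syndromes are rechecked and any inconsistency is reported as
failure rather than returned silently.

Two consequences of the 2-bits-per-base packing are worth stating
explicitly:

* the parity adds 14 bits = 7 bases to every payload;
* a base spans 2 adjacent bits, so a single base substitution can straddle
  a symbol boundary and corrupt two symbols. Substitutions confined to one
  symbol are always corrected; straddling ones may exceed t = 1 and are
  then reported as failures (never as wrong text, except for the
  unavoidable distance-3 miscorrection cases, which re-encode consistently
  and can only be caught by content checks).
* with minimum distance 3, two symbol errors are usually detected but can
  occasionally land within distance 1 of a different codeword; such
  miscorrections are parity-consistent and undetectable at the code level.
  Consensus over many reads, applied before ECC, is the practical guard.

The pad rule: when the total bit count 7(n+2) is odd, one 0 bit is appended
before base conversion and a `padded` flag recorded. The bit→base map
(00→A, 01→C, 10→G, 11→T) is a convention fixed here; any bijection works.
Parity is per word, because the word is the unit of assembly and random
access. Word payload lengths therefore follow ⌈7(n+2)/2⌉ — e.g. a
three-word sentence of 7+6+5 characters assembles to 205 nt with six 20-nt
addresses.

## Pixel codec

Frames are 16×16 with four colours (2 bits/pixel), flattened row-major from
the top-left. Two pixels (4 bits) map to one 3-base codon. The table is the
lexicographically smallest 16 of the 36 codons with no adjacent repeated
base (a seeded random 16-subset is available). Because every table codon is
internally repeat-free, a run of 3 across any junction would require a
repeat inside one of the two codons — so *any* codon concatenation has
maximum homopolymer run ≤ 2. This is verified exhaustively over all 256
ordered pairs and on constant-colour frames, the worst case the code exists
for. The guarantee covers the 48-nt payload only; the fixed 20-nt addresses
and the 2-nt index are exogenous sequences and excluded from it.

Oligo layout is forward-address ∥ index ∥ payload ∥ reverse-address
(20+2+48+20 = 90 nt). The index is big-endian base-4 under the shared
2-bit base map, supporting 16 ordinals of which 8 are used per frame.
Missing indices decode to a masked hole; unknown codons are per-pixel-pair
erasures — both reported, never raised.

Byte accounting: the raw pixel payload of a frame is 256 px × 2 bit = 64 B
(`pixel_codec.raw_payload_bytes`). The capacity calculator instead takes
file-level bytes per oligo as an input (e.g. a 0.27–0.28 kB image file over
8 oligos ≈ 34–35 B/oligo), since container overhead is part of the stored
file. Both figures are exposed and labelled.

## Assembly simulator

Data strands are single-stranded, 5'→3'. A splint is the reverse complement
of the 30-nt junction (last 15 nt of the upstream fragment + first 15 nt of
the downstream fragment); it validates a junction and never enters the
product. The 15+15 split of the 30-mer is a fixed design choice.
Hybridisation requires exact 15-mer matches — mismatch-tolerant annealing
and off-target ligation are not modelled. Ligation requires a
phosphorylated downstream 5' end (settable to false to model the
no-ligation control).

Yield: each junction converts min(upstream, downstream available copies) ×
e into product, with e = 0.185 by default — the efficiency implied by qPCR
copy numbers (1.67×10¹² ligated from 9.04×10¹² input). In expectation mode
this is deterministic and conservation (product + leftovers = inputs) holds
exactly; Bernoulli mode draws binomial counts under an explicit seed.
Serial junctions compound multiplicatively (e.g. 0.185⁴ ≈ 0.117% → 0.1% at
one decimal); e is an exogenous parameter — no dependence on ligase amount,
time or temperature is modelled. Unligated leftovers stay in the merged
droplet; downstream analyses either size-select (`products_only`, the
in-silico analogue of cutting a band) or rely on PCR random access.

A parallel step carries k ≥ 2 distinct splints sharing one upstream and
produces k product species in one droplet; branches draw sequentially from
the remaining upstream copies, preserving conservation.

## Read simulator

The simulator emulates full-length amplicon sequencing of pool species
(≤500 nt, so no fixed-cycle truncation): species are sampled by a
multinomial on copy numbers at a chosen per-species depth, each molecule is
read from either strand with probability ½, and errors are i.i.d. per base
— substitutions uniform over the 3 alternatives, insertions a uniform base
before the current position. Qualities are constant Q30 placeholders; the
decoder is count-based and ignores them. A truth ledger (origin species,
orientation, per-read edit counts) makes error-class fractions exact and
decoder-independent.

Default per-base rates (sub 2×10⁻³, del 10⁻³, ins 10⁻³) produce a per-read
imperfection of the same order as real amplicon runs on ~200-nt species.
Real per-read class percentages entangle synthesis, ligation, PCR and
sequencing errors, from which no per-base rates are derivable; the
simulator's classes are therefore checked against binomial theory and
against its own ledger, not against any instrument's figures. Passing tests
show the pipeline's logic is correct under this error model, not that the
model reproduces a particular sequencer's error spectrum (context-dependent
errors, quality decay along the read, PCR bias and chimeras are absent).

## Decoder

Reads are oriented by scanning both the read and its reverse complement and
keeping the direction with more matched address bases (fewer mismatches on
ties); undecidable reads pass through flagged `unknown`. A hit is either a
full 20-nt window with ≤ 5 mismatches, or an exact contiguous ≥ 15-nt match
where an address is truncated at a read end; overlapping candidates resolve
by (longer match, fewer mismatches, leftmost). The 15-of-20 floor is safe
because synthetic address books enforce pairwise Hamming distance ≥ 8
(also against reverse complements) by seeded rejection sampling — a
stand-in constraint for orthogonal primer design.

Forward-role addresses anchor at offsets 0–5 (so a 15-mer suffix still ends
by base 20) and, because serial products contain interior forward
addresses at every word junction, they are also sought from base 21 onward
together with all other addresses.

Payloads are the spans strictly between consecutive hits (zero-length
junction spans between a reverse and the following forward address are
kept, flagged, and skipped by the codecs). Species are demultiplexed purely
by address path — plus the 2-nt index prefixes for the pixel codec, since
indexed oligos share one address pair. Each payload cohort is restricted to
its modal length (ties to the smaller) before a per-position plurality vote
with a deterministic lexicographic tie-break; minority-length reads are
excluded from consensus but counted in the error classes, which is exactly
how the payload-length filter acts. R1 and R2 are decoded independently
after orientation; no overlap merging.

`min_reads` (default 1; 3 in the CLI decode/demo) drops address paths
supported by fewer reads: errors inside an address hit create spurious
singleton paths whose "consensus" would be a single corrupted read. Dropped
reads stay in the aligned count and classify as `other`, preserving the
filter monotonicity aligned ≥ length-match ≥ perfect.

Error classes are assigned by the length rule (equal length and identical →
perfect; equal length → substitution; 1–2 nt short → deletion; longer →
insertion; else other). An edit-distance alignment could classify
compensating indels differently; the length rule is the one the per-class
counts are defined by here.

Random access models PCR selection as ordered primer-site containment:
keep species containing the forward address followed by the reverse
address (book addresses are stored in fragment orientation, so the
physical reverse primer is the reverse complement of the book entry).
Amplification kinetics and primer thermodynamics are not modelled.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (NumPy `default_rng`);
seeded runs are byte-identical. The test suite and acceptance checks use
desk-scale sizes chosen to make the statistical assertions sharp: 3–4-word
sentences at depths 10–300, three frames at depth 10–50, 10,000 reads for
the binomial class-fraction checks (3-SE tolerance), 500 seeded instances
for the scan-vs-brute-force oracle, 1000 random frames for the round-trip
property, and exhaustive enumeration wherever the space is small (all
single-symbol RS corruptions, all 256 codon junctions).

## Known limitations

* No mismatch-tolerant hybridisation or off-target ligation; splint
  junction matching is exact.
* The error model is i.i.d. per base; no quality-aware calling, PCR bias or
  chimeras.
* Consensus is unweighted plurality; qualities and R1/R2 provenance are not
  weighted.
* Efficiency is a constant per junction; no kinetics.
* Only 4-colour frames with pixel counts divisible by 32 are supported
  generically; only 16×16 is exercised against the headline layout numbers.
* Sentence species lengths follow this package's deterministic layout
  (e.g. 205 nt for a 7+6+5-character sentence); layouts that include
  unpublished per-word padding will differ at the few-base level.
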