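# Methods

This note documents the models, defaults and numerical choices behind
`cugkit`, and what the synthetic fixtures do and do not establish about
real data.

## Genetic codes and degeneracy

Codes are complete 64-codon DNA tables. The built-ins are the standard
nuclear code and two single-codon reassignments of it: CUG→Ser (the
"alternative yeast nuclear code" of the CUG-Ser clades) and CUG→Ala. DNA
(T) is the canonical alphabet; U is normalized to T on input. Ambiguous
bases are rejected rather than guessed at — a recoding or degeneracy
verdict on a sequence containing N would not be trustworthy. Internal stop
codons are reported as `*`, never raised as errors: verification must see
the complete translation under every code, and it is the caller's job to
decide whether an internal stop is a problem. Codon positions are 1-based
in codon units in all user-facing reports (how biologists count codons);
internal indices are 0-based half-open.

A CDS is degenerate across a set of codes iff its translation is identical
under all of them; since the three built-ins differ only at CUG, this is
equivalent to being CUG-free, and the property tests assert that
equivalence explicitly.

## Usage tables and the recoding pipeline

Usage tables store raw in-frame codon counts pooled across the reference
CDSs and normalize them *within synonymous families* (relative synonymous
codon usage) under a chosen code — that is the quantity a
one-amino-acid-to-one-codon optimizer consumes. Stop codons are tabulated
under `*` but are never substitution targets, and Met/Trp (single-codon
families) are never substituted either.

The recode is two passes:

1. **CTG→TTG replacement.** Silent under the standard code (both leucine),
   so the donor protein is untouched; applied before optimization so the
   sequence entering the optimizer is already CUG-free. These replacements
   do **not** count toward the change cap — the cap governs the usage
   optimization pass only. The alternative reading (cap shared across both
   passes) is achievable by calling the optimizer with the raw donor, since
   forbidden-codon positions are mandatory candidates there.
2. **Capped one-to-one optimization** (default cap 25, default forbidden
   set {CTG}, default target code CUG-Ser). Every codon differing from its
   amino acid's preferred codon is a candidate; candidates are ranked by
   frequency gain (preferred fraction minus current fraction), ties broken
   to the 5'-most codon. The ranking rule is this package's own
   deterministic choice — external optimizers do not document theirs — and
   every substitution is logged (index, from, to, reason) so a recode is
   replayable byte-for-byte. Positions holding a forbidden codon are
   mandatory, rank first, and the recode fails loudly if the cap cannot
   accommodate them: emitting a non-degenerate "optimized" marker would be
   worse than failing.

Preferred-codon ties break to the lexicographically smallest codon; amino
acids never observed in the reference set fall back to the smallest
non-forbidden family codon. Both rules exist to make runs reproducible and
auditable rather than for any biological reason.

`reintroduce_cug` restores the donor's CUG codons into an optimized
backbone, producing the control genes that separate codon-identity effects
from optimization effects. `verify_recoding` checks the three contract
properties: protein preserved (recoded translation under the target code
equals the donor's standard-code product), CUG-free, degenerate across all
three codes.

## CUG-decoding inference

The conserved-column argument — "the homologs show serine where this gene
has CUG" — is formalized as an additive log-probability score. The query is
translated with CTG masked as `X` so the unknown residue cannot bias its
own placement ( `X` scores 0 against every profile column), globally
aligned to the homolog profile (Needleman–Wunsch/Gotoh, affine gaps, open
11 / extend 1 — the familiar BLOSUM62 defaults; substitution score is the
expected BLOSUM62 score against the column's residue frequencies), and
each aligned CUG column contributes

    log[(count(residue implied by candidate) + pseudocount) / (depth + 20·pseudocount)]

per candidate code. Defaults: pseudocount 1, decision margin 2 nats,
columns with more than 50% gaps excluded. The margin makes the scorer
abstain (`indeterminate`) rather than guess when the evidence is thin; the
recovery tests require not just high accuracy but *zero* wrong calls —
failures must be abstentions. All CUG positions are aggregated into one
score; with several positions the evidence compounds, which is why three
conserved columns at 90% conservation separate candidates by far more than
the margin. Pseudocount > 0 keeps every score finite on any profile.

The aligner is a profile aligner by design (the tool takes a pre-aligned
homolog FASTA as canonical input); homolog discovery and multiple-sequence
alignment are upstream of this package. On ungapped equal-length inputs the
optimal alignment is the identity mapping, which the brute-force
enumeration oracle in the tests confirms on small cases.

## tRNA classification

Isotype calling is reduced to sequence-level identity elements: the
discriminator base (position 73, the unpaired base 5' of the 3'-CCA, or
the final base when CCA is absent) decides — G73 serine-type, A73
leucine-type, anything else unknown — and a long (≥10 nt) variable arm is
recorded as corroborating (type-II, consistent with both Ser and Leu, so
never decisive). Cloverleaf recognition is a deliberate heuristic: the
anticodon must sit centered in a 7-nt loop closed by ≥4 Watson-Crick/GU
pairs, the longest closing stem wins (ties 5'-most), and the T-arm is
located by canonical arm geometry from the 3' end (7 acceptor + 5 T-stem +
7 T-loop + 5 T-stem nucleotides). This is not a covariance model and is
not meant to scan genomes; it annotates sequences already believed to be
tRNAs. The identity-element rule set is small and documented precisely so
it can be extended if further elements (acceptor-stem pairs, D-arm
features) need to be scored.

## Digest, inverse PCR, and junction mapping

Restriction sites are fixed-literal matches (degenerate sites
unsupported); overlapping occurrences are all reported; circular mode
detects origin-spanning sites. The default enzyme model is CfoI (HhaI
isoschizomer): recognition GCGC, cut after offset 3 (GCG^C). Fragment
identity, not cut chemistry, drives every downstream analysis, so the
offset is configurable and immaterial to mapping results.

Expected spacing between sites under an i.i.d. base model is
`1 / Π_b p(b)` with p(G)=p(C)=gc/2; at GC 0.404 and a 4-base all-GC site
this gives ≈ 601 bp, which matches the observed mean spacing on simulated
1-Mb genomes to within sampling error — the "cut site every ~600 bp"
regime a frequent cutter needs for this protocol.

The inverse-PCR simulator enforces the protocol's own precondition (no
recognition site inside the cassette, reported with the violating
position), finds the digest fragment carrying both outward primer sites,
circularizes it, and returns cassette-tail + downstream flank + re-ligated
junction + upstream flank + cassette-head. Junction mapping strips the
cassette portion by locating a cassette terminus (20 bp probe), then
exact-matches the adjacent genomic flank against both strands of the
assembly; the downstream-flank side is tried first with fallback to the
upstream side, so a zero-length flank on one side (cassette abutting a cut)
still maps. Status is `unique` / `ambiguous` / `unmapped` by the number of
genomic placements of the first `min_flank` (default 20) bases; exact
matching replaces a local aligner because simulated amplicons are
error-free, and a ≤2-mismatch scan is available behind a flag for noisy
inputs. A ±150-bp verification-window report (expected wild-type vs
insertion product sizes) stands in for thermodynamic primer design, which
is out of scope.

## Synthetic data: what it emulates, what it does not

All generators take an explicit seed and are byte-deterministic given it;
each fixture carries a truth record sufficient to score downstream calls
without re-derivation. Defaults used throughout the tests:

* genomes: i.i.d. bases, GC 0.40 (yeast-like), 100 kb for end-to-end
  insertion runs, 1 Mb for spacing statistics;
* donor ORFs: uniform sense codons between ATG and TAA — a 500-codon ORF
  carries ~8 CUGs by chance, the scale real markers show;
* homolog families: 20 homologs, 150-residue proteins, per-column
  conservation 0.9 (0.95 outside the stress tests), 3 CUG positions;
  homologs are sampled independently per column (ancestral residue with
  probability = conservation, else uniform over the other 19);
* tRNAs: canonical cloverleaf with a 5-pair anticodon stem, 7-pair
  acceptor stem, ≥10-nt variable arm, 3'-CCA; the generator rejects draws
  where the anticodon triplet recurs elsewhere or a chance pairing would
  extend the planted stem, so planted landmark coordinates are exact;
* cassettes: 693 bp (ORF plus two 60-bp homology hooks), scrubbed of the
  digest site; random insertion positions are redrawn if a junction would
  create a new recognition site straddling a cassette boundary — the
  protocol's site-free-cassette condition enforced in genomic context.

The deliberate simplifications: no phylogenetic correlation between
homologs (real alignments have correlated errors and indels), no
sequencing error in amplicons (real junction reads need the
mismatch-tolerant mode or an aligner), no repeat structure in genomes
(real assemblies make more flanks ambiguous), and i.i.d. base composition
(real GC varies locally, so real digest fragments are more dispersed than
the geometric model). Passing tests therefore demonstrate correctness of
the algorithms under their stated assumptions, not performance on any
particular genome.

## Problem sizes in the test suite

The suite runs 1,000-ORF recoding sweeps, 150 inference families (50 per
true code), 200 tRNAs, 10×1 Mb digests, and 100 end-to-end insertion
simulations — sizes chosen so each statistical bound is a ≥3σ check while
the whole suite stays interactive (~10 s).
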