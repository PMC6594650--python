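# Methods

This note records the models, parameter choices and numerical decisions
behind `rbgrp`, and what the synthetic-data tests do and do not establish
about real data.

## Family identification

The family is defined jointly by domain evidence and composition: an
RNA-recognition motif (RRM) or cold-shock domain (CSD) plus a glycine-rich
region of (Gly)n-X type. Domain evidence arrives as a precomputed HMMER
per-domain table; the package deliberately does not run the profile search
itself, so any HMMER version or profile set can feed it. The default
accession map covers seven RRM-clan profiles (PF00076, PF04059, PF08777,
PF10378, PF10598, PF13893, PF14259), the CSD profile PF00313, and the CCHC
(PF00098) and RanBP2 (PF00641) zinc-finger profiles; unknown accessions
become `OTHER` and never block classification.

Choices that matter:

* **E-value threshold** 1×10⁻⁴, strict (`<`). The full-sequence E-value
  gates family membership; the per-domain independent E-value gates which
  envelopes become architecture tokens. The table carries both, and using
  the weaker full-sequence value for inclusion avoids dropping genuine
  members whose individual domains are split into weak envelopes.
* **Glycine window**: strictly more than 50% glycine in some 20-residue
  window, i.e. ≥ 11/20, window sliding by one. Sequences shorter than the
  window are scored over their full length rather than auto-rejected.
* **Architecture resolution**: envelopes sorted by start; same-class
  envelopes with reciprocal overlap above half the shorter envelope merge
  into one token, so repeated weak hits on a single RRM are not read as
  class IVd.
* **Classification precedence**: CSD first (any CSD ⇒ IVc, with or without
  zinc fingers), then ≥ 2 RRMs ⇒ IVd, then one RRM + zinc finger(s) ⇒ IVb
  (RanBP2-type fingers count), then a lone RRM ⇒ IVa. The CSD-first rule
  follows observed family rosters, which assign CSD plus a *single* CCHC to
  IVc even though the textbook definition asks for two or more fingers; a
  roster row assigning a bare RRM to IVb exists in the literature but is
  internally inconsistent and is not reproduced here.
* **Non-redundancy**: one protein per locus, the longest isoform (ties to
  the lexicographically smaller id). The same rule picks the exon set of
  the longest mRNA in the GFF reader.
* **Properties**: average (not monoisotopic) residue masses for molecular
  weight; pI by bisection on [0, 14] of the Henderson–Hasselbalch net
  charge under the Bjellqvist pKa set (the one behind the ExPASy
  calculator), to |charge| < 10⁻⁶. `X` residues are an error by default;
  `allow_x` substitutes the mean residue mass and no charge.

## Genome context

Coordinates are 0-based half-open internally and converted at the GFF3
boundary (1-based inclusive). Gene rank — the 1-based position in the
start-sorted order of a chromosome, ties broken by gene id — is the unit of
the duplication rules. Strand is carried but ignored by ranking; the rank
arithmetic is purely physical. "Linked on the same chromosome" has no
standard definition; it is operationalised as rank gap ≤ 10 and exposed as
a parameter (set 1 for strict adjacency).

## Phylogenetics

Distances use pairwise deletion (columns with `-` or `X` in either row
dropped per pair) and Poisson correction d = −ln(1−p), which presumes
equal rates across sites and no back-substitution bias — exactly the model
the alignment simulator implements. NJ is Saitou–Nei on the Q criterion
with two determinism guarantees: exactly-rounded row sums (`math.fsum`), so
join choices cannot depend on input order, and Q ties broken toward the
lexicographically smallest pair of cluster representatives. Negative branch
lengths are clamped to zero with the deficit moved to the sibling edge, as
MEGA does. Bootstrap resamples columns to the original length; replicates
with an all-gap pair or a saturated distance are redrawn and counted.
Support is the rounded percentage of replicates containing the same leaf
bipartition; edges survive collapse only with support strictly above the
threshold (50 by default), so a 50% edge is contracted. The default 1000
replicates match common practice; tests use 40–200 for speed.

## Duplication and selection

Tandem duplicates: a homologous pair on one chromosome with |Δrank| = 1,
each unordered pair reported once. Collinear blocks: per chromosome pair
and orientation, anchors are chained by dynamic programming requiring
strictly monotone ranks in both genomes and rank gaps ≤ 25, scored +1 per
anchor minus (gap_a+gap_b)/(2·max_gap) per transition; chains are peeled
off best-first, each anchor used once per orientation, and chains shorter
than 5 anchors are dropped (the MCScanX convention). This is a simplified
stand-in for MCScanX's e-value-weighted chaining: block *boundaries* can
differ from MCScanX on real data, though planted diagonals are recovered
exactly.

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous site fractions with
mutations to stop codons excluded from the denominator (renormalised
within the position, so S+N = 3 per codon); differences averaged over all
orderings of the differing positions, pathways through stops excluded
(with a fallback to the unrestricted set when every pathway is blocked,
and a flag to count stop-crossing steps as nonsynonymous instead);
Jukes–Cantor correction applied to both proportions, raising a saturation
error at p ≥ 3/4. NG86 substitutes for ML codon models: on real data its
values differ from PAML's, typically modestly, and the package documents
rather than hides that. ω is undefined at Ks = 0. Ortholog pairing keeps
the minimum-Ks anchor mate with a Ks ≤ 3 saturation guard ("small Ks"
having no published cutoff). Divergence time T = Ks/(2r) requires an
explicit synonymous rate r — none is assumed, because no defensible
default exists.

A calibration subtlety the tests exercise: when a codon carries two
substitutions, pathway averaging can route through nonsynonymous
intermediates, so Ka can be slightly positive even when every realised
substitution was synonymous. At the calibration divergence (Ks ≈ 0.2)
this, plus the JC approximation, leaves mean ω̂ within about 10% of the
planted acceptance ratio at ω ∈ {0.1, 0.5, 1.0}.

## Expression

Replicates are averaged on the Ct scale before ΔCt = Ct_target −
Ct_reference and ΔΔCt = ΔCt_sample − ΔCt_control; fold = E^(−ΔΔCt) with
E = 2 by default (an `efficiency` parameter accepts validated values below
2). No confidence intervals are computed by default. Two exact invariants
anchor the tests: the control sample's fold is 1 by construction, and
adding a constant to every Ct of one sample leaves all folds unchanged.
BH adjustment is the standard step-up, delegated to
`statsmodels.multipletests` behind a validating wrapper and checked
against a brute-force definition in tests.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed); each draws from its own
sub-stream derived from (seed, generator id), so adding a generator never
perturbs another's output. Background protein composition is uniform
except glycine at 7% (roughly proteome-typical), which makes the
domain-only decoys non-trivial: their glycine content is then *capped* at
9/20 per window so they sit below the 11/20 threshold with a margin of
one. Planted members place a 14/20-glycine window after the last domain.
Genome pairs plant ordered ortholog segments (optionally inverted) among
filler genes, with insertions/deletions at a configurable rate and
adjacent-rank tandem copies of block genes; homology noise is a configured
*count* of uniform non-orthologous pairs, keeping test expectations exact.
Codon pairs evolve by proposed point mutations (Poisson per site),
accepting synonymous changes always and nonsynonymous ones with
probability ω, rejecting stops — so ω is an acceptance ratio, the quantity
NG86 estimates. Ct tables put the reference gene at a constant baseline
and subtract the log2 effect from the target's Ct, with Gaussian noise
(sd 0.2, 3 replicates by default).

What passing these tests shows: the implementations are internally
correct (oracle-equivalent), deterministic under seeds, and recover
planted structure perfectly in the noiseless regime. What they do not
show: robustness to real-data phenomena the generators omit — fragmented
assemblies, split/merged gene models, codon usage bias, rate variation
across sites and lineages, domain-call boundary errors, and qPCR
efficiency drift. Real-genome rosters therefore need the usual manual
curation even when every test here is green.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 1000-sequence
oracle scans, 100 additive matrices (n ≤ 12), 200 NG86 calibration
replicates of 300 codons per ω, 40–200 bootstrap replicates, 100 simulated
Ct tables. Scaling any of these up is a matter of the corresponding
parameter; defaults that mirror published practice (bootstrap 1000,
min_anchors 5, E < 10⁻⁴, >50%/20-aa glycine rule, |Δrank| = 1) are kept at
those published values.
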