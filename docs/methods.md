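# Methods

## The estimation problem

An antibody library is a collection of highly similar coding sequences
(~360–380 nt single-domain VH constructs, or ~700–800 nt scFv
constructs) whose diversity cannot be referenced against a genome:
every discrepancy between two reads is either biology (a genuinely
distinct member) or a technical error, and deep-sequencing coverage is
far below saturation.  `dealkit` resolves the ambiguity with two
independent per-base reliability descriptors and collapses reads into
identity clusters only where the disagreement is *reliable*.

## Preprocessing model

Reads arrive demultiplexed per index.  Each of the four indexes carries
a different number of "shifter" bases between the sequencing primer and
the insert (R1: 0/1/7/8, R2: 13/12/11/10); removing them re-aligns all
reads on the insert while ensuring that a systematically bad cycle hits
a different insert position in each index, which is what makes per-cycle
error compensation possible downstream.  Reads are kept when their
median Phred score is ≥ 32; for even-length quality vectors the median
is the *lower* middle value (a conservative choice; the convention is
not otherwise fixed).  Reads are then cropped to fixed lengths (R1
320 nt, R2 220 nt — applied after shifter removal so that all
pseudo-reads align position-for-position), re-paired by id, and either

* concatenated (scFv): pseudo-read = R1 + revcomp(R2), 540 nt, with a
  per-position record of the originating mate and sequencing cycle
  (reverse-complementing reverses cycle order); or
* overlap-merged (VH): the reverse-complemented mate is slid ungapped
  along the forward read; the offset maximising matches − mismatches
  wins provided the overlap is ≥ 30 nt with ≤ 10% mismatches.  In the
  overlap, a concordant position keeps the higher of the two qualities;
  a discordant position keeps the higher-quality base; a discordant
  *tie* keeps the forward base demoted to the lower quality, so the
  position is likely flagged downstream — a deliberate conservative
  propagation of uncertainty.  Offset search uses exact 16-mer probes
  with a full-scan fallback, so occasional errors in a probe window do
  not lose the pair.

An optional adapter-dimer purge (first 12 bases matching the mate
adapter with ≤ 1 mismatch) is available when adapter sequences are
supplied; the original pipeline delegates this to an external trimmer
without stating parameters, so a minimal logged heuristic is used.

All user-facing coordinates (seed regions, flagged positions) are
1-based; intervals are end-exclusive, so the default scFv seed regions
(280, 300) + (470, 490) give a 40 nt seed.

## Error model

Per-cycle mismatch percentages are measured by placing control-phage
spike-in reads at their best ungapped offset on the control reference
(both strands; k-mer probes, dense-probe fallback, no indel alignment —
indel rates on this platform are negligible for the purpose).  Reads
below 70% best identity are excluded as non-control; the cutoff is a
logged default.  Cycles never observed are *absent*, not zero.

A pseudo-read position is flagged unreliable when any of:

* reported quality < 32 (`min_phred`),
* control mismatch rate of its originating (mate, cycle) > 1%
  (`max_cycle_error`),
* the base is N or an ambiguity code,
* its cycle is absent from the profile (fail-unsafe: the premise of the
  design is that Phred alone cannot be trusted).

Flagging is monotone in both thresholds.  The profile is aggregated
over tiles by default; per-tile granularity is representable in the
profile format but flagging at tile level is not enabled by default.

## The collapse

Reads are partitioned by exact identity of the seed (concatenated CDR3
substrings).  Seeding ignores flags: an error inside a seed creates a
singleton rather than a false merge.  Within a group, each read is
compared in input order against the consensus of every existing cluster
(creation order) and joins the first match — input order is preserved
from file order and is part of the contract, making runs reproducible.
The three per-position outcomes:

1. both sides reliable, bases differ → the sequences are distinct
   (no grouping);
2. exactly one side flagged → the reliable base wins and the position
   becomes unflagged.  This also discards any ambiguity previously
   accumulated there, so a later reliable conflicting base forces a
   split rather than silently extending ambiguity;
3. both sides flagged → the merged base is the IUPAC code of the union
   of the two base sets (three or more accumulated bases extend the
   union naturally, e.g. A∪G∪T → D) and the position stays flagged.

Sequences are stored as 4-bit base masks, so the union is a bitwise OR
and a whole comparison is a handful of vectorised operations.
Comparison is against merged consensi, not against all prior members —
the cheaper of the two readings of the sequential-comparison rule, and
the one implemented here.  Reads of unequal length never match, which
is how variable-length (VH) input is supported.

## Complexity estimation

Let `Nseq(x)` be the number of clusters of cardinality `x`.

* **Observed complexity** = total cluster count.
* **Minimal complexity** = clusters with `x ≥ 2`.  The singleton class
  additionally contains every read whose errors escaped flagging, so it
  is excluded from the lower bound.
* **Theoretical complexity**: nonlinear least squares of
  `Nseq(x) = C · NB(x; p, s)` over `x ∈ [x_min, x_max]`, default
  `x_min = 2`.  The pmf is the *untruncated* negative binomial, so `C`
  estimates the total complexity including the unobserved zero class;
  `C` may legitimately exceed the observed cluster count.  A 13×13
  (p, s) grid with the closed-form optimal `C = Σyf/Σf²` at each node
  seeds a bounded least-squares refinement (best four starts); `C` is
  optimised on a log scale.  Least squares on counts (a regression fit)
  is used rather than maximum likelihood, which is out of scope.  The
  fit is scale-equivariant in the counts.
* **Outliers**: clusters whose log-cardinality exceeds
  median + 3.5·MAD are reported (their count is a library-balance
  indicator) and excluded from the fitted histogram — backbone
  contamination is not library diversity.  With the vector backbone
  sequence supplied they are annotated by ≥ 90% ungapped identity; for
  concatenated (scFv) pseudo-reads the two blocks are matched
  separately via `join_point`, since the pseudo-read is not a
  contiguous substring of the vector.

## Protein-level diversity

Frame class is `(length − anchor_offset) mod 3`; the anchor is the
first codon base from the fixed construct geometry (0 for the
simulator's constructs, which start at the coding scaffold).  Codons in
the CDS are expanded over their IUPAC ambiguity sets: a codon whose
every expansion is a stop is a *definite* stop; one with both stop and
non-stop expansions is a *possible* stop and translates to X.  Since an
error-flagged position may or may not be real, functional quantities
are ranges: the conservative bound excludes possible stops, the
optimistic bound only definite ones.

In-frame clusters are synonym-collapsed greedily; X matches any single
residue (parallel to the nucleotide flag-merge philosophy; a
strict-identity mode exists), but X never matches a literal stop —
a stop is not a residue.  A protein group's stop status is the most
optimistic among its members: one member that certainly encodes the
protein stop-free makes the group functional.  Definite-stop
translations carry a literal `*` and can only merge with other definite
stops.  Out-of-frame clusters cannot be translated; each counts as its
own protein-level group.  Percent-in-frame is computed over nucleotide
clusters, percent-without-stop over in-frame clusters, and full-CDS as
their product.  The two-chain (scFv) functional fraction is reported as
the square of the single-chain full-CDS fraction — explicitly an
independence assumption between chains.

## Primer assortment

Class assignment takes the fewest-mismatch primer over an anchored
window at the 5' or 3' end; degenerate primer bases match any of their
expansions.  Ties and matches beyond `max_mismatch` (default 2 — the
tolerance is not otherwise specified, so it is configurable) are
Unclassified rather than arbitrarily resolved, which avoids inflating
any class.  Expected pair frequencies are the outer product of the
classified marginals; the per-cell log2(observed/expected) matrix and a
descriptive chi-square statistic summarise departures from independent
assortment.

## The simulator

`dealkit.simulate` emulates the experiment at sequence level:

* **Constructs**: a forward-primer scaffold (one of six 21 nt V-class
  recognition sequences), constant framework segments, a 30 nt variable
  region (CDR1/2-like), a hypervariable CDR3 (30–48 nt in codon steps
  for VH; two fixed 42 nt stretches for scFv) positioned to cover the
  clustering seed windows, and a reverse-primer scaffold (one of five
  J classes).  All random coding stretches are drawn from the 61
  non-stop codons with segment boundaries codon-aligned, so stop codons
  occur exactly where the truth table says.  Frameshifted members get
  1–2 extra bases inserted in the CDR3; stop-bearing in-frame members
  get one CDR3 codon replaced by a stop.  Distinctness is enforced on
  the full sequence and is always visible inside the sequenced windows.
  For scFv the construct length (default 750 nt) keeps the two reads
  non-overlapping (320 + 220 < 750); VH lengths (360–378 nt) guarantee
  ≥ 160 nt of overlap.
* **Abundance**: uniform, lognormal, or negative-binomial copy numbers
  (the experiment's true abundance law is unknown, so it is a choice,
  not an assertion).  Read counts are multinomial in the weights by
  default; `coverage="exact"` assigns deterministic proportional counts
  for conditions that presume every member is observed.
* **Errors**: per-cycle substitution rates = baseline plus spike
  windows, identical for library and control reads; indels are not
  simulated.  Reported Phred is the calibrated value of the true rate
  except inside a configurable early-cycle window (default cycles
  1–40) where a fixed high score is reported regardless — reproducing
  the regime where reported quality fails to predict the mismatch rate,
  so that control-profile flagging is genuinely exercised.
* **Control spike-in**: reads drawn from a fixed *synthetic* control
  reference (5386 nt, generated deterministically; it stands in for a
  control-phage genome at the sequence level) with the same
  cycle-indexed error process.
* **Truth**: per-read source id, index, injected error cycles, V/J
  class, frame and stop status; byte-identical outputs under identical
  config + seed.

What the simulator does **not** model: PCR chimeras, indels, per-tile
spatial effects, cluster-density optics, quality-score jitter within a
cycle.  Passing tests therefore demonstrate the pipeline's logic under
controlled error structure, not performance on any particular real
instrument run.

## Problem sizes and numerical choices

The test-suite and acceptance runs use 400–5000 unique members,
6×–7.5× coverage, and 10–30k read pairs — comfortably past the regime
where the collapse and the fit behave asymptotically, and the
negative-binomial recovery check uses 10⁵ members (copy-number level).
Degenerate inputs: empty read sets yield complexity 0 with a warning
path; a fit needs ≥ 3 distinct cardinalities; an all-unclassified
assortment is an error.  Greedy collapse is order-dependent by
construction (as any sequential identity collapse); order is logged via
the member lists.  The fit bounds are p ∈ (10⁻⁶, 1−10⁻⁶),
s ∈ (10⁻⁴, 10⁴), log C ∈ (−5, 60).

## Known limitations

* Approximate (mismatch-tolerant) seed grouping is deliberately out of
  scope; an error inside a seed region always creates a singleton.
* The collapse compares to consensi, so extremely adversarial orderings
  can split groups that member-wise comparison would join.
* `C` from the fit carries no confidence interval beyond multi-seed
  spread; MLE and richness estimators of the Chao family are non-goals.
* Protein grouping with the X wildcard is not transitive; the greedy
  order is the read/cluster order.
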