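# Methods

## The index

The index **F** is an array of `m` signed integers addressed by `n` hash
functions. Building processes genomes sequentially; for each k-mer of each
genome (forward and reverse-complement strand) and each of its `n` hash
positions the entry is updated as: empty (0) → genome id; same id →
unchanged; another genome's id → dirty (−1); dirty → unchanged. The final
entry state is therefore independent of genome insertion order: an entry
holds id `g` iff only genome `g` ever wrote it, and −1 iff at least two
distinct genomes did.

A query gathers the `n` entry values of a k-mer and returns genome `g` only
on a unanimous positive vote; otherwise the k-mer is discarded. Because both
strands were inserted, queries look the k-mer up as read. Two consequences
shape the method's error profile:

* **No wrong ids for unique k-mers.** A k-mer present in exactly one genome
  can only return that genome or be discarded — its entries were all written
  by its own genome (possibly dirtied by collisions), never cleanly by
  another. Shrinking `m` raises the dirty rate and therefore the discard
  rate, but cannot create misattributions of this kind.
* **False positives come from novel k-mers.** A k-mer absent from every
  reference (a sequencing error, or an error that reconstructs a related
  strain's variant) can hash onto a unanimous set of one genome's entries
  and cast a spurious vote. This is the error class the coverage filter
  exists to absorb.

Entries are stored in the narrowest signed dtype that fits the genome count
(int8/int16/int32). The default `m` keeps the expected load factor at or
below one half, estimated from total genome length (distinct k-mers ≈ 2 ×
total bp, times `n` writes). k is limited to 1..32 so a k-mer packs into a
single 64-bit code; the default k = 31 is the conventional species-level
choice for bacterial k-mer methods.

### Hash family

Each of the `n` functions XORs the packed k-mer code with a per-function
64-bit seed, applies the murmur3 `fmix64` avalanche finalizer, and reduces
mod `m`. Per-function seeds derive from one master seed via a splitmix64
recurrence, so an index is fully reproducible from `(genomes, k, m, n,
master_seed)` — identical inputs give bit-identical entry arrays. k-mers
containing an ambiguous base (N) are skipped at build and discarded at
query; ambiguity carries no signature information.

## Read classification

Every k-mer window of a read that passes the quality gate is queried; the
read is assigned to the modal genome id iff its share of surviving votes
strictly exceeds `majority_threshold` (default 0.5, i.e. "more than half").
Ties at the threshold, modal ties between two ids, reads shorter than k, and
reads with no surviving votes are discarded — the deterministic reading of a
majority rule in the unanimity spirit of the index. Paired mates are
classified independently. The quality gate discards k-mers whose mean Phred
score is below `quality_threshold` (default 0 = off); it applies only at
query time, since references carry no quality strings. Raising the gate can
only shrink each read's vote set, which is the basis of the monotonicity
properties asserted in the tests.

## Coverage filter

For each called species, approximate coverage = total identified read bases
/ genome length (for uniform read length L this is reads × L / genome
length; the base-count form also handles mixed-length input). Species with
zero identified reads never enter the table.

Species are clustered by coverage with 1-D K-means, K = 2 by default
(present vs. artifact), on log10 coverage — coverages span orders of
magnitude, and on a linear scale the split is dominated by the single most
abundant species. The cluster with the lowest mean is removed, whatever K.
In one dimension the K-means optimum is a contiguous partition of the
sorted values, so it is solved exactly by dynamic programming over split
points (O(K n²) with prefix sums) instead of Lloyd iterations with random
restarts: restarts were observed to land in local optima on ordinary inputs,
and an estimator of "the lowest-mean cluster" should not depend on a random
seed. The `seed` argument is retained in the result and report for
provenance and interface stability; it does not affect the partition.

Degenerate inputs skip filtering: fewer species than K, or zero variance in
(scaled) coverage, return a sentinel result that keeps every species.

The filter is classifier-agnostic: `ingest_external_assignments` builds the
same coverage table from any tool's per-read `read_id → species` TSV plus a
genome-length table (with a uniform read length when the TSV lacks one).

## Evaluation

Species sets are scored with precision = TP/(TP+FP), recall = TP/(TP+FN)
and their harmonic mean F1; empty denominators score 0. Identity is by
normalized name (case-folded, whitespace-collapsed) — the package carries no
taxonomy database, and rank-aware matching is out of scope.

## The simulator

`CommunitySpec` describes a reference universe of i.i.d. uniform-ACGT
genomes (default 20 × 20 kb), a present subset (default the first half),
target coverage per present species (default 2×), read length (default 75
bp, a common short-read regime), and a substitution-only error model
(default rate 0.5% per base). Read count per species is
round(coverage × genome length / read length); positions are uniform over
both strands. Correct bases draw Phred scores around mean 38, erroneous
bases around mean 12 (sd 3, clipped to 2..41), giving the quality gate a
signal aligned with how base callers down-weight miscalls. Everything is
deterministic under the master seed, including the FASTQ byte stream.

`strain_pair_community` is the canonical stress design: each present genome
has an absent twin at 2% per-base divergence in the index universe. k-mers
shared between twins go dirty (lowering the identified-read rate to ~70%),
and a sequencing error at a divergent site occasionally reconstructs the
absent twin's unique k-mer, producing genuine low-coverage false species —
the strain-variation failure mode the coverage filter targets, at desk
scale.

What the simulator does **not** emulate: indels, position- or
motif-dependent Illumina error profiles, GC bias, repeat structure and
mobile elements within genomes, realistic (log-normal) abundance
distributions, or contamination. Passing tests therefore demonstrate the
method's internal logic — index soundness, vote arithmetic, filter
behavior under coverage separation — not its accuracy on real microbiomes.

## Problem sizes and numerical choices

The test and acceptance workloads use 10–20 genomes of 20 kb, ~5,000 reads
per sample and 50 replicates for the filter-recovery check — large enough
that each stage's statistics are meaningful (hundreds of thousands of
distinct k-mers, 2–7 spurious species per replicate), small enough to run
comfortably on a laptop. Cluster means are compared exactly (ties broken by
the smallest label); WCSS comparisons in tests use an absolute tolerance of
1e-9; the index's no-wrong-id property is checked exhaustively against an
exact k-mer dictionary rather than sampled.

## Known limitations

* When no false positives are present and true coverages are tight but not
  identical, removing the lowest-mean cluster discards genuine species
  (recall loss with precision 1.0). The zero-variance sentinel does not
  guard this unimodal case; inspecting the cluster-mean gap in the report
  is advisable before trusting the filter on low-complexity samples.
* Genome ids, not taxonomy: two reference assemblies of the same species
  compete for k-mers and dirty each other's signatures.
* k > 32 is unsupported by the packed-code fast path.
* The classifier holds per-read state only; no pair-aware rescue of a mate
  whose partner was identified.
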