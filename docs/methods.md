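# Methods

## The graph model and its accounting

A pangenome graph is stored as GFA-style segments (DNA nodes), a set of
canonical oriented links, and named haplotype paths. Links are canonicalized
so that a traversal a+→b+ and its reverse complement b−→a− are the same
edge; the link set therefore has true set semantics. Path names follow
PanSN (`sample#haplotype#contig`); names without `#` are tolerated as
`sample == contig`, haplotype `"0"`, so plain FASTA contig names work as
reference paths. GFA v1.0 (S/L/P, overlaps `0M`/`*`) and v1.1 (W-lines) are
read and written; serialization orders segments by id, links
lexicographically, and paths by name, so the writer is byte-deterministic
and `parse(write(G)) == G` on the model.

Mean degree is **links / segments** (not the graph-theoretic 2E/N); this is
the convention under which whole-genome chicken pangenomes with 49M/67M and
33M/45M nodes/edges both report 1.4 at one decimal, and summaries round it
to one decimal accordingly. `total_length` is the sum of segment lengths
and is path-independent; `path_length` counts repeated traversals
(A + 2B + C for a tandem-duplicated B); `traversed_length` per sample is
the length of the union of touched segments, so a duplication makes
`path_length` strictly exceed it.

Coordinates are 0-based internally; every reported reference position is
1-based (VCF convention). Projection of an off-reference base walks
backwards along a haplotype path through the segment to the nearest
on-reference segment and returns its last preceding reference base with
`on_reference = false`; on reference segments the first traversal of a
looping reference path wins.

## Bubble detection and variant calling

Anchors between the reference path and a haplotype path are computed as the
longest strictly increasing subsequence (LIS) of reference indices over the
haplotype's steps (orientation must match). This is the LCS of the two
node-id sequences when reference ids are unique — which the generator
guarantees — at O(n log n) instead of quadratic cost. The patience-LIS
tie-break keeps the *later* copy of a tandem-duplicated block as anchors,
so the extra copy surfaces as an insertion *before* the block, already in
left-aligned form. Maximal deviating intervals between consecutive anchors
become bubbles; each haplotype's genotype at a bubble is resolved by exact
walk match (reference walk → allele 0, each distinct alternate walk → an
alt allele; haplotypes missing either anchor → missing genotype).
Haplotypes sharing no anchor at all are reported as uncalled rather than
raising.

Biallelic records are normalized with the standard parsimony/left-alignment
algorithm (trim shared trailing bases, extending left over the reference
when an allele would empty; then trim shared leading bases). Multiallelic
records get shared prefix/suffix trimming only — no left shift — since a
joint shift is not well defined. Record kind is SNV/INS/DEL when the
allele shapes agree, COMPLEX otherwise; indel or SV alleles with a length
difference above 50 bp are flagged structural. SVs are reported only as
insertions and deletions (a tandem duplication is an insertion of the
block; no INV/TRA classification).

**Nested variation.** When a bubble has several distinct alternate walks
that share internal anchors (e.g., an insertion whose carriers differ at
internal SNVs), the most common internal walk — ties broken by smallest
sequence — becomes the *backbone*: the parent record stays biallelic
(insertion present/absent), and each internal deviation is emitted as a
child record with a 1-based offset into the inserted sequence
(`INFO PARENT=<id>;SUBPOS=<offset>` in VCF, placed at the parent's anchor
POS). Parents with children are deliberately *not* left-shifted, because
child offsets are defined within the un-rotated insertion allele. Child
genotypes are missing for haplotypes that lack the parent insertion — they
have no sequence at the site. Alternate walks that do not share clean
anchors with the backbone remain additional alleles of the parent.

## Synthetic pangenomes

The generator draws a uniform-random reference sequence, places structural
events first and then rate-driven small variants (SNV count ~
Binomial(L, snv_rate); indels with geometric lengths, p = 0.5, insertion
and deletion equiprobable), realizes every variant as a minimal bubble by
cutting the reference into segments at variant breakpoints, and derives
links implicitly from the paths. One seeded NumPy generator drives all
randomness; identical configs give byte-identical GFA/FASTA/VCF. Event
placement is rejection-sampled with a 1 bp guard and a 1000-try bound;
small variants are kept outside structural-event footprints so that every
truth record corresponds to exactly one bubble and truth genotypes are
unambiguous. Carrier sets default to a uniform 1..(n−1) carrier count.

Nested SNVs inside an insertion share a single carrier subset drawn as a
strict minority of the insertion carriers (hence ≥ 3 carriers are required
when nesting), so the unmodified insertion sequence is always the majority
internal allele and the caller's backbone rule recovers the truth
representation exactly. Nested offsets avoid the first and last inserted
base to keep the insertion's terminal segments as shared anchors. The
mobile-element insertion is a fixed 7.5 kb random block (the real ev21
element is "over 7 kb") labeled `SOURCE=ELEMENT_INS`; a duplication's truth
record is the left-normalized insertion of its block and carries
`SOURCE=DUP`.

The truth set can rebuild every haplotype by pure string editing of the
reference — an oracle independent of the graph construction — and the test
suite requires byte-identical agreement with the graph-derived sequences,
plus exact recovery of all records (position, alleles, carriers, genotypes)
by the caller.

What the generator does **not** emulate: realistic chromosome structure,
repeat families, clustered or overlapping variation, assembly errors, and
missing assembly coverage (every haplotype spans the whole reference).
Passing tests therefore demonstrate correctness of the algorithms on clean
bubble graphs, not robustness to the pathologies of real assemblies.

## K-locus fixture

The fixture reproduces the topology of the chicken K feathering locus with
seven labeled diagnostic edges: all paths enter via e1; at the element
juncture a path skips via e5 or takes e6 → element (7.5 kb) → e7; at the
duplication fork it exits via e2 or loops back via e3 → a 30 bp junction
segment → e4 to traverse the 3 kb duplicated block a second time (the
late-feathering allele). The junction segment is a modeling choice — a
pure tandem loop would need only a single back edge, but the two-edge loop
lets the fixture expose separate e3/e4 junctions. Segment sizes (2 kb
flanks, 3 kb pre-block, 2 × 1.5 kb block) are desk-scale stand-ins. An
early-feathering ev21− haplotype touches exactly {e1, e5, e2} among the
labeled edges and every node it covers exactly once.

## Edge-support SV genotyping

A read (GAF walk plus aligned interval) supports an edge iff the walk
contains the oriented segment pair and the alignment covers at least one
base on each side of the junction; a read ending exactly at the junction
does not count. Events with several required edges on one side use the
minimum per-edge count (bottleneck rule). With k presence reads out of
n = k_presence + k_absence informative reads, two exact two-sided binomial
tests are run: H_present: θ = θ_present and H_absent: θ = θ_absent.
Call = present iff H_present is retained and H_absent rejected at
α (default 0.05); absent in the reverse case; inconclusive when both are
retained *or both rejected*; and no_data when n < min_reads (default 4) —
distinguishing absence of evidence from evidence of absence. Defaults:
θ_present = 0.98 and θ_absent = 0.02 for a simple insertion (ε = 0.02
noise), θ_present = 0.5 for a hemizygous tandem duplication, because a
carrier chromosome traverses the loop-back and the exit edge once each.

A consequence of exact two-sided testing worth knowing: at n = 30 and
θ_present = 0.5 the true hypothesis itself is rejected for k ≤ 9 or
k ≥ 21, i.e., with probability ≈ 4.3%, so a few percent of true
duplication carriers are *inconclusive* (never miscalled) at 30×. The test
suite asserts zero present↔absent swaps, ≥ 99% correctness of conclusive
calls, and an inconclusive fraction under 5%.

## Read simulation and accuracy scoring

Fragments are sampled uniformly along selected path sequences (paths
weighted by length, fragment length ~ Normal(400, 60) clamped to the
read length); fragments overlapping path ends are resampled, not clipped.
Per template base: an indel event starts with probability 0.00029
(insertion of random bases or deletion of template bases, geometric length,
p = 0.5), otherwise the base is emitted with substitution probability
0.0024 (uniform over the three alternatives). Defaults follow empirical
short-read error estimates. Quality strings are a constant Q30
placeholder. Truth tables record the pre-error origin (path, 0-based
start, strand) per mate.

Alignment accuracy is the fraction of **all** simulated reads that are
mapped, pass a mapq ≥ t filter, and lie within a tolerance (default
100 bp — the comparison window is a free parameter, chosen to absorb
small coordinate jitter) of their truth origin, for t = 0..60; unmapped
and missing reads count as incorrect, which makes the curve monotone
non-increasing by construction. Graph alignments are projected to
reference coordinates through their first aligned base for comparison
against projected truth.

## Reference bias

The pileup counts aligned (match/mismatch) bases only, after dropping
unmapped, secondary, and supplementary records and mapq < 10; base
qualities are ignored; depth is capped at 100 in read order (cap first,
then filter — so the het decision is made on capped counts, matching
pileup-tool behavior at that setting). A putative heterozygous site has
capped depth ≥ 10 and a second-most-frequent base holding ≥ 25% of the
depth. The *minor* allele of the filter is the second-most-frequent base,
reference or not; the *alternate* allele of the statistic is the
most-frequent non-reference base (ties broken in A<C<G<T order) — the two
notions are deliberately kept distinct. Bias is |mean alt fraction − 0.5|
with the sign reported separately; the reduction between a linear and a
graph pipeline is 100·(bias_linear − bias_graph)/bias_linear, computed
per sample and averaged when several samples are compared.

## Concordance

Records below QUAL 10 are dropped first (records with no QUAL are kept);
two records match when they share contig, position, and reference allele
and have at least one alternate allele in common; each record matches at
most one partner. Genotype agreement compares unordered multisets of
resolved allele *sequences* (so 0/1 == 1/0 and allele reordering between
files is harmless). A missing genotype against a called one is a
disagreement; two missing genotypes agree (configurable). Samples with no
shared sites are reported as NA and excluded from the mean/SD (sample SD,
ddof = 1). SNV vs indel subsetting classifies a record as SNV iff all its
alleles have length 1.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data at
desk scale, chosen to make every statistical check well-powered while the
full suite stays fast: truth recovery on a 100 kb, 12-haplotype graph with
all event classes; error-rate recovery over 3 × 10⁶ simulated bases with
3σ binomial bounds; 500 simulated SV events at 30×; 2,000 heterozygous
sites at depth 30 for bias recovery (standard error of the mean fraction
≈ 0.002, against a ±0.01 band); 200 random graphs against the brute-force
attribution oracle. Greedy ties in attribution are broken
lexicographically by sample name; all tie-breaks in the package are
deterministic so that fixed seeds give byte-identical outputs.

## Known limitations

* Bubble anchoring assumes the reference path visits each segment once
  (true for generator output); heavily looping reference paths would fall
  back to first-occurrence indexing and may merge anchors.
* Terminal deviations (before the first or after the last shared anchor)
  are not called.
* Nested calling handles internal SNVs and simple internal indels; deeply
  recursive nesting (variants inside nested alleles) is not modeled.
* The read simulator has no base-quality profile, PCR duplicates, or
  GC bias; the pileup ignores base quality by design.
* Genotype comparison is haplotype-unaware (phasing is ignored).
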