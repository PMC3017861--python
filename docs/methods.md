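# Methods

`venomest` re-implements, as one tested pipeline, the analysis stages of a
classic venom-gland EST (expressed sequence tag) project: single-pass cDNA
reads are cleaned, clustered into unisequences (contigs + singletons),
annotated against labeled reference collections, profiled for toxin-class
abundance, and mined for SNPs/indels, microsatellites, transposable
elements (TEs), TE–host chimeric transcripts, and long inverted repeats
(IRs). Because the original raw traces and era-specific databases are not
reproducible on a desk, the pipeline ships with a synthetic-library
generator that emulates the statistical structure of such a library and
records complete ground truth, so every stage is tested end to end with no
downloads.

## Local alignment and E-values

All similarity searches use one affine-gap Smith–Waterman engine
(numba-compiled). The default nucleotide scheme is BLASTN-like: match +1,
mismatch −3, gap open −5, gap extend −2 (a length-L gap costs
`gap_open + L·gap_extend`). `N` always scores as a mismatch (conservative).
Coordinates are 0-based half-open internally; report files print 1-based
inclusive.

Significance uses ungapped Karlin–Altschul statistics applied to gapped
scores: `E = K·m·n·exp(−λS)`, with λ solved from
`Σᵢⱼ pᵢpⱼ exp(λ·sᵢⱼ) = 1` by Brent's method (rel. tol. 1e-12) and K a
stored constant (default 0.5). This is an approximation — a gapped λ/K
would need simulation — but E-values here only implement coarse cut-offs
(1e-5 for annotation, 1e-10 for repeat search), and both λ and K are
configurable. Effective lengths m and n are raw lengths (no edge
correction). Search-space n is the total length of the database searched.

Multiple hits per query are reported by masking the covered query interval
and re-running, so hits never share query letters; the returned list is
sorted by score with ties broken by smallest query then subject start.
Within the dynamic program, tied optima resolve to the smallest end
coordinates, which is equivalent for equal-length alignments.

## Synthetic library generator

The generator is the study-condition definition, not a test convenience.
Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_reads` | 5000 | library size |
| `n_plates` | 3 | sequencing plates (one library per animal) |
| `toxin_fraction_of_total` | 0.23 | toxin ESTs / all ESTs |
| `hit_fraction_of_total` | 0.30 | annotatable ESTs / all ESTs |
| toxin-class mixture | 0.81 / 0.088 / 0.056 / 0.019 / 0.015 / 0.012 | SVMP, BPP/CNP, PLA2, serine proteinase, C-type lectin, other toxins |
| length model | truncated normal on [100, 848] bp, mean 562, sd 150 | post-cleaning read length |
| `per_base_error` | 0.005 | substitution rate |
| vector prefix | p=0.3, 20–60 bp | 5' cloning-vector contamination |
| polyA tail | p=0.5, 15–30 bp | 3' tail |
| quality profile | PHRED 40 − 0.015/base, jitter sd 2 | linear 3' decay |

The truncated-normal *location* is solved numerically so that the mean of
the truncated distribution equals the target mean; naively centering the
normal at the target would bias the realized mean ~10 bp low because the
upper truncation bites harder than the lower.

Each read samples a class group (toxin / other-hit / unknown), a toxin
class by the mixture, a template by abundance weight, a uniform window of
the sampled length, planted alleles at their configured frequencies, a
deposition strand (so assembly must handle both orientations),
decorations, substitution errors, and a plate. Unknown-class templates are
random sequences absent from the reference collection — the no-hit
fraction is realized mechanistically, not by labels.

Within-group abundance weights are Dirichlet(1.5) with a floor
(`0.3/n + 0.7·Dirichlet`): EST libraries are strongly skewed, but every
template that carries a planted feature must be expressed for the
evaluation harness to be meaningful.

Planted features (default panel): 12 SNP loci (minor-allele frequency 0.5,
inside CDSs of metalloproteinase/PLA2/housekeeping templates), 4 short
deletions in 3'UTRs, 6 microsatellites spanning the motif classes, 3
pure-TE transcripts (BovB-, CR1-, L2-like elements with short flanks), 3
TE–host fusions (TE segment appended to a 700-bp host-gene fragment,
TE coverage ≈ 0.26), and 2 IRs — one with the classic architecture
(132-nt perfect arms separated by a 183-nt inter-IR domain) in a BPP/CNP
template, one smaller and slightly mutated. Two deliberate departures from
naive realism keep the evaluation identifiable: chimera host genes are
reference-only records (known to the databases, not independently
expressed — otherwise host and fusion transcripts co-cluster), and
TE-bearing templates carry distinct elements or disjoint segments
(otherwise the shared repeat bridges unrelated transcripts during
clustering, the classic repeat-induced misassembly).

What the generator does **not** emulate: chromatogram-level noise and
base-calling, quality-correlated error (errors are flat-rate
substitutions; qualities are a smooth decay), indel sequencing errors,
sequence similarity between paralogous toxin templates, realistic codon
usage, and 3'-anchored oligo-dT priming (windows are uniform). Passing
tests therefore demonstrate correctness of the algorithms under the stated
statistical structure, not performance on real traces.

## Cleaning

Stage order: vector excision → quality trimming → polyA/polyT trimming →
slippage flagging → length filter (< 100 bp discarded, strictly). Vector
removal comes first so contaminant bases cannot distort quality windows.

* Quality trimming keeps the longest segment whose every sliding
  20-base-window mean PHRED is ≥ 16.
* Vector intervals are any alignments to the vector library scoring ≥ 18
  (≈ an 18-bp exact match; chance hits at read scale have E ≈ 1e-6); if
  excision leaves disjoint fragments the longest is kept.
* polyA (3') / polyT (5') removal takes the longest terminal run whose
  innermost base matches, containing ≥ 10 matching bases and ≤ 1
  non-matching base. The run may extend through one mismatch into
  adjacent genuine A's — unavoidable for any mismatch-tolerant rule.
* "Slippage" is operationalized (it has no standard definition) as any
  50-base window in which one nucleotide reaches 80% of the bases or one
  dinucleotide's occurrences cover 80% of the window; flagged reads are
  discarded.

Cleaning only ever removes bases (every output is a contiguous interval of
its input) and is idempotent.

## Clustering and assembly

Pairwise overlaps are accepted when the best local alignment between two
reads (either orientation) spans ≥ 100 columns at ≥ 95% identity, both
boundaries inclusive, identity measured over the overlap alignment (not
the whole reads). Clusters are the transitive closure (union–find) over
accepted overlaps. Candidate pairs come from canonical (k=14, w=12)
minimizers, which guarantee a shared seed in any shared exact stretch of
≥ 25 bp regardless of the reads' relative phase; a shared minimizer also
fixes a diagonal, and pairs whose implied overlap on that diagonal is
< 100 bp are skipped without alignment. The index only proposes pairs —
acceptance is always the alignment rule.

Each cluster is assembled greedily: the highest-scoring edge seeds a
layout; the unplaced read with the best edge to a placed read is aligned
to the current consensus, placed with pads, and the consensus (per-column
quality-weighted majority; ties by cumulative quality then alphabetical
base; pad-majority columns are dropped from the consensus but kept in the
layout) is updated. Reads that cannot be placed at the overlap gates are
split off and assembled separately, so one input cluster can yield several
contigs — consensus correctness is favored over contig length. Canonical
ordering (reads sorted by id, deterministic tie-breaks) makes assembly
invariant to input order. This is deliberately a simple greedy assembler,
not a CAP3 re-implementation; the published contig/singleton totals of the
original libraries depend on the deposited traces and legacy tool behavior
and are out of scope.

## Annotation and abundance

Each unisequence is searched, both strands, against every reference record
(the synthetic reference collection stands in for the public protein /
nucleotide databases and carries class labels and CDS coordinates). Hits
require E ≤ 1e-5 over the total reference length; the class is the best
hit's label; a hit whose subject interval is disjoint from the CDS is
3'UTR-only. For coding hits the alignment path maps unisequence positions
into reference codon coordinates (the reading frame used later for SNP
classification); gap columns are frame-unknown.

Abundance is EST-level: a contig contributes its member-read count. Both
published denominators are reported — percentages of all ESTs and of toxin
ESTs — and report tables round to one decimal.

## SNPs, indels, microsatellites

A layout column yields a SNP iff: the contig has ≥ 3 reads; ≥ 2 alleles
each have ≥ 2 supporting reads with base quality ≥ 20 *and* ≥ 10% of the
usable reads at that column; supporting reads jointly span ≥ 2 plates; and
supporting reads are pad-free for 5 columns on each side. The plate rule
is the artifact control from preparing libraries/plates independently.
The 10% allele-fraction rule is this implementation's addition (standard
in quality-aware callers): without it, columns covered ~20× call spurious
SNPs whenever two reads happen to share a sequencing error. With the
default 0.5% error rate some such doublets still pass at moderate depth —
the default-run SNP list is "putative" in the same sense the original
surveys' lists were; the recovery guarantees are stated for the error-free
suite.

Indels: a maximal run of pad-containing columns yields one call when both
alleles meet the support/quality/plate rules. Reads with zero bases across
the run carry the deletion; reads with any base carry the insertion — gap
*placement* inside the run varies between reads in a progressive layout,
so classifying by exact pad pattern would be wrong.

Classification substitutes each allele into its codon through the inferred
frame (standard genetic code, Biopython translation): identical residues →
synonymous, else non-synonymous; outside the CDS → noncoding; unmappable →
frame-unknown. Symmetric in allele order by construction.

Microsatellites are exact tandem arrays of primitive 1–6-nt motifs with
minimum copies 12/7/5/4/4/4 (mono→hexa; external-tool thresholds are not
published, these are stated defaults), reported maximal and non-nested
with the motif in its lexicographically smallest rotation. Unisequences
carrying any TE annotation are excluded from the final microsatellite
tally (sequence-level exclusion).

## TEs, chimeras, inverted repeats

TE annotation gates, all applied to both-strand alignments against the
repeat library: E ≤ 1e-10, alignment ≥ 50 bp, identity > 80% (strict),
coverage ≥ 10% *of the unisequence* (the element-length reading of the
coverage rule is possible but not the default). One annotation per
non-overlapping query interval.

Chimera test: eligible iff total TE coverage lies strictly inside
(10%, 90%); the TE intervals are masked with N and the remainder searched
against the host references; chimeric iff the best hit involves ≥ 50% of
the *unmasked* length at ≥ 70% identity. The unmasked-length convention is
forced: a TE at 89% coverage leaves 11% of the full length, so a
whole-length 50% rule would be unsatisfiable. Note that under the default
+1/−3 scoring any positive-scoring alignment already exceeds 75% identity,
so the 70% gate only becomes active under milder scoring schemes; it is
implemented as printed and its boundary is exercised in tests with a
+1/−1 scheme.

IR discovery aligns each sequence against its own reverse complement and
keeps gap-free diagonal segments (one maximal-scoring segment per
positive-score excursion, so segments start and end on matches), mapped
back to forward coordinates as arm pairs with: arm ≥ 30 bp ("long" is not
defined in the source material; 30 is the stated choice), Hamming mismatch
fraction ≤ 10% (inclusive), self-alignment E ≤ 1e-5 over an L×L space, and
non-overlapping arms (which excludes the trivial self-match). The
automated mismatch rule replaces manual inspection of opposite-strand
self-alignments. Arms are gap-free deliberately: the motivating example is
a perfect palindrome, and gap-free arms admit an exact quadratic
brute-force verifier. Inter-IR length = right arm start − left arm end.
Chance extension of an arm by adjacent random matches can shift reported
coordinates by a base or two; the evaluation harness therefore matches
planted IRs by overlap, while exact-coordinate recovery is asserted on
full-length sequences (the 132/183 architecture round-trip).

## Evaluation harness

Calls are scored against the generator's registry. Each unisequence maps
to its majority true template; orientation and a column→template offset
come from the member reads' recorded origins (median over members, robust
to ±2-column pad shifts). SNP positions are mapped exactly by majority
vote across supporting reads (undoing each read's planted deletion
alleles); interval features use the affine map with a ±5 tolerance and
overlap semantics for TEs/IRs. Matching is many-to-one: one planted
feature may legitimately be recovered on several unisequences when a
template tiles into more than one contig. Sensitivity = planted features
matched / planted; precision = calls matching a planted feature / calls;
an empty call set reports precision as undefined (null). Microsatellite
precision is measured against templates that carry planted arrays (chance
arrays in random sequence are otherwise counted as false).

## Problem sizes and determinism

The composition suite runs 5,000 reads (the published library is 5,350;
5,000 keeps binomial error on every target percentage below ±1.5 points at
two sigma) over ~60 transcript species, completing in a few minutes on one
CPU. Planted-feature recovery uses a focused 1,000-read configuration
(fewer templates, zero error) so every SNP locus sees well over the 6×
coverage the calling rules assume. All randomness flows from a single
integer seed through `numpy` `SeedSequence` spawning; identical seed and
configuration give byte-identical artifacts.

## Known limitations

* Greedy progressive consensus can split a template into multiple contigs
  at low coverage, and gap placement near indels is not normalized
  (left-aligned); the indel caller compensates.
* E-values are ungapped statistics on gapped scores; absolute values are
  approximate, cut-off behavior is what is relied upon.
* The annotation model is a single labeled reference collection; the
  original multi-database hit/no-hit contrast is out of scope.
* Toxin paralogs are sequence-independent in the generator, so annotation
  is easier than against real multigene families; class-assignment
  accuracy on real data would be lower.
* The published dataset totals (contig/singleton counts, 132 SNPs, 492
  TE-bearing unisequences, etc.) depend on deposited traces and legacy
  databases and are intentionally not reproduction targets; the targets
  are the composition percentages and the stated recovery guarantees.
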