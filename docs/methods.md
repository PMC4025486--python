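# Methods

This note records the models, rules and numerical choices behind
`apakit`, and what the synthetic benchmark does and does not establish.

## Tail detection and orientation

A poly(A) tail is the *longest* terminal window of a read whose adenine
fraction is at least `min_purity` and whose length is at least
`min_tail_length` ("maximal by left extension"). Two platform rule sets
are provided: `EST` (≥ 10 nt, purity 1.0 — classic EST chemistry yields
long clean tails, and purity below 1 is not meaningful for a strict
A-run) and `NGS` (≥ 15 nt, purity ≥ 0.95). `N` counts as non-A.
Purity is evaluated over the terminal window, not over an arbitrary
internal segment; a consequence worth knowing is that a sufficiently
long tail can absorb one non-A base from the read body (20 A's plus one
body base is still 0.952 pure), which shifts the mapped 3' end — and
hence the called site — upstream by a nucleotide. This behaves like
extra microheterogeneity and is absorbed by PAC clustering.

Reads recorded from the antisense strand of the cDNA begin with a
poly(T) run. A read is reverse-complemented (and flagged) when its
reverse complement, but not the read itself, carries a qualifying tail.
When both ends qualify the trailing A-run wins: the read is treated as
already sense-oriented, which avoids double-counting chimeric inserts.

## Mapping and site calling

Trimmed bodies are unspliced 3'-terminal fragments, so a spliced
aligner is unnecessary: bodies are placed by an exact, unique match of
their 3'-terminal 20-mer, extended maximally toward the 5' end. Seeds
are retried at 3'-end offsets 0..3 so that nontemplated additions
between the mapped end and the tail are tolerated; the successful
offset is the read's nontemplated count. Ambiguous seeds (more than
one hit over both strands) discard the read — no multi-mapping
resolution is attempted.

At the aligned 3' end, up to 4 trailing genomically-encoded adenines
are reassigned to the tail (they cannot be distinguished from tail
adenines); more than 4 rejects the read. The cleavage site is the last
aligned base after reassignment, reported as a 1-based coordinate on
the transcript strand (the "−1 position"). Alignments whose 3' end
touches the contig edge are rejected with a distinct reason code, since
the templated status of the tail cannot be decided there.

Internal priming — an oligo(dT) primer annealing to genomic adenines
rather than a true tail — is filtered with a dual rule on the
sense-strand −10..+10 window around the candidate site: drop if the
window contains a run of ≥ 6 consecutive A, or ≥ 7 A inside any fully
contained 10-nt subwindow. Both thresholds are arguments. At contig
edges the window is clamped and evaluated on the available bases.

## PAC clustering

Unique sites with ≥ 3 supporting reads are clustered per chromosome
and strand. The objective is the Ward minimum-variance criterion with
sites weighted by read support (each site contributes its coordinate
with multiplicity equal to its support), subject to a hard cap on the
genomic span of any cluster (24 nt by default; the span cap, not a
dendrogram height, is what defines cluster granularity here, and it is
a parameter of this package rather than an empirical claim). Among
contiguous partitions whose blocks all satisfy the cap, the partition
with the fewest blocks is selected, ties broken by minimal total
weighted within-cluster sum of squares. Rather than cutting a greedy
agglomerative dendrogram — which does not guarantee the optimal
partition — the optimum is computed exactly by an O(n²) dynamic program
over contiguous blocks; the test suite checks it against exhaustive
enumeration for up to six sites. Clusters are contiguous and
strand-separated by construction, so PACs never interleave.

Each PAC is represented by its highest-support member; ties go to the
3'-most member in transcript sense (the most processive cleavage).
Flanks are sense-strand 150-mers with the representative base at label
−1 (−100..−1 then +1..+50), N-padded and flagged at contig edges.

## Region assignment

Gene models carry unioned per-type intervals (exon, CDS, 5'-UTR,
3'-UTR) across transcripts; introns are the gaps between exons. Every
3'-UTR is extended 50 nt downstream in transcript sense, truncated at
the contig edge or one base short of the next same-strand gene start —
the extension exists to rescue truncated 3'-end annotations, so a site
within it is assigned to that gene's 3'-UTR. Within a gene the
precedence is extended 3'-UTR > CDS > 5'-UTR > intron; across
overlapping genes the nearest annotated 3' end wins (consistent with
the extension's motivation). Strand-mismatched containment is
intergenic: antisense sites are flagged as future work, not analyzed.
Intergenic sites record their signed distance to the nearest
same-strand annotated 3' end (positive downstream).

## Signal scanning and significance

Three counting modes over a fixed window of position labels:

- **overlapping** — every match start counts;
- **distribution** — greedy left-to-right; a new occurrence is counted
  only if its start is ≥ (previous counted start) + k + gap. With
  gap = 0 this is adjacent non-overlapping counting; the semantics
  reproduce the defining example that ATATATAT counts ATATAT and
  TATATA once each at gap = 2;
- **frequency** — at most one count per sequence, at the occurrence
  whose motif end lies closest to the site (ties go 3').

Windows containing `N` are skipped both in counting and in the
position total. Frequencies are counts divided by the number of
scanned sequences, so overlapping/distribution frequencies may exceed 1
while frequency-mode frequencies are true per-sequence fractions;
ranking is by frequency with lexicographic tie-break. The per-motif
"PSSM" output is the distribution of counted occurrence starts over the
window's position labels, normalized to unit mass when the motif occurs.

Significance uses an order-m Markov background (m = 3 by default, and
m = 0 gives the product-of-base-frequencies null) trained with add-one
smoothing on the very sequence set being scanned — the natural null of
"this composition, no positional signal"; an external background set
can be supplied instead. A motif's probability is its smoothed m-gram
prefix probability times the smoothed transition probabilities. With n
scanned window starts and p the motif probability, E = np and
Z = (obs − E)/√(np(1−p)). The binomial variance is an approximation —
occurrences at overlapping starts are not independent — but it is
exact in expectation, and the suite verifies the null calibration
empirically: over 10,000 i.i.d. uniform sequences the mean Z across
all 1,024 pentamers is within ±0.1 of zero. A warning is emitted when
the training data are sparse relative to 4^(m+1) parameters, which is
the norm at desk scale with m = 3; smoothing keeps every probability
strictly inside (0, 1).

## APA classification and splicing interplay

Gene-level rules: one PAC → constitutive; with ≥ 2 PACs, a PAC holding
≥ 75 % (inclusive) of the gene's summed support is strong and its
siblings weak; otherwise all median. APA extent is computed over
PAC-bearing genes (not all annotated genes) — the denominator choice is
switchable, and gene-percentage columns appear only when a caller
supplies a total-gene denominator. Extent-vs-size uses the standard
Pearson product-moment correlation with the t-transform p-value; fewer
than three records or a constant coordinate raise an error.

An intron "contains" a PAC when a representative position lies strictly
inside its interval on the same strand (span-overlap is available
behind a flag); multi-PAC introns count once. Cell percentages are
with-PAC counts over totals, and the class means average cell
percentages (e.g. the constitutive mean averages the coding and
noncoding constitutive cells). Splice classes are inputs, never
inferred. Length comparisons draw control groups of matched size
without replacement from the PAC-free pool (groups independent,
seeded) and use a two-sided rank-sum test: exact enumeration of all
assignments with half-credit ties for n₁, n₂ ≤ 8, the tie-corrected
normal approximation above.

## Synthetic data: what it emulates, and what it does not

The generator plants everything the pipeline is supposed to find.
Defaults and their reasoning:

- `gc_fraction = 0.6345` — the GC content of the target genome class.
- genome 50 kb, 20 genes, 1–2 introns each, fixed architecture
  (5'-UTR, alternating CDS exons/introns, 3'-UTR) on random strands
  with 200–500 nt spacers: the smallest layout that exercises every
  region label and the 3'-UTR extension.
- `reads_per_site = 30` — derived from the shallowest real platform the
  package emulates: ~338 k tailed EST reads over ~11 k clusters is
  ~30 reads per site; deeper platforms only raise this. A constant
  depth (rather than a count law) keeps support accounting exactly
  checkable.
- `microheterogeneity_sd = 1.0` nt, discretized normal around each true
  site — cleavage scatter well inside the 24-nt PAC span cap.
- tails: EST 12–35 nt pure; NGS 15–26 nt with per-base impurity 0.01;
  nontemplated additions 0–3 bases (probabilities 0.7/0.15/0.1/0.05)
  drawn from {C,G,T} so they never blend into the tail accounting.
- `antisense_fraction = 0.2` of reads emitted as reverse complements
  (poly(T)-headed), exercising orientation.
- 5 decoys: A-runs of 6–12 nt planted in CDS/introns; decoy reads end
  at the run with **no synthetic tail**, emulating oligo(dT)
  mispriming. Under NGS tail rules a ≤ 12 nt run never qualifies as a
  tail, so NGS decoys die at tail detection; under EST rules runs
  ≥ 10 nt reach — and are removed by — the internal-priming filter.
- The UGUAA signal is planted at −22..−18 of every true site, and each
  site's neighbourhood is sanitized (no A at −4..−1, internal-priming
  window kept clean) so that recovery measures the pipeline, not
  collisions between the random genome and the planted truth.

Per-site read depth is constant, so synthetic APA genes have balanced
site usage and end-to-end runs produce only constitutive and median
categories; the strong/weak logic is exercised by direct unit tests.
Other real-data features the generator does not model: sequencing
errors outside the tail, paralogs and repeats (mapping ambiguity is
tested separately with constructed duplications), spliced read bodies,
expression-level variation, and base qualities (FASTQ qualities are
constant). Passing the benchmark therefore shows the rules compose
correctly and recover planted truth at realistic desk-scale depth — not
that the thresholds are optimal for any particular real library.

All randomness flows from a single seed; a fixed seed reproduces every
output byte-identically.

## Problem sizes

The default test and acceptance runs use 50-kb genomes with 20 genes
(~30–40 true sites, ~1,000–1,500 reads), 3 seeds for end-to-end
recovery, 1,000 random 150-mers for scanner-oracle equivalence, 10,000
uniform 30-mers for Z-score null calibration, and exhaustive oracles up
to n = 6 (clustering) and n₁, n₂ = 8 (rank-sum).
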