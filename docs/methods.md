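# Methods

This note documents the models and procedures implemented in
`mutascope`, the parameter defaults and why they were chosen, what the
synthetic-study generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Mutation catalogs

Input is per-subclone somatic variant calls (VCF or TSV) with a variant
allele fraction (VAF). Coordinates are 1-based fully closed for
variants; interval inputs (BED, bedGraph) are 0-based half-open and
converted at their readers. For VCF input the VAF is taken from the
`VAF` FORMAT field, then `AF`, then computed as alt/(ref+alt) from
`AD`, in that order. Multi-allelic rows are split; alleles are trimmed
to the left-aligned single-anchor-base convention; length-matched
multi-base substitutions are expanded into per-base records and
re-merged by adjacency later, so an MNV row and two adjacent SNV rows
are equivalent inputs. Duplicate (chrom, pos, ref, alt) keys within a
sample are collapsed to one record keeping the maximum VAF, with a
warning.

Filters reflect the clonal design of mutation-accumulation
experiments. Individual variants are kept at VAF strictly greater than
0.2 (a heterozygous de novo mutation in a clonal population sits near
0.5; low-VAF calls are subclonal or artifactual). A sample whose mean
VAF is strictly below 0.4 is flagged polyclonal — the single-cell
bottleneck failed — and is excluded from burden and signature
quantitation. De novo mutations are obtained by subtracting the
parental clone's key set when a parental call set exists, otherwise by
removing keys shared with any sibling subclone.

Two adjacent substitutions on one contig are merged into a doublet;
runs of three or more adjacent substitutions are set aside as
multi-base events and contribute to neither the SBS nor the DBS
catalog, avoiding contamination of both spectra (their count is
reported). Channel sets:

* **SBS96** — pyrimidine-centric substitution crossed with both
  flanking bases; purine-reference mutations are reverse complemented
  together with their context.
* **DBS78** — doublets canonicalized by reverse complement onto the
  78 published canonical doublet changes (the canonical list is stored
  as a constant; canonicalization is an idempotent lookup).
* **ID83** — indels by size (1, 2, 3, 4, 5+), type, and context:
  1 bp indels by strand-collapsed base (C/T) and homopolymer length
  (deletions count the deleted base, 1–6+; insertions count existing
  bases, 0–5+); longer indels by repeat-unit copies at the site, or by
  microhomology length at the junction for deletions without a full
  flanking copy. Labels follow the `size:type:class:count` scheme; the
  exact label strings are this package's own convention and are
  internally consistent between the classifier, the signature math and
  the generator. A deletion is classified from both junctions
  (microhomology is the longer of the prefix match downstream and the
  suffix match upstream). An auxiliary motif tally reports 1 bp T
  deletions by flanking trinucleotide class (ATA / ATG / other) and
  1 bp T insertions matching the `[T0–1]A` motif, since 1 bp T indels
  at those motifs are the discriminating feature of the indel pattern
  this pipeline targets.

Duplex-sequencing burden uses only variants with VAF strictly below
0.01 (ultralow-frequency mutations in a bulk population; higher-VAF
variants are germline or clonal) and reports mutations per megabase of
informative duplex bases.

Non-primary and mitochondrial contigs can be excluded with a contig
allowlist at the reader level; the synthetic studies use a single
contig.

## Signature derivation by background subtraction

Cultured clones accumulate background mutations regardless of
treatment, so a treated clone's profile is modeled as a mixture of a
background signature and a possible treatment signature.

1. **Background**: channel-wise sum of the untreated control catalogs,
   normalized. Controls must be clonal (non-polyclonal).
2. **Envelope**: for each burden *n* on a logarithmic grid of 12 points
   from 50 to 50 000, draw 1000 multinomial samples of *n* mutations
   from the background and record the mean and sd of their cosine
   similarity to the background. This captures how far a
   background-only sample is expected to stray at a given burden
   (small burdens stray far; the mean cosine rises toward 1 with
   burden). Between grid points the mean and sd are interpolated
   linearly in burden; because the mean is concave in burden this
   interpolation slightly underestimates it, making detection
   conservative.
3. **Detection**: a treated catalog with burden *n* and cosine *c* to
   the background is declared to carry a novel signature iff
   *c* < mean(*n*) − k·sd(*n*), with k = 3 by default (a three-sigma
   departure from background-only behavior).
4. **Subtraction**: the derived signature is the renormalized residual
   max(0, *t*ₖ − *n*₀·*b*ₖ). The background burden *n*₀ defaults to the
   mean de novo burden of matched untreated subclones (times the number
   of treated catalogs aggregated): equal culture time implies
   comparable background accumulation. This default is overridable.
5. **Reference comparison**: cosine ranking against a channels ×
   signatures reference table; ties keep input column order; cosines
   are reported to 3 decimals.

The three-sigma default keeps the false-positive rate of detection at
or below the percent level across burdens (verified by simulation in
the test suite); parameter-recovery simulations show median cosine
≥ 0.95 between recovered and planted signatures for burdens ≥ 2000 and
novel fractions ≥ 0.5.

## Chance-doublet permutation null

A heavy substitution load produces some adjacent pairs by coincidence.
For *m* uniformly placed distinct sites on a sequence of *L* sites the
expected number of adjacent pairs is m(m−1)/L (each of the L−1 adjacent
site pairs is jointly occupied with probability m(m−1)/(L(L−1))); this
closed form anchors the permutation machinery in tests.

Each permutation replicate independently re-places every substitution —
uniformly over interior genome positions, or (default) uniformly over
positions sharing its exact trinucleotide context — re-drawing on
collisions within a replicate. Adjacent placements are counted, and
paired leftmost-first into chance doublets whose DBS78 spectrum
(formed from the two records' own alleles in position order) is
aggregated across replicates. The report gives: the fraction of
replicates with at least the observed doublet count (p-value), the
observed/mean-chance fold enrichment, and the cosine between observed
and chance spectra. The observed doublet load is called *legitimate*
(a genuine doublet process) when p < 0.01 and cosine < 0.9, both
configurable. Context matching is the default because doublet-prone
contexts are not composition-neutral; the uniform mode exists to match
the analytic oracle and is used where the closed form is the yardstick.

## Topography

All profile analyses are mutation-centered with a 2 kb window
(offsets −1000 … +1000).

* **G4 scan**: both strands are scanned for
  G≥3 N₁₋₇ G≥3 N₁₋₇ G≥3 N₁₋₇ G≥3 (minus strand via the C-run motif),
  greedy, leftmost-first, non-overlapping per strand.
* **G4 enrichment**: occurrence(offset) = number of mutations whose
  position + offset lies in a G4 interval; score = occurrence divided
  by its mean across offsets (so the profile mean is exactly 1;
  median normalization is offered as an option since either convention
  appears in the literature, and the mean matches the formula used
  here). The control curve repeats the computation on simulated
  mutations, each re-placed uniformly among positions within ±10 kb
  sharing its exact trinucleotide context (original site excluded;
  unmatched mutations are skipped and counted). The control isolates
  composition: G4 motifs are G-rich, so AT-context mutations are
  compositionally rare inside them — the control curve shows a narrow
  dip at offset 0 for that reason alone, and real avoidance must be
  judged against it, not against 1.
* **Nucleosome profile**: score(offset) = sum of a per-base signal at
  mutation+offset over mutations, divided by the number of mutations
  contributing at that offset; no normalization. Windows truncated at
  contig ends contribute to neither numerator nor denominator at
  out-of-range offsets. Periodicity is summarized by the lag of the
  autocorrelation maximum in a lag band; the estimator carries a ±1 bp
  finite-window bias, well inside the ±10 bp tolerance used in tests.
* **Replication timing**: per-base timing values are cut into 10
  equal-mass deciles; observed per-decile mutation fractions are
  compared with the mean ± sd over 100 bootstrap resamples (with
  replacement, same size) of the matched simulated mutation set.
* **Strand asymmetry**: a substitution inside a single-strand gene
  footprint is assigned to the untranscribed (coding) strand when its
  pyrimidine-representation base lies on the coding strand; mutations
  outside genes or under overlapping opposite-strand genes are
  excluded. Counts per six-class substitution type are tested against
  0.5 with exact two-sided binomial tests, Benjamini–Hochberg adjusted
  across classes (no test is standard here; the exact binomial is the
  natural choice for two-strand counts). Replicative strand asymmetry
  reuses the machinery with a left/right fork-direction track; the
  convention is that a plus-strand pyrimidine in a right-replicating
  region counts as leading-strand.

## Damage potential

For each gene (one canonical transcript per gene, the longest CDS),
every possible substitution at every CDS position is enumerated and
classified by consequence via the standard genetic code (stop gain,
synonymous, or missense — stop-loss is grouped with missense), plus the
three substitutions at each of the two canonical splice-site bases at
both ends of each intron (consequence splice_site). CDS whose length
is not a multiple of 3 are skipped with a warning; interior stop codons
are tolerated with a warning (random toy CDS contain them by
construction). Channels use the genomic plus-strand,
pyrimidine-collapsed trinucleotide context regardless of gene strand —
strand awareness belongs to the consequence, not the channel.

A signature's consequence ratio is Σₖ sₖ n₍ₖ,c₎ / Σₖ sₖ Nₖ, normalized
by the same ratio under the flat (uniform) signature; the flat
signature therefore scores exactly 1 for every consequence. Missense
severity is the signature-weighted mean blosum62 score over the
amino-acid substitution inventory (weights sₖ × count), reported raw
and as the difference from the flat signature's score (flat scores
exactly 0). The blosum62 matrix is the standard published table as
shipped with Biopython.

## Synthetic-study generator

The generator emulates a treatment-versus-vehicle mutation-accumulation
experiment with full ground truth:

* **Genome**: one contig of random sequence (default 10 Mb, GC 0.40),
  with G4 motifs satisfying the consensus planted at recorded,
  non-overlapping positions on random strands (default density 10⁻⁴
  per bp).
* **Tracks**: a square-wave nucleosome signal (147 bp cores at 1.0,
  53 bp linkers at 0.1, period 200 bp, global phase — phase is not
  coupled to the planted G4s so the two biases stay independently
  recoverable); a linear early-to-late replication-timing gradient;
  non-overlapping two-exon CDS gene models with random strands
  (default 200 genes of ~5 kb); alternating left/right replication
  direction intervals.
* **Clones**: genotypes × treatments arms, each with a parental clone
  (300 background mutations shared by all its subclones) and 2–4
  subclones (default 3). Untreated subclones draw their de novo counts
  from the background signatures; treated subclones draw the same
  background load plus treatment-signature mutations on top (defaults:
  SBS 1500 vs 20 000 total, DBS 20 vs 200, indels 100 vs 400 — i.e. a
  ~13× substitution excess, 10× doublets, 4× indels, mirroring the
  scale of a strongly mutagenic exposure). Clonal VAFs are drawn from
  N(0.5, 0.04) clipped to [0.3, 0.7]; samples configured polyclonal
  draw VAFs uniformly from [0.05, 0.35].
* **Placement**: every mutation is placed by rejection sampling among
  positions matching its channel (trinucleotide index for
  substitutions, dinucleotide index for doublets, construct-and-
  classify probing for indels), with per-position acceptance weight
  equal to the product of the planted bias factors — linker ×3,
  G4 ± 100 bp ×0.2, timing trend factor^timing (default 1.0 = flat),
  untranscribed-strand ×2 for the T>A, T>C, T>G and C>A classes. The
  weights define an exact generative model, so recovery tests know the
  planted truth. Doublets are emitted as two adjacent rows sharing one
  VAF (in cis by construction). Indel placement accepts a candidate
  site only if the package's own classifier returns the drawn channel,
  guaranteeing exact round-trips; the default planted indel signatures
  are supported on channels common enough in random sequence for this
  probing to succeed quickly.
* **Spacing invariant**: every placement leaves at least one untouched
  base between events within an arm. Consequently no chance
  adjacencies or key collisions arise among planted mutations, and the
  catalog built from the emitted calls equals the planted channel
  draws exactly — the round-trip identity the test suite asserts.

What the generator does **not** emulate: sequencing noise and caller
artifacts (calls are exact), copy-number and rearrangement context,
overlapping genes and isoform structure, realistic human base
composition and repeat landscape, chromatin-state heterogeneity beyond
the square-wave nucleosome model, and correlated placement of multiple
biases (weights multiply independently). Passing tests therefore
demonstrate correctness of the analysis machinery under a known model,
not robustness to real-data artifacts upstream of variant calling.

## Problem sizes and determinism

The test suite runs studies of 120–500 kb with burdens up to 8000 and
completes in well under a minute; `scripts/acceptance.py` runs the
default 10 Mb study (18 subclones, ~200 000 placed mutations) plus all
analyses in about a minute. Sizes were chosen so every statistic has
comfortable resolution (e.g. thousands of genic mutations per strand
class) while staying desk-scale. All randomness flows through
`numpy.random.default_rng` seeds derived from a single master seed via
`SeedSequence`; fixed seeds give byte-identical studies, envelopes,
permutations and bootstraps.

## Known limitations

* The ID83 label strings are internally consistent but not guaranteed
  to match other tools' label spellings channel-for-channel; use the
  exported channel-order constants when interfacing.
* The subtraction scale *n*₀ is a design choice (matched-control mean);
  if background accumulation differs systematically between arms the
  derived signature inherits that bias.
* The damage-potential enumeration uses one canonical transcript per
  gene and 2 bp splice sites; consequence classes for indels and
  doublets are out of scope.
* Replicative strand assignment follows a fixed left/right convention;
  tracks with a different orientation convention must be relabeled.
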