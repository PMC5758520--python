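# Methods

This note documents the models, parameters and numerical choices behind
`panlineage`, in the spirit of a methods supplement: what each stage
computes, which knobs matter, and what the synthetic cohorts do and do not
emulate.

## The analysis problem

Given a collection of conspecific bacterial isolates, each sequenced from a
human host of known age and (optionally) household, the pipeline answers
three questions: (1) which accessory gene families are preferentially
carried by strains from younger or older hosts; (2) which strains carry
CRISPR repeat-spacer arrays usable as strain fingerprints and PCR targets;
(3) which within-family strain pairs are so similar — genome-wide identity
plus shared spacer content — that they must descend from one recently
transmitted clone.

## Gene families

Proteins are compared all-against-all with a local Smith–Waterman aligner:
BLOSUM62 substitution scores and affine gaps where a gap of length *g*
costs 11 + *g* (the classical "open 11 / extend 1" convention). An edge is
kept iff

* E-value ≤ 10⁻⁴, with E = *K·m·n·*exp(−λ*S*) using the gapped
  Karlin–Altschul constants λ = 0.267, *K* = 0.041 — an explicit
  approximation to BLAST statistics, not a replication; it can be bypassed
  (`use_evalue=False`) to filter on identity/coverage alone;
* percent identity over alignment columns ≥ 50;
* the alignment spans ≥ 50% of *either* sequence (literal "either"
  reading; a strict-both mode is available via `coverage_mode="both"`).

Because the scorer is symmetric, the kept graph is reciprocal by
construction. Two performance devices are exact in the regimes they are
used in and can be disabled: a shared-6-mer prefilter (pairs must share
≥ 2 distinct 6-mers; pairs below the 50% identity cut-off essentially
never do), and a diagonal band on the DP matrix (the pipeline default,
half-width 32, is exact whenever the optimal local path stays within 32
diagonals of the length-difference corridor — always the case for the
substitution-dominated divergence the cohorts produce; `band=-1` runs the
full matrix and is the library default).

Families are the clusters of the Markov Cluster Algorithm on the
score-weighted graph: self-loops set to each node's maximum incident
weight, alternating expansion (matrix squaring of the column-stochastic
matrix) and inflation (entrywise power *r* = 2.0, then column
renormalization) with pruning of entries < 10⁻⁵, until the matrix moves
by < 10⁻⁶ or 200 iterations (then a warning plus the current partition).
Clusters are read off the attractor structure; a node supported by several
attractor systems goes to its largest-probability attractor, ties to the
cluster with the smallest member id. MCL runs per connected component, so
clusters can never span components. Inflation 2.0 is the canonical
default; the original tool chain's granularity settings are not published,
so no attempt is made to mimic them.

## Pan-genome structure

The presence matrix is binary (strain × family), with a parallel
copy-number matrix; a family present in all strains is *core*, otherwise
*dispensable*; single-copy core families are core with copy number exactly
1 everywhere. Strain dendrograms use average linkage on either
1 − Pearson *r* or a covariance-derived distance
(*c*max − cov(*i*,*j*), rescaled to [0, 1]); the covariance rescaling is a
documented in-house choice since the clustering tool the protocol
descends from does not publish its exact transform. A constant profile
has Pearson distance 1 to everything. The ORF-count–age association uses
tie-aware Spearman correlation, with the exact permutation p-value when
n ≤ 9 and the t approximation otherwise.

## Age enrichment

For each dispensable family present in 6 … *n* − 6 strains, the host ages
of carriers and non-carriers enter a two-sided Mann–Whitney U test (U
reported as min(U₁, U₂); exact enumeration when n₁ + n₂ ≤ 12 without
ties, otherwise normal approximation with tie-corrected variance and
continuity correction). All tested families receive one global FDR
correction: Storey q-values with π₀ estimated on the λ-grid
0.05 … 0.95 (cubic-polynomial smoother evaluated at the top of the grid,
clamped to (0, 1]); `method="bh"` fixes π₀ = 1, which is exactly
Benjamini–Hochberg. A family is *younger*-enriched when q < 0.2 and the
carrier median host age is below the non-carrier median (mirror-image for
*older*). Carrier-vs-non-carrier host ages is the grouping that makes a
per-family test over ~1,500 families coherent; the alternative reading
(presence compared between two age-defined strain groups) is not the
default.

Detection rates (fraction of a segment's strains carrying the family) are
z-scored per family across the 14 host-age segments and clustered
(Pearson distance, average linkage, cut at k = 4); each cluster is
labelled infant / adult / elderly by the segment block (< 10 y, 10–59 y,
≥ 60 y) with the highest mean z, or *none* when the best block mean is
below 0.25 (a flat profile).

## CRISPR typing

The detector seeds on exactly repeated 11-mers whose consecutive
occurrences fall within 1 kb, extends each seed run to the maximal repeat
unit by requiring ≥ 90% column consensus across copies, and accepts a
candidate iff: repeat length 23–55 bp; ≥ 3 copies with ≥ 90% mean
pairwise identity; every spacer 0.6–2.5× the repeat length; and spacers
mutually dissimilar. The dissimilarity rule is applied to the **mean**
pairwise spacer identity (< 60%, edit-distance based): with 24–58 random
spacers per array the maximum over ~1,600 pairs exceeds 60% often enough
that an any-pair rule would reject a substantial fraction of genuine
arrays, while a tandem-repeat impostor still fails the mean decisively.
Overlapping candidates resolve to the one with most repeat copies, then
leftmost. Arrays are reported in contig-forward orientation; leader-end
inference is out of scope, so deletion vs acquisition between two arrays
is not polarized. "Spacer" is used throughout for the repeat-flanked
segments of the host array (some sources call these protospacers; the
canonical protospacer is the invader-side sequence).

Array comparison: number of shared spacers = longest common subsequence
under exact spacer equality, after trying the second array
reverse-complemented and keeping the better orientation; *full* = lists
identical, *none* = nothing shared, else *partial*.

Primer design enumerates 18–25-mers inside spacers absent (forward and
reverse-complement) from every other genome, pairs them with reverse
primers from the downstream region, requires GC 40–60%, Wallace-rule
Tm = 2(A+T)+4(G+C) in 55–65 °C with pairwise gap ≤ 3 °C and a product of
80–300 bp, and accepts the first pair whose in-silico PCR (≤ 1 mismatch,
none in the 3′-terminal 3 nt, convergent sites within 2 kb) amplifies
exactly once in the target and never elsewhere. The Wallace rule is a
deliberate stand-in for a full nearest-neighbour Tm model. Transmitted
clone pairs are expected to be rejected ("no strain-specific locus").

## Transmission

ANI follows the fragment convention: consecutive 1,020-bp fragments of the
query are each placed on the subject by exact 16-mer seeding (densest
offset cluster) and aligned with an infix edit-distance alignment in a
±80 bp window; identity = 1 − distance/1020; fragments below 70% identity
are discarded (with a reverse-complement retry), and ANI is the mean
identity of kept fragments, averaged over both directions. Seeded
placement replaces a per-fragment full-genome local alignment; at the
≥ 70% identity the filter keeps, seed hits are essentially guaranteed, and
unrelated sequence correctly yields "not computable". A pair is
*transmitted* when ANI ≥ 99.5% (a 99.9% strict profile exists) **and**
either the spacer arrays match (full or partial) or neither strain has an
array and the gene-content Jaccard is ≥ 0.95. The 99.5% default is an
inference from the clonal-pair regime the analysis targets (observed
clonal pairs sit above 99.5%, background conspecific pairs well below),
not a published constant. Only within-family pairs are scanned by default
(`all_pairs=True` widens this), and transmitted pairs are reported
transitively as connected components — a three-member chain appears as
one component of three strains.

## Core phylogeny

Per-family alignments are progressive: pairwise edit distances give a
single-linkage guide order, merges are frequency-profile global
alignments under +1 match / −1 mismatch / −2 gap (linear gaps). Using the
edit-distance metric for the guide order only (not for the merges) is a
speed substitution with no effect on merge scoring. Blocks concatenate
with per-column family bookkeeping; every block must cover every taxon,
which single-copy core selection guarantees. Trees are neighbor joining
on Jukes–Cantor distances (p-distances over mutually ungapped sites;
saturated or incomparable pairs capped at 3.0), with deterministic
tie-breaking by smallest leaf-label pair and negative branch lengths
clamped to zero with the deficit moved to the sister branch. Support is
the percentage of 100 column-bootstrap replicates containing each
bipartition; the reported tree is the majority-rule (> 50%) consensus,
rooted on the midpoint of the outgroup's pendant edge. Column resampling
is implemented by reweighting precomputed per-pair mismatch columns —
algebraically identical to recomputing distances on the resampled matrix.
Distance-based NJ deliberately replaces maximum likelihood: the claims
made on the tree (family clades, outgroup placement) are topology-level,
and NJ is exactly testable through additive matrices. Whether to
concatenate before tree building or consense per-family trees is genuinely
ambiguous in protocols of this kind; this package concatenates, then
bootstraps the concatenation.

## Synthetic cohorts

The generator emulates the cohort design the analysis assumes, and its
defaults are the study conditions of the acceptance fixture:

* **113 strains** distributed over the 14 host-age segments by the
  emulated cohort's genome-count column (5, 5, 11, 7, 9, 7, 12, 9, 10,
  10, 11, 12, 5, 0); ages uniform within each segment. The infant
  segment boundaries (preweaning < 0.5 y, weaning 0.5–1.5 y, weaned
  toddler 1.5–4 y) are configurable since cohort tables of this kind
  publish only group means.
* **Gene content**: 120 core + 300 dispensable families (~240
  genes/genome), each family from one ancestral CDS (protein length
  uniform 150–600 aa, sense codons only); every carrying strain receives
  a copy substituted at 1%/site (stop codons reverted), so within-family
  protein identity ≈ 96% — far above the 50% orthology cut-off — and
  between-family identity is random-background. CDS first, protein by
  translation, so orthology (protein) and ANI (nucleotide) see one
  consistent divergence dial. Two core families carry a duplicate in one
  (non-clone) strain each, exercising single-copy-core exclusion.
* **Carriage model**: dispensable family *g* is carried by a strain of
  age *a* with probability sigmoid(β₀ᵍ + β₁ᵍ·*a*/10). 26 families are
  younger-enriched (β₀ ∈ [1.5, 2.5], β₁ ∈ [−2.2, −1.2]) and 9
  older-enriched (β₀ ∈ [−3.5, −2.5], β₁ ∈ [0.6, 1.0]) — the ~12%
  enriched share mirroring the regime the statistic targets; neutral
  baselines are solved so the cohort mean gene count lands on target.
  The net younger excess also produces the negative ORF-count–age
  correlation.
* **Families and clones**: ten households; one three-generation chain
  (ages ≈ 1, 36, 65) plus two two-member chains give 5 transmitted pairs;
  twenty unrelated within-family pairs are the negatives. A clone is its
  donor's genome substituted at 10⁻⁴/site (ANI ≈ 99.98%), inheriting the
  donor's array, minus — with probability 0.6 — an internal block of 1–3
  spacers (the partial-match signature). Spacer turnover is modelled as
  deletion only; acquisition is off by default because array orientation
  is not polarized.
* **CRISPR arrays**: exactly 50 strains carry one array (repeat 36 bp,
  24–58 spacers of 32–40 bp, globally unique), inserted at a recorded
  coordinate; chain founders are always among the 50 so clones inherit
  arrays.

All randomness flows from one seed through named substreams (ages,
sequences, carriage, crispr, clones); identical configs produce
byte-identical FASTA/metadata and, through the pipeline, byte-identical
result tables.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: genome rearrangement and gene-order
variation (genomes are collinear), intergenic DNA, operons and mobile
elements, horizontal transfer within families other than whole-genome
clonality, sequencing/assembly error, contamination, and within-host
strain mixtures. Recovery rates of 100% on planted signals reflect the
separation built into the fixture (within-family identity ≫ cut-offs,
clones ≫ ANI threshold ≫ background) and validate the machinery, not the
difficulty of real cohorts.

## Problem sizes and determinism

The default test fixture ("mini") uses 30 strains × ~100 genes; the
full-scale fixture 113 strains × ~240 genes, 20 single-copy core families
and 100 bootstrap replicates for the tree — sizes chosen so the whole
pipeline runs end-to-end in minutes on one CPU while keeping every
planted-signal margin wide. The Smith–Waterman kernel and profile DP are
numba-compiled; first use in a fresh environment pays a one-time
compilation cost.

## Known limitations

* E-values are approximate (see above); identity/coverage filters carry
  the real selectivity.
* The banded similarity search is exact only for near-collinear pairs; it
  is the pipeline profile's setting, not the library default.
* The CRISPR detector assumes near-identical repeats (planted or real
  high-conservation arrays); heavily degenerate repeats below ~90% column
  consensus will fragment.
* ANI identity is edit-distance based, which counts indels as single
  events; against the 0.5-percentage-point margins used here this is
  immaterial, but the absolute values are not calibrated against
  BLAST-based ANI to better than a few tenths of a percent.
* Majority-rule consensus trees carry supports but no branch lengths.
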