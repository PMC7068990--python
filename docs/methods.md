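# Methods

This note records the models, conventions and design choices behind
`agtbarcode`, in the spirit of a methods supplement: what is computed,
under which assumptions, and where the edges are.

## The marker model

The package assumes a *two-part barcode*: a conserved exon fragment
(264 bp by default) followed by an intron of roughly 100–400 bp, with a
short downstream-exon remnant (14 bp) at the 3' end of the amplicon.
Coordinates are 0-based half-open throughout; a record carries
`exon_end` (exon/intron boundary) and `intron_end` (intron/remnant
boundary). `split_regions` trims the exon to at most 264 bp from the 5'
end and cuts the intron at the remnant boundary. When boundaries are
not annotated, `locate_boundaries` places them by the best local match
of a reference exon — a pragmatic mechanism that relies on the exon
being conserved, which is the premise of the marker class.

IUPAC ambiguity codes (Sanger double peaks) are retained on input and
treated as missing data everywhere downstream: they never match in
alignment scoring, and sites containing them are excluded from K2P and
site statistics. Only the forward strand is considered, because
barcodes are amplified with fixed primer orientation.

## Alignment and hit statistics

Both aligners use one scoring scheme: match +1, mismatch −2, *linear*
gap cost (default 2 per gapped position), word size 28, maximum
E-value 10 — megablast-flavoured settings appropriate for >95%-identity
comparisons of short amplicons.

* The **global** aligner (identity computation) is banded
  Needleman–Wunsch; the band allows `|i−j| ≤ |len_a−len_b| + 32`, ample
  for intron-indel length differences. Identity is the number of
  identical aligned positions divided by the length of the shorter
  sequence (CD-HIT-EST's convention; configurable), so a terminal
  overhang does not dilute identity.
* The **local** aligner (identification) is full Smith–Waterman with
  linear gaps, run only against subjects that share at least one exact
  28-mer with the query (queries shorter than the word size fall back
  to aligning everything). No low-complexity masking is applied: the
  marker is short and curated.

Bit scores are `S' = (λS − ln K)/ln 2` with the ungapped
Karlin–Altschul λ solved from the scoring scheme (for +1/−2 and uniform
base composition, the positive root of `0.25·e^λ + 0.75·e^{−2λ} = 1`,
λ ≈ 1.3327) and K fixed at 0.62 (configurable). E-values use
`E = K·m·n·e^{−λS}` without edge corrections. Since λ and K are
constants per search, bit-score order equals raw-score order; every
decision downstream depends only on that order, so the choice of K is
inconsequential for outcomes. Exact bit-score magnitudes of specific
commercial implementations are not reproducible, because their λ/K for
linear-gap mode are unpublished; rankings are.

The DP inner loops are JIT-compiled (numba) so that hundreds of
database alignments per query run in milliseconds; the recurrences are
written out explicitly and verified against plain-Python full-matrix
oracles in the test suite.

## Distances and site statistics

K2P distances use pairwise deletion (sites with a gap or ambiguity in
either sequence are dropped); complete deletion is available. When the
observed proportions saturate the model (`1−2P−Q ≤ 0` or `1−2Q ≤ 0`)
the pair is masked in matrices rather than set to infinity, keeping
matrices usable and forcing an explicit decision (drop taxa or impute)
before tree building.

Variable sites require ≥2 distinct unambiguous states; parsimony-
informative sites require ≥2 states each in ≥2 rows. Gaps are excluded
from state counts by default (the common convention in alignment
statistics software); a strict mode counts the gap as a fifth state,
since published counts cannot always be audited without knowing which
convention produced them.

## Clustering

Greedy incremental clustering, longest sequence first (ties by record
id), each sequence joining the *first* representative it matches at or
above the threshold (first-fit, the documented CD-HIT strategy), else
seeding a new cluster. Default threshold 0.98. Because the processing
order is a pure function of (length, id), output is independent of
input order. No k-mer prefilter is applied by default — datasets here
are hundreds of sequences, not millions. Cluster labels: a cluster is a
`species_cluster` if all members are conspecific, `supported` if its
species share a species group (or genus for ungrouped species),
`unsupported` otherwise; species missing from the taxonomy make a
cluster `unknown` rather than guessing.

## Identification

Queries are one record per species sampled from at least two distinct
provenances (the lexicographically smallest record id, for
determinism): only then does a conspecific from another origin exist to
be found. The query's own record is removed from the database —
without self-hit removal every search would be trivially correct. The
decision rule: let B be the maximum bit score among hits; the call is
*correct* iff the species set at B is exactly the query's species,
*ambiguous* if the query's species is in a larger tie set, *incorrect*
otherwise, *no_hit* for an empty list. "Strictly lower" is exact
raw-score inequality — with integer raw scores and fixed λ/K, bit-score
ties are precisely raw-score ties, so no epsilon is needed.
Genus/clade-level success asks whether the single top-ranked hit shares
the query's species group.

## Barcoding gap and rank-sum test

Pairs are classified as intraspecific (same species), congeneric (same
species group, different species), intergeneric (same subfamily,
different group), or interfamilial. The gap report contrasts
intraspecific against all heterospecific distances; `overlap` is true
when the largest intraspecific distance reaches the smallest
interspecific one.

The Wilcoxon rank-sum test is implemented in full. Exact p-values by
enumeration of rank assignments are used for tie-free data when the
smaller sample has ≤8 observations (and the enumeration stays under
5·10⁵ subsets); otherwise a normal approximation with midranks,
tie-corrected variance and continuity correction. Two-sided throughout.
Identical samples give p = 1 by convention. Near the regime boundary
(8 vs 8) exact and corrected-normal p-values track each other to about
0.01, with individual draws near p ≈ 0.5 reaching ≈ 0.011 — inherent to
the continuity correction, and covered by a property test. A caveat
applies to the gap test as such: pairwise distances share sequences and
are not independent, so the p-value is descriptive, not a calibrated
error rate over datasets.

## Trees and hybrid assignment

Neighbor joining follows Saitou–Nei with deterministic tie-breaking by
the lexicographically smallest pair of ids (internal nodes inherit the
smallest leaf id beneath them). Additive matrices are reconstructed
exactly; negative branch lengths are clamped to zero and counted.
Bootstrap resamples alignment columns with replacement, rebuilds the
K2P matrix and NJ tree per replicate, and reports the percentage of
non-skipped replicates containing each original bipartition; replicates
with saturated pairs are skipped and counted. ML tree inference is
deliberately out of scope: the quantity this package needs from a tree
is clade membership and support for allele assignment, which NJ with
bootstrap provides at a fraction of the complexity.

Allele-to-genepool assignment places each cloned allele with the pool
containing its nearest reference by K2P over global alignment. The
*margin* is the distance between the best and second-best pool minima.
An individual is flagged `putative_hybrid` when its alleles are
*confidently* assigned to two different pools, where confident means
margin ≥ `min_margin` (default 0.01 substitutions/site — an order of
magnitude above typical intraspecific noise and well below divergence
between candidate parental pools). The gate exists because an
individual that belongs to *neither* pool sits nearly equidistant from
both, and alignment noise can then flip its two alleles into different
pools; such an assignment carries no parentage signal. Exact ties go to
the lexicographically first pool and are flagged as ties. Geographic
plausibility of a hybrid's parents is outside the package's scope; only
the allele-assignment signal is computed.

## The synthetic-data generator

`simulate` emulates the data regime the marker class was described on:

| parameter | default | meaning |
|---|---|---|
| `exon_length` | 264 | conserved exon fragment (bp) |
| `intron_length_range` | (100, 400) | root intron length draw (bp) |
| `exon_divergence_target` | 0.01 | expected between-species exon K2P within a group |
| `intraspecific_divergence` | 0.004 | expected within-species K2P (overlapping the interspecific range, as observed for such markers) |
| `intron_rate_multiplier` | 5 | intron substitution rate relative to exon |
| `kappa` | 2.0 | transition/transversion odds per substitution event |
| `indel_rate` | 0.3 | per-branch probability of one intron indel |
| `indel_length` | 0.25 | geometric length parameter (mean 4 nt) |
| `het_fraction` | 0.15 | accessions carrying two intron alleles (≈ the observed cloning rate for such markers) |
| `accessions_per_species` | 3 | star-shaped within-species sampling |

Structure: a family root sequence splits into subfamilies (stem 3× the
divergence target) and species groups (stem 1.5×); each group radiates
through a pure-birth (Yule) tree rescaled so that the *mean* expected
tip-pair exon K2P equals the target. With `calibrate_to="min"` the mean
calibration is kept and every terminal branch is extended just enough
that the *shallowest* species pair also reaches the target — used to
plant guaranteed-separation datasets without inflating deep branches.
Substitutions are placed per branch as a Poisson number of K80-style
events with transition:transversion odds `kappa:1`; at the low
divergences simulated this is indistinguishable from exact matrix
exponentiation and keeps the generator transparent. Indels (geometric
lengths, insertion/deletion with equal probability, floor of 50 bp on
intron length) never touch the exon, matching the observation that
allelic differences in such markers are confined to the intron.
Heterozygous accessions emit two records whose introns differ by at
least one forced indel; hybrids receive one allele evolved from each of
two parental species, preferentially from different species groups.
A target whose deepest expected intron path exceeds 2 substitutions/site
is rejected as saturating.

What the generator does **not** model: coalescent genealogies within
species (a star is used — only divergence magnitudes matter to the
pipeline), selection, codon structure, base-composition bias, alignment
error in the exon (its true alignment is gap-free by construction), and
chloroplast capture. Passing tests on this substrate therefore show
that the *pipeline logic* is correct under the stated divergence
regime, not that any particular real marker meets that regime.

## Problem sizes and determinism

The shipped tests and the acceptance script run planted datasets of
~20 species × 3 accessions (60–70 records, sequences of 350–700 bp),
10 replicate seeds for stochastic checks, 2000 null replicates for the
rank-sum calibration, 50 random additive matrices for NJ recovery, and
100–1000 bootstrap replicates depending on context — sizes at which
every result is reproduced in seconds to a couple of minutes on one
core. All randomness flows through explicit `numpy` generators seeded
from a single integer; identical inputs and seeds give byte-identical
pipeline outputs (a property the test suite asserts).

## Known limitations

* Real CD-HIT-EST cluster counts can differ slightly: its short-word
  heuristics and version-dependent defaults are not replicated, only
  the greedy longest-first/first-fit strategy and the identity
  definition.
* E-value magnitudes are nominal (ungapped λ with fixed K, no edge
  corrections); they gate obviously spurious hits but are not
  comparable to a specific BLAST build's numbers.
* The rank-sum test on distance matrices inherits the dependence
  caveat above.
* `locate_boundaries` assumes the exon is the 5' part of the amplicon
  and conserved enough to anchor a local alignment.
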