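# Methods

## The problem

The human genome carries ~100 integrated copies (proviruses) of the
HERV-K(HML-2) endogenous retrovirus lineage. A handful of recently
integrated loci still encode a full-length Env protein, a candidate
tumour-associated antigen, so the question "which locus is actually
transcribed?" matters clinically. It is also statistically hard: the
youngest proviruses differ from one another by only ~1.5% at the nucleotide
level, so a 100-nt RNA-Seq read from one of them frequently aligns equally
well to several. How multi-mapping reads are allocated decides the answer.

`hml2quant` implements the full locus-resolved quantification pipeline —
faux-genome mapping with explicit multi-mapping policies, diagnostic
unique-SNP k-mer counting, enrichment-bait design, and the summary
statistics — together with a synthetic provirus-family generator that makes
every stage testable end-to-end against known truth.

## Faux genome and counting policies

Reads are mapped against a *faux genome*: the provirus sequences
concatenated with 100-nt N spacers (the spacer stops a read from spanning
two loci; internally coordinates are 0-based half-open, all exported GTF is
1-based inclusive). Each mapped read yields its set of best-scoring loci;
a single best locus makes the read *unique*, ties make it a *multi-mapper*.
Four allocation policies are implemented as the method's contract:

| policy | allocation of a read tying k loci | known bias |
|---|---|---|
| `random_multimap` | one of the k, uniformly at random (seeded) | unbiased for groups of similar loci; smooths expression *within* such a group |
| `unique_only` | dropped | collapses the share of near-identical young loci |
| `count_all` | all k loci (counted k times) | inflates similar loci |
| `proportional` | split ∝ each candidate's unique-read count | biased toward older, more diverged loci |

Per locus and per input, `unique_only ≤ random_multimap ≤ count_all` holds
deterministically. For production data the package ingests external SAM/BAM
(multi-mappers recognised by tied alignment score, AS tag); the built-in
aligner (semi-global edit distance via edlib, both strands, exact-tie
semantics, unmapped above an edit fraction of 0.25 short / 0.40 long) exists
so that synthetic-scale validation controls the tie structure exactly.

RPKM normalisation is `count / (locus_kb × family-assigned reads / 1e6)`;
the denominator is family-assigned (not total sequenced) reads, with the
per-run totals reported separately. The Env fraction is the RPKM share of
the Env-encoding loci; the enrichment fold is the ratio of family-assigned
read fractions between an enriched and an unenriched run; replicate
concordance is Spearman's rho with average ranks.

## Diagnostic alleles

Mapping cannot separate near-twins, but an allele carried by exactly one
locus can. In the *env* alignment of the young subfamily, each column's
majority base is taken as ancestral ("inferred by commonality"; ties are
skipped); a base carried by exactly one row is a candidate diagnostic
allele, written `G(96)A` (ancestral, 1-based column, derived). A window of
31 nt (short reads), 17 nt (high-error long reads) or 11 nt (multi-allele
scan) centred on the variant is cut from the carrier's ungapped sequence
and verified by exact substring search — both strands by default — against
*every* provirus in the universe; a hit elsewhere clears `verified_unique`
and records the sharing locus. A second variant inside the window sets
`combination` (the combination, not the single base, is unique). Counting
is exact substring matching in FASTQ, one count per read per allele,
reported per run with the mean across runs. Because the windows are nested
and centred, counts are monotone in window length per read:
counts(31) ≤ counts(17) ≤ counts(11).

Design choices worth stating:

* Reverse-complement search defaults **on** (library strandedness is not
  guaranteed); a strict sense-only mode is a flag.
* The tandem-duplicate pair (identical *env*) is treated as a single
  carrier for uniqueness; an `exclude=` mode reruns the analysis with one
  copy deleted.
* Mismatch-tolerant flank matching is deliberately not a counting mode —
  it blurs the exactness that makes the statistic interpretable.
* The k-mer counter never applies a mapping-quality gate (it sees only
  FASTQ); the Q≥20 gate exists separately for long-read *mapping-based*
  counts in `ingest_alignment(mapq_min=20)`. Both conventions are therefore
  computable.

The 11-nt scanner flags reads carrying alleles of ≥2 different proviruses
(carrier sets disjoint). Such reads arise from template-switch
recombination *or* from an unsequenced polymorphism shared between loci;
the two causes are indistinguishable from a single read, which is exactly
the caveat the analysis scripts print.

## Bait design

The enrichment consensus is a mechanical majority-rule consensus of the
young subfamily's env alignment: columns with a gap majority are dropped
(the threshold `min_nongap_fraction` is configurable), ties break in fixed
base order A<C<G<T, and per-column support is recorded. With the default
reference configuration (12 of 20 young loci carrying the 292-nt type-1
deletion) the consensus drops those columns and is 1808 nt. Probes default
to 120 nt (standard RNA bait length) tiled at ×10: step = probe_len/10,
last probe right-aligned, interior positions covered exactly 10×.

## The synthetic family generator

The generator's defaults *are* the study conditions; they are fixed, not
tuned per experiment.

**Phylogeny.** Young subfamily: a two-level star — ancestral sequence →
sister-pair ancestors → tips. Within-pair divergence defaults to 0.2%
(about a dozen substitutions per 6-kb locus), reflecting the near-twin
pairs in the real family (the extreme being the tandem duplication, whose
env is identical by construction and which is always the last pair); the
between-pair level is solved so the mean pairwise divergence of the emitted
env alignment hits the 1.5% target. Setting `young_sister_divergence=None`
gives a one-level star (all pairs equidistant), used for the
well-separated 5% validation family. Old loci are single branches at 15%
pairwise (with a closed-form correction for same-site double hits) and are
truncated to a random 2–6 kb window, emulating internal-sequence loss.
Mutation placement is stratified: each branch receives exactly
`round(len × p)` substitutions per segment (env / non-env), so the realized
divergence of every emitted alignment sits within a few percent of target
— the generator's calibration contract is ±20%.

**Annotations and pathologies.** A configurable fraction of young loci get
the 292-nt deletion at the *pol–env* junction (type 1; shown as gaps in the
alignment and absent from the sequence); non-type-1 loci may receive a
premature stop codon (env ORF is generated stop-free otherwise, starting
ATG); optional loci are G→A hypermutated at a high rate on the sense
strand and excluded from the env alignment. Insertional polymorphism is a
per-locus population frequency; a sampled genome draws presence Bernoulli.
Shared alleles are planted as whole 31-nt windows copied between loci —
visibly (in the reference set, where verification must catch them) or
*cryptically* (only in the sampled genome's copy of the expressed sharer,
which reproduces the misattribution artifact: an absent locus's
"verified-unique" allele still collects reads).

**Expression and reads.** Expression is Dirichlet(0.3) over present loci
(a few dominant loci) unless explicit proportions are given. Short reads:
N(110, 25) nt clipped to [50, 200], substitution error 0.5% by default;
long reads: N(2000, 900) nt (≥200), substitution error 12%, so median
read identity ~88%. Errors are i.i.d. substitutions only — no indels —
so exact k-mer counting has the analytic expectation
P(window of k intact) = (1−e)^k, which the tests verify against exact
binomial bounds. Qualities encode the true error rate (Phred+33). Reads
are emitted on a random strand. A `recombinant_fraction` of reads
template-switch between two full-length young loci at a uniform breakpoint;
a `background_fraction` comes from a random decoy sequence (the off-target
background used for enrichment-fold measurement — enrichment is modelled
only as this background dilution, not as capture chemistry). Truth tables
record presence, proportions and per-read source/breakpoint/error counts.

**The 95-locus reference configuration** (`reference_family_config()`)
scales the same structure to the real family's size: 20 young loci
(10 pairs, 12 type-1 → 8 Env-encoding, one tandem pair), 2 hypermutated,
73 old — 95 loci total. All "reference" checks (interval round-trips,
tandem env tie, uniqueness soundness) run on it. It is synthetic and
labelled so wherever written to disk.

## What the simulations do and do not show

Passing tests establish that the counting policies, the diagnostic-allele
machinery and the statistics behave as designed under a faithful
*statistical* caricature of the data: correct divergence structure, locus
pathologies, dominance, read lengths and substitution errors. They do not
model indel-dominated error profiles (Ion Torrent homopolymers, nanopore),
coverage bias from capture or fragmentation, splice structure, PCR
duplicates, or genome-wide mapping competition from loci outside the
family — a read attracted to a non-family locus is invisible here. Real
aligner score nuances (Bowtie2/minimap2) are out of contract: external
SAM/BAM is the fidelity path, with equal-score ties as the multi-mapper
definition.

## Numerical choices and problem sizes

* Consensus ties: fixed base order A<C<G<T; consensus is row-order and
  uniform-duplication invariant.
* Ancestral-state ties at an alignment column: column skipped, logged.
* Variants within half a window of a sequence end: allele skipped with a
  warning (probe cannot be centred).
* `random_multimap` is bit-reproducible for a given seed; all randomness
  in the package flows through explicit integer seeds, and derived seeds
  stay below 2^31.
* Amino-acid divergence translates in-frame codons (the alignment keeps
  frame); any codon containing a gap or N in either row is excluded; a
  stop codon mismatches every residue, including another stop.
* Default analysis sizes — 20-locus families, 50k short reads, ~1k long
  reads, 10-20k reads for calibration checks — were chosen so each
  pipeline stage runs in seconds-to-minutes on one core while keeping
  binomial/multinomial sampling error well inside the asserted bounds.
  The 95-locus reference configuration is used where family size itself
  is the property under test.

## Known limitations

* The built-in aligner is exhaustive per locus and per read; it is meant
  for desk-scale validation, not production alignment.
* `proportional` implements per-read allocation proportional to candidate
  loci's unique-read counts; transcript-model EM approaches (and k-mer
  pseudoalignment quantifiers) are out of scope, with the diagnostic-allele
  route as the nearest in-package analogue.
* Population frequencies affect presence draws only; heterozygosity and
  allelic variation within a genome (beyond the cryptic plantings) are not
  modelled.
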