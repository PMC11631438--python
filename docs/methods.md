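# Methods

## Surrogate-parent DNM calling

A de novo mutation (DNM) is called at a site where the proband is
heterozygous and every configured parent — real or surrogate — is
homozygous for the reference allele. Requiring hom-ref (rather than
merely "does not carry the alt") polarizes calls between siblings: a site
where sibling 1 is het and sibling 2 is hom-ref cannot be re-explained as
a DNM in sibling 2. Calls are only interpretable inside *accessible
regions*, where the configured parents jointly cover both of the
proband's inherited haplotypes:

* **both real parents** — the whole autosomal genome;
* **one real parent + surrogate siblings** — the union over siblings of
  IBD segments labeled with the *missing* parent's origin;
* **no parents, two-surrogate mode** — the intersection of
  (hapA shared with some surrogate) and (hapB shared with some
  surrogate); a single sibling covers both haplotypes at once over the
  ~25% of the genome where the pair is IBD through both parents.

When two surrogates are used, which one is called "surrogate mother" is
scientifically arbitrary; we assign the lexicographically smaller sample
id for determinism. All interval arithmetic is 0-based, half-open;
conversion to VCF's 1-based coordinates happens only at the I/O boundary.

## IBD inference

Segments are detected by a native match-run scan over phased haplotypes
at common markers (minor allele frequency > 0.10 by default — rare
variants are uninformative for IBD and enriched for genotyping and
phasing error). Maximal runs where one haplotype of each individual
agrees at every retained marker are merged across physical gaps ≤ 1 kb
(tolerating isolated discordances), then filtered to ≥ 2 Mb and ≥ 100
markers. These defaults mirror common seed-and-extend IBD-detector usage
translated to physical coordinates; an open question is whether cM-scale
seed/extend thresholds should be mapped through the genetic map, and we
deliberately keep the scanner in bp because the simulator's maps are
uniform. Segment endpoints are accurate to one inter-marker interval,
which is why candidate calls near segment ends are handled by the density
filter rather than by trusting boundaries.

Parental origin of a sibling-shared haplotype is assigned by comparison
with the mother (when available) over the segment's retained markers:
≥ 99% identity to either maternal haplotype → maternal; otherwise
paternal. The 1% slack tolerates isolated genotype errors without
flipping labels; segments with no informative markers stay unknown.

## Filter stack

Filters annotate calls rather than deleting them (a `pass` verdict is
derived), so each filter's contribution can be audited and benchmarked.

* **panel** — the site segregates in the reference panel (alt frequency
  > 0). Presence, not frequency, is the criterion: a panel variant seen
  "de novo" is far more likely inherited from an unsequenced parent.
* **shared** — the variant is carried by ≥ 2 pedigree members not on one
  ancestor–descendant line. Sharing between, say, cousins indicates
  inheritance through a missing parent or a gene-conversion artifact; a
  parent–child pair is exempt because a true DNM can be transmitted.
  This filter knowingly sacrifices the 1–2% of DNMs shared between
  siblings through germline mosaicism; no rescue is attempted.
* **cluster** — a chain of more than 6 calls pairwise within 50 bp that
  contains a known (annotated) variant; such clusters are inherited
  haplotype bleed-through at mis-inferred IBD, not multinucleotide
  mutation events.
* **vaf** — variant allele fraction < 0.30. Germline heterozygotes
  center at VAF 0.5; a low-VAF excess marks somatic contamination. A
  separate per-individual screen flags any sample whose median call VAF
  falls below 0.40 so its rate estimate can be excluded wholesale.
* **density** — applied at the region level: any 100 kb window holding
  more than 3 Mendelian violations is excised (with a 10 kb margin), and
  candidates inside excised windows are dropped. True DNMs are sparse
  (~1 per 20 Mb per child); dense violation clusters are the signature of
  false IBD. The window/threshold pair is config-exposed; the values are
  this package's declared defaults.

The per-generation rate estimate divides passing calls by twice the
accessible length (two haplotypes at risk).

## Parental-age burden model

Expected per-type counts are linear in parental age (maternal and
paternal slopes/intercepts per 1-mer type), summed across parents, and
multiplied by a single accessibility scale `accessible_bp /
reference_genome_bp`. Family- and group-level tests scale each child
first, then sum observed and expected counts. Significance uses the
exact Poisson upper tail `P(X ≥ obs)` computed from the regularized
incomplete gamma function (identical to the pmf tail sum; no normal
approximation — expectations here are single-digit counts for most
types). No multiple-testing correction is applied by default; a
Bonferroni option exists. The detection threshold for an expectation λ is
the smallest count c with `P(X ≥ c) < α`; attributing the implied excess
`c − λ` entirely to the carrier parent gives the minimum detectable fold
elevation of that parent's rate, and the same arithmetic applied to an
observed count gives the estimated fold.

Because counts are discrete, the attained size of the test is below the
nominal α; averaged over realistic per-family expectations it sits near
0.045, which is what the calibration test measures.

For the BXD mouse panel, each strain's C>A rate per site per generation
is regressed (OLS) on generation time (years of inbreeding / generations
of inbreeding, centered at the minimum observed value) plus a categorical
*Mutyh* genotype term; a genotype × age interaction is fitted separately
to test slope homogeneity. Parallel slopes with separated intercepts
indicate the mutator acts during embryonic development rather than gamete
ageing.

The cellular repair-function score is `log2(f_variant / f_WT)` over the
fraction of repair-positive transfected cells, with a 10⁻³ pseudocount
for zero numerators.

## Simulator

The generator works at genotype level (no reads/BAMs): this exercises
every caller and filter decision at desk scale without alignment
machinery. Defaults:

* **genome** — 2 autosomes × 100 Mb at a uniform 1 cM/Mb: seconds-scale,
  with ~1 crossover per chromosome per meiosis, matching the human
  genome-wide average map density.
* **founders** — two unrelated diploids over Poisson-placed markers
  (10⁻³ /bp), alt frequencies ~ Uniform(0.1, 0.9) emulating a
  common-variant panel after a 10% MAF cut. No linkage disequilibrium or
  demography is modeled — founder realism is irrelevant to the IBD and
  calling geometry being benchmarked.
* **meiosis** — crossover counts ~ Poisson(genetic length in Morgans),
  uniform positions, independent chromosomes. Children's hapA is
  maternal, hapB paternal.
* **mutations** — per-child, per-type, per-parent counts ~
  Poisson(parental-age model), placed uniformly at non-segregating
  positions on the corresponding haplotype. The default truth
  coefficients are documented synthetic values giving ≈ 70 DNMs per child
  at ages (28, 32), ≈ 75% paternal and ≈ 10% C>A — the qualitative
  anatomy of human germline mutagenesis scaled to the small genome. A
  mutator multiplies the targeted parent's rate for the targeted type;
  the embryonic mode instead adds unphased post-zygotic mutations at rate
  (fold − 1) × the type's total expectation, landing on a random
  haplotype.
* **noise** — gene conversion (0.5 tracts/meiosis, 300 bp, copying the
  untransmitted parental haplotype) is on by default; per-genotype error
  is 0 by default so the headline benchmark is the clean-data oracle
  equivalence, and tests switch errors on explicitly. Allele depths:
  total ~ Poisson(50), alt ~ Binomial(depth, ½) for hets.

Truth records carry every planted DNM, gamete map, conversion tract and
error flip; `benchmark` partitions false negatives into inaccessible /
sib-shared / filtered / missed and attributes false positives to
conversion tracts, error sites, or IBD-boundary proximity (50 kb margin).

What passing simulator-based tests does **not** show: performance under
real phasing error, alignment artifacts, LD structure, CpG hotspot
clustering, or population-level allele-frequency misspecification — the
simulator has none of these.

## Problem sizes and numerical choices

Tests run the full pipeline on 2 × 50 Mb (clean-family fixtures) and
2 × 10 Mb (replicate studies) genomes; the sharing-geometry Monte Carlo
uses 1,000 pairs on 2 × 100 Mb; mutator-recovery uses 500 replicate
3-child families; the null-calibration draw is 10,000 units. These sizes
give Monte-Carlo standard errors comfortably inside the asserted
tolerances. Poisson tails are exact; detection thresholds are found by
scanning upward from a quantile warm start; interval operations are
integer-exact. Degenerate inputs (empty region sets, missing depths,
absent mothers, single-genotype BXD tables) raise or warn explicitly as
documented in each docstring.

## Known limitations

* IBD endpoints are only marker-resolution; the density filter, not
  boundary trust, protects calls near segment ends.
* The shared-variant filter misses sib-shared mosaic DNMs by design.
* Two-surrogate calls cannot be phased to parent of origin.
* The accessibility correction is a single multiplicative scale; no
  per-region mutation-rate heterogeneity is modeled.
* The BXD regression assumes strain records are independent and
  homoskedastic; no phylogenetic correlation between strains is modeled.
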