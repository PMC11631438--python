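# kinfolk

De novo mutation (DNM) calling in nuclear families with missing parents,
using siblings as **surrogate parents**, plus a parental-age Poisson
framework for testing children's mutation burdens for mutator phenotypes
(e.g. the C>A excess caused by defective *MUTYH* base-excision repair).

## Who this is for

Standard DNM calling needs both parental genomes: a DNM is a Mendelian
violation, a heterozygous variant in the child absent from both parents.
When a parent is deceased or unsequenced, whole families drop out of
germline mutation-rate studies. But full siblings co-inherit each parental
haplotype over half of the autosomes. Wherever a proband shares an
inherited haplotype identical-by-descent (IBD) with a sibling, that
sibling's genome stands in for the missing parent: a variant carried by
the proband but absent from the shared haplotype arose de novo. `kinfolk`
implements this surrogate-parent method end-to-end — IBD inference,
accessible-region computation, calling, filtering, phasing — together
with a pedigree simulator that benchmarks every step against planted
truth, and the burden-testing statistics used to size parental mutator
effects.

## The model in brief

**Accessibility.** With one real parent and *n* surrogate siblings, a
locus is callable unless all *n* siblings inherited the other haplotype
of the missing parent, so a fraction `1 − 2⁻ⁿ` of DNMs is callable. With
no parents, both haplotypes must be covered independently: `(1 − 2⁻ⁿ)²`.
A single sibling can even act as a *double surrogate* wherever the pair
shares both parental haplotypes — about 25% of the genome.

**Rates.** Within accessible regions, `rate = n_DNM / (2 × accessible bp)`.

**Burden testing.** Expected counts of each 1-mer mutation type *c*
(C>A, C>G, C>T, A>C, A>G, A>T) are linear in parental age at conception:

```
y_c,mat(a_mat) = m_c,mat · a_mat + b_c,mat
y_c,pat(a_pat) = m_c,pat · a_pat + b_c,pat
```

maternal and paternal expectations add to the child's expected burden,
scaled by the accessible genome fraction. Observed counts are tested
against expectation with exact one-tailed Poisson tails, `P(X ≥ obs)`.
Excess counts are converted into carrier-parent fold elevations
(attributing the whole excess to the carrier parent's germline), and
detection thresholds give the minimum effect size a family has power to
detect. Coefficient tables are an external input (TSV) — they come from
regressions on large control trio cohorts and are never hard-coded.

A companion regression for the BXD recombinant-inbred mouse panel models
each strain's per-generation C>A rate as a function of generation time
and *Mutyh* genotype, separating gametic-ageing from embryonic mutation
accumulation.

## Worked example

Simulate a 3-child family (mother and father available in the VCF, but we
call DNMs in `child1` using the mother plus both siblings as surrogate
fathers), infer IBD, compute accessible regions, and call:

```
kinfolk simulate --seed 11 --n-children 3 --out-prefix fam
kinfolk ibd --vcf fam.vcf --ped fam.ped --out fam.ibd.tsv
kinfolk regions --ibd fam.ibd.tsv --ped fam.ped --layout fam.layout.tsv \
    --proband child1 --surrogates child2 --surrogates child3 \
    --real-parents mother --out-prefix fam.regions
kinfolk call --vcf fam.vcf --ped fam.ped --regions-prefix fam.regions \
    --parents mother --parents child2 --parents child3 \
    --ibd fam.ibd.tsv --out-prefix fam
```

Output of the last command:

```
{
  "proband": "child1",
  "n_candidates": 54,
  "n_pass": 54,
  "accessible_bp": 140753063,
  "rate_per_bp_per_generation": 1.9182531040194842e-07,
  "median_vaf": 0.49489795918367346,
  "somatic_contamination_flag": false,
  "spectrum": {"C>A": 5, "C>G": 5, "C>T": 25, "A>C": 2, "A>G": 15, "A>T": 2}
}
```

The callable fraction (0.704 of the 200 Mb simulated genome) sits near
the theoretical `1 − 2⁻² = 0.75` for one parent plus two surrogate
siblings. Scoring against the simulation truth (`kinfolk benchmark`):
precision 1.0, and all 54 of the 73 planted DNMs that fall inside
accessible regions are recovered (`recall_in_accessible = 1.0`); the 19
misses are all in inaccessible regions, as the theory predicts. The
median VAF near 0.5 is the germline-heterozygote signature, and 44 of the
53 phased calls are paternal — the expected ~75% paternal share of
germline mutation.

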