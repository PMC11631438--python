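"""De novo mutation calling against real and/or surrogate parents.

Candidates are Mendelian violations: in-region sites where the proband is
heterozygous and every configured parent — real or surrogate sibling — is
homozygous for the reference allele. Restricting to hom-ref parents
polarizes the call: a site where sibling 1 is het and sibling 2 is hom-ref
cannot instead be a de novo mutation in sibling 2.

Filters annotate calls rather than deleting them so each filter's
contribution can be audited; downstream counting uses ``pass`` calls only.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .genotypes import ALT, REF, PhasedGenotypeMatrix
from .ibd import AccessibleRegionSet, IBDSegment
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

MUTATION_TYPES = ("C>A", "C>G", "C>T", "A>C", "A>G", "A>T")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

FILTER_NAMES = ("panel", "shared", "cluster", "vaf", "density")


def classify_spectrum(ref_allele: str, alt_allele: str) -> str:
    """Collapse a substitution to its pyrimidine-ancestral 1-mer class.

    Purine-ancestral changes are reported as the reverse complement so the
    ancestral allele is always C or A (e.g. G>T becomes C>A).
    """
    ref_allele = ref_allele.upper()
    alt_allele = alt_allele.upper()
    if ref_allele not in _COMPLEMENT or alt_allele not in _COMPLEMENT:
        raise ValueError(f"not a SNV: {ref_allele}>{alt_allele}")
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles are identical")
    if ref_allele in ("G", "T"):
        ref_allele = _COMPLEMENT[ref_allele]
        alt_allele = _COMPLEMENT[alt_allele]
    return f"{ref_allele}>{alt_allele}"


@dataclass(frozen=True)
class DNMCall:
    proband: str
    chrom: str
    pos: int                       # 0-based
    ref_allele: str
    alt_allele: str
    vaf: float                     # nan when no depths available
    depth: int
    spectrum_class: str
    alt_haplotype: Optional[str] = None   # "A"/"B" when proband is phased
    phase: str = "unknown"                # maternal / paternal / unknown
    filters: frozenset[str] = frozenset()

    @property
    def passed(self) -> bool:
        return not (set(self.filters) & set(FILTER_NAMES))


@dataclass(frozen=True)
class RateEstimate:
    proband: str
    n_pass: int
    accessible_bp: int
    rate_per_bp_per_generation: float


def call_mendelian_violations(
    genotypes: PhasedGenotypeMatrix,
    proband: str,
    parent_set: Iterable[str],
    regions: AccessibleRegionSet,
) -> list[DNMCall]:
    """Emit a candidate at every accessible site where the proband is het
    and all real/surrogate parents are hom-ref."""
    parent_set = list(parent_set)
    if not parent_set:
        raise ValueError("parent_set must name at least one real or surrogate parent")
    pro = genotypes.samples[proband]
    parents = [genotypes.samples[p] for p in parent_set]

    calls: list[DNMCall] = []
    n_skipped = 0
    for chrom in genotypes.chromosomes:
        if chrom not in regions.regions:
            continue
        sl = genotypes.chrom_slice(chrom)
        for i in range(sl.start, sl.stop):
            pos = int(genotypes.pos[i])
            if not regions.contains(chrom, pos):
                continue
            if pro.is_missing(i):
                n_skipped += 1
                continue
            if not pro.is_het(i):
                continue
            if not all(p.is_hom_ref(i) for p in parents):
                continue
            alt_hap = None
            if pro.phased:
                alt_hap = "A" if pro.hap_a[i] == ALT else "B"
            calls.append(DNMCall(
                proband=proband, chrom=chrom, pos=pos,
                ref_allele=str(genotypes.ref[i]),
                alt_allele=str(genotypes.alt[i]),
                vaf=genotypes.vaf(proband, i),
                depth=genotypes.depth(proband, i),
                spectrum_class=classify_spectrum(
                    str(genotypes.ref[i]), str(genotypes.alt[i])),
                alt_haplotype=alt_hap,
            ))
    if n_skipped:
        logger.info("%s: %d sites skipped for missing proband genotype",
                    proband, n_skipped)
    return calls


# ---------------------------------------------------------------------------
# filter stack
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterParams:
    min_vaf: float = 0.30
    cluster_count: int = 6        # groups strictly larger are suspect
    cluster_span_bp: int = 50
    panel_filter: bool = True


def _cluster_groups(calls: list[DNMCall], span_bp: int) -> list[list[int]]:
    """Transitive closure of pairwise-within-span links, per chromosome."""
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].pos))
    groups: list[list[int]] = []
    for idx in order:
        c = calls[idx]
        if (groups
                and calls[groups[-1][-1]].chrom == c.chrom
                and c.pos - calls[groups[-1][-1]].pos <= span_bp):
            groups[-1].append(idx)
        else:
            groups.append([idx])
    return groups


def apply_site_filters(
    calls: list[DNMCall],
    genotypes: PhasedGenotypeMatrix,
    pedigree: Pedigree,
    params: FilterParams = FilterParams(),
    known_variant_sites: Optional[set[tuple[str, int]]] = None,
) -> list[DNMCall]:
    """Annotate each call with the filter stack; returns all calls.

    * ``panel``   — the site segregates in the reference panel (alt
      frequency > 0): likely inherited, not de novo.
    * ``shared``  — the variant is carried by two or more pedigree members
      who are not on one ancestor–descendant line; such sharing indicates
      inheritance from an unsequenced parent (or gene conversion), with the
      parent–child exception preserving transmitted true mutations.
    * ``cluster`` — the call sits in a chain of more than ``cluster_count``
      calls pairwise within ``cluster_span_bp`` that includes a known
      (annotated) variant: an inherited haplotype bleeding through.
    * ``vaf``     — variant allele fraction below ``min_vaf``; germline hets
      center at 0.5, low VAF suggests somatic origin. Calls without depth
      information pass this filter with a warning.
    """
    known_variant_sites = known_variant_sites or set()
    flags: list[set[str]] = [set() for _ in calls]

    for k, call in enumerate(calls):
        try:
            i = genotypes.site_index(call.chrom, call.pos)
        except KeyError:
            i = None

        if params.panel_filter and i is not None:
            f = genotypes.panel_alt_freq[i]
            if f == f and f > 0:  # non-nan, segregating in panel
                flags[k].add("panel")

        if i is not None:
            carriers = genotypes.carriers(i) & set(pedigree.ids)
            if len(carriers) >= 2 and any(
                    not pedigree.is_lineal(a, b)
                    for a in carriers for b in carriers if a < b):
                flags[k].add("shared")

        if call.vaf != call.vaf:  # nan: no allele depths at this site
            logger.warning("%s %s:%d has no allele depths; VAF filter passed",
                           call.proband, call.chrom, call.pos)
        elif call.vaf < params.min_vaf:
            flags[k].add("vaf")

    for group in _cluster_groups(calls, params.cluster_span_bp):
        if len(group) > params.cluster_count and any(
                (calls[i].chrom, calls[i].pos) in known_variant_sites
                for i in group):
            for i in group:
                flags[i].add("cluster")

    out = [replace(c, filters=c.filters | frozenset(f))
           for c, f in zip(calls, flags)]
    for name in FILTER_NAMES:
        n = sum(1 for c in out if name in c.filters)
        if n:
            logger.info("filter %s marked %d calls", name, n)
    logger.info("%d of %d calls pass all filters",
                sum(c.passed for c in out), len(out))
    return out


# ---------------------------------------------------------------------------
# phasing, rates, VAF screen
# ---------------------------------------------------------------------------

def phase_dnm(
    call: DNMCall,
    segments: Iterable[IBDSegment],
    double_surrogate_mode: bool = False,
) -> str:
    """Assign a call to the parental haplotype it arose on.

    The alt-bearing proband haplotype is looked up in the origin-labeled
    sibling IBD segments covering the site: a non-maternal shared segment
    implies the mutation rose on the paternally inherited chromosome, and
    vice versa. In two-surrogate mode the maternal/paternal identity of the
    shared haplotypes is unknowable, so calls stay unphased.
    """
    if double_surrogate_mode or call.alt_haplotype is None:
        return "unknown"
    for seg in segments:
        if (seg.involves(call.proband)
                and seg.chrom == call.chrom
                and seg.start <= call.pos < seg.end
                and seg.hap_of(call.proband) == call.alt_haplotype
                and seg.origin in ("maternal", "paternal")):
            return seg.origin
    return "unknown"


def estimate_rate(calls_pass: list[DNMCall],
                  regions: AccessibleRegionSet) -> RateEstimate:
    """Per-generation mutation rate: count / (2 x accessible bp).

    The factor 2 reflects the two inherited haplotypes on which mutations
    could have arisen within the accessible region.
    """
    if regions.total_bp <= 0:
        raise ValueError("accessible region set is empty; rate undefined")
    n = sum(1 for c in calls_pass if c.passed)
    return RateEstimate(
        proband=regions.proband, n_pass=n, accessible_bp=regions.total_bp,
        rate_per_bp_per_generation=n / (2.0 * regions.total_bp))


def screen_vaf_distribution(
    calls: list[DNMCall],
    flag_threshold: float = 0.40,
) -> tuple[float, bool]:
    """Flag probable somatic contamination from the VAF distribution.

    Germline heterozygotes sit on one of two haplotypes, so their VAFs
    center at 0.5; a median well below that indicates an admixture of
    somatic (subclonal) mutations and the individual's rate estimate should
    not be trusted.
    """
    vafs = [c.vaf for c in calls if c.depth > 0 and c.vaf == c.vaf]
    if not vafs:
        logger.warning("no calls with depth; VAF screen not applicable")
        return float("nan"), False
    med = statistics.median(vafs)
    return med, med < flag_threshold


def spectrum_counts(calls: Iterable[DNMCall],
                    pass_only: bool = True) -> dict[str, int]:
    """Observed 1-mer spectrum of a call set."""
    counts = {t: 0 for t in MUTATION_TYPES}
    for c in calls:
        if pass_only and not c.passed:
            continue
        counts[c.spectrum_class] += 1
    return counts
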