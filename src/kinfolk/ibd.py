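"""Sibling IBD segment inference and accessible-region computation.

Full siblings share each parental haplotype over ~50% of the autosomes.
Wherever a proband shares an inherited haplotype with a sibling, that
sibling's genome can stand in for the missing parent ("surrogate parent"):
a variant carried by the proband but absent from the shared haplotype must
have arisen de novo. This module finds the shared tracts from phased
genotypes, labels their parental origin when a mother is available, and
derives the regions of the genome accessible to de-novo calling under each
real/surrogate parent configuration.

The segment scanner is a native match-run scan over common markers
(minor allele frequency above a cutoff), merging runs across short gaps and
discarding tracts that are too short or too marker-poor — the same shape of
filtering used by seed-and-extend IBD detectors on phased panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from ._intervals import (Interval, contains, intersect, merge, subtract,
                         total_length, union)
from .genome import GenomeLayout
from .genotypes import MISSING, PhasedGenotypeMatrix
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

ORIGINS = ("maternal", "paternal", "both", "unknown")


@dataclass(frozen=True)
class IBDSegment:
    """A tract over which one haplotype of ``individual_a`` matches one
    haplotype of ``individual_b``. Coordinates are 0-based half-open."""

    individual_a: str
    hap_a: str            # "A" or "B"
    individual_b: str
    hap_b: str
    chrom: str
    start: int
    end: int
    origin: str = "unknown"
    n_markers: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if self.hap_a not in ("A", "B") or self.hap_b not in ("A", "B"):
            raise ValueError("haplotype labels must be 'A' or 'B'")
        if self.origin not in ORIGINS:
            raise ValueError(f"invalid origin {self.origin!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def involves(self, iid: str) -> bool:
        return iid in (self.individual_a, self.individual_b)

    def hap_of(self, iid: str) -> str:
        if iid == self.individual_a:
            return self.hap_a
        if iid == self.individual_b:
            return self.hap_b
        raise KeyError(iid)

    def other(self, iid: str) -> str:
        if iid == self.individual_a:
            return self.individual_b
        if iid == self.individual_b:
            return self.individual_a
        raise KeyError(iid)


@dataclass(frozen=True)
class IBDParams:
    """Scanner settings; defaults mirror common hap-IBD-style usage where
    they translate to physical coordinates."""

    min_maf: float = 0.10
    min_length_bp: int = 2_000_000
    min_markers: int = 100
    max_gap_bp: int = 1000


@dataclass(frozen=True)
class SurrogateConfiguration:
    """Which relatives cover the proband's two inherited haplotypes."""

    real_parents: frozenset[str] = frozenset()
    surrogate_mothers: frozenset[str] = frozenset()
    surrogate_fathers: frozenset[str] = frozenset()
    double_surrogates: frozenset[str] = frozenset()

    @property
    def all_parents(self) -> frozenset[str]:
        return (self.real_parents | self.surrogate_mothers
                | self.surrogate_fathers | self.double_surrogates)

    @property
    def surrogates(self) -> frozenset[str]:
        return (self.surrogate_mothers | self.surrogate_fathers
                | self.double_surrogates)


@dataclass
class AccessibleRegionSet:
    """Regions of a proband's genome where de-novo calls are interpretable
    under a given parent configuration."""

    proband: str
    configuration: SurrogateConfiguration
    regions: dict[str, list[Interval]]
    genome_bp: int

    @property
    def total_bp(self) -> int:
        return sum(total_length(iv) for iv in self.regions.values())

    @property
    def callable_fraction(self) -> float:
        return self.total_bp / self.genome_bp if self.genome_bp else 0.0

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom in self.regions and contains(self.regions[chrom], pos)


# ---------------------------------------------------------------------------
# segment inference
# ---------------------------------------------------------------------------

def _match_runs(match: np.ndarray, pos: np.ndarray,
                params: IBDParams) -> list[tuple[int, int, int]]:
    """Maximal runs of True in ``match``, merged across bp gaps <= max_gap_bp.

    Returns (start_bp, end_bp, n_markers) with end half-open at last
    matching marker + 1.
    """
    idx = np.flatnonzero(match)
    if len(idx) == 0:
        return []
    # break raw runs at mismatching markers
    runs: list[tuple[int, int]] = []  # index ranges [i, j] inclusive into idx
    run_start = 0
    for k in range(1, len(idx)):
        if idx[k] != idx[k - 1] + 1:
            runs.append((run_start, k - 1))
            run_start = k
    runs.append((run_start, len(idx) - 1))

    # merge runs whose bp gap is small (tolerates isolated discordances)
    merged: list[tuple[int, int]] = []
    for lo, hi in runs:
        if merged and pos[idx[lo]] - pos[idx[merged[-1][1]]] <= params.max_gap_bp:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))

    out = []
    for lo, hi in merged:
        n_markers = hi - lo + 1
        start_bp = int(pos[idx[lo]])
        end_bp = int(pos[idx[hi]]) + 1
        if n_markers >= params.min_markers and end_bp - start_bp >= params.min_length_bp:
            out.append((start_bp, end_bp, n_markers))
    return out


def infer_sibling_ibd(
    genotypes: PhasedGenotypeMatrix,
    pair: tuple[str, str],
    params: IBDParams = IBDParams(),
) -> list[IBDSegment]:
    """Detect haplotype sharing between two phased individuals.

    Only common markers (MAF > ``min_maf``) with non-missing haplotype calls
    in both individuals are considered; rare variants are uninformative for
    IBD and enriched for genotyping error.
    """
    a, b = pair
    for iid in pair:
        if not genotypes.samples[iid].phased:
            raise ValueError(
                f"{iid} is unphased; phase externally or use the simulator's "
                "truth phase before IBD inference")
    maf = genotypes.minor_allele_freq()
    sa, sb = genotypes.samples[a], genotypes.samples[b]

    segments: list[IBDSegment] = []
    for chrom in genotypes.chromosomes:
        sl = genotypes.chrom_slice(chrom)
        keep = (
            (maf[sl] > params.min_maf)
            & (sa.hap_a[sl] != MISSING) & (sa.hap_b[sl] != MISSING)
            & (sb.hap_a[sl] != MISSING) & (sb.hap_b[sl] != MISSING)
        )
        pos = genotypes.pos[sl][keep]
        if len(pos) == 0:
            continue
        haps_a = {"A": sa.hap_a[sl][keep], "B": sa.hap_b[sl][keep]}
        haps_b = {"A": sb.hap_a[sl][keep], "B": sb.hap_b[sl][keep]}
        for ha in ("A", "B"):
            for hb in ("A", "B"):
                for start, end, n in _match_runs(
                        haps_a[ha] == haps_b[hb], pos, params):
                    segments.append(IBDSegment(
                        individual_a=a, hap_a=ha,
                        individual_b=b, hap_b=hb,
                        chrom=chrom, start=start, end=end,
                        n_markers=n))
    return segments


# ---------------------------------------------------------------------------
# parental-origin labeling
# ---------------------------------------------------------------------------

def classify_parental_origin(
    segments: Iterable[IBDSegment],
    genotypes: Optional[PhasedGenotypeMatrix] = None,
    mother_id: Optional[str] = None,
    params: IBDParams = IBDParams(),
    match_threshold: float = 0.99,
) -> list[IBDSegment]:
    """Label sibling IBD segments maternal or paternal using the mother.

    The shared haplotype is compared to both maternal haplotypes over the
    segment's common markers: a match proportion >= ``match_threshold`` to
    either maternal haplotype labels the segment maternal; matching neither
    labels it paternal. Without a mother all segments stay ``unknown`` and
    callers must fall back on double-surrogate logic.
    """
    segments = list(segments)
    if genotypes is None or mother_id is None:
        return [replace(s, origin="unknown") if s.origin == "unknown" else s
                for s in segments]
    mother = genotypes.samples[mother_id]
    if not mother.phased:
        raise ValueError(f"mother {mother_id} is unphased")
    maf = genotypes.minor_allele_freq()

    out: list[IBDSegment] = []
    for seg in segments:
        sl = genotypes.chrom_slice(seg.chrom)
        pos = genotypes.pos[sl]
        child = genotypes.samples[seg.individual_a]
        shared = child.hap_a[sl] if seg.hap_a == "A" else child.hap_b[sl]
        in_seg = (
            (pos >= seg.start) & (pos < seg.end)
            & (maf[sl] > params.min_maf) & (shared != MISSING)
            & (mother.hap_a[sl] != MISSING) & (mother.hap_b[sl] != MISSING)
        )
        n = int(in_seg.sum())
        if n == 0:
            out.append(replace(seg, origin="unknown"))
            continue
        frac_a = float(np.mean(shared[in_seg] == mother.hap_a[sl][in_seg]))
        frac_b = float(np.mean(shared[in_seg] == mother.hap_b[sl][in_seg]))
        if max(frac_a, frac_b) >= match_threshold:
            out.append(replace(seg, origin="maternal"))
        else:
            out.append(replace(seg, origin="paternal"))
    return out


# ---------------------------------------------------------------------------
# accessible regions
# ---------------------------------------------------------------------------

def _segment_intervals(
    segments: Iterable[IBDSegment], proband: str, chrom: str,
    partner: Optional[str] = None, proband_hap: Optional[str] = None,
    origin: Optional[str] = None,
) -> list[Interval]:
    out = []
    for s in segments:
        if s.chrom != chrom or not s.involves(proband):
            continue
        if partner is not None and s.other(proband) != partner:
            continue
        if proband_hap is not None and s.hap_of(proband) != proband_hap:
            continue
        if origin is not None and s.origin != origin:
            continue
        out.append((s.start, s.end))
    return merge(out)


def designate_surrogate_roles(surrogates: Iterable[str]) -> tuple[str, ...]:
    """Deterministic surrogate mother/father assignment: the
    lexicographically smallest id is the surrogate mother. The choice is
    arbitrary science-wise; determinism makes runs reproducible."""
    return tuple(sorted(surrogates))


def accessible_regions(
    proband: str,
    pedigree: Pedigree,
    segments: Iterable[IBDSegment],
    configuration: SurrogateConfiguration,
    layout: GenomeLayout,
) -> AccessibleRegionSet:
    """Compute where de-novo calls are interpretable for ``proband``.

    * Both real parents: the whole autosomal genome.
    * One real parent plus surrogate siblings covering the other: the union
      over surrogates of segments labeled with the missing parent's origin.
    * No real parents, two-surrogate mode: regions where the proband shares
      haplotype A with some surrogate and haplotype B with some surrogate
      (possibly the same sibling — a double-surrogate region).
    """
    segments = list(segments)
    for iid in configuration.all_parents:
        if iid not in pedigree:
            raise KeyError(f"configuration names unknown individual {iid!r}")

    regions: dict[str, list[Interval]] = {}
    if len(configuration.real_parents) >= 2:
        for c in layout:
            regions[c.name] = [(0, c.length_bp)]
    elif len(configuration.real_parents) == 1:
        # real mother (or father) present: need surrogate coverage of the
        # other parent's haplotype
        real = next(iter(configuration.real_parents))
        missing_origin = ("paternal"
                          if pedigree[real].sex in ("female", "unknown")
                          else "maternal")
        surrogates = configuration.surrogates
        for c in layout:
            ivs: list[Interval] = []
            for sib in surrogates:
                ivs = union(ivs, _segment_intervals(
                    segments, proband, c.name, partner=sib,
                    origin=missing_origin))
            regions[c.name] = ivs
    else:
        surrogates = configuration.surrogates
        for c in layout:
            hap_a_cov: list[Interval] = []
            hap_b_cov: list[Interval] = []
            for sib in surrogates:
                hap_a_cov = union(hap_a_cov, _segment_intervals(
                    segments, proband, c.name, partner=sib, proband_hap="A"))
                hap_b_cov = union(hap_b_cov, _segment_intervals(
                    segments, proband, c.name, partner=sib, proband_hap="B"))
            regions[c.name] = intersect(hap_a_cov, hap_b_cov)

    return AccessibleRegionSet(
        proband=proband, configuration=configuration,
        regions=regions, genome_bp=layout.total_bp)


def theoretical_callable_fraction(n_surrogate_sibs: int,
                                  real_parent_present: bool,
                                  both_parents_present: bool = False) -> float:
    """Expected fraction of de-novo mutations callable in a family.

    With one real parent and n surrogate siblings the missing parent's
    haplotype is covered unless all n siblings inherited the other
    haplotype: 1 - 2^-n. With no parents both haplotypes must be covered
    independently: (1 - 2^-n)^2. Both parents present: 1.
    """
    if n_surrogate_sibs < 0:
        raise ValueError("number of surrogate siblings must be >= 0")
    if both_parents_present:
        return 1.0
    single = 1.0 - 2.0 ** (-n_surrogate_sibs)
    return single if real_parent_present else single ** 2


def density_filter(
    regions: AccessibleRegionSet,
    candidate_sites: dict[str, Iterable[int]],
    window_bp: int = 100_000,
    max_violations: int = 3,
    margin_bp: int = 10_000,
) -> AccessibleRegionSet:
    """Excise region windows with implausibly dense Mendelian violations.

    True de-novo mutations are sparse; tight clusters of violations mark
    mis-inferred IBD boundaries where polymorphic differences between
    haplotypes masquerade as mutations. Any window of ``window_bp`` holding
    more than ``max_violations`` candidates is removed (with a safety
    margin) from the accessible set.
    """
    new_regions: dict[str, list[Interval]] = {}
    for chrom, ivs in regions.regions.items():
        sites = np.sort(np.asarray(list(candidate_sites.get(chrom, [])),
                                   dtype=np.int64))
        if len(sites) <= max_violations:
            new_regions[chrom] = list(ivs)
            continue
        excised: list[Interval] = []
        # sliding window anchored at each candidate: the densest windows
        # are always anchored at a violation
        k = max_violations  # need > max_violations sites within window_bp
        for i in range(len(sites) - k):
            if sites[i + k] - sites[i] < window_bp:
                excised.append((int(sites[i]) - margin_bp,
                                int(sites[i + k]) + 1 + margin_bp))
        excised = [(max(0, s), e) for s, e in merge(excised)]
        new_regions[chrom] = subtract(ivs, excised)
        n_removed = total_length(ivs) - total_length(new_regions[chrom])
        if n_removed:
            logger.info("density filter removed %d bp on %s", n_removed, chrom)
    return AccessibleRegionSet(
        proband=regions.proband, configuration=regions.configuration,
        regions=new_regions, genome_bp=regions.genome_bp)
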