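"""Synthetic multi-sibling families with full truth records.

The generator emulates the benchmarking design for surrogate-parent
de-novo calling at the genotype level: two unrelated founders, children
produced by recombinant meioses on a uniform genetic map, de novo
mutations planted per 1-mer type at parental-age-dependent Poisson rates
(optionally inflated in one parent or in the early embryo by a mutator),
non-crossover gene-conversion tracts, genotype errors, and binomially
sampled allele depths. Every stochastic choice is recorded in a truth
record so callers can be scored against known answers.

Haplotype convention for children: hapA is maternally inherited, hapB
paternally inherited.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from ._intervals import Interval, intersect, merge, total_length
from .agemodel import AgeModelCoefficients, TypeCoefficients, expected_counts
from .caller import MUTATION_TYPES, classify_spectrum
from .genome import DEFAULT_LAYOUT, GenomeLayout
from .genotypes import ALT, REF, PhasedGenotypeMatrix
from .ibd import IBDSegment
from .pedigree import Individual, Pedigree

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def default_truth_coefficients(layout: GenomeLayout = DEFAULT_LAYOUT) -> AgeModelCoefficients:
    """Documented synthetic parental-age coefficients for simulation truth.

    Shaped to the qualitative anatomy of human germline mutagenesis —
    roughly 70 mutations per child at maternal age 28 / paternal age 32,
    about 75% of them paternal in origin, and about 10% C>A — while the
    absolute numbers are scaled to the simulated genome (the coefficients'
    reference genome is the layout itself, so no accessibility rescaling
    applies by default).
    """
    # per-type shares of the 1-mer spectrum (sum to 1)
    shares = {"C>A": 0.10, "C>G": 0.09, "C>T": 0.38,
              "A>C": 0.07, "A>G": 0.26, "A>T": 0.10}
    # totals: maternal 0.54/yr + 2.3, paternal 1.5/yr + 4.5
    per_type = {
        t: TypeCoefficients(
            m_mat=0.54 * s, b_mat=2.3 * s,
            m_pat=1.50 * s, b_pat=4.5 * s)
        for t, s in shares.items()
    }
    return AgeModelCoefficients(per_type=per_type,
                                reference_genome_bp=layout.total_bp)


@dataclass(frozen=True)
class FrequencySpectrum:
    """Alt-allele frequency distribution for founder variants.

    The default uniform(0.1, 0.9) mimics a common-variant panel after a
    10% minor-allele-frequency cut, the marker set informative for IBD.
    """

    kind: str = "uniform"          # uniform | beta | fixed
    params: tuple[float, ...] = (0.1, 0.9)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, n)
        if self.kind == "beta":
            a, b = self.params
            return rng.beta(a, b, n)
        if self.kind == "fixed":
            return np.full(n, self.params[0])
        raise ValueError(f"unknown spectrum kind {self.kind!r}")


@dataclass(frozen=True)
class MutatorConfig:
    target: str = "none"           # none | maternal | paternal | embryonic
    mutation_type: str = "C>A"
    fold: float = 1.0

    def __post_init__(self) -> None:
        if self.target not in ("none", "maternal", "paternal", "embryonic"):
            raise ValueError(f"invalid mutator target {self.target!r}")
        if self.fold < 1.0:
            raise ValueError("mutator fold must be >= 1")
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"invalid mutation type {self.mutation_type!r}")


@dataclass(frozen=True)
class SimulationConfig:
    layout: GenomeLayout = DEFAULT_LAYOUT
    n_children: int = 5
    a_mat: float = 28.0
    a_pat: float = 32.0
    coefficients: Optional[AgeModelCoefficients] = None
    mutator: MutatorConfig = MutatorConfig()
    marker_density: float = 1e-3           # markers per bp
    founder_spectrum: FrequencySpectrum = FrequencySpectrum()
    depth_mean: float = 50.0
    genotype_error_rate: float = 0.0
    gene_conversion_rate: float = 0.5      # tracts per meiosis
    gene_conversion_tract_bp: int = 300
    seed: int = 0

    def truth_coefficients(self) -> AgeModelCoefficients:
        return (self.coefficients
                if self.coefficients is not None
                else default_truth_coefficients(self.layout))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GameteMap:
    """Which parental haplotype (0 or 1) each genomic position came from.

    Per chromosome: the starting haplotype and the sorted crossover
    positions at which the source switches.
    """

    start_hap: dict[str, int]
    breakpoints: dict[str, tuple[int, ...]]

    def source_at(self, chrom: str, pos: int) -> int:
        n_before = bisect.bisect_right(self.breakpoints[chrom], pos)
        return (self.start_hap[chrom] + n_before) % 2

    def source_intervals(self, chrom: str, length: int) -> list[tuple[int, int, int]]:
        out = []
        cur = 0
        hap = self.start_hap[chrom]
        for b in self.breakpoints[chrom]:
            if b > cur:
                out.append((cur, b, hap))
            cur = b
            hap ^= 1
        if cur < length:
            out.append((cur, length, hap))
        return out


def sample_gamete_map(layout: GenomeLayout, rng: np.random.Generator) -> GameteMap:
    """Poisson crossovers on each chromosome's genetic map; independent
    across chromosomes; random starting haplotype."""
    start = {}
    breaks = {}
    for c in layout:
        n_x = rng.poisson(c.genetic_length_morgans)
        pos = np.sort(rng.integers(0, c.length_bp, n_x))
        start[c.name] = int(rng.integers(0, 2))
        breaks[c.name] = tuple(int(p) for p in pos)
    return GameteMap(start_hap=start, breakpoints=breaks)


def shared_source_intervals(a: GameteMap, b: GameteMap,
                            layout: GenomeLayout) -> dict[str, list[Interval]]:
    """Regions where two gametes from the same parent carry the same
    parental haplotype — i.e. where two siblings are IBD through that
    parent."""
    out: dict[str, list[Interval]] = {}
    for c in layout:
        pieces: list[Interval] = []
        cuts = sorted(set(a.breakpoints[c.name]) | set(b.breakpoints[c.name])
                      | {0, c.length_bp})
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            if lo >= hi:
                continue
            mid = lo  # source is constant on [lo, hi); evaluate at lo
            if a.source_at(c.name, mid) == b.source_at(c.name, mid):
                pieces.append((lo, hi))
        out[c.name] = merge(pieces)
    return out


def simulate_meiosis(
    genotypes: PhasedGenotypeMatrix,
    parent_id: str,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> tuple[np.ndarray, GameteMap]:
    """Produce one gamete's allele vector from a phased parent."""
    gmap = sample_gamete_map(layout, rng)
    parent = genotypes.samples[parent_id]
    gamete = np.empty(genotypes.n_sites, dtype=np.int8)
    for chrom in genotypes.chromosomes:
        sl = genotypes.chrom_slice(chrom)
        pos = genotypes.pos[sl]
        length = layout[chrom].length_bp
        for lo, hi, hap in gmap.source_intervals(chrom, length):
            i0, i1 = np.searchsorted(pos, [lo, hi])
            src = parent.hap_a if hap == 0 else parent.hap_b
            gamete[sl.start + i0:sl.start + i1] = src[sl.start + i0:sl.start + i1]
    return gamete, gmap


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None
                      ) -> PhasedGenotypeMatrix:
    """Two unrelated phased founders over Poisson-placed common markers."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for c in config.layout:
        n = rng.poisson(c.length_bp * config.marker_density)
        pos = np.unique(rng.integers(0, c.length_bp, n))
        chroms.extend([c.name] * len(pos))
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.array([], dtype=np.int64)
    if len(pos_all) == 0:
        raise ValueError("marker density too low: zero markers placed")

    n_sites = len(pos_all)
    freq = config.founder_spectrum.sample(n_sites, rng)
    bases = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, n_sites)
    alt_shift = rng.integers(1, 4, n_sites)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + alt_shift) % 4]

    m = PhasedGenotypeMatrix(
        chrom=np.array(chroms, dtype=object), pos=pos_all,
        ref=ref.astype(object), alt=alt.astype(object),
        panel_alt_freq=freq)
    for sample in ("mother", "father"):
        hap_a = (rng.random(n_sites) < freq).astype(np.int8)
        hap_b = (rng.random(n_sites) < freq).astype(np.int8)
        m.add_sample(sample, hap_a, hap_b, phased=True)
    return m


# ---------------------------------------------------------------------------
# full family simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedDNM:
    child: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    spectrum_class: str
    parent_of_origin: str          # maternal | paternal | embryonic
    haplotype: str                 # "A" or "B"


@dataclass(frozen=True)
class ConversionTract:
    child: str
    parent: str                    # maternal | paternal meiosis
    chrom: str
    start: int
    end: int


@dataclass
class TruthRecord:
    children: list[str]
    dnms: list[PlantedDNM]
    gamete_maps: dict[str, dict[str, GameteMap]]   # child -> {maternal, paternal}
    conversion_tracts: list[ConversionTract]
    genotype_error_sites: list[tuple[str, str, int]]  # (sample, chrom, pos)
    layout: GenomeLayout

    def dnms_of(self, child: str) -> list[PlantedDNM]:
        return [d for d in self.dnms if d.child == child]

    def pair_sharing(self, a: str, b: str, parent: str) -> dict[str, list[Interval]]:
        return shared_source_intervals(
            self.gamete_maps[a][parent], self.gamete_maps[b][parent], self.layout)

    def true_ibd_segments(self, a: str, b: str) -> list[IBDSegment]:
        """Sibling IBD truth: hapA/hapA sharing is maternal, hapB/hapB
        paternal (children's haplotype convention)."""
        segs: list[IBDSegment] = []
        for parent, hap, origin in (("maternal", "A", "maternal"),
                                    ("paternal", "B", "paternal")):
            for chrom, ivs in self.pair_sharing(a, b, parent).items():
                for start, end in ivs:
                    segs.append(IBDSegment(
                        individual_a=a, hap_a=hap, individual_b=b, hap_b=hap,
                        chrom=chrom, start=start, end=end, origin=origin))
        return segs


@dataclass
class FamilySimulation:
    config: SimulationConfig
    genotypes: PhasedGenotypeMatrix
    pedigree: Pedigree
    truth: TruthRecord


def _dnm_alleles(mtype: str, rng: np.random.Generator) -> tuple[str, str]:
    """Choose ref/alt for a planted mutation of a pyrimidine-collapsed
    class, on a random reference strand."""
    anc, der = mtype.split(">")
    if rng.random() < 0.5:
        anc, der = _COMPLEMENT[anc], _COMPLEMENT[der]
    return anc, der


def simulate_family(config: SimulationConfig) -> FamilySimulation:
    """Simulate founders plus ``n_children`` full siblings with truth.

    Same seed, same config -> byte-identical output (single generator
    threaded through every stochastic step).
    """
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    layout = config.layout
    coeffs = config.truth_coefficients()
    children = [f"child{i + 1}" for i in range(config.n_children)]

    # 1. meioses: child haplotype alleles over founder sites
    gamete_maps: dict[str, dict[str, GameteMap]] = {}
    child_haps: dict[str, dict[str, np.ndarray]] = {}
    conversion_tracts: list[ConversionTract] = []
    for child in children:
        hap_a, gm_mat = simulate_meiosis(founders, "mother", layout, rng)
        hap_b, gm_pat = simulate_meiosis(founders, "father", layout, rng)
        gamete_maps[child] = {"maternal": gm_mat, "paternal": gm_pat}
        child_haps[child] = {"A": hap_a, "B": hap_b}
        # gene conversion: short tracts copying the homologous parental
        # haplotype into the gamete
        for parent_label, parent_id, hap_key, gmap in (
                ("maternal", "mother", "A", gm_mat),
                ("paternal", "father", "B", gm_pat)):
            n_tracts = rng.poisson(config.gene_conversion_rate)
            for _ in range(n_tracts):
                c = layout.chromosomes[rng.integers(0, len(layout.chromosomes))]
                start = int(rng.integers(0, max(1, c.length_bp - config.gene_conversion_tract_bp)))
                end = start + config.gene_conversion_tract_bp
                sl = founders.chrom_slice(c.name)
                pos = founders.pos[sl]
                i0, i1 = np.searchsorted(pos, [start, end])
                if i1 > i0:
                    parent = founders.samples[parent_id]
                    # copy from the haplotype NOT transmitted here
                    mid = start
                    other = 1 - gmap.source_at(c.name, mid)
                    src = parent.hap_a if other == 0 else parent.hap_b
                    child_haps[child][hap_key][sl.start + i0:sl.start + i1] = \
                        src[sl.start + i0:sl.start + i1]
                conversion_tracts.append(ConversionTract(
                    child=child, parent=parent_label, chrom=c.name,
                    start=start, end=end))

    # 2. de novo mutations per child, Poisson per type and parent of origin
    exp = expected_counts(coeffs, config.a_mat, config.a_pat)
    planted: list[PlantedDNM] = []
    occupied: set[tuple[str, int]] = {
        (founders.chrom[i], int(founders.pos[i]))
        for i in range(founders.n_sites)}
    chrom_names = [c.name for c in layout]
    chrom_lengths = np.array([c.length_bp for c in layout], dtype=float)
    chrom_weights = chrom_lengths / chrom_lengths.sum()

    def place(child: str, mtype: str, origin: str, haplotype: str) -> None:
        while True:
            ci = rng.choice(len(chrom_names), p=chrom_weights)
            chrom = chrom_names[ci]
            pos = int(rng.integers(0, layout[chrom].length_bp))
            if (chrom, pos) not in occupied:
                occupied.add((chrom, pos))
                break
        ref, alt = _dnm_alleles(mtype, rng)
        planted.append(PlantedDNM(
            child=child, chrom=chrom, pos=pos, ref_allele=ref,
            alt_allele=alt, spectrum_class=mtype,
            parent_of_origin=origin, haplotype=haplotype))

    mut = config.mutator
    for child in children:
        for t in MUTATION_TYPES:
            lam_mat = exp.expected_mat[t]
            lam_pat = exp.expected_pat[t]
            lam_emb = 0.0
            if mut.target != "none" and t == mut.mutation_type:
                if mut.target == "maternal":
                    lam_mat *= mut.fold
                elif mut.target == "paternal":
                    lam_pat *= mut.fold
                else:  # embryonic: post-zygotic excess, unphased origin
                    lam_emb = (mut.fold - 1.0) * (lam_mat + lam_pat)
            for _ in range(rng.poisson(lam_mat)):
                place(child, t, "maternal", "A")
            for _ in range(rng.poisson(lam_pat)):
                place(child, t, "paternal", "B")
            for _ in range(rng.poisson(lam_emb)):
                place(child, t, "embryonic", "A" if rng.random() < 0.5 else "B")

    # 3. assemble the full matrix: founder sites + DNM sites
    dnm_by_site: dict[tuple[str, int], PlantedDNM] = {
        (d.chrom, d.pos): d for d in planted}
    all_sites: list[tuple[str, int]] = []
    for c in layout:
        founder_pos = founders.pos[founders.chrom_slice(c.name)] \
            if c.name in founders.chromosomes else np.array([], dtype=np.int64)
        dnm_pos = sorted(p for ch, p in dnm_by_site if ch == c.name)
        merged_pos = np.unique(np.concatenate([
            founder_pos, np.array(dnm_pos, dtype=np.int64)]))
        all_sites.extend((c.name, int(p)) for p in merged_pos)

    n_all = len(all_sites)
    chrom_arr = np.array([s[0] for s in all_sites], dtype=object)
    pos_arr = np.array([s[1] for s in all_sites], dtype=np.int64)
    ref_arr = np.empty(n_all, dtype=object)
    alt_arr = np.empty(n_all, dtype=object)
    freq_arr = np.zeros(n_all)  # DNM sites are absent from the panel

    founder_index = {
        (founders.chrom[i], int(founders.pos[i])): i
        for i in range(founders.n_sites)}
    src_idx = np.full(n_all, -1, dtype=np.int64)
    for j, key in enumerate(all_sites):
        if key in founder_index:
            i = founder_index[key]
            src_idx[j] = i
            ref_arr[j] = founders.ref[i]
            alt_arr[j] = founders.alt[i]
            freq_arr[j] = founders.panel_alt_freq[i]
        else:
            d = dnm_by_site[key]
            ref_arr[j] = d.ref_allele
            alt_arr[j] = d.alt_allele

    matrix = PhasedGenotypeMatrix(chrom=chrom_arr, pos=pos_arr,
                                  ref=ref_arr, alt=alt_arr,
                                  panel_alt_freq=freq_arr)

    def expand(arr: np.ndarray) -> np.ndarray:
        out = np.zeros(n_all, dtype=np.int8)
        mask = src_idx >= 0
        out[mask] = arr[src_idx[mask]]
        return out

    sample_haps: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "mother": (expand(founders.samples["mother"].hap_a),
                   expand(founders.samples["mother"].hap_b)),
        "father": (expand(founders.samples["father"].hap_a),
                   expand(founders.samples["father"].hap_b)),
    }
    site_lookup = {key: j for j, key in enumerate(all_sites)}
    for child in children:
        ha = expand(child_haps[child]["A"])
        hb = expand(child_haps[child]["B"])
        for d in planted:
            if d.child == child:
                j = site_lookup[(d.chrom, d.pos)]
                (ha if d.haplotype == "A" else hb)[j] = ALT
        sample_haps[child] = (ha, hb)

    # 4. genotype errors: flip a random haplotype allele per affected call
    error_sites: list[tuple[str, str, int]] = []
    if config.genotype_error_rate > 0:
        for sample, (ha, hb) in sample_haps.items():
            n_err = rng.binomial(n_all, config.genotype_error_rate)
            idx = rng.choice(n_all, size=n_err, replace=False)
            for j in idx:
                target = ha if rng.random() < 0.5 else hb
                target[j] = ALT if target[j] == REF else REF
                error_sites.append((sample, str(chrom_arr[j]), int(pos_arr[j])))

    # 5. allele depths: Poisson total depth, binomial alt reads for hets
    for sample, (ha, hb) in sample_haps.items():
        depth = rng.poisson(config.depth_mean, n_all)
        n_alt_alleles = (ha == ALT).astype(int) + (hb == ALT).astype(int)
        alt_reads = np.where(
            n_alt_alleles == 1, rng.binomial(depth, 0.5),
            np.where(n_alt_alleles == 2, depth, 0))
        matrix.add_sample(sample, ha, hb, phased=True,
                          ref_depth=depth - alt_reads, alt_depth=alt_reads)

    pedigree = Pedigree(
        [Individual("mother", sex="female"), Individual("father", sex="male")]
        + [Individual(c, mother_id="mother", father_id="father")
           for c in children])
    truth = TruthRecord(
        children=children, dnms=planted, gamete_maps=gamete_maps,
        conversion_tracts=conversion_tracts,
        genotype_error_sites=error_sites, layout=layout)
    return FamilySimulation(config=config, genotypes=matrix,
                            pedigree=pedigree, truth=truth)


# ---------------------------------------------------------------------------
# fast haplotype-sharing geometry (no genotypes needed)
# ---------------------------------------------------------------------------

def sibling_sharing_fractions(
    n_pairs: int,
    layout: GenomeLayout = DEFAULT_LAYOUT,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Monte-Carlo geometry of haplotype sharing between sibling pairs.

    For each simulated pair of full siblings, returns the fraction of the
    genome shared through the mother, through the father, and through both
    parents simultaneously (the double-surrogate regions). The expected
    values are 1/2, 1/2 and 1/4.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    total = layout.total_bp
    mat = np.empty(n_pairs)
    pat = np.empty(n_pairs)
    both = np.empty(n_pairs)
    for k in range(n_pairs):
        g = [sample_gamete_map(layout, rng) for _ in range(4)]
        share_m = shared_source_intervals(g[0], g[1], layout)
        share_p = shared_source_intervals(g[2], g[3], layout)
        mat[k] = sum(total_length(iv) for iv in share_m.values()) / total
        pat[k] = sum(total_length(iv) for iv in share_p.values()) / total
        both[k] = sum(
            total_length(intersect(share_m[c.name], share_p[c.name]))
            for c in layout) / total
    return {"maternal": mat, "paternal": pat, "both": both}


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkResult:
    proband: str
    n_true: int
    n_true_accessible: int
    n_tp: int
    n_fp: int
    n_fn: int
    precision: float
    recall: float
    recall_in_accessible: float
    fn_by_cause: dict[str, int]
    fp_by_cause: dict[str, int]


def benchmark(calls, truth: TruthRecord, regions,
              ibd_boundary_margin_bp: int = 50_000) -> BenchmarkResult:
    """Score a call set against simulation truth.

    False negatives are partitioned into inaccessible (outside the
    configured regions), sib-shared (also planted in a sibling — germline
    mosaicism), filtered (called but flagged), and missed. False positives
    are attributed to gene conversion tracts, genotype errors, or proximity
    to a true IBD-sharing boundary.
    """
    proband = regions.proband
    if proband not in truth.children:
        raise ValueError(
            f"regions are for {proband!r}, which is not a simulated child")
    true_sites = {(d.chrom, d.pos): d for d in truth.dnms_of(proband)}
    sib_sites = {(d.chrom, d.pos) for d in truth.dnms
                 if d.child != proband}
    pass_calls = {(c.chrom, c.pos) for c in calls if c.passed}
    all_calls = {(c.chrom, c.pos) for c in calls}

    tp = pass_calls & set(true_sites)
    fp = pass_calls - set(true_sites)
    fn = set(true_sites) - pass_calls

    fn_by_cause = {"inaccessible": 0, "sib_shared": 0, "filtered": 0, "missed": 0}
    for site in fn:
        chrom, pos = site
        if not regions.contains(chrom, pos):
            fn_by_cause["inaccessible"] += 1
        elif site in sib_sites:
            fn_by_cause["sib_shared"] += 1
        elif site in all_calls:
            fn_by_cause["filtered"] += 1
        else:
            fn_by_cause["missed"] += 1

    conv_by_chrom: dict[str, list[Interval]] = {}
    for t in truth.conversion_tracts:
        conv_by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    conv_by_chrom = {c: merge(iv) for c, iv in conv_by_chrom.items()}
    err_sites = {(c, p) for _s, c, p in truth.genotype_error_sites}
    boundary: dict[str, list[Interval]] = {}
    for child in truth.children:
        for parent in ("maternal", "paternal"):
            gm = truth.gamete_maps[child][parent]
            for chrom, bks in gm.breakpoints.items():
                for b in bks:
                    boundary.setdefault(chrom, []).append(
                        (max(0, b - ibd_boundary_margin_bp),
                         b + ibd_boundary_margin_bp))
    boundary = {c: merge(iv) for c, iv in boundary.items()}

    from ._intervals import contains as iv_contains
    fp_by_cause = {"gene_conversion": 0, "genotype_error": 0,
                   "ibd_boundary": 0, "other": 0}
    for chrom, pos in fp:
        if chrom in conv_by_chrom and iv_contains(conv_by_chrom[chrom], pos):
            fp_by_cause["gene_conversion"] += 1
        elif (chrom, pos) in err_sites:
            fp_by_cause["genotype_error"] += 1
        elif chrom in boundary and iv_contains(boundary[chrom], pos):
            fp_by_cause["ibd_boundary"] += 1
        else:
            fp_by_cause["other"] += 1

    n_true = len(true_sites)
    n_acc = sum(1 for (c, p) in true_sites if regions.contains(c, p))
    n_tp, n_fp, n_fn = len(tp), len(fp), len(fn)
    return BenchmarkResult(
        proband=proband, n_true=n_true, n_true_accessible=n_acc,
        n_tp=n_tp, n_fp=n_fp, n_fn=n_fn,
        precision=n_tp / (n_tp + n_fp) if n_tp + n_fp else float("nan"),
        recall=n_tp / n_true if n_true else float("nan"),
        recall_in_accessible=n_tp / n_acc if n_acc else float("nan"),
        fn_by_cause=fn_by_cause, fp_by_cause=fp_by_cause)
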