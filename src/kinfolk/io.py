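"""Readers and writers for the standard formats the pipeline touches.

VCF input goes through cyvcf2; everything written here is plain text (VCF
v4.2, BED3 + JSON sidecar, hap-IBD-style TSV, results TSV/JSON). VCF
positions are 1-based and converted to the internal 0-based, half-open
convention at the boundary; BED is half-open and needs no shift.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Optional

import numpy as np

from . import __version__
from .caller import DNMCall, classify_spectrum
from .genome import Chromosome, GenomeLayout
from .genotypes import ALT, MISSING, REF, PhasedGenotypeMatrix
from .ibd import AccessibleRegionSet, IBDSegment, SurrogateConfiguration

logger = logging.getLogger(__name__)

_GT_CODE = {REF: "0", ALT: "1", MISSING: "."}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> PhasedGenotypeMatrix:
    """Load biallelic SNVs from a VCF into a genotype matrix.

    Multiallelic records and indels are skipped (and counted); the INFO
    ``AF`` field, when present, populates the panel alt frequency used by
    the IBD marker filter and the panel filter.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has no samples")

    chroms, poss, refs, alts, freqs = [], [], [], [], []
    haps_a: dict[str, list[int]] = {s: [] for s in samples}
    haps_b: dict[str, list[int]] = {s: [] for s in samples}
    ref_d: dict[str, list[int]] = {s: [] for s in samples}
    alt_d: dict[str, list[int]] = {s: [] for s in samples}
    unphased: set[str] = set()
    any_ad = False
    n_skipped = 0

    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)          # VCF is 1-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        af = v.INFO.get("AF")
        freqs.append(float(af) if af is not None else np.nan)
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            any_ad = True
        for k, s in enumerate(samples):
            g = v.genotypes[k]          # [allele0, allele1, phased]
            a0 = g[0] if g[0] in (0, 1) else MISSING
            a1 = g[1] if g[1] in (0, 1) else MISSING
            haps_a[s].append(a0)
            haps_b[s].append(a1)
            if not g[2] and a0 != a1:
                unphased.add(s)
            if ad is not None and ad[k][0] >= 0:
                ref_d[s].append(int(ad[k][0]))
                alt_d[s].append(int(ad[k][1]))
            else:
                ref_d[s].append(0)
                alt_d[s].append(0)

    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV records", n_skipped)
    if not poss:
        raise ValueError("no biallelic SNV records in VCF")
    m = PhasedGenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        panel_alt_freq=np.array(freqs, dtype=float))
    for s in samples:
        m.add_sample(
            s, haps_a[s], haps_b[s], phased=s not in unphased,
            ref_depth=ref_d[s] if any_ad else None,
            alt_depth=alt_d[s] if any_ad else None)
    return m


def write_vcf(matrix: PhasedGenotypeMatrix, path: str,
              layout: Optional[GenomeLayout] = None) -> None:
    """Emit a phased VCF v4.2 with GT:AD and INFO AF."""
    samples = matrix.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel alt allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        if layout is not None:
            for c in layout:
                fh.write(f"##contig=<ID={c.name},length={c.length_bp}>\n")
        else:
            for c in matrix.chromosomes:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i in range(matrix.n_sites):
            f = matrix.panel_alt_freq[i]
            info = f"AF={f:.6g}" if f == f else "."
            fields = [
                str(matrix.chrom[i]), str(int(matrix.pos[i]) + 1), ".",
                str(matrix.ref[i]), str(matrix.alt[i]), ".", ".", info, "GT:AD",
            ]
            for s in samples:
                smp = matrix.samples[s]
                sep = "|" if smp.phased else "/"
                gt = _GT_CODE[int(smp.hap_a[i])] + sep + _GT_CODE[int(smp.hap_b[i])]
                if smp.ref_depth is not None:
                    ad = f"{int(smp.ref_depth[i])},{int(smp.alt_depth[i])}"
                else:
                    ad = ".,."
                fields.append(f"{gt}:{ad}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# IBD TSV (hap-IBD style)
# ---------------------------------------------------------------------------

_HAP_CODE = {"A": "1", "B": "2"}
_HAP_DECODE = {"1": "A", "2": "B"}

IBD_TSV_HEADER = "id1\thap1\tid2\thap2\tchrom\tstart\tend\tn_markers\torigin"


def write_ibd_tsv(segments: Iterable[IBDSegment], path: str) -> None:
    """hap-IBD-style TSV; start is written 1-based inclusive, matching the
    convention of hap-IBD output, and the last column carries the marker
    count plus an origin label."""
    with open(path, "w") as fh:
        fh.write(IBD_TSV_HEADER + "\n")
        for s in segments:
            fh.write("\t".join([
                s.individual_a, _HAP_CODE[s.hap_a],
                s.individual_b, _HAP_CODE[s.hap_b],
                s.chrom, str(s.start + 1), str(s.end),
                str(s.n_markers), s.origin]) + "\n")


def read_ibd_tsv(path: str) -> list[IBDSegment]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("id1", "#")):
                continue
            f = line.split("\t")
            origin = f[8] if len(f) > 8 else "unknown"
            out.append(IBDSegment(
                individual_a=f[0], hap_a=_HAP_DECODE[f[1]],
                individual_b=f[2], hap_b=_HAP_DECODE[f[3]],
                chrom=f[4], start=int(f[5]) - 1, end=int(f[6]),
                n_markers=int(f[7]), origin=origin))
    return out


# ---------------------------------------------------------------------------
# accessible regions: BED3 + JSON sidecar
# ---------------------------------------------------------------------------

def write_regions(regions: AccessibleRegionSet, prefix: str) -> tuple[str, str]:
    bed_path = prefix + ".bed"
    json_path = prefix + ".json"
    with open(bed_path, "w") as fh:
        for chrom in regions.regions:
            for start, end in regions.regions[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")
    cfg = regions.configuration
    with open(json_path, "w") as fh:
        json.dump({
            "proband": regions.proband,
            "configuration": {
                "real_parents": sorted(cfg.real_parents),
                "surrogate_mothers": sorted(cfg.surrogate_mothers),
                "surrogate_fathers": sorted(cfg.surrogate_fathers),
                "double_surrogates": sorted(cfg.double_surrogates),
            },
            "genome_bp": regions.genome_bp,
            "total_bp": regions.total_bp,
            "callable_fraction": regions.callable_fraction,
        }, fh, indent=2)
    return bed_path, json_path


def read_regions(prefix: str) -> AccessibleRegionSet:
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    regions: dict[str, list[tuple[int, int]]] = {}
    with open(prefix + ".bed") as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end = line.split()[:3]
            regions.setdefault(chrom, []).append((int(start), int(end)))
    cfg = meta["configuration"]
    return AccessibleRegionSet(
        proband=meta["proband"],
        configuration=SurrogateConfiguration(
            real_parents=frozenset(cfg["real_parents"]),
            surrogate_mothers=frozenset(cfg["surrogate_mothers"]),
            surrogate_fathers=frozenset(cfg["surrogate_fathers"]),
            double_surrogates=frozenset(cfg["double_surrogates"])),
        regions=regions, genome_bp=meta["genome_bp"])


# ---------------------------------------------------------------------------
# DNM calls
# ---------------------------------------------------------------------------

CALLS_TSV_HEADER = ("proband\tchrom\tpos\tref\talt\tvaf\tdepth\t"
                    "spectrum_class\talt_haplotype\tphase\tfilters")


def write_calls_tsv(calls: Iterable[DNMCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(CALLS_TSV_HEADER + "\n")
        for c in calls:
            fh.write("\t".join([
                c.proband, c.chrom, str(c.pos), c.ref_allele, c.alt_allele,
                "NA" if c.vaf != c.vaf else f"{c.vaf:.6g}",
                str(c.depth), c.spectrum_class,
                c.alt_haplotype or "NA", c.phase,
                ",".join(sorted(c.filters)) or "PASS"]) + "\n")


def read_calls_tsv(path: str) -> list[DNMCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("proband\t"):
                continue
            f = line.split("\t")
            out.append(DNMCall(
                proband=f[0], chrom=f[1], pos=int(f[2]),
                ref_allele=f[3], alt_allele=f[4],
                vaf=float("nan") if f[5] == "NA" else float(f[5]),
                depth=int(f[6]), spectrum_class=f[7],
                alt_haplotype=None if f[8] == "NA" else f[8],
                phase=f[9],
                filters=frozenset() if f[10] == "PASS"
                else frozenset(f[10].split(","))))
    return out


def write_calls_vcf(calls: Iterable[DNMCall], path: str) -> None:
    """DNM calls as a minimal VCF with filter/phase/class in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PROBAND,Number=1,Type=String,Description="Sample carrying the DNM">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="1-mer spectrum class">\n')
        fh.write('##INFO=<ID=PHASE,Number=1,Type=String,Description="Parent of origin">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            filt = ";".join(sorted(c.filters)) if c.filters else "PASS"
            vaf = f";VAF={c.vaf:.6g}" if c.vaf == c.vaf else ""
            fh.write("\t".join([
                c.chrom, str(c.pos + 1), ".", c.ref_allele, c.alt_allele,
                ".", filt,
                f"PROBAND={c.proband};CLASS={c.spectrum_class};"
                f"PHASE={c.phase}{vaf}"]) + "\n")


# ---------------------------------------------------------------------------
# burden results
# ---------------------------------------------------------------------------

def write_burden_results(results, path_prefix: str) -> None:
    """Burden test results as TSV plus JSON."""
    rows = []
    for r in results:
        for key in r.observed:
            rows.append({
                "unit": r.unit, "type": key,
                "observed": r.observed[key],
                "expected": r.expected[key],
                "p_upper": r.p_values[key],
                "enrichment": r.enrichment[key],
                "significant": r.significant(key),
            })
    with open(path_prefix + ".tsv", "w") as fh:
        cols = ["unit", "type", "observed", "expected", "p_upper",
                "enrichment", "significant"]
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    with open(path_prefix + ".json", "w") as fh:
        json.dump(rows, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# genome layout TSV
# ---------------------------------------------------------------------------

def read_layout_tsv(path: str) -> GenomeLayout:
    """Layout TSV: columns name, length_bp, optional cm_per_mb."""
    chroms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "name\t")):
                continue
            f = line.split("\t")
            chroms.append(Chromosome(
                f[0], int(f[1]), float(f[2]) if len(f) > 2 else 1.0))
    return GenomeLayout(tuple(chroms))


def write_layout_tsv(layout: GenomeLayout, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tlength_bp\tcm_per_mb\n")
        for c in layout:
            fh.write(f"{c.name}\t{c.length_bp}\t{c.cm_per_mb}\n")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    command: str
    seed: Optional[int]
    config_hash: str
    input_digests: dict[str, str]
    package_version: str
    timestamp: str


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str, command: str, seed: Optional[int] = None,
                   config: Optional[dict] = None,
                   inputs: Iterable[str] = ()) -> RunManifest:
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = RunManifest(
        command=command, seed=seed,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        input_digests={p: _sha256(p) for p in inputs},
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat())
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    return manifest
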