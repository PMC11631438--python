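"""In-memory container for phased diploid genotypes over biallelic SNVs.

Sites are held as parallel numpy arrays sorted by (chromosome, position);
each individual contributes two haplotype allele vectors (0 = ref, 1 = alt,
-1 = missing) plus optional per-site allele depths. Haplotype "A" is the
first written allele of the genotype; in simulated data the convention is
hapA = maternally inherited, hapB = paternally inherited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

REF, ALT, MISSING = 0, 1, -1


@dataclass
class SampleGenotypes:
    hap_a: np.ndarray              # int8, one entry per site
    hap_b: np.ndarray
    phased: bool = True
    ref_depth: Optional[np.ndarray] = None
    alt_depth: Optional[np.ndarray] = None

    def genotype(self, i: int) -> tuple[int, int]:
        return int(self.hap_a[i]), int(self.hap_b[i])

    def is_het(self, i: int) -> bool:
        a, b = self.genotype(i)
        return {a, b} == {REF, ALT}

    def is_hom_ref(self, i: int) -> bool:
        return self.genotype(i) == (REF, REF)

    def is_missing(self, i: int) -> bool:
        a, b = self.genotype(i)
        return a == MISSING or b == MISSING


class PhasedGenotypeMatrix:
    """Genotypes for a set of individuals over a shared, ordered site list."""

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        panel_alt_freq: Optional[np.ndarray] = None,
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        n = len(self.pos)
        if panel_alt_freq is None:
            panel_alt_freq = np.full(n, np.nan)
        self.panel_alt_freq = np.asarray(panel_alt_freq, dtype=float)
        self.samples: dict[str, SampleGenotypes] = {}
        self._validate_order()
        self._chrom_slices = self._build_slices()

    def _validate_order(self) -> None:
        seen: dict[str, int] = {}
        order: list[str] = []
        for c in self.chrom:
            if c not in seen:
                seen[c] = len(order)
                order.append(c)
        # positions strictly increasing within each chromosome block
        for c in order:
            mask = self.chrom == c
            p = self.pos[mask]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"site positions not strictly increasing on {c}")
        # chromosome blocks must be contiguous
        boundaries = np.flatnonzero(self.chrom[1:] != self.chrom[:-1])
        if len(boundaries) != len(order) - 1:
            raise ValueError("chromosome blocks are interleaved")

    def _build_slices(self) -> dict[str, slice]:
        slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                slices[self.chrom[start]] = slice(start, i)
                start = i
        return slices

    # -- construction ------------------------------------------------------
    def add_sample(self, sample_id: str, hap_a, hap_b, phased: bool = True,
                   ref_depth=None, alt_depth=None) -> None:
        if sample_id in self.samples:
            raise ValueError(f"duplicate sample {sample_id!r}")
        hap_a = np.asarray(hap_a, dtype=np.int8)
        hap_b = np.asarray(hap_b, dtype=np.int8)
        if len(hap_a) != self.n_sites or len(hap_b) != self.n_sites:
            raise ValueError("haplotype length does not match site count")
        self.samples[sample_id] = SampleGenotypes(
            hap_a, hap_b, phased,
            None if ref_depth is None else np.asarray(ref_depth, dtype=np.int32),
            None if alt_depth is None else np.asarray(alt_depth, dtype=np.int32),
        )

    # -- access ------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def site_index(self, chrom: str, pos: int) -> int:
        sl = self._chrom_slices[chrom]
        p = self.pos[sl]
        i = int(np.searchsorted(p, pos))
        if i >= len(p) or p[i] != pos:
            raise KeyError(f"no site at {chrom}:{pos}")
        return sl.start + i

    def vaf(self, sample_id: str, i: int) -> float:
        s = self.samples[sample_id]
        if s.ref_depth is None or s.alt_depth is None:
            return float("nan")
        depth = int(s.ref_depth[i]) + int(s.alt_depth[i])
        return float(s.alt_depth[i]) / depth if depth > 0 else float("nan")

    def depth(self, sample_id: str, i: int) -> int:
        s = self.samples[sample_id]
        if s.ref_depth is None or s.alt_depth is None:
            return 0
        return int(s.ref_depth[i]) + int(s.alt_depth[i])

    def minor_allele_freq(self) -> np.ndarray:
        f = self.panel_alt_freq
        return np.where(np.isnan(f), np.nan, np.minimum(f, 1.0 - f))

    def carriers(self, i: int) -> set[str]:
        """Samples carrying at least one alt allele at site ``i``."""
        out = set()
        for sid, s in self.samples.items():
            if ALT in s.genotype(i):
                out.add(sid)
        return out
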