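"""Autosomal genome layouts with uniform recombination maps."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Chromosome:
    """One autosome with a constant recombination rate.

    ``cm_per_mb`` is the genetic map density in centimorgans per megabase;
    the human genome-wide average is about 1 cM/Mb.
    """

    name: str
    length_bp: int
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length must be positive")
        if self.cm_per_mb < 0:
            raise ValueError(f"chromosome {self.name}: negative map density")

    @property
    def genetic_length_morgans(self) -> float:
        return self.cm_per_mb * (self.length_bp / 1e6) / 100.0


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered collection of autosomes."""

    chromosomes: tuple[Chromosome, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def uniform(cls, n_chromosomes: int = 2, length_bp: int = 100_000_000,
                cm_per_mb: float = 1.0) -> "GenomeLayout":
        """Simple layout of equal-length autosomes, e.g. 2 x 100 Mb at 1 cM/Mb."""
        return cls(tuple(
            Chromosome(f"chr{i + 1}", length_bp, cm_per_mb)
            for i in range(n_chromosomes)
        ))


DEFAULT_LAYOUT = GenomeLayout.uniform()
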