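import numpy as np
import pytest

import kinfolk as kf
from kinfolk.genome import GenomeLayout


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    """Two 50 Mb chromosomes at 1 cM/Mb: seconds-scale but with ~1
    crossover per meiosis overall."""
    return GenomeLayout.uniform(2, 50_000_000)


@pytest.fixture(scope="session")
def clean_family(small_layout):
    """A 3-child family with no genotype error; session-scoped because the
    simulation is deterministic and read-only."""
    config = kf.SimulationConfig(layout=small_layout, n_children=3, seed=42)
    return kf.simulate_family(config)


@pytest.fixture(scope="session")
def clean_family_segments(clean_family):
    """Origin-labeled inferred IBD segments for all sibling pairs."""
    sim = clean_family
    params = kf.IBDParams()
    segs = []
    kids = sim.truth.children
    for i, a in enumerate(kids):
        for b in kids[i + 1:]:
            s = kf.infer_sibling_ibd(sim.genotypes, (a, b), params)
            segs.extend(kf.classify_parental_origin(
                s, sim.genotypes, "mother", params))
    return segs


def make_matrix(pos, haps, chrom="chr1", freq=0.5, ref="C", alt="A",
                depths=None):
    """Tiny hand-built genotype matrix. ``haps`` maps sample -> (hapA, hapB)
    allele lists."""
    n = len(pos)
    m = kf.PhasedGenotypeMatrix(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array([ref] * n, dtype=object),
        alt=np.array([alt] * n, dtype=object),
        panel_alt_freq=np.full(n, freq, dtype=float))
    for sid, (a, b) in haps.items():
        kwargs = {}
        if depths and sid in depths:
            kwargs = {"ref_depth": depths[sid][0], "alt_depth": depths[sid][1]}
        m.add_sample(sid, a, b, phased=True, **kwargs)
    return m
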