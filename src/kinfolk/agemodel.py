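"""Parental-age mutation model, Poisson burden tests, and effect sizes.

Expected de novo mutation counts of each 1-mer type c are linear in
parental age at conception:

    y_c,mat(a_mat) = m_c,mat * a_mat + b_c,mat
    y_c,pat(a_pat) = m_c,pat * a_pat + b_c,pat

and the maternal + paternal expectations add up to the expected burden in
the child. Observed burdens are compared to expectation with exact
one-tailed Poisson tests (P(X >= observed)); enrichments, carrier-parent
fold elevations, and minimum detectable effects follow from the same
Poisson machinery.

Coefficient tables are an input, not a constant: slopes/intercepts come
from an external regression fit on large control trio cohorts and are
loaded from TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .caller import MUTATION_TYPES

logger = logging.getLogger(__name__)

TOTAL = "total"


@dataclass(frozen=True)
class TypeCoefficients:
    m_mat: float   # mutations / year, maternal slope
    b_mat: float   # mutations, maternal intercept
    m_pat: float
    b_pat: float


@dataclass(frozen=True)
class AgeModelCoefficients:
    """Per-type maternal/paternal linear model coefficients."""

    per_type: Mapping[str, TypeCoefficients]
    reference_genome_bp: int

    def __post_init__(self) -> None:
        missing = set(MUTATION_TYPES) - set(self.per_type)
        if missing:
            raise ValueError(f"missing mutation types: {sorted(missing)}")
        extra = set(self.per_type) - set(MUTATION_TYPES)
        if extra:
            raise ValueError(f"unknown mutation types: {sorted(extra)}")
        if self.reference_genome_bp <= 0:
            raise ValueError("reference_genome_bp must be positive")

    # -- TSV schema: columns type, m_mat, b_mat, m_pat, b_pat; a header
    # comment line carries the reference genome size the fit was made on.
    @classmethod
    def from_tsv(cls, path) -> "AgeModelCoefficients":
        ref_bp = None
        with open(path) as fh:
            header_lines = []
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    if key.strip() == "reference_genome_bp":
                        ref_bp = int(float(val))
                else:
                    header_lines.append(line)
        if ref_bp is None:
            raise ValueError("coefficient TSV lacks '#reference_genome_bp=' header")
        df = pd.read_csv(path, sep="\t", comment="#",
                         float_precision="round_trip")
        per_type = {
            row["type"]: TypeCoefficients(
                float(row["m_mat"]), float(row["b_mat"]),
                float(row["m_pat"]), float(row["b_pat"]))
            for _, row in df.iterrows()
        }
        return cls(per_type=per_type, reference_genome_bp=ref_bp)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#reference_genome_bp={self.reference_genome_bp}\n")
            fh.write("type\tm_mat\tb_mat\tm_pat\tb_pat\n")
            for t in MUTATION_TYPES:
                c = self.per_type[t]
                fh.write(f"{t}\t{c.m_mat!r}\t{c.b_mat!r}\t{c.m_pat!r}\t{c.b_pat!r}\n")


@dataclass(frozen=True)
class BurdenExpectation:
    child: str
    a_mat: float
    a_pat: float
    accessibility_scale: float
    expected_mat: Mapping[str, float]
    expected_pat: Mapping[str, float]

    @property
    def expected_total(self) -> dict[str, float]:
        return {t: self.expected_mat[t] + self.expected_pat[t]
                for t in MUTATION_TYPES}

    @property
    def grand_total(self) -> float:
        return sum(self.expected_total.values())


@dataclass(frozen=True)
class BurdenTestResult:
    unit: str
    observed: Mapping[str, int]      # per type plus "total"
    expected: Mapping[str, float]
    p_values: Mapping[str, float]
    enrichment: Mapping[str, float]
    alpha: float = 0.05

    def significant(self, key: str) -> bool:
        return self.p_values[key] < self.alpha


def expected_counts(
    coeffs: AgeModelCoefficients,
    a_mat: float,
    a_pat: float,
    accessibility_scale: float = 1.0,
    child: str = "child",
) -> BurdenExpectation:
    """Per-type expected maternal/paternal mutation counts for one child.

    ``accessibility_scale`` multiplies every expectation, correcting for
    the fraction of the genome accessible to calling relative to the
    genome the coefficients were fit on (accessible_bp / reference_bp).
    """
    if a_mat <= 0 or a_pat <= 0:
        raise ValueError("parental ages must be positive")
    if not (0 < accessibility_scale <= 1):
        raise ValueError("accessibility_scale must be in (0, 1]")
    exp_mat: dict[str, float] = {}
    exp_pat: dict[str, float] = {}
    for t in MUTATION_TYPES:
        c = coeffs.per_type[t]
        m = accessibility_scale * (c.m_mat * a_mat + c.b_mat)
        p = accessibility_scale * (c.m_pat * a_pat + c.b_pat)
        if m < 0 or p < 0:
            logger.warning("negative expectation for %s floored at 0", t)
        exp_mat[t] = max(m, 0.0)
        exp_pat[t] = max(p, 0.0)
    return BurdenExpectation(
        child=child, a_mat=a_mat, a_pat=a_pat,
        accessibility_scale=accessibility_scale,
        expected_mat=exp_mat, expected_pat=exp_pat)


def combine_expectations(expectations: Iterable[BurdenExpectation],
                         unit: str = "family") -> BurdenExpectation:
    """Sum per-child expectations for family- or group-level testing.

    Each child is accessibility-scaled individually before summing.
    """
    expectations = list(expectations)
    if not expectations:
        raise ValueError("no expectations to combine")
    mat = {t: sum(e.expected_mat[t] for e in expectations)
           for t in MUTATION_TYPES}
    pat = {t: sum(e.expected_pat[t] for e in expectations)
           for t in MUTATION_TYPES}
    return BurdenExpectation(
        child=unit, a_mat=float("nan"), a_pat=float("nan"),
        accessibility_scale=float("nan"), expected_mat=mat, expected_pat=pat)


def poisson_upper_tail(observed: int, expected: float) -> float:
    """Exact upper-tail Poisson probability P(X >= observed | lambda).

    Computed from the regularized upper incomplete gamma function, which
    equals the exact tail sum; no normal approximation is involved.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


def burden_test(
    observed: Mapping[str, int],
    expectation: BurdenExpectation,
    unit: str = "child",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> BurdenTestResult:
    """One-tailed Poisson burden test per mutation type and in total.

    ``observed`` maps each 1-mer type to its passing call count. No
    multiple-testing correction is applied by default; ``bonferroni``
    tightens alpha by the number of types tested.
    """
    obs = {t: int(observed.get(t, 0)) for t in MUTATION_TYPES}
    exp = dict(expectation.expected_total)
    obs[TOTAL] = sum(obs[t] for t in MUTATION_TYPES)
    exp[TOTAL] = sum(exp[t] for t in MUTATION_TYPES)

    pvals = {}
    enrich = {}
    for key, e in exp.items():
        o = obs[key]
        pvals[key] = poisson_upper_tail(o, e) if e > 0 else 1.0
        enrich[key] = o / e if e > 0 else float("inf") if o else float("nan")
    eff_alpha = alpha / len(MUTATION_TYPES) if bonferroni else alpha
    return BurdenTestResult(unit=unit, observed=obs, expected=exp,
                            p_values=pvals, enrichment=enrich, alpha=eff_alpha)


def detection_threshold(expected: float, alpha: float = 0.05) -> tuple[int, float]:
    """Smallest observed count that is significant, and the implied excess.

    Returns (critical_count, critical_count - expected) where
    critical_count is the minimum integer c with P(X >= c) < alpha.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    # P(X >= c) = sf(c - 1); find the smallest significant c.
    c = int(stats.poisson.isf(alpha, expected))  # near the answer
    c = max(c - 2, 1)
    while poisson_upper_tail(c, expected) >= alpha:
        c += 1
    return c, c - expected


def parental_fold_elevation(
    observed_total: int,
    expected_mat: float,
    expected_pat: float,
    carrier: str,
) -> float:
    """Fold elevation of the carrier parent's rate implied by an excess.

    The total excess over the parental-age expectation is attributed
    entirely to the carrier parent's germline: fold =
    (expected_carrier + excess) / expected_carrier. A deficit yields a
    fold below 1, reported as-is with a warning.
    """
    if carrier not in ("mother", "father"):
        raise ValueError("carrier must be 'mother' or 'father'")
    expected_carrier = expected_mat if carrier == "mother" else expected_pat
    if expected_carrier <= 0:
        raise ValueError("carrier parent expectation must be positive")
    excess = observed_total - (expected_mat + expected_pat)
    fold = (expected_carrier + excess) / expected_carrier
    if fold < 1.0:
        logger.warning("negative excess: implied fold %.3f < 1", fold)
    return fold


def min_detectable_fold(
    expectation: BurdenExpectation,
    carrier: str,
    mutation_type: str = "C>A",
    alpha: float = 0.05,
) -> float:
    """Smallest carrier-parent fold elevation with power to detect.

    The detection threshold on the unit's total expectation for
    ``mutation_type`` gives the minimum significant count; attributing that
    count's excess to the carrier parent gives the minimum fold.
    """
    e_mat = expectation.expected_mat[mutation_type]
    e_pat = expectation.expected_pat[mutation_type]
    critical, _ = detection_threshold(e_mat + e_pat, alpha)
    return parental_fold_elevation(critical, e_mat, e_pat, carrier)


# ---------------------------------------------------------------------------
# BXD recombinant-inbred mouse regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BXDStrainRecord:
    """Per-strain inbreeding summary for the BXD mouse panel.

    Each strain is fixed B or D at the Mutyh locus; generation time is
    years of inbreeding per generation, and the C>A rate is per site per
    generation over the accessible genome.
    """

    strain: str
    mutyh_genotype: str            # "B" or "D"
    n_generations: int
    n_years: float
    ca_count: int
    accessible_bp: int

    def __post_init__(self) -> None:
        if self.mutyh_genotype not in ("B", "D"):
            raise ValueError("mutyh_genotype must be 'B' or 'D'")
        if self.n_generations <= 0 or self.n_years <= 0:
            raise ValueError("inbreeding history must be positive")

    @property
    def generation_time(self) -> float:
        return self.n_years / self.n_generations

    @property
    def ca_rate(self) -> float:
        return self.ca_count / self.n_generations / self.accessible_bp


@dataclass(frozen=True)
class BXDRegressionResult:
    slope: float                   # C>A rate per site per year
    intercept_B: float             # rate per site per generation at min age
    intercept_D: float
    p_slope: float
    p_genotype: float
    p_interaction: float
    min_generation_time: float
    n_strains: int


def bxd_regression(
    records: Iterable[BXDStrainRecord],
    min_generation_time: Optional[float] = None,
) -> BXDRegressionResult:
    """OLS of per-generation C>A rate on generation time and Mutyh genotype.

    The age covariate is centered at the minimum observed generation time,
    so intercepts are the B- and D-strain rates at that age. A separate fit
    with a genotype x age interaction tests whether the two genotypes
    accumulate age-dependent mutations at different rates.
    """
    import statsmodels.api as sm

    records = list(records)
    for g in ("B", "D"):
        if sum(r.mutyh_genotype == g for r in records) < 3:
            raise ValueError(f"need >= 3 strains of genotype {g}")
    gt = np.array([r.generation_time for r in records])
    if min_generation_time is None:
        min_generation_time = float(gt.min())
    x_age = gt - min_generation_time
    x_d = np.array([1.0 if r.mutyh_genotype == "D" else 0.0 for r in records])
    y = np.array([r.ca_rate for r in records])

    X = sm.add_constant(np.column_stack([x_age, x_d]))
    fit = sm.OLS(y, X).fit()
    Xi = sm.add_constant(np.column_stack([x_age, x_d, x_age * x_d]))
    fit_i = sm.OLS(y, Xi).fit()

    return BXDRegressionResult(
        slope=float(fit.params[1]),
        intercept_B=float(fit.params[0]),
        intercept_D=float(fit.params[0] + fit.params[2]),
        p_slope=float(fit.pvalues[1]),
        p_genotype=float(fit.pvalues[2]),
        p_interaction=float(fit_i.pvalues[3]),
        min_generation_time=min_generation_time,
        n_strains=len(records),
    )


def load_bxd_csv(path) -> list[BXDStrainRecord]:
    """Read a BXD strain summary CSV with columns strain, genotype,
    n_generations, n_years, ca_count, accessible_bp."""
    df = pd.read_csv(path)
    return [
        BXDStrainRecord(
            strain=str(row["strain"]),
            mutyh_genotype=str(row["genotype"]),
            n_generations=int(row["n_generations"]),
            n_years=float(row["n_years"]),
            ca_count=int(row["ca_count"]),
            accessible_bp=int(row["accessible_bp"]),
        )
        for _, row in df.iterrows()
    ]


def function_score(
    repair_pos_fraction_variant: float,
    repair_pos_fraction_wt: float,
    pseudocount: float = 1e-3,
) -> float:
    """log2 repair-function score of a variant relative to wild type.

    0 means wild-type-like repair; negative means deficient. A zero
    variant fraction receives a small pseudocount so the score stays
    finite.
    """
    if repair_pos_fraction_wt <= 0:
        raise ValueError("wild-type repair fraction must be positive")
    v = repair_pos_fraction_variant
    if v < 0:
        raise ValueError("repair fraction cannot be negative")
    if v == 0:
        v = pseudocount
    return math.log2(v / repair_pos_fraction_wt)
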