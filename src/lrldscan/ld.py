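"""Two-locus linkage disequilibrium estimation and testing.

For a pair of biallelic loci with designated major alleles A and B, the sample
haplotype frequency ``p_AB`` together with the marginal frequencies gives

    D = p_AB - p_A * p_B
    X^2 = 2n * D^2 / (p_A (1 - p_A) p_B (1 - p_B))

where ``n`` is the number of diploid individuals (``2n`` haplotypes).  ``X^2`` is
referred to a 1-df chi-square distribution; the exact alternative is the
one-tailed Fisher test on the 2x2 haplotype count table, taken in the direction
of the observed D.  D' rescales D by its maximum attainable magnitude given the
allele frequencies.  When A and B are the major alleles, ``p_AB`` is confined to
``[1 - p_a - p_b, 1 - max(p_a, p_b)]`` with ``p_a, p_b`` the minor allele
frequencies, and the equilibrium point ``(1 - p_a)(1 - p_b)`` sits asymmetrically
inside that interval — the reason small samples produce spurious long-range LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import HaplotypePanel

__all__ = [
    "TwoLocusHaplotypeTable",
    "LDEstimate",
    "PabBounds",
    "build_two_locus_table",
    "estimate_ld",
    "fisher_exact_test",
    "pab_bounds",
]


@dataclass(frozen=True)
class TwoLocusHaplotypeTable:
    """2x2 haplotype counts for a variant pair.

    A/B denote the designated major allele at each locus, a/b the alternates.
    ``n`` is the number of diploid individuals, so counts sum to ``2n``.
    """

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int
    n: int

    def __post_init__(self) -> None:
        counts = (self.n_AB, self.n_Ab, self.n_aB, self.n_ab)
        if any(c < 0 for c in counts):
            raise ValueError("haplotype counts must be non-negative")
        if sum(counts) != 2 * self.n:
            raise ValueError(
                f"haplotype counts sum to {sum(counts)}, expected 2n = {2 * self.n}"
            )

    @property
    def total(self) -> int:
        return 2 * self.n

    @property
    def p_AB(self) -> float:
        return self.n_AB / self.total

    @property
    def p_A(self) -> float:
        return (self.n_AB + self.n_Ab) / self.total

    @property
    def p_B(self) -> float:
        return (self.n_AB + self.n_aB) / self.total

    @property
    def d_hat(self) -> float:
        return self.p_AB - self.p_A * self.p_B

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_AB, self.n_Ab], [self.n_aB, self.n_ab]])


@dataclass(frozen=True)
class LDEstimate:
    """Point estimates and test results for one variant pair."""

    d_hat: float
    dprime: float
    r2: float
    chi2: float
    p_chi2: float
    p_fisher: float


@dataclass(frozen=True)
class PabBounds:
    """Admissible range of the major-major haplotype frequency."""

    p_a: float
    p_b: float
    lower: float
    upper: float
    equilibrium: float


def pab_bounds(p_a: float, p_b: float) -> PabBounds:
    """Bounds of the major-major haplotype frequency from minor allele frequencies.

    ``p_AB`` lies in ``[1 - p_a - p_b, 1 - max(p_a, p_b)]`` and equals
    ``(1 - p_a)(1 - p_b)`` at linkage equilibrium.
    """
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not 0.0 < p <= 0.5:
            raise ValueError(f"{name}={p} is not a minor allele frequency in (0, 0.5]")
    return PabBounds(
        p_a=p_a,
        p_b=p_b,
        lower=1.0 - p_a - p_b,
        upper=1.0 - max(p_a, p_b),
        equilibrium=(1.0 - p_a) * (1.0 - p_b),
    )


def major_coded(column: np.ndarray) -> np.ndarray:
    """Recode a 0/1 haplotype column as the indicator of its major allele.

    The higher-frequency allele is designated major; an exact tie is broken
    toward the reference side (the 0-coded allele).
    """
    column = np.asarray(column)
    freq1 = column.mean()
    return column if freq1 > 0.5 else 1 - column


def build_two_locus_table(
    panel: HaplotypePanel, variant_i: int, variant_j: int
) -> TwoLocusHaplotypeTable:
    """Tally major-allele haplotype counts for two variant columns of a panel.

    ``variant_i``/``variant_j`` are column indices into ``panel``.  The higher
    frequency allele at each site is designated A (resp. B); ties break toward
    the reference allele.
    """
    a = major_coded(panel.haplotypes[:, variant_i])
    b = major_coded(panel.haplotypes[:, variant_j])
    n_AB = int(np.sum((a == 1) & (b == 1)))
    n_Ab = int(np.sum((a == 1) & (b == 0)))
    n_aB = int(np.sum((a == 0) & (b == 1)))
    n_ab = int(np.sum((a == 0) & (b == 0)))
    return TwoLocusHaplotypeTable(n_AB, n_Ab, n_aB, n_ab, panel.n_samples)


def dprime_from_freqs(d: float, p_A: float, p_B: float) -> float:
    """D' = D / D_max with the sign-dependent normalizer; 0 when D == 0."""
    if d > 0:
        d_max = min(p_A * (1.0 - p_B), (1.0 - p_A) * p_B)
    elif d < 0:
        d_max = min(p_A * p_B, (1.0 - p_A) * (1.0 - p_B))
    else:
        return 0.0
    return d / d_max


def estimate_ld(table: TwoLocusHaplotypeTable) -> LDEstimate:
    """Chi-square LD test, Fisher exact p, D-hat, D' and r2 for one table.

    Both margins must be polymorphic; monomorphic loci are a caller error
    (the scan filters them out before testing).
    """
    p_A, p_B = table.p_A, table.p_B
    if not (0.0 < p_A < 1.0) or not (0.0 < p_B < 1.0):
        raise ValueError(
            f"monomorphic margin (p_A={p_A}, p_B={p_B}); filter monomorphic loci first"
        )
    d = table.d_hat
    denom = p_A * (1.0 - p_A) * p_B * (1.0 - p_B)
    r2 = d * d / denom
    chi2 = table.total * r2  # 2n * r^2, exactly
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    return LDEstimate(
        d_hat=d,
        dprime=dprime_from_freqs(d, p_A, p_B),
        r2=r2,
        chi2=chi2,
        p_chi2=p_chi2,
        p_fisher=fisher_exact_test(table),
    )


def fisher_exact_test(table: TwoLocusHaplotypeTable, tail: str = "auto") -> float:
    """One-tailed Fisher exact p-value on the haplotype count table.

    ``tail='auto'`` takes the tail in the direction of the observed D-hat
    (``'greater'`` on a tie), i.e. the probability of tables at least as extreme
    toward the observed sign of disequilibrium with margins fixed.
    """
    if tail == "auto":
        # integer sign of D (n_AB * 2n - nA * nB) avoids float ties
        d_sign = table.n_AB * table.total - (table.n_AB + table.n_Ab) * (
            table.n_AB + table.n_aB
        )
        tail = "greater" if d_sign >= 0 else "less"
    if tail not in ("greater", "less"):
        raise ValueError(f"tail must be 'auto', 'greater' or 'less', got {tail!r}")
    _, p = stats.fisher_exact(table.as_array(), alternative=tail)
    return float(p)


# ---------------------------------------------------------------------------
# Vectorized helpers shared by the sampling simulator and the genome scan.
# Inputs are arrays of haplotype counts (n_AB, n_Ab, n_aB, n_ab) per pair.
# ---------------------------------------------------------------------------

def chi2_from_counts(n_AB, n_Ab, n_aB, n_ab):
    """Vectorized X^2 and upper-tail p for arrays of 2x2 haplotype counts.

    Pairs with a monomorphic margin get X^2 = 0, p = 1.
    """
    n_AB = np.asarray(n_AB, dtype=np.float64)
    total = n_AB + n_Ab + n_aB + n_ab
    nA = n_AB + n_Ab
    nB = n_AB + n_aB
    poly = (nA > 0) & (nA < total) & (nB > 0) & (nB < total)
    pA = np.divide(nA, total, where=total > 0, out=np.zeros_like(n_AB))
    pB = np.divide(nB, total, where=total > 0, out=np.zeros_like(n_AB))
    pAB = np.divide(n_AB, total, where=total > 0, out=np.zeros_like(n_AB))
    d = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    chi2 = np.zeros_like(d)
    np.divide(total * d * d, denom, where=poly, out=chi2)
    p = np.where(poly, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p, d, poly


def fisher_one_tailed_from_counts(n_AB, n_Ab, n_aB, n_ab):
    """Vectorized one-tailed Fisher p (direction of observed D) via hypergeometric tails."""
    n_AB = np.asarray(n_AB, dtype=np.int64)
    n_Ab = np.asarray(n_Ab, dtype=np.int64)
    n_aB = np.asarray(n_aB, dtype=np.int64)
    n_ab = np.asarray(n_ab, dtype=np.int64)
    total = n_AB + n_Ab + n_aB + n_ab
    nA = n_AB + n_Ab
    nB = n_AB + n_aB
    d = n_AB * total - nA * nB  # sign of D without division
    p_hi = stats.hypergeom.sf(n_AB - 1, total, nA, nB)
    p_lo = stats.hypergeom.cdf(n_AB, total, nA, nB)
    return np.where(d >= 0, p_hi, p_lo)
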