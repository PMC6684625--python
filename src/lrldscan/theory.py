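"""Deterministic detection theory for long-range LD tests.

Three questions are answered in closed form, without simulation:

* over the admissible haplotype-frequency range of a variant pair, which grid
  points does each test (chi-square, one-tailed Fisher) declare out of
  equilibrium at a given sample size?  (:func:`detection_profile`)
* how much recombination does a physical distance imply under the Haldane or
  Kosambi map function?  (:func:`map_distance_to_recombination`)
* how much spurious LD does pooling two diverged subpopulations create, and is
  it detectable at a given sample size?  (:func:`pooled_two_population_ld`,
  :func:`substructure_significance_grid`)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ld import TwoLocusHaplotypeTable, estimate_ld

__all__ = [
    "DetectionProfile",
    "PooledLD",
    "detection_profile",
    "map_distance_to_recombination",
    "pooled_two_population_ld",
    "substructure_significance_grid",
]


@dataclass
class DetectionProfile:
    """Test decisions over the admissible p_AB grid at step 1/(2n).

    ``grid`` has one row per admissible haplotype count, with columns
    ``p_AB, dprime, chi2, p_chi2, p_fisher, chi2_significant, fisher_significant``.
    ``p_a``/``p_b`` are the realized minor allele frequencies after rounding the
    allele counts to integers.
    """

    n: int
    p_a: float
    p_b: float
    alpha: float
    grid: pd.DataFrame


def detection_profile(n: int, p_a: float, p_b: float, alpha: float = 0.05) -> DetectionProfile:
    """Evaluate both LD tests at every admissible haplotype frequency.

    Allele counts are fixed at ``round(2n * p)`` minor copies per locus; the
    major-major haplotype count then ranges over all integers compatible with
    those margins, i.e. p_AB runs from ``1 - p_a - p_b`` to ``1 - max(p_a, p_b)``
    in steps of ``1/(2n)``.  Both tests are one-tailed in the direction of the
    observed disequilibrium at level alpha: Fisher by construction, and the
    chi-square via its signed root (one-sided p = upper-tail(X^2)/2), so the
    two tests are compared at the same one-tailed level.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    total = 2 * n
    k_a = round(total * p_a)
    k_b = round(total * p_b)
    if min(k_a, k_b) < 1 or max(k_a, k_b) > total - 1:
        raise ValueError("allele frequencies leave no polymorphic integer counts")
    nA = total - k_a  # major allele count, locus A
    nB = total - k_b
    k_min = max(nA + nB - total, 0)
    k_max = min(nA, nB)
    if k_min > k_max:
        raise ValueError("no admissible haplotype count for these margins")
    rows = []
    for k in range(k_min, k_max + 1):
        table = TwoLocusHaplotypeTable(k, nA - k, nB - k, total - nA - nB + k, n)
        est = estimate_ld(table)
        p_chi2_one_sided = est.p_chi2 / 2.0 if est.d_hat != 0 else 0.5 + est.p_chi2 / 2.0
        rows.append(
            {
                "p_AB": k / total,
                "dprime": est.dprime,
                "chi2": est.chi2,
                "p_chi2": est.p_chi2,
                "p_chi2_one_sided": p_chi2_one_sided,
                "p_fisher": est.p_fisher,
                "chi2_significant": p_chi2_one_sided <= alpha,
                "fisher_significant": est.p_fisher <= alpha,
            }
        )
    return DetectionProfile(
        n=n, p_a=k_a / total, p_b=k_b / total, alpha=alpha, grid=pd.DataFrame(rows)
    )


def map_distance_to_recombination(
    distance_bp: float, cm_per_mb: float = 1.15, function: str = "haldane"
) -> float:
    """Convert a physical distance to a recombination fraction.

    The distance is first converted to map length ``d`` in Morgans assuming a
    uniform ``cm_per_mb`` rate; then Haldane ``r = (1 - exp(-2d))/2`` (no
    interference) or Kosambi ``r = tanh(2d)/2`` (with interference) is applied.
    """
    if distance_bp < 0:
        raise ValueError("distance_bp must be >= 0")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be > 0")
    d = distance_bp * cm_per_mb / (100.0 * 1e6)  # Morgans
    if function == "haldane":
        return (1.0 - math.exp(-2.0 * d)) / 2.0
    if function == "kosambi":
        return math.tanh(2.0 * d) / 2.0
    raise ValueError(f"unknown map function {function!r}")


@dataclass
class PooledLD:
    """Spurious LD of a two-subpopulation mixture at within-subpop equilibrium."""

    w: float
    pA1: float
    pA2: float
    pB1: float
    pB2: float
    pooled_pA: float
    pooled_pB: float
    pooled_pAB: float
    pooled_D: float
    chi2_significant: bool | None = None
    fisher_significant: bool | None = None


def pooled_two_population_ld(
    w: float, pA1: float, pA2: float, pB1: float, pB2: float
) -> PooledLD:
    """Closed-form pooled LD when two equilibrium subpopulations are mixed.

    ``w`` is the proportion of subpopulation 2.  Pooled allele frequencies are
    the mixture means and, because each subpopulation factorizes, the pooled
    haplotype frequency is ``(1-w) pA1 pB1 + w pA2 pB2``; the resulting
    disequilibrium reduces to ``w (1-w) (pA1 - pA2)(pB1 - pB2)``.
    """
    if not 0.0 < w < 1.0:
        raise ValueError("mixing ratio w must be in (0, 1)")
    for name, p in (("pA1", pA1), ("pA2", pA2), ("pB1", pB1), ("pB2", pB2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    pA = (1.0 - w) * pA1 + w * pA2
    pB = (1.0 - w) * pB1 + w * pB2
    pAB = (1.0 - w) * pA1 * pB1 + w * pA2 * pB2
    return PooledLD(
        w=w, pA1=pA1, pA2=pA2, pB1=pB1, pB2=pB2,
        pooled_pA=pA, pooled_pB=pB, pooled_pAB=pAB, pooled_D=pAB - pA * pB,
    )


def _evaluate_pooled_cell(pooled: PooledLD, n_total: int, alpha: float) -> tuple[bool, bool]:
    """Test decisions for the expected haplotype table of a pooled population.

    The chi-square statistic is evaluated on the unrounded expected frequencies;
    Fisher's test needs integer counts, so all four expected cells are rounded
    to the nearest integer (the rounded total defines the table's margins).
    """
    total = 2 * n_total
    pA, pB, pAB = pooled.pooled_pA, pooled.pooled_pB, pooled.pooled_pAB
    if not (0.0 < pA < 1.0) or not (0.0 < pB < 1.0):
        return False, False
    d = pooled.pooled_D
    chi2 = total * d * d / (pA * (1 - pA) * pB * (1 - pB))
    # one-tailed decision in the direction of the pooled D, as in the profiles
    p_one = stats.chi2.sf(chi2, df=1) / 2.0 if d != 0 else 1.0
    chi2_sig = bool(p_one <= alpha)

    cells = np.rint(
        np.array(
            [pAB, pA - pAB, pB - pAB, 1.0 - pA - pB + pAB], dtype=float
        ) * total
    ).astype(int)
    cells = np.maximum(cells, 0)
    n_eff = int(cells.sum())
    if n_eff == 0 or cells[0] + cells[1] in (0, n_eff) or cells[0] + cells[2] in (0, n_eff):
        return chi2_sig, False
    # rounding can make the total odd, so test the raw 2x2 rather than a
    # TwoLocusHaplotypeTable (which requires counts summing to an even 2n)
    tail = "greater" if d >= 0 else "less"
    _, p_f = stats.fisher_exact(
        [[cells[0], cells[1]], [cells[2], cells[3]]], alternative=tail
    )
    return chi2_sig, bool(p_f <= alpha)


def substructure_significance_grid(
    n_total: int,
    w_values: Sequence[float],
    locus_a_freqs: Sequence,
    locus_b_freqs: Sequence | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Significance surface for spurious LD from two pooled subpopulations.

    Two grid modes:

    * ``locus_b_freqs is None`` — the worst-case coupling where both loci share
      the same allele frequency within each subpopulation: ``locus_a_freqs`` is
      a 1-D list of frequencies and each cell ``(f1, f2)`` sets
      ``pA1 = pB1 = f1`` and ``pA2 = pB2 = f2``.
    * otherwise — ``locus_a_freqs``/``locus_b_freqs`` are lists of
      ``(p1, p2)`` subpopulation frequency pairs and the full cross product is
      evaluated.

    Returns a tidy DataFrame with one row per ``(w, cell)``.
    """
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    if locus_b_freqs is None:
        cells = [
            ((f1, f2), (f1, f2))
            for f1 in locus_a_freqs
            for f2 in locus_a_freqs
        ]
    else:
        cells = [
            (tuple(a), tuple(b)) for a in locus_a_freqs for b in locus_b_freqs
        ]
    rows = []
    for w in w_values:
        for (pA1, pA2), (pB1, pB2) in cells:
            pooled = pooled_two_population_ld(w, pA1, pA2, pB1, pB2)
            chi2_sig, fisher_sig = _evaluate_pooled_cell(pooled, n_total, alpha)
            rows.append(
                {
                    "w": w,
                    "pA1": pA1,
                    "pA2": pA2,
                    "pB1": pB1,
                    "pB2": pB2,
                    "pooled_D": pooled.pooled_D,
                    "chi2_significant": chi2_sig,
                    "fisher_significant": fisher_sig,
                }
            )
    return pd.DataFrame(rows)
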