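"""Two-factor sufficient-cause disease model and case-control odds-ratio simulation.

Disease arises from either of two disjoint sufficient causes: a purely
environmental cause present in a fraction ``E`` of the population, or a
gene-environment interaction whose environmental component has frequency
``E_G`` and which requires carrying the interacting allele (dominant model:
one or more copies).  Penetrances are therefore

    P(case | carrier)     = E + E_G
    P(case | non-carrier) = E
    K (lifetime incidence) = E + carrier_frequency * E_G

With the defaults E = 0.03 and E_G = 0.05 a fully penetrant carrier pool
(carrier frequency 1) gives K = 0.08, and the large-sample dominant odds ratio
of the disease variant itself converges to

    OR = (E + E_G)(1 - E) / (E (1 - E - E_G))  ~= 2.812

independently of the carrier frequency.  The simulator resamples phased panel
individuals, assigns case status from carrier state at a designated disease
variant, and ranks every regional variant by its dominant odds ratio — the
experiment that quantifies how local LD and long-range LD partners outrank the
true disease variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

__all__ = [
    "DiseaseModelParams",
    "CaseControlStudy",
    "penetrance_and_incidence",
    "case_genotype_frequencies",
    "dominant_odds_ratio",
    "asymptotic_disease_or",
    "simulate_case_control",
    "detection_error_rate",
]


@dataclass(frozen=True)
class DiseaseModelParams:
    """Sufficient-cause model parameters (dominant carrier definition)."""

    E: float = 0.03
    E_G: float = 0.05
    model: str = "dominant"

    def __post_init__(self) -> None:
        if self.E < 0 or self.E_G < 0 or self.E + self.E_G > 1:
            raise ValueError("need E >= 0, E_G >= 0 and E + E_G <= 1")
        if self.model != "dominant":
            raise ValueError("only the dominant carrier model is implemented")


def penetrance_and_incidence(
    params: DiseaseModelParams, carrier_frequency: float
) -> tuple[float, float, float]:
    """(P(case|carrier), P(case|non-carrier), lifetime incidence K).

    The two causes are disjoint, so penetrances add: carriers are affected with
    probability ``E + E_G`` and the incidence is ``E + carrier_frequency * E_G``.
    """
    if not 0.0 <= carrier_frequency <= 1.0:
        raise ValueError("carrier_frequency must be in [0, 1]")
    f_carrier = params.E + params.E_G
    f_noncarrier = params.E
    K = params.E + carrier_frequency * params.E_G
    return f_carrier, f_noncarrier, K


def case_genotype_frequencies(
    params: DiseaseModelParams, genotype_frequencies: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype frequencies among cases and controls by Bayes' rule.

    ``genotype_frequencies`` are population frequencies of 0/1/2 risk-allele
    copies; under the dominant model genotypes with >= 1 copy are carriers.
    Returns ``(case_freqs, control_freqs)``, each summing to 1.
    """
    g = np.asarray(genotype_frequencies, dtype=float)
    if g.shape != (3,) or np.any(g < 0) or abs(g.sum() - 1.0) > 1e-9:
        raise ValueError("genotype_frequencies must be 3 non-negative values summing to 1")
    carrier = np.array([0.0, 1.0, 1.0])
    pen = params.E + carrier * params.E_G
    K = float(np.sum(pen * g))
    if K <= 0.0 or K >= 1.0:
        raise ValueError(f"degenerate incidence K={K}")
    case = pen * g / K
    control = (1.0 - pen) * g / (1.0 - K)
    return case, control


def dominant_odds_ratio(
    case_counts: tuple[int, int], control_counts: tuple[int, int]
) -> float:
    """Dominant odds ratio with the Haldane-Anscombe zero-cell correction.

    ``case_counts``/``control_counts`` are (carrier, non-carrier) counts; any
    zero cell adds 0.5 to all four cells.
    """
    a, b = case_counts
    c, d = control_counts
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def asymptotic_disease_or(params: DiseaseModelParams) -> float:
    """Large-sample dominant OR of the disease variant itself."""
    f1 = params.E + params.E_G
    f0 = params.E
    return (f1 * (1 - f0)) / (f0 * (1 - f1))


@dataclass
class CaseControlStudy:
    """One simulated case-control replicate with per-variant odds ratios."""

    disease_variant: tuple[str, int]
    n_cases: int
    n_controls: int
    seed: int
    odds_ratios: pd.DataFrame = field(repr=False)
    correct_flag: bool = False  # disease variant strictly tops the OR ranking


def _region_columns(
    panel: HaplotypePanel,
    disease_variant: tuple[str, int],
    regions: Sequence[tuple[str, int, int]] | None,
    window_bp: int,
) -> np.ndarray:
    chrom, pos = str(disease_variant[0]), int(disease_variant[1])
    if regions is None:
        regions = [(chrom, pos - window_bp, pos + window_bp)]
    keep = np.zeros(panel.n_variants, dtype=bool)
    vc = panel.variants["chrom"].astype(str).to_numpy()
    vp = panel.variants["pos"].to_numpy()
    for rc, start, end in regions:
        keep |= (vc == str(rc)) & (vp >= start) & (vp <= end)
    keep[panel.variant_index(chrom, pos)] = True
    return np.flatnonzero(keep)


def simulate_case_control(
    panel: HaplotypePanel,
    disease_variant: tuple[str, int],
    params: DiseaseModelParams = DiseaseModelParams(),
    n_cases: int = 1000,
    n_controls: int = 1000,
    seed: int = 0,
    regions: Sequence[tuple[str, int, int]] | None = None,
    window_bp: int = 10_000,
    max_draw_factor: float = 50.0,
) -> CaseControlStudy:
    """Simulate one case-control study from a phased panel.

    Individuals are resampled with replacement; each draw becomes a case with
    probability ``E + E_G`` if it carries the risk allele at the disease
    variant and ``E`` otherwise, until the requested case and control pools are
    filled.  Controls are drawn from the unaffected.  Every variant in the
    configured regions (default: +/- ``window_bp`` around the disease variant)
    gets a dominant odds ratio.  Raises if the pools cannot be filled within
    ``max_draw_factor`` times the expected number of draws.
    """
    chrom, pos = str(disease_variant[0]), int(disease_variant[1])
    cols = _region_columns(panel, disease_variant, regions, window_bp)
    carrier = panel.genotype_counts()[:, cols] >= 1
    dis_col = int(np.flatnonzero(cols == panel.variant_index(chrom, pos))[0])
    dis_carrier = carrier[:, dis_col]
    carrier_freq = float(dis_carrier.mean())
    if carrier_freq in (0.0, 1.0):
        raise ValueError(f"disease variant {chrom}:{pos} has no carrier polymorphism")
    f1, f0, K = penetrance_and_incidence(params, carrier_freq)

    rng = np.random.default_rng(seed)
    n_ind = panel.n_samples
    expected_draws = n_cases / K + n_controls / (1.0 - K)
    max_draws = int(np.ceil(max_draw_factor * expected_draws))
    case_idx: list[np.ndarray] = []
    control_idx: list[np.ndarray] = []
    n_case = n_control = drawn = 0
    batch = min(max(1024, int(expected_draws // 4)), 1 << 18)
    while (n_case < n_cases or n_control < n_controls) and drawn < max_draws:
        batch = min(batch, max_draws - drawn)
        idx = rng.integers(0, n_ind, size=batch)
        p_case = np.where(dis_carrier[idx], f1, f0)
        is_case = rng.random(batch) < p_case
        drawn += batch
        if n_case < n_cases:
            take = idx[is_case][: n_cases - n_case]
            case_idx.append(take)
            n_case += take.size
        if n_control < n_controls:
            take = idx[~is_case][: n_controls - n_control]
            control_idx.append(take)
            n_control += take.size
    if n_case < n_cases or n_control < n_controls:
        raise RuntimeError(
            f"could not fill {n_cases} cases / {n_controls} controls within "
            f"{max_draws} draws (incidence K={K:.4g}); increase max_draw_factor "
            "or the penetrance parameters"
        )
    cases = np.concatenate(case_idx)
    controls = np.concatenate(control_idx)

    case_car = carrier[cases].sum(axis=0).astype(float)
    ctrl_car = carrier[controls].sum(axis=0).astype(float)
    a, b = case_car, n_cases - case_car
    c, d = ctrl_car, n_controls - ctrl_car
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a = np.where(zero, a + 0.5, a)
    b = np.where(zero, b + 0.5, b)
    c = np.where(zero, c + 0.5, c)
    d = np.where(zero, d + 0.5, d)
    ors = (a * d) / (b * c)

    odds = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"].to_numpy()[cols],
            "pos": panel.variants["pos"].to_numpy()[cols],
            "odds_ratio": ors,
            "case_carriers": case_car.astype(int),
            "control_carriers": ctrl_car.astype(int),
            "is_disease_variant": np.arange(cols.size) == dis_col,
        }
    )
    others = ors[np.arange(cols.size) != dis_col]
    correct = bool(others.size == 0 or ors[dis_col] > others.max())
    return CaseControlStudy(
        disease_variant=(chrom, pos),
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
        odds_ratios=odds,
        correct_flag=correct,
    )


def detection_error_rate(
    panel: HaplotypePanel,
    disease_variants: Sequence[tuple[str, int]],
    params: DiseaseModelParams = DiseaseModelParams(),
    n_cases: int = 1000,
    n_controls: int = 1000,
    n_replicates: int = 1000,
    seed: int = 0,
    regions: Sequence[tuple[str, int, int]] | None = None,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Error rate of OR-based disease-variant identification, per disease variant.

    For each designated disease variant the study is replicated; a replicate is
    an error when any other variant's odds ratio is at least the disease
    variant's (the true variant must be *strictly* the maximum to count as a
    correct identification).  Returns columns
    ``chrom, pos, n_replicates, error_rate``.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for dv, child in zip(disease_variants, ss.spawn(len(disease_variants))):
        rep_seeds = child.generate_state(n_replicates) % (2**31)
        errors = 0
        for s in rep_seeds:
            study = simulate_case_control(
                panel, dv, params, n_cases, n_controls, int(s),
                regions=regions, window_bp=window_bp,
            )
            errors += not study.correct_flag
        rows.append(
            {
                "chrom": str(dv[0]),
                "pos": int(dv[1]),
                "n_replicates": n_replicates,
                "error_rate": errors / n_replicates,
            }
        )
    return pd.DataFrame(rows)
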