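"""Shared fixtures: synthetic panels, planted scans, and exact-test oracles."""

from math import comb

import numpy as np
import pytest

import lrldscan as L


def fisher_enumeration_oracle(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> float:
    """One-tailed Fisher p by full hypergeometric enumeration (exact integers).

    Sums the probabilities of all tables with the observed margins whose
    major-major count is at least as extreme as observed, toward the sign of
    the observed disequilibrium (ties go to the 'greater' tail).
    """
    total = n_AB + n_Ab + n_aB + n_ab
    nA = n_AB + n_Ab
    nB = n_AB + n_aB
    d_sign = n_AB * total - nA * nB
    k_min = max(0, nA + nB - total)
    k_max = min(nA, nB)
    if d_sign >= 0:
        ks = range(n_AB, k_max + 1)
    else:
        ks = range(k_min, n_AB + 1)
    num = sum(comb(nA, k) * comb(total - nA, nB - k) for k in ks)
    return num / comb(total, nB)


def random_polymorphic_table(rng: np.random.Generator, max_n: int = 200):
    """A random haplotype table with both margins polymorphic."""
    while True:
        n = int(rng.integers(2, max_n))
        counts = rng.multinomial(2 * n, rng.dirichlet(np.ones(4)))
        t = L.TwoLocusHaplotypeTable(*[int(c) for c in counts], n=n)
        if 0 < t.p_A < 1 and 0 < t.p_B < 1:
            return t


@pytest.fixture(scope="session")
def base_spec() -> L.PanelSpec:
    return L.PanelSpec(seed=11)


@pytest.fixture(scope="session")
def base_panels(base_spec):
    return L.generate_panel(base_spec)


@pytest.fixture(scope="session")
def planted_pairs(base_panels):
    """Twenty D'=1 pairs at allele frequency 0.3, >= 5 Mb apart, all populations."""
    first = next(iter(base_panels.values()))
    pos = first.variants["pos"].to_numpy()
    half = len(pos) // 2
    pairs = []
    for k in range(20):
        pa, pb = int(pos[k]), int(pos[half + k])
        assert pb - pa >= L.MIN_LRLD_DISTANCE_BP
        pairs.append(
            L.PlantedLRLD(pa, pb, 1.0, tuple(base_panels), (0.3, 0.3))
        )
    return pairs


@pytest.fixture(scope="session")
def planted_panels(base_panels, planted_pairs):
    return L.plant_lrld(base_panels, planted_pairs, seed=12)


@pytest.fixture(scope="session")
def planted_scan(planted_panels):
    return L.scan_pairs(planted_panels, L.ScanConfig(), keep_all=True)
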