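"""Chromosome-wide long-range LD scan with FDR control.

The scan takes one phased panel per population sharing a variant universe,
keeps variants whose analysis-allele frequency lies in a common band in every
population, tests every intra-chromosomal pair at least ``min_distance_bp``
apart with the two-locus chi-square, and adjusts p-values with the
Benjamini-Hochberg step-up procedure (per chromosome per population by
default).  Downstream helpers flag centromere-proximal pairs, tally
per-population intersection counts against their expected-if-independent
values, and call hotspot variants participating in many significant pairs.

The ``workers`` setting is a chunking hint only: pairs are processed in
``workers`` contiguous chunks and results canonically sorted, so the output is
identical for any worker count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .panel import HaplotypePanel

__all__ = [
    "ScanConfig",
    "ScanResult",
    "IntersectionSummary",
    "scan_pairs",
    "bh_adjust",
    "apply_centromere_filter",
    "population_intersections",
    "expected_intersections",
    "find_hotspots",
]

RECORD_COLUMNS = [
    "population", "chromosome", "pos_a", "pos_b",
    "d_hat", "dprime", "chi2", "p_raw", "q_fdr", "centromeric_flag",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    ``min_distance_bp`` is inclusive: a pair exactly at the threshold is
    long-range.  ``fdr_scope`` is ``"per_chromosome"`` (BH within each
    population x chromosome) or ``"genome_wide"`` (BH within each population,
    pooling chromosomes).
    """

    min_distance_bp: int = 5_000_000
    maf_min: float = 0.1
    maf_max: float = 0.9
    fdr_alpha: float = 0.05
    centromere_pad_bp: int = 5_000_000
    populations: tuple[str, ...] | None = None
    workers: int = 1
    fdr_scope: str = "per_chromosome"

    def __post_init__(self) -> None:
        if self.min_distance_bp <= 0:
            raise ValueError("min_distance_bp must be > 0")
        if not 0.0 < self.maf_min < self.maf_max < 1.0:
            raise ValueError("need 0 < maf_min < maf_max < 1")
        if self.fdr_scope not in ("per_chromosome", "genome_wide"):
            raise ValueError(f"unknown fdr_scope {self.fdr_scope!r}")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass
class ScanResult:
    """Output of :func:`scan_pairs`.

    ``records`` holds one row per FDR-significant pair per population;
    ``tested_pairs`` gives the number of tested pairs per chromosome (shared
    across populations since the variant universe is shared).
    """

    records: pd.DataFrame
    tested_pairs: pd.Series
    config: ScanConfig
    n_variants_tested: int = 0


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, 'BH' semantics)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _common_universe(panels: Mapping[str, HaplotypePanel], config: ScanConfig):
    """Variants passing the frequency filter in every population.

    Returns, per population, the column indices of the shared filtered
    universe, ordered identically (by chromosome then position).
    """
    pops = list(config.populations) if config.populations else sorted(panels)
    keys_per_pop = {}
    for pop in pops:
        panel = panels[pop]
        freqs = panel.allele_frequencies()
        ok = (freqs >= config.maf_min) & (freqs <= config.maf_max)
        passing = {
            k for k, keep in zip(
                zip(panel.variants["chrom"].astype(str), panel.variants["pos"].astype(int)),
                ok,
            ) if keep
        }
        keys_per_pop[pop] = passing
    shared = set.intersection(*keys_per_pop.values()) if pops else set()
    if not shared:
        raise ValueError("no variants pass the frequency filter in every population")
    universe = sorted(shared)
    indices = {}
    for pop in pops:
        panel = panels[pop]
        lookup = {
            (str(c), int(p)): i
            for i, (c, p) in enumerate(zip(panel.variants["chrom"], panel.variants["pos"]))
        }
        indices[pop] = np.array([lookup[k] for k in universe], dtype=int)
    return pops, universe, indices


def _pair_stats(C: np.ndarray, pA: np.ndarray, total: int,
                i_idx: np.ndarray, j_idx: np.ndarray):
    """Vectorized D-hat, D', chi-square and p for the given column pairs.

    ``C`` is the full haplotype co-occurrence frequency matrix
    ``M.T @ M / (2n)`` of the major-coded panel, ``pA`` its column means.
    """
    from scipy import stats

    pAB = C[i_idx, j_idx]
    pa = pA[i_idx]
    pb = pA[j_idx]
    d = pAB - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    chi2 = total * d * d / denom
    p = stats.chi2.sf(chi2, df=1)
    d_max = np.where(
        d >= 0,
        np.minimum(pa * (1 - pb), (1 - pa) * pb),
        np.minimum(pa * pb, (1 - pa) * (1 - pb)),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.where(d == 0, 0.0, d / d_max)
    return d, dprime, chi2, p


def scan_pairs(
    panels: Mapping[str, HaplotypePanel],
    config: ScanConfig = ScanConfig(),
    keep_all: bool = False,
) -> ScanResult:
    """Run the long-range LD scan over a set of population panels.

    Returns FDR-significant records (``q_fdr < fdr_alpha``) in canonical order
    (population, chromosome, pos_a, pos_b) and the tested-pair count per
    chromosome.  With ``keep_all=True`` the result also carries every tested
    pair in ``result.all_tests``.
    """
    pops, universe, indices = _common_universe(panels, config)
    chroms = sorted({c for c, _ in universe})
    uni_df = pd.DataFrame(universe, columns=["chrom", "pos"])

    all_rows = []
    tested_counts = {}
    for chrom in chroms:
        sel = uni_df["chrom"] == chrom
        pos = uni_df.loc[sel, "pos"].to_numpy()
        order = np.flatnonzero(sel.to_numpy())
        m = pos.size
        if m < 2:
            tested_counts[chrom] = 0
            continue
        # pairs (i < j) at or beyond the distance threshold (inclusive)
        dist = pos[None, :] - pos[:, None]
        i_idx, j_idx = np.nonzero(dist >= config.min_distance_bp)
        tested_counts[chrom] = int(i_idx.size)
        if i_idx.size == 0:
            continue
        chunks = np.array_split(np.arange(i_idx.size), config.workers)
        for pop in pops:
            panel = panels[pop]
            cols = indices[pop][order]
            H = panel.haplotypes[:, cols].astype(np.float64)
            freq1 = H.mean(axis=0)
            flip = freq1 <= 0.5  # major-allele coding; tie breaks toward reference
            M = np.where(flip[None, :], 1.0 - H, H)
            pA = M.mean(axis=0)
            total = M.shape[0]
            C = (M.T @ M) / total
            parts = []
            for chunk in chunks:
                if chunk.size == 0:
                    continue
                d, dprime, chi2, p = _pair_stats(C, pA, total, i_idx[chunk], j_idx[chunk])
                parts.append((i_idx[chunk], j_idx[chunk], d, dprime, chi2, p))
            ii = np.concatenate([p[0] for p in parts])
            jj = np.concatenate([p[1] for p in parts])
            all_rows.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "chromosome": chrom,
                        "pos_a": pos[ii],
                        "pos_b": pos[jj],
                        "d_hat": np.concatenate([p[2] for p in parts]),
                        "dprime": np.concatenate([p[3] for p in parts]),
                        "chi2": np.concatenate([p[4] for p in parts]),
                        "p_raw": np.concatenate([p[5] for p in parts]),
                    }
                )
            )
    if not all_rows:
        raise ValueError("no testable long-range pairs in the shared variant universe")
    tests = pd.concat(all_rows, ignore_index=True)

    group_cols = ["population"] if config.fdr_scope == "genome_wide" else [
        "population", "chromosome"
    ]
    tests["q_fdr"] = (
        tests.groupby(group_cols, sort=False)["p_raw"].transform(lambda p: bh_adjust(p))
    )
    tests["centromeric_flag"] = False

    records = tests[tests["q_fdr"] < config.fdr_alpha].copy()
    records = records.sort_values(
        ["population", "chromosome", "pos_a", "pos_b"], kind="mergesort"
    ).reset_index(drop=True)

    result = ScanResult(
        records=records[RECORD_COLUMNS],
        tested_pairs=pd.Series(tested_counts, name="n_pairs"),
        config=config,
        n_variants_tested=len(universe),
    )
    if keep_all:
        result.all_tests = tests  # type: ignore[attr-defined]
    return result


def apply_centromere_filter(
    records: pd.DataFrame,
    centromere_intervals: Mapping[str, tuple[int, int]],
    pad_bp: int = 5_000_000,
) -> pd.DataFrame:
    """Flag records with either variant within +/- pad of its centromere.

    The padded interval is closed: a variant exactly at ``cen_start - pad`` or
    ``cen_end + pad`` is flagged.  Every record chromosome must have a
    centromere interval.
    """
    out = records.copy()
    flags = np.zeros(len(out), dtype=bool)
    for chrom, grp in out.groupby("chromosome", sort=False):
        if chrom not in centromere_intervals:
            raise KeyError(f"no centromere interval for chromosome {chrom}")
        start, end = centromere_intervals[chrom]
        lo, hi = start - pad_bp, end + pad_bp
        a = grp["pos_a"].to_numpy()
        b = grp["pos_b"].to_numpy()
        flags[grp.index] = ((a >= lo) & (a <= hi)) | ((b >= lo) & (b <= hi))
    out["centromeric_flag"] = flags
    return out


@dataclass
class IntersectionSummary:
    """Per-chromosome LRLD counts by population subset, observed and expected.

    ``counts`` maps scope (``"total"`` / ``"noncentromeric"``) to a DataFrame
    indexed by chromosome (plus a ``"Sum"`` row) whose columns are single
    populations, population pairs (``"AFR&EUR"``) and ``"ALL"``.  ``expected``
    carries the expected-if-independent intersection counts for the same
    scopes when tested-pair counts were provided.
    """

    counts: dict[str, pd.DataFrame]
    expected: dict[str, pd.DataFrame] = field(default_factory=dict)


def _subset_columns(pops: Sequence[str]) -> list[tuple[str, tuple[str, ...]]]:
    cols: list[tuple[str, tuple[str, ...]]] = [(p, (p,)) for p in pops]
    for r in range(2, len(pops)):
        for combo in itertools.combinations(pops, r):
            cols.append(("&".join(combo), combo))
    if len(pops) >= 2:
        cols.append(("ALL", tuple(pops)))
    return cols


def population_intersections(
    records: pd.DataFrame,
    tested_pairs: pd.Series | None = None,
    populations: Sequence[str] | None = None,
) -> IntersectionSummary:
    """Observed (and optionally expected) intersection counts across populations.

    A pair is keyed by (chromosome, pos_a, pos_b); a subset column counts pairs
    significant in *every* population of the subset.  Counts are reported both
    for all records and excluding centromere-flagged records.
    """
    pops = list(populations) if populations else sorted(records["population"].unique())
    cols = _subset_columns(pops)
    chroms = sorted(records["chromosome"].unique())
    summary = IntersectionSummary(counts={})
    for scope in ("total", "noncentromeric"):
        sub = records if scope == "total" else records[~records["centromeric_flag"]]
        table = {}
        for chrom in chroms:
            chrom_rec = sub[sub["chromosome"] == chrom]
            keys = {
                pop: set(
                    zip(
                        chrom_rec.loc[chrom_rec["population"] == pop, "pos_a"],
                        chrom_rec.loc[chrom_rec["population"] == pop, "pos_b"],
                    )
                )
                for pop in pops
            }
            row = {}
            for name, combo in cols:
                inter = set.intersection(*(keys[p] for p in combo))
                row[name] = len(inter)
            table[chrom] = row
        df = pd.DataFrame(table).T
        df.loc["Sum"] = df.sum()
        summary.counts[scope] = df
        if tested_pairs is not None:
            per_pop = df.drop(index="Sum")[pops]
            summary.expected[scope] = expected_intersections(per_pop, tested_pairs)
    return summary


def expected_intersections(
    counts_per_population: pd.DataFrame, tested_pairs: pd.Series
) -> pd.DataFrame:
    """Expected intersection counts if detections were independent per population.

    For a chromosome with ``N`` tested pairs and per-population detection
    counts ``n_X``, the expected pairwise intersection is ``n_X n_Y / N`` and
    the expected all-population intersection is ``prod(n) / N^(k-1)``.  Summed
    over chromosomes in the final ``"Sum"`` row.
    """
    pops = list(counts_per_population.columns)
    cols = [c for c in _subset_columns(pops) if len(c[1]) >= 2]
    rows = {}
    for chrom in counts_per_population.index:
        N = float(tested_pairs.get(chrom, 0))
        if N <= 0:
            raise ValueError(f"zero tested pairs on chromosome {chrom}")
        row = {}
        for name, combo in cols:
            prod = np.prod([counts_per_population.loc[chrom, p] for p in combo])
            row[name] = prod / N ** (len(combo) - 1)
        rows[chrom] = row
    df = pd.DataFrame(rows).T
    df.loc["Sum"] = df.sum()
    return df


def find_hotspots(records: pd.DataFrame, min_pairs: int = 2) -> pd.DataFrame:
    """Variants participating in at least ``min_pairs`` significant pairs.

    Participation is counted per population; returns columns
    ``population, chromosome, pos, n_pairs``.
    """
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2")
    long = pd.concat(
        [
            records[["population", "chromosome", "pos_a"]].rename(columns={"pos_a": "pos"}),
            records[["population", "chromosome", "pos_b"]].rename(columns={"pos_b": "pos"}),
        ],
        ignore_index=True,
    )
    counts = (
        long.groupby(["population", "chromosome", "pos"]).size().rename("n_pairs").reset_index()
    )
    hot = counts[counts["n_pairs"] >= min_pairs]
    return hot.sort_values(
        ["population", "chromosome", "pos"], kind="mergesort"
    ).reset_index(drop=True)
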