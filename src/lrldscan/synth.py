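"""Synthetic multi-population phased panels with plantable long-range LD.

The generator emulates the study conditions every downstream stage expects:
three continental populations of ~500 diploids, common variants (allele
frequency 0.1-0.9 in each population), block-like local LD, long-range LD
pairs planted at a target D' in chosen populations, centromere and gene/SV
annotation tracks, and optional two-subpopulation admixture with controlled
allele-frequency divergence.

Local LD uses a block-mosaic model: within each block a haplotype either
copies one of a small pool of founder haplotypes (probability
``within_block_dprime``) or draws its alleles independently.  This reproduces
block-like correlation without a coalescent simulation; variants in different
blocks are independent in expectation.  After the draw, each column is
repaired to exactly ``round(2n p)`` copies of the analysis allele so realized
frequencies respect the configured band.

Planting rewrites exactly two columns: the first column is set to its target
frequency and the partner column is resampled conditional on it so the
realized haplotype frequency hits ``p_AB = p_a p_b + D' * D_max``.  Everything
else in the panel stays untouched and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, RegionAnnotation, SVInterval
from .panel import HaplotypePanel

__all__ = [
    "MIN_LRLD_DISTANCE_BP",
    "PanelSpec",
    "PlantedLRLD",
    "AdmixtureSpec",
    "AnnotationTracks",
    "generate_panel",
    "plant_lrld",
    "generate_admixed_panel",
    "generate_annotation_tracks",
    "emit_fixture_set",
]

MIN_LRLD_DISTANCE_BP = 5_000_000


@dataclass(frozen=True)
class PanelSpec:
    """Conditions for one synthetic multi-population panel (one chromosome)."""

    n_individuals: int = 500
    n_variants: int = 300
    chromosome_length: int = 200_000_000
    chromosome: str = "1"
    populations: tuple[str, ...] = ("AFR", "EUR", "EAS")
    maf_range: tuple[float, float] = (0.1, 0.9)
    block_length: int = 100_000
    within_block_dprime: float = 0.8
    pop_divergence: float = 0.05  # sd of per-population frequency deviation
    n_founders: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("maf_range must satisfy 0 < low < high < 1")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.block_length <= 0:
            raise ValueError("block_length must be > 0")
        if not 0.0 <= self.within_block_dprime <= 1.0:
            raise ValueError("within_block_dprime must be in [0, 1]")
        if self.n_variants > self.chromosome_length:
            raise ValueError(
                f"cannot place {self.n_variants} unique positions on a "
                f"{self.chromosome_length} bp chromosome"
            )
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


@dataclass(frozen=True)
class PlantedLRLD:
    """A long-range pair to plant at a target D' in selected populations.

    ``allele_freqs`` maps population -> (freq_a, freq_b) of the analysis
    alleles; a single pair applies to all named populations.
    """

    pos_a: int
    pos_b: int
    target_dprime: float
    populations: tuple[str, ...]
    allele_freqs: Mapping[str, tuple[float, float]] | tuple[float, float] = (0.3, 0.3)

    def __post_init__(self) -> None:
        if abs(self.pos_b - self.pos_a) < MIN_LRLD_DISTANCE_BP:
            raise ValueError(
                f"planted pair distance {abs(self.pos_b - self.pos_a)} below the "
                f"long-range threshold of {MIN_LRLD_DISTANCE_BP} bp"
            )
        if not 0.0 <= self.target_dprime <= 1.0:
            raise ValueError("target_dprime must be in [0, 1]")

    def freqs_for(self, population: str) -> tuple[float, float]:
        if isinstance(self.allele_freqs, Mapping):
            return tuple(self.allele_freqs[population])
        return tuple(self.allele_freqs)


@dataclass(frozen=True)
class AdmixtureSpec:
    """Two equilibrium subpopulations pooled at a mixing ratio.

    ``subpop_allele_freqs`` has shape (2, m): analysis-allele frequencies per
    subpopulation per variant.  Only within-subpopulation linkage equilibrium
    is supported (each subpopulation's haplotype frequencies factorize).
    """

    mixing_ratio: float
    subpop_allele_freqs: tuple[tuple[float, ...], tuple[float, ...]]
    positions: tuple[int, ...] | None = None
    chromosome: str = "1"
    within_subpop_equilibrium: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.mixing_ratio < 1.0:
            raise ValueError("mixing_ratio must be in (0, 1)")
        freqs = np.asarray(self.subpop_allele_freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[0] != 2:
            raise ValueError("subpop_allele_freqs must have shape (2, n_variants)")
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("subpopulation allele frequencies must lie in [0, 1]")
        if self.positions is not None and len(self.positions) != freqs.shape[1]:
            raise ValueError("positions length must match the number of variants")
        if not self.within_subpop_equilibrium:
            raise ValueError(
                "only within-subpopulation linkage equilibrium is supported"
            )


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Strictly increasing unique 1-based positions on [1, length]."""
    pool: set[int] = set()
    while len(pool) < n:
        need = n - len(pool)
        pool.update(rng.integers(1, length + 1, size=2 * need).tolist())
    arr = np.array(sorted(pool), dtype=np.int64)
    if arr.size > n:
        arr = np.sort(rng.choice(arr, size=n, replace=False))
    return arr


def _exact_count_repair(
    rng: np.random.Generator, column: np.ndarray, target_ones: int
) -> None:
    """Flip random entries so the column has exactly ``target_ones`` ones."""
    ones = np.flatnonzero(column == 1)
    if ones.size > target_ones:
        drop = rng.choice(ones, size=ones.size - target_ones, replace=False)
        column[drop] = 0
    elif ones.size < target_ones:
        zeros = np.flatnonzero(column == 0)
        add = rng.choice(zeros, size=target_ones - ones.size, replace=False)
        column[add] = 1


def generate_panel(spec: PanelSpec) -> dict[str, HaplotypePanel]:
    """Generate one phased panel per population; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n2 = 2 * spec.n_individuals
    m = spec.n_variants
    lo, hi = spec.maf_range

    positions = _draw_positions(rng, m, spec.chromosome_length)
    base = rng.uniform(lo, hi, size=m)
    pop_freqs = {
        pop: np.clip(base + rng.normal(0.0, spec.pop_divergence, size=m), lo, hi)
        for pop in spec.populations
    }

    block_ids = positions // spec.block_length
    blocks = [np.flatnonzero(block_ids == b) for b in np.unique(block_ids)]

    variants = pd.DataFrame(
        {
            "chrom": spec.chromosome,
            "pos": positions,
            "id": [f"var{k:06d}" for k in range(m)],
            "ref": "A",
            "alt": "C",
        }
    )

    panels = {}
    for pop in spec.populations:
        p = pop_freqs[pop]
        H = np.zeros((n2, m), dtype=np.uint8)
        for cols in blocks:
            pb = p[cols]
            K = spec.n_founders
            founders = np.zeros((K, cols.size), dtype=np.uint8)
            for j, pv in enumerate(pb):
                carriers = int(round(K * pv))
                founders[rng.permutation(K)[:carriers], j] = 1
            assign = rng.integers(0, K, size=n2)
            copy = rng.random(n2) < spec.within_block_dprime
            indep = (rng.random((n2, cols.size)) < pb[None, :]).astype(np.uint8)
            H[:, cols] = np.where(copy[:, None], founders[assign], indep)
        for j in range(m):
            _exact_count_repair(rng, H[:, j], int(round(n2 * p[j])))
        panels[pop] = HaplotypePanel(
            population=pop,
            samples=[f"{pop}{i:04d}" for i in range(spec.n_individuals)],
            variants=variants.copy(),
            haplotypes=H,
        )
    return panels


def plant_lrld(
    panels: Mapping[str, HaplotypePanel],
    plants: Sequence[PlantedLRLD],
    seed: int = 0,
) -> dict[str, HaplotypePanel]:
    """Plant long-range LD pairs by column rewrite; returns new panels.

    For each plant and named population, the first column is rewritten to its
    target allele frequency (exact count) unless a previous plant already set
    it, then the partner column is resampled conditional on the first so that
    the haplotype frequency matches ``p_a p_b + D' * D_max``.  Populations not
    named keep both columns untouched.
    """
    rng = np.random.default_rng(seed)
    out = {pop: panel.copy() for pop, panel in panels.items()}
    written: set[tuple[str, int]] = set()
    for plant in plants:
        for pop in plant.populations:
            if pop not in out:
                raise KeyError(f"population {pop!r} not in panel set")
            panel = out[pop]
            ia = panel.variant_index(panel.variants["chrom"].iloc[0], plant.pos_a)
            ib = panel.variant_index(panel.variants["chrom"].iloc[0], plant.pos_b)
            f_a, f_b = plant.freqs_for(pop)
            for name, f in (("freq_a", f_a), ("freq_b", f_b)):
                if not 0.0 < f < 1.0:
                    raise ValueError(
                        f"{name}={f} must be strictly inside (0, 1) to plant LD"
                    )
            n2 = panel.n_haplotypes
            if (pop, ia) not in written:
                col_a = np.zeros(n2, dtype=np.uint8)
                col_a[rng.permutation(n2)[: int(round(n2 * f_a))]] = 1
                panel.haplotypes[:, ia] = col_a
                written.add((pop, ia))
            a = panel.haplotypes[:, ia]
            d_max = min(f_a * (1.0 - f_b), (1.0 - f_a) * f_b)
            p_ab = f_a * f_b + plant.target_dprime * d_max
            p_b_given_a1 = p_ab / f_a
            p_b_given_a0 = (f_b - p_ab) / (1.0 - f_a)
            if not (0.0 <= p_b_given_a1 <= 1.0 and 0.0 <= p_b_given_a0 <= 1.0):
                raise ValueError(
                    f"target haplotype frequency {p_ab:.4f} violates the admissible "
                    f"range [max(0, {f_a}+{f_b}-1), min({f_a}, {f_b})] for allele "
                    f"frequencies ({f_a}, {f_b})"
                )
            u = rng.random(n2)
            col_b = np.where(
                a == 1, u < p_b_given_a1, u < p_b_given_a0
            ).astype(np.uint8)
            panel.haplotypes[:, ib] = col_b
            written.add((pop, ib))
    return out


def generate_admixed_panel(
    spec: AdmixtureSpec, n_individuals: int, seed: int = 0
) -> HaplotypePanel:
    """Pool two equilibrium subpopulations into one phased panel.

    Subpopulation 2 contributes ``round(mixing_ratio * n_individuals)``
    individuals.  Haplotypes are drawn independently per variant within each
    subpopulation, so the expected pooled two-locus D equals the closed form
    ``w (1 - w) (pA1 - pA2)(pB1 - pB2)``.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(spec.subpop_allele_freqs, dtype=float)
    m = freqs.shape[1]
    n2_sub2 = 2 * int(round(spec.mixing_ratio * n_individuals))
    n2_sub1 = 2 * n_individuals - n2_sub2
    h1 = (rng.random((n2_sub1, m)) < freqs[0][None, :]).astype(np.uint8)
    h2 = (rng.random((n2_sub2, m)) < freqs[1][None, :]).astype(np.uint8)
    positions = (
        np.asarray(spec.positions, dtype=np.int64)
        if spec.positions is not None
        else np.arange(1, m + 1) * 10_000_000
    )
    variants = pd.DataFrame(
        {
            "chrom": spec.chromosome,
            "pos": positions,
            "id": [f"adm{k:06d}" for k in range(m)],
            "ref": "A",
            "alt": "C",
        }
    )
    return HaplotypePanel(
        population="ADMIXED",
        samples=[f"ADM{i:04d}" for i in range(n_individuals)],
        variants=variants,
        haplotypes=np.concatenate([h1, h2], axis=0),
    )


@dataclass
class AnnotationTracks:
    """Annotation fixtures: gene models, region track, SVs and centromeres."""

    genes: list[GeneModel]
    annotation: RegionAnnotation
    sv_intervals: list[SVInterval]
    centromeres: dict[str, tuple[int, int]]


def generate_annotation_tracks(
    spec: PanelSpec,
    gene_density: float = 8.0,
    sv_density: float = 0.3,
    seed: int = 0,
) -> AnnotationTracks:
    """Random gene models, SV intervals and a centromere for the spec's chromosome.

    ``gene_density``/``sv_density`` are per megabase.  Genes are placed in
    disjoint slots (hence non-overlapping); ~80% are coding with UTR/CDS/intron
    structure.  SV lengths are drawn uniformly from 310-60,000 bp, the length
    range of common structural variants; exactly one centromere interval is
    emitted per chromosome.
    """
    if gene_density < 0 or sv_density < 0:
        raise ValueError("densities must be >= 0")
    rng = np.random.default_rng(seed)
    L = spec.chromosome_length
    chrom = spec.chromosome

    genes: list[GeneModel] = []
    n_genes = int(round(gene_density * L / 1e6))
    if n_genes > 0:
        slot = L // n_genes
        max_len = min(25_000, slot - 10_001)
        if max_len < 2_000:
            raise ValueError("gene_density too high for non-overlapping gene placement")
        for i in range(n_genes):
            slot_start = i * slot + 1
            length = int(rng.integers(2_000, max_len + 1))
            start = int(slot_start + 5_000 + rng.integers(0, max(1, slot - length - 10_000)))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            coding = bool(rng.random() < 0.8)
            name = f"gene{i:05d}"
            if coding:
                u5 = max(100, length // 20)
                u3 = max(150, length // 10)
                left, right = start + u5, end - u3
                n_exons = int(rng.integers(1, 4))
                cuts = np.sort(rng.integers(left + 1, right, size=2 * (n_exons - 1)))
                exon_bounds = [left, *cuts.tolist(), right]
                cds = tuple(
                    (exon_bounds[2 * k], exon_bounds[2 * k + 1]) for k in range(n_exons)
                )
                if strand == "+":
                    utr5, utr3 = ((start, left - 1),), ((right + 1, end),)
                else:
                    utr5, utr3 = ((right + 1, end),), ((start, left - 1),)
                genes.append(
                    GeneModel(chrom, start, end, strand, True, name, cds, utr5, utr3)
                )
            else:
                genes.append(GeneModel(chrom, start, end, strand, False, name))

    centromeres = {chrom: (L // 2 - 1_500_000, L // 2 + 1_500_000)}

    svs: list[SVInterval] = []
    n_sv = int(round(sv_density * L / 1e6))
    types = np.array(["deletion", "inversion", "CNV", "insertion"])
    for k in range(n_sv):
        sv_type = str(rng.choice(types, p=[0.5, 0.2, 0.2, 0.1]))
        length = 1 if sv_type == "insertion" else int(rng.integers(310, 60_001))
        start = int(rng.integers(1, L - length + 1))
        svs.append(SVInterval(chrom, start, start + length - 1, sv_type, f"esv{k:05d}"))

    annotation = RegionAnnotation.from_gene_models(genes, chromosomes=[chrom])
    return AnnotationTracks(genes, annotation, svs, centromeres)


def emit_fixture_set(
    output_dir: str | Path,
    panels: Mapping[str, HaplotypePanel],
    tracks: AnnotationTracks | None = None,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: VCF, sample lists, BED/GFF3 tracks.

    The VCF carries all populations' samples with phased GT; SV intervals are
    emitted both as esv-identified VCF records and as a typed BED.  Files
    round-trip losslessly through the package readers.
    """
    from . import io as _io

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    vcf_path = output_dir / "panel.vcf"
    _io.write_phased_vcf(
        panels, vcf_path, sv_records=tracks.sv_intervals if tracks else ()
    )
    paths["vcf"] = vcf_path

    for pop, panel in panels.items():
        p = output_dir / f"{pop}.samples.txt"
        p.write_text("".join(f"{s}\n" for s in panel.samples))
        paths[f"samples_{pop}"] = p

    if tracks is not None:
        paths["centromeres"] = output_dir / "centromeres.bed"
        _io.write_centromere_bed(tracks.centromeres, paths["centromeres"])
        paths["genes"] = output_dir / "genes.gff3"
        _io.write_genes_gff3(tracks.genes, paths["genes"])
        paths["svs"] = output_dir / "svs.bed"
        _io.write_sv_bed(tracks.sv_intervals, paths["svs"])
    return paths
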