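"""Phased haplotype panel container.

A :class:`HaplotypePanel` holds one population's phased biallelic haplotypes as a
``(2n, m)`` 0/1 matrix (two rows per diploid individual, one column per variant)
together with variant metadata.  Every LD computation in this package operates on
this container; after allele selection an entry of 1 always denotes the designated
analysis allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class HaplotypePanel:
    """Phased haplotypes for one population.

    Parameters
    ----------
    population
        Population label (e.g. ``"AFR"``).
    samples
        Diploid sample identifiers, length ``n``.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt`` (1-based positions),
        sorted by ``(chrom, pos)`` with unique positions per chromosome.
    haplotypes
        ``(2n, m)`` array of 0/1; rows ``2i`` and ``2i+1`` are the two phased
        haplotypes of sample ``i``.
    """

    population: str
    samples: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n2, m = self.haplotypes.shape
        if n2 != 2 * len(self.samples):
            raise ValueError(
                f"haplotype matrix has {n2} rows but {len(self.samples)} samples "
                "(expected 2 rows per sample)"
            )
        if m != len(self.variants):
            raise ValueError(
                f"haplotype matrix has {m} columns but {len(self.variants)} variant records"
            )
        if m and self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype entries must be 0/1 after allele selection")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on chromosome {chrom} not strictly increasing")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the analysis allele (the 1-coded allele) per variant."""
        return self.haplotypes.mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """``(n, m)`` matrix of analysis-allele copy counts per individual."""
        return (
            self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2].astype(np.int16)
        )

    def variant_index(self, chrom: str, pos: int) -> int:
        """Column index of the variant at ``(chrom, pos)``; KeyError if absent."""
        mask = (self.variants["chrom"] == str(chrom)) & (self.variants["pos"] == int(pos))
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size != 1:
            raise KeyError(f"variant {chrom}:{pos} not present exactly once in panel")
        return int(idx[0])

    def column(self, chrom: str, pos: int) -> np.ndarray:
        return self.haplotypes[:, self.variant_index(chrom, pos)]

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            population=self.population,
            samples=list(self.samples),
            variants=self.variants.copy(),
            haplotypes=self.haplotypes.copy(),
        )

    def subset_variants(self, indices: np.ndarray) -> "HaplotypePanel":
        indices = np.asarray(indices, dtype=int)
        return HaplotypePanel(
            population=self.population,
            samples=list(self.samples),
            variants=self.variants.iloc[indices],
            haplotypes=self.haplotypes[:, indices],
        )

    @classmethod
    def concat(cls, panels: list["HaplotypePanel"]) -> "HaplotypePanel":
        """Concatenate panels over disjoint chromosomes (same samples)."""
        first = panels[0]
        for p in panels[1:]:
            if p.samples != first.samples:
                raise ValueError("can only concatenate panels with identical samples")
        variants = pd.concat([p.variants for p in panels], ignore_index=True)
        haps = np.concatenate([p.haplotypes for p in panels], axis=1)
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
        return cls(first.population, list(first.samples), variants.iloc[order], haps[:, order])
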