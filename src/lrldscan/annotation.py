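"""Genic-region classification and structural-variant overlap statistics.

Positions are classified into ten mutually exclusive region codes:

    1 CDS                        6 within 1,000 bp upstream of a gene start
    2 5' UTR                     7 within 1,000 bp downstream of a gene end
    3 3' UTR                     8 within 5,000 bp upstream
    4 noncoding gene             9 within 5,000 bp downstream
    5 intron                    10 remaining nongenic

When a position overlaps several features (e.g. the CDS of one gene and the
intron of another) the lowest code wins, so CDS is the strongest call and
nongenic the weakest.  Upstream/downstream windows respect strand when the
annotation provides it and fall back to genome orientation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "CODE_LABELS",
    "GeneModel",
    "SVInterval",
    "RegionAnnotation",
    "classify_region",
    "region_proportions",
    "sv_overlap",
    "annotate_records",
]

CODE_LABELS = {
    1: "CDS",
    2: "five_prime_UTR",
    3: "three_prime_UTR",
    4: "noncoding_gene",
    5: "intron",
    6: "upstream_1kb",
    7: "downstream_1kb",
    8: "upstream_5kb",
    9: "downstream_5kb",
    10: "nongenic",
}

SV_TYPES = ("deletion", "inversion", "insertion", "CNV")


@dataclass(frozen=True)
class GeneModel:
    """A gene with optional coding structure; intervals are 1-based closed."""

    chrom: str
    start: int
    end: int
    strand: str | None = None  # '+', '-' or None (strand-agnostic)
    coding: bool = True
    name: str = ""
    cds: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class SVInterval:
    """A typed structural-variant interval (1-based closed; insertions are points)."""

    chrom: str
    start: int
    end: int
    sv_type: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(
                f"untyped or unknown SV type {self.sv_type!r}; expected one of {SV_TYPES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _subtract(span: tuple[int, int], parts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Closed-interval subtraction: span minus the union of parts."""
    gaps = []
    cur = span[0]
    for s, e in sorted(parts):
        if s > cur:
            gaps.append((cur, min(s - 1, span[1])))
        cur = max(cur, e + 1)
    if cur <= span[1]:
        gaps.append((cur, span[1]))
    return gaps


class RegionAnnotation:
    """Interval index mapping every covered-chromosome position to a region code."""

    def __init__(
        self,
        code_intervals: Mapping[str, Mapping[int, Iterable[tuple[int, int]]]],
        chromosomes: Iterable[str],
    ):
        """``code_intervals[chrom][code]`` lists 1-based closed intervals for codes 1-9.

        ``chromosomes`` declares the chromosomes the annotation covers; code 10
        is implicit (everything not hit by codes 1-9).
        """
        self.chromosomes = set(map(str, chromosomes))
        self._trees: dict[str, dict[int, IntervalTree]] = {}
        for chrom, by_code in code_intervals.items():
            chrom = str(chrom)
            self.chromosomes.add(chrom)
            trees = {}
            for code, intervals in by_code.items():
                if not 1 <= int(code) <= 9:
                    raise ValueError(f"region code {code} outside 1-9")
                tree = IntervalTree()
                for s, e in intervals:
                    if e >= s:
                        tree.addi(int(s), int(e) + 1)  # closed -> half-open
                trees[int(code)] = tree
            self._trees[chrom] = trees

    @classmethod
    def from_gene_models(
        cls, genes: Sequence[GeneModel], chromosomes: Iterable[str] = ()
    ) -> "RegionAnnotation":
        """Build the ten-code track from gene models.

        Coding genes contribute CDS/UTR intervals plus introns (gene body minus
        exonic parts); noncoding genes contribute their whole body as code 4.
        Flanking windows of 1 kb / 5 kb are placed on the 5' (upstream) and 3'
        (downstream) side, using strand when present.
        """
        intervals: dict[str, dict[int, list[tuple[int, int]]]] = {}
        chroms = set(map(str, chromosomes)) | {g.chrom for g in genes}
        for g in genes:
            by_code = intervals.setdefault(g.chrom, {c: [] for c in range(1, 10)})
            if g.coding:
                by_code[1].extend(g.cds)
                by_code[2].extend(g.utr5)
                by_code[3].extend(g.utr3)
                exonic = list(g.cds) + list(g.utr5) + list(g.utr3)
                by_code[5].extend(_subtract((g.start, g.end), exonic))
            else:
                by_code[4].append((g.start, g.end))
            if g.strand == "-":
                up1 = (g.end + 1, g.end + 1000)
                up5 = (g.end + 1, g.end + 5000)
                down1 = (max(1, g.start - 1000), g.start - 1)
                down5 = (max(1, g.start - 5000), g.start - 1)
            else:
                up1 = (max(1, g.start - 1000), g.start - 1)
                up5 = (max(1, g.start - 5000), g.start - 1)
                down1 = (g.end + 1, g.end + 1000)
                down5 = (g.end + 1, g.end + 5000)
            by_code[6].append(up1)
            by_code[8].append(up5)
            by_code[7].append(down1)
            by_code[9].append(down5)
        return cls(intervals, chroms)

    def classify(self, chrom: str, pos: int) -> int:
        """Region code (1-10) of a position; lowest overlapping code wins."""
        chrom = str(chrom)
        if chrom not in self.chromosomes:
            raise KeyError(f"chromosome {chrom} not covered by this annotation")
        trees = self._trees.get(chrom, {})
        for code in range(1, 10):
            tree = trees.get(code)
            if tree is not None and tree[int(pos)]:
                return code
        return 10

    def classify_many(self, positions: Iterable[tuple[str, int]]) -> np.ndarray:
        return np.array([self.classify(c, p) for c, p in positions], dtype=int)


def classify_region(position: tuple[str, int], annotation: RegionAnnotation) -> int:
    """Functional wrapper: region code of ``(chrom, pos)`` under ``annotation``."""
    chrom, pos = position
    return annotation.classify(chrom, pos)


def region_proportions(
    variant_sets: Mapping[str, Sequence[tuple[str, int]]],
    annotation: RegionAnnotation,
) -> pd.DataFrame:
    """Per-class proportions of variants in each of the ten region codes.

    ``variant_sets`` maps a class label (e.g. ``"all tested"``, ``"LRLD"``,
    ``"hotspots"``) to its (chrom, pos) variants.  Rows sum to 1.
    """
    rows = {}
    for label, variants in variant_sets.items():
        variants = list(variants)
        if not variants:
            raise ValueError(f"variant set {label!r} is empty")
        codes = annotation.classify_many(variants)
        counts = np.bincount(codes, minlength=11)[1:11]
        rows[label] = counts / counts.sum()
    return pd.DataFrame(rows, index=pd.Index(range(1, 11), name="code")).T


@dataclass
class SVOverlapReport:
    """Structural-variant overlap statistics for one variant set."""

    n_variants: int
    n_in_deletion_or_inversion: int
    pct_in_deletion_or_inversion: float
    n_on_insertion: int
    pct_on_insertion: float
    per_sv: pd.DataFrame = field(repr=False)
    sv_length_mean: float = float("nan")
    sv_length_min: float = float("nan")
    sv_length_max: float = float("nan")


def sv_overlap(
    variants: Sequence[tuple[str, int]],
    sv_intervals: Sequence[SVInterval],
) -> SVOverlapReport:
    """Overlap of a variant set with typed structural-variant intervals.

    Counts variants inside deletion/inversion intervals and on insertion
    positions, and tallies per-SV contained-variant counts with length
    statistics over the SVs that contain at least one variant.
    """
    variants = list(variants)
    trees: dict[str, IntervalTree] = {}
    sv_by_id = {}
    for k, sv in enumerate(sv_intervals):
        key = sv.id or f"sv{k}"
        sv_by_id[key] = sv
        trees.setdefault(sv.chrom, IntervalTree()).addi(sv.start, sv.end + 1, key)

    n_delinv = 0
    n_ins = 0
    hits: dict[str, int] = {}
    for chrom, pos in variants:
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        in_delinv = False
        on_ins = False
        for iv in tree[int(pos)]:
            sv = sv_by_id[iv.data]
            hits[iv.data] = hits.get(iv.data, 0) + 1
            if sv.sv_type in ("deletion", "inversion"):
                in_delinv = True
            elif sv.sv_type == "insertion":
                on_ins = True
        n_delinv += in_delinv
        n_ins += on_ins

    per_sv = pd.DataFrame(
        [
            {
                "id": key,
                "chrom": sv_by_id[key].chrom,
                "start": sv_by_id[key].start,
                "end": sv_by_id[key].end,
                "sv_type": sv_by_id[key].sv_type,
                "length": sv_by_id[key].length,
                "n_variants": n,
            }
            for key, n in sorted(hits.items())
        ],
        columns=["id", "chrom", "start", "end", "sv_type", "length", "n_variants"],
    )
    n_tot = len(variants)
    lengths = per_sv["length"].to_numpy() if len(per_sv) else np.array([])
    return SVOverlapReport(
        n_variants=n_tot,
        n_in_deletion_or_inversion=n_delinv,
        pct_in_deletion_or_inversion=100.0 * n_delinv / n_tot if n_tot else 0.0,
        n_on_insertion=n_ins,
        pct_on_insertion=100.0 * n_ins / n_tot if n_tot else 0.0,
        per_sv=per_sv,
        sv_length_mean=float(lengths.mean()) if lengths.size else float("nan"),
        sv_length_min=float(lengths.min()) if lengths.size else float("nan"),
        sv_length_max=float(lengths.max()) if lengths.size else float("nan"),
    )


def annotate_records(
    records: pd.DataFrame,
    annotation: RegionAnnotation | None = None,
    sv_intervals: Sequence[SVInterval] = (),
) -> pd.DataFrame:
    """Attach region codes and SV membership flags to scan records.

    Adds ``region_code_a/b`` (1-10) when an annotation is given and
    ``sv_flag_a/b`` (inside any non-insertion SV interval) when SV intervals
    are given.
    """
    out = records.copy()
    if annotation is not None:
        out["region_code_a"] = [
            annotation.classify(c, p) for c, p in zip(out["chromosome"], out["pos_a"])
        ]
        out["region_code_b"] = [
            annotation.classify(c, p) for c, p in zip(out["chromosome"], out["pos_b"])
        ]
    trees: dict[str, IntervalTree] = {}
    for sv in sv_intervals:
        if sv.sv_type == "insertion":
            continue
        trees.setdefault(sv.chrom, IntervalTree()).addi(sv.start, sv.end + 1)

    def _flag(chrom, pos) -> bool:
        tree = trees.get(str(chrom))
        return bool(tree and tree[int(pos)])

    if sv_intervals:
        out["sv_flag_a"] = [_flag(c, p) for c, p in zip(out["chromosome"], out["pos_a"])]
        out["sv_flag_b"] = [_flag(c, p) for c, p in zip(out["chromosome"], out["pos_b"])]
    return out
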