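"""Readers and writers for the formats the pipeline touches.

Conventions: internal coordinates are 1-based closed (VCF-native); BED input
(0-based half-open) is converted at the boundary.  Phased VCF records are read
with cyvcf2; any record with an unphased or missing genotype among the
selected samples is rejected and counted rather than imputed, because the
scan's accuracy rests on the input phasing.  Records whose ID starts with
"esv" are structural variants and are routed to the SV track instead of the
haplotype matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import GeneModel, SVInterval
from .panel import HaplotypePanel

__all__ = [
    "VcfReadResult",
    "read_sample_list",
    "read_phased_vcf",
    "select_analysis_allele",
    "read_region_bed",
    "read_sv_bed",
    "read_genes_gff3",
    "write_phased_vcf",
    "write_centromere_bed",
    "write_sv_bed",
    "write_genes_gff3",
    "write_results",
]

_SVTYPE_MAP = {
    "DEL": "deletion",
    "INV": "inversion",
    "INS": "insertion",
    "CNV": "CNV",
    "DUP": "CNV",
}


def read_sample_list(path: str | Path) -> list[str]:
    """Plain-text sample list, one ID per line; blank lines ignored."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def select_analysis_allele(pooled_alt_freqs: Sequence[float]) -> int:
    """Index (0-based into the ALT list) of the analysis allele.

    The alternate allele with the largest minor allele frequency
    ``min(f, 1 - f)`` pooled over all configured populations is selected; ties
    break toward the first-listed allele.
    """
    freqs = np.asarray(pooled_alt_freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("variant has no alternate alleles")
    maf = np.minimum(freqs, 1.0 - freqs)
    return int(np.argmax(maf))


@dataclass
class VcfReadResult:
    """Panels per population plus a rejection/routing report."""

    panels: dict[str, HaplotypePanel]
    sv_records: list[SVInterval] = field(default_factory=list)
    n_unphased_rejected: int = 0
    n_monomorphic_skipped: int = 0
    n_multiallelic_recoded: int = 0


def read_phased_vcf(
    path: str | Path, samples_by_pop: Mapping[str, Sequence[str]]
) -> VcfReadResult:
    """Read a phased VCF into one HaplotypePanel per population.

    ``samples_by_pop`` maps population label to its sample IDs (all must exist
    in the VCF).  Multi-allelic sites are recoded to the analysis allele
    selected by pooled MAF over all listed samples; records with any unphased
    or missing genotype among the listed samples are rejected and counted.
    """
    from cyvcf2 import VCF

    all_samples: list[str] = []
    for pop in samples_by_pop:
        all_samples.extend(samples_by_pop[pop])
    vcf = VCF(str(path), samples=all_samples, gts012=False)
    have = set(vcf.samples)
    missing = [s for s in all_samples if s not in have]
    if missing:
        raise ValueError(f"samples not present in VCF: {missing[:5]}...")
    order = {s: i for i, s in enumerate(vcf.samples)}
    pop_cols = {
        pop: np.array([order[s] for s in samples], dtype=int)
        for pop, samples in samples_by_pop.items()
    }

    result = VcfReadResult(panels={})
    meta_rows = []
    columns: list[np.ndarray] = []  # per-variant haplotype vector over all samples
    n_sel = len(vcf.samples)

    for var in vcf:
        vid = var.ID or ""
        if vid.startswith("esv"):
            svtype = _SVTYPE_MAP.get(str(var.INFO.get("SVTYPE", "CNV")), "CNV")
            end = int(var.INFO.get("END", var.end))
            result.sv_records.append(
                SVInterval(str(var.CHROM), int(var.POS), end, svtype, vid)
            )
            continue
        gts = var.genotypes  # [a1, a2, phased] per selected sample
        alleles = np.empty((n_sel, 2), dtype=np.int16)
        ok = True
        for i, g in enumerate(gts):
            if len(g) < 3 or not g[2] or g[0] < 0 or g[1] < 0:
                ok = False
                break
            alleles[i, 0], alleles[i, 1] = g[0], g[1]
        if not ok:
            result.n_unphased_rejected += 1
            continue
        flat = alleles.reshape(-1)
        n_alt = len(var.ALT)
        if n_alt > 1:
            pooled = np.array(
                [np.mean(flat == k) for k in range(1, n_alt + 1)], dtype=float
            )
            sel = select_analysis_allele(pooled) + 1
            result.n_multiallelic_recoded += 1
            alt_allele = var.ALT[sel - 1]
        else:
            sel = 1
            alt_allele = var.ALT[0] if var.ALT else "."
        hap = (flat == sel).astype(np.uint8)
        if hap.min() == hap.max():
            result.n_monomorphic_skipped += 1
            continue
        columns.append(hap)
        meta_rows.append(
            {"chrom": str(var.CHROM), "pos": int(var.POS), "id": vid or ".",
             "ref": var.REF, "alt": alt_allele}
        )
    vcf.close()

    variants = pd.DataFrame(meta_rows, columns=["chrom", "pos", "id", "ref", "alt"])
    matrix = (
        np.stack(columns, axis=1) if columns else np.zeros((2 * n_sel, 0), np.uint8)
    )
    for pop, cols in pop_cols.items():
        hap_rows = np.empty(2 * cols.size, dtype=int)
        hap_rows[0::2] = 2 * cols
        hap_rows[1::2] = 2 * cols + 1
        result.panels[pop] = HaplotypePanel(
            population=pop,
            samples=list(samples_by_pop[pop]),
            variants=variants.copy(),
            haplotypes=matrix[hap_rows],
        )
    return result


def read_region_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED3+ intervals as 1-based closed, sorted per chromosome; no merging."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: expected at least 3 BED columns")
        try:
            start0, end0 = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from exc
        if end0 <= start0:
            raise ValueError(f"{path}:{ln}: empty or inverted BED interval")
        intervals.setdefault(parts[0], []).append((start0 + 1, end0))
    for chrom in intervals:
        intervals[chrom].sort()
    return intervals


def read_sv_bed(path: str | Path) -> list[SVInterval]:
    """Typed SV BED: chrom, start, end, id, type (deletion|inversion|insertion|CNV)."""
    svs: list[SVInterval] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 5:
            raise ValueError(f"{path}:{ln}: SV BED needs chrom,start,end,id,type")
        try:
            sv = SVInterval(parts[0], int(parts[1]) + 1, int(parts[2]), parts[4], parts[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from exc
        svs.append(sv)
    return svs


def _gff3_attrs(text: str) -> dict[str, str]:
    return dict(
        kv.split("=", 1) for kv in text.strip().split(";") if kv and "=" in kv
    )


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Gene models from GFF3 gene/CDS/UTR features (1-based closed, as in GFF3)."""
    genes: dict[str, dict] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
        chrom, _, ftype, start, end, _, strand, _, attrs_text = parts
        start, end = int(start), int(end)
        attrs = _gff3_attrs(attrs_text)
        if ftype in ("gene", "ncRNA_gene"):
            gid = attrs.get("ID", f"gene_at_{chrom}:{start}")
            coding = ftype == "gene" and attrs.get("biotype", "protein_coding") not in (
                "noncoding", "ncRNA"
            )
            genes[gid] = {
                "chrom": chrom, "start": start, "end": end,
                "strand": strand if strand in "+-" else None,
                "coding": coding, "name": gid,
                "cds": [], "utr5": [], "utr3": [],
            }
        elif ftype in ("CDS", "five_prime_UTR", "three_prime_UTR"):
            parent = attrs.get("Parent")
            if parent not in genes:
                raise ValueError(f"{path}:{ln}: feature with unknown Parent {parent!r}")
            key = {"CDS": "cds", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}[ftype]
            genes[parent][key].append((start, end))
    return [
        GeneModel(
            g["chrom"], g["start"], g["end"], g["strand"], g["coding"], g["name"],
            tuple(sorted(g["cds"])), tuple(sorted(g["utr5"])), tuple(sorted(g["utr3"])),
        )
        for g in genes.values()
    ]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_phased_vcf(
    panels: Mapping[str, HaplotypePanel],
    path: str | Path,
    sv_records: Sequence[SVInterval] = (),
) -> None:
    """Write the merged multi-population panel as a phased VCF 4.2 text file."""
    pops = list(panels)
    first = panels[pops[0]]
    for pop in pops[1:]:
        if not first.variants[["chrom", "pos"]].equals(panels[pop].variants[["chrom", "pos"]]):
            raise ValueError("panels must share a variant universe to write one VCF")
    samples = [s for pop in pops for s in panels[pop].samples]

    sv_alt = {"deletion": "<DEL>", "inversion": "<INV>", "insertion": "<INS>", "CNV": "<CNV>"}
    sv_code = {"deletion": "DEL", "inversion": "INV", "insertion": "INS", "CNV": "CNV"}
    n_total = len(samples)

    rows: list[tuple[str, int, str]] = []
    for k in range(first.n_variants):
        meta = first.variants.iloc[k]
        gts = []
        for pop in pops:
            H = panels[pop].haplotypes
            for i in range(panels[pop].n_samples):
                gts.append(f"{H[2 * i, k]}|{H[2 * i + 1, k]}")
        line = (
            f"{meta['chrom']}\t{meta['pos']}\t{meta['id']}\t{meta['ref']}\t"
            f"{meta['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
        rows.append((str(meta["chrom"]), int(meta["pos"]), line))
    null_gt = "\t".join(["0|0"] * n_total)
    for sv in sv_records:
        info = f"SVTYPE={sv_code[sv.sv_type]};END={sv.end}"
        line = (
            f"{sv.chrom}\t{sv.start}\t{sv.id or '.'}\tN\t{sv_alt[sv.sv_type]}\t.\tPASS\t"
            f"{info}\tGT\t{null_gt}"
        )
        rows.append((sv.chrom, sv.start, line))
    rows.sort(key=lambda r: (r[0], r[1]))

    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for alt_id in ("DEL", "INV", "INS", "CNV"):
        header.append(f"##ALT=<ID={alt_id},Description=\"{alt_id}\">")
    for chrom in dict.fromkeys(r[0] for r in rows):
        header.append(f"##contig=<ID={chrom}>")
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    Path(path).write_text("\n".join(header + [r[2] for r in rows]) + "\n")


def write_centromere_bed(
    centromeres: Mapping[str, tuple[int, int]], path: str | Path
) -> None:
    lines = [
        f"{chrom}\t{start - 1}\t{end}\tcentromere"
        for chrom, (start, end) in sorted(centromeres.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_sv_bed(svs: Sequence[SVInterval], path: str | Path) -> None:
    lines = [
        f"{sv.chrom}\t{sv.start - 1}\t{sv.end}\t{sv.id or '.'}\t{sv.sv_type}"
        for sv in sorted(svs, key=lambda s: (s.chrom, s.start))
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_genes_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        strand = g.strand or "."
        biotype = "protein_coding" if g.coding else "noncoding"
        lines.append(
            f"{g.chrom}\tlrldscan\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t"
            f"ID={g.name};biotype={biotype}"
        )
        for ftype, parts in (("five_prime_UTR", g.utr5), ("CDS", g.cds),
                             ("three_prime_UTR", g.utr3)):
            for s, e in parts:
                lines.append(
                    f"{g.chrom}\tlrldscan\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\tParent={g.name}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(
    frame: pd.DataFrame,
    path: str | Path,
    metadata: Mapping | None = None,
    sort_by: Sequence[str] | None = None,
    input_paths: Sequence[str | Path] = (),
) -> None:
    """Deterministic TSV with a JSON run-metadata sidecar.

    Rows are sorted by ``sort_by`` (default: all columns) and columns kept in
    frame order; the sidecar records the package version, caller-supplied
    metadata (config, seed, ...) and SHA-256 digests of any input files.
    """
    path = Path(path)
    out = frame.copy()
    keys = list(sort_by) if sort_by else list(out.columns)
    if keys and len(out):
        out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False)
    sidecar = {
        "version": __version__,
        "metadata": dict(metadata or {}),
        "inputs": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in input_paths
        },
        "columns": list(out.columns),
        "n_rows": int(len(out)),
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True, default=str) + "\n"
    )
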