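"""Map candidate SNPs to nearby genes within a symmetric distance window.

Coordinates are 1-based inclusive internally (VCF/GFF3 convention); BED input
(0-based half-open) is converted on read. Distance is 0 for a SNP inside a
gene, otherwise the gap to the nearest gene edge; strand is carried but not
used (the window is symmetric upstream/downstream, as with bedtools closest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 50_000


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class OverlapRecord:
    snp_id: str
    gene_id: str
    distance: int  # bp; 0 when the SNP lies within the gene


def read_annotation(path, fmt: str | None = None) -> list[GeneInterval]:
    """Read gene intervals from GFF3 (gene-type rows only) or BED4+.

    BED's 0-based half-open coordinates are converted to 1-based inclusive.
    Malformed lines raise with their line number; non-gene GFF3 rows are
    skipped with a logged count.
    """
    path = str(path)
    if fmt is None:
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gff3(path: str) -> list[GeneInterval]:
    genes, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line has {len(fields)} fields, expected 9")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            if ftype != "gene":
                skipped += 1
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            gid = _gff3_id(attrs) or f"gene_at_{chrom}:{s}"
            genes.append(GeneInterval(gid, chrom, s, e, strand))
    if skipped:
        log.info("read_annotation: skipped %d non-gene GFF3 rows", skipped)
    return genes


def _gff3_id(attrs: str) -> str | None:
    for pair in attrs.split(";"):
        if "=" in pair:
            k, v = pair.split("=", 1)
            if k.strip() in ("ID", "gene_id", "Name"):
                return v.strip()
    return None


def _read_bed(path: str) -> list[GeneInterval]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 fields (chrom start end name)")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                s, e = int(start), int(end)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            genes.append(GeneInterval(name, chrom, s + 1, e, strand))  # to 1-based inclusive
    return genes


def closest_genes(
    snps: pd.DataFrame,
    genes: list[GeneInterval],
    window: int = DEFAULT_WINDOW,
) -> list[OverlapRecord]:
    """All genes within ``window`` bp of each SNP (inclusive boundary).

    ``snps`` is a marker table with columns id, chrom, pos. SNPs on
    chromosomes absent from the annotation yield no records. Results are
    sorted by (snp_id, gene_id) so output is invariant to input order.
    """
    trees: dict[str, IntervalTree] = {}
    by_iv: dict[tuple, GeneInterval] = {}
    for gene in genes:
        # inflate each gene by the window; intervaltree is half-open, so +1 on end
        lo, hi = gene.start - window, gene.end + window + 1
        trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, gene)
    records = []
    for row in snps.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.at(int(row.pos)):
            gene = iv.data
            if row.pos < gene.start:
                d = gene.start - int(row.pos)
            elif row.pos > gene.end:
                d = int(row.pos) - gene.end
            else:
                d = 0
            if d <= window:
                records.append(OverlapRecord(str(row.id), gene.gene_id, d))
    return sorted(records, key=lambda r: (r.snp_id, r.gene_id))


def direct_overlap_filter(records: list[OverlapRecord]) -> set[str]:
    """Gene ids with at least one SNP at distance 0 (deduplicated per gene)."""
    return {r.gene_id for r in records if r.distance == 0}


def genes_of_candidates(records: list[OverlapRecord]) -> set[str]:
    """Deduplicated gene set hit by any candidate SNP within the window."""
    return {r.gene_id for r in records}


def snp_gene_map(records: list[OverlapRecord]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for r in records:
        out.setdefault(r.snp_id, set()).add(r.gene_id)
    return out


def write_overlaps(records: list[OverlapRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)
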