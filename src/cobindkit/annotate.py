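"""Genomic-distribution classification of peaks relative to gene models.

Each peak is represented by a single anchor point (summit when present,
else midpoint) and assigned to exactly one category with the priority
promoter > exonic > intronic > intergenic, so the categories always
partition the peak set. "Promoter" means the anchor lies within a fixed
distance (default 1 kb) of some transcription start site, on either side;
the strand-aware upstream-only variant is computed alongside because both
definitions are in common use. A gene with no exon annotation counts its
whole span as intronic for anchors inside it (gene-body fallback).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import Peak, PeakSet

CATEGORIES = ("promoter", "exonic", "intronic", "intergenic")
DEFAULT_PROMOTER_BP = 1000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span for {self.gene_id}")
        if self.exons:
            prev = self.start - 1
            for s, e in self.exons:
                if not (self.start <= s < e <= self.end) or s < prev:
                    raise ValueError(f"bad exons for {self.gene_id}")
                prev = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class LocationBreakdown:
    percentages: dict[str, float]
    counts: dict[str, int]
    upstream_promoter_percent: float
    n_peaks: int


def read_gene_models(path) -> list[GeneModel]:
    """Read a BED6/BED12-like gene model TSV.

    Columns: chrom, start, end, gene_id, score, strand and optionally
    blockCount, blockSizes, blockStarts (comma lists, BED12 style) for
    exons.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns")
            chrom, start, end, gid, _score, strand = f[:6]
            start, end = int(start), int(end)
            exons = None
            if len(f) >= 9 and f[6]:
                sizes = [int(x) for x in f[7].rstrip(",").split(",")]
                offs = [int(x) for x in f[8].rstrip(",").split(",")]
                if len(sizes) != int(f[6]) or len(offs) != int(f[6]):
                    raise ValueError(f"{path}:{lineno}: block count mismatch")
                exons = tuple(
                    (start + o, start + o + s) for o, s in zip(offs, sizes)
                )
            genes.append(GeneModel(gid, chrom, strand, start, end, exons))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cols = [g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand]
            if g.exons:
                cols += [
                    str(len(g.exons)),
                    ",".join(str(e - s) for s, e in g.exons),
                    ",".join(str(s - g.start) for s, _ in g.exons),
                ]
            fh.write("\t".join(cols) + "\n")


class GeneIndex:
    """Per-chromosome TSS arrays and gene span lists for fast lookups."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
        for g in genes:
            by_chrom[g.chrom].append(g)
        self.tss: dict[str, np.ndarray] = {}
        self.tss_strand: dict[str, np.ndarray] = {}
        self.spans: dict[str, list[GeneModel]] = {}
        for chrom, gs in by_chrom.items():
            order = np.argsort([g.tss for g in gs], kind="stable")
            self.tss[chrom] = np.asarray([gs[i].tss for i in order])
            self.tss_strand[chrom] = np.asarray(
                [1 if gs[i].strand == "+" else -1 for i in order]
            )
            self.spans[chrom] = sorted(gs, key=lambda g: g.start)

    def near_tss(self, chrom: str, pos: int, dist: int) -> bool:
        t = self.tss.get(chrom)
        if t is None or len(t) == 0:
            return False
        i = np.searchsorted(t, pos)
        for j in (i - 1, i):
            if 0 <= j < len(t) and abs(int(t[j]) - pos) <= dist:
                return True
        return False

    def upstream_of_tss(self, chrom: str, pos: int, dist: int) -> bool:
        t = self.tss.get(chrom)
        if t is None or len(t) == 0:
            return False
        lo = int(np.searchsorted(t, pos - dist, side="left"))
        hi = int(np.searchsorted(t, pos + dist, side="right"))
        for j in range(lo, hi):
            delta = pos - int(t[j])  # >0 means downstream of a + strand TSS
            strand = int(self.tss_strand[chrom][j])
            if -dist <= delta * strand < 0:
                return True
        return False

    def covering_genes(self, chrom: str, pos: int) -> list[GeneModel]:
        return [
            g for g in self.spans.get(chrom, []) if g.start <= pos < g.end
        ]


def classify_peak_location(
    p: Peak,
    genes: GeneIndex | Sequence[GeneModel],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> str:
    """Assign one category to a peak by its anchor point.

    Priority: promoter (anchor within ``promoter_bp`` of a TSS, either
    side) > exonic > intronic > intergenic.
    """
    idx = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    anchor = p.anchor
    if idx.near_tss(p.chrom, anchor, promoter_bp):
        return "promoter"
    covering = idx.covering_genes(p.chrom, anchor)
    if not covering:
        return "intergenic"
    for g in covering:
        if g.exons and any(s <= anchor < e for s, e in g.exons):
            return "exonic"
    return "intronic"


def genomic_distribution(
    peaks: PeakSet,
    genes: GeneIndex | Sequence[GeneModel],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> LocationBreakdown:
    """Per-category percentages over all peaks, plus the strand-aware
    upstream-only promoter percentage as a separate statistic."""
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    idx = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    counts = {c: 0 for c in CATEGORIES}
    upstream = 0
    for p in peaks:
        counts[classify_peak_location(p, idx, promoter_bp)] += 1
        if idx.upstream_of_tss(p.chrom, p.anchor, promoter_bp):
            upstream += 1
    n = len(peaks)
    return LocationBreakdown(
        percentages={c: 100.0 * k / n for c, k in counts.items()},
        counts=counts,
        upstream_promoter_percent=100.0 * upstream / n,
        n_peaks=n,
    )
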