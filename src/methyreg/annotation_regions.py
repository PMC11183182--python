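"""Regulatory, CDS and intergenic region assignment.

The regulatory region (RR) of a gene runs from ``upstream_bp`` (default 500)
upstream of the A of the ATG start codon to ``downstream_bp`` (default 100)
downstream, the downstream window counted with the A itself as position 1.
When the window would overlap the nearest upstream gene on the same strand,
the RR is truncated to start at the base immediately after that gene's end
(mirrored arithmetic on the minus strand, where upstream means higher
coordinates). An upstream gene overlapping the start codon collapses the RR
to the downstream window alone.

Intergenic regions are the complement of CDS union RR, so every contig base
belongs to at least one region kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import BedInterval, GeneRecord, GenomeSequence


@dataclass(frozen=True)
class RegionConfig:
    upstream_bp: int = 500
    downstream_bp: int = 100
    truncate_same_strand_only: bool = True
    # When False, intergenic = complement of CDS only (RRs ignored).
    intergenic_excludes_regulatory: bool = True

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("upstream_bp and downstream_bp must be non-negative")


@dataclass(frozen=True)
class RegionAssignment:
    """A gene-anchored (or intergenic) interval, 1-based inclusive.

    ``anchor`` is the genomic coordinate of the A of the gene's start codon
    (gene.start on '+', gene.end on '-'); None for intergenic. ``wrap`` marks
    a circular-origin-spanning region covering [start..contig_end] + [1..end].
    """

    contig_id: str
    kind: str  # regulatory | CDS | intergenic
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    gene_id: Optional[str] = None
    anchor: Optional[int] = None
    wrap: bool = False

    def __post_init__(self) -> None:
        if not self.wrap and self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.kind not in ("regulatory", "CDS", "intergenic"):
            raise ValueError(f"unknown region kind {self.kind!r}")

    def contains(self, position: int) -> bool:
        if self.wrap:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


def assign_regulatory_region(
    gene: GeneRecord,
    neighbors: Sequence[GeneRecord],
    config: RegionConfig,
    contig_length: int,
    circular: bool = False,
) -> RegionAssignment:
    """Place the regulatory region of ``gene`` among same-contig ``neighbors``."""
    if gene.start < 1 or gene.end > contig_length:
        raise ValueError(
            f"gene {gene.gene_id} at {gene.start}..{gene.end} outside contig "
            f"of length {contig_length}"
        )
    up, down = config.upstream_bp, config.downstream_bp
    others = [
        n
        for n in neighbors
        if n.gene_id != gene.gene_id
        and (n.strand == gene.strand or not config.truncate_same_strand_only)
    ]

    if gene.strand == "+":
        anchor = gene.start
        raw_start = anchor - up
        end = anchor + down - 1
        upstream = [n for n in others if n.start < anchor]
        if upstream:
            e = max(n.end for n in upstream)
            if e >= anchor:
                raw_start = anchor  # degenerate: downstream window only
            elif e >= raw_start:
                raw_start = e + 1
        start = raw_start
    else:
        anchor = gene.end
        start = anchor - down + 1
        raw_end = anchor + up
        upstream = [n for n in others if n.end > anchor]
        if upstream:
            b = min(n.start for n in upstream)
            if b <= anchor:
                raw_end = anchor
            elif b <= raw_end:
                raw_end = b - 1
        end = raw_end

    wrap = False
    if circular:
        if start < 1:
            start = contig_length + start
            wrap = True
        if end > contig_length:
            end = end - contig_length
            wrap = True
    else:
        start = max(1, start)
        end = min(contig_length, end)

    return RegionAssignment(
        contig_id=gene.contig_id,
        kind="regulatory",
        start=start,
        end=end,
        strand=gene.strand,
        gene_id=gene.gene_id,
        anchor=anchor,
        wrap=wrap,
    )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def derive_all_regions(
    genes: Sequence[GeneRecord],
    genome: GenomeSequence,
    config: RegionConfig = RegionConfig(),
) -> list[RegionAssignment]:
    """One regulatory + one CDS region per gene, plus maximal intergenic gaps.

    Regions may overlap one another (a site can sit in gene A's RR and gene
    B's CDS at once); the union of all three kinds covers the contig.
    """
    contig_genes = [g for g in genes if g.contig_id == genome.contig_id]
    regions: list[RegionAssignment] = []
    covered: list[tuple[int, int]] = []
    for gene in sorted(contig_genes, key=lambda g: (g.start, g.end, g.gene_id)):
        rr = assign_regulatory_region(
            gene, contig_genes, config, genome.length, circular=genome.circular
        )
        cds = RegionAssignment(
            contig_id=gene.contig_id,
            kind="CDS",
            start=gene.start,
            end=gene.end,
            strand=gene.strand,
            gene_id=gene.gene_id,
            anchor=gene.start if gene.strand == "+" else gene.end,
        )
        regions.extend([rr, cds])
        covered.append((cds.start, cds.end))
        if config.intergenic_excludes_regulatory:
            if rr.wrap:
                covered.extend([(rr.start, genome.length), (1, rr.end)])
            else:
                covered.append((rr.start, rr.end))

    cursor = 1
    for s, e in _merge_intervals(covered):
        if s > cursor:
            regions.append(
                RegionAssignment(
                    contig_id=genome.contig_id,
                    kind="intergenic",
                    start=cursor,
                    end=s - 1,
                    strand=".",
                )
            )
        cursor = max(cursor, e + 1)
    if cursor <= genome.length:
        regions.append(
            RegionAssignment(
                contig_id=genome.contig_id,
                kind="intergenic",
                start=cursor,
                end=genome.length,
                strand=".",
            )
        )
    return regions


def region_bed_rows(region: RegionAssignment, contig_length: int) -> list[BedInterval]:
    """BED rows for a region; origin-wrapping regions emit two rows, one name."""
    name = region.gene_id or "intergenic"
    if region.wrap:
        return [
            BedInterval(region.contig_id, region.start, contig_length, name, 0, region.strand),
            BedInterval(region.contig_id, 1, region.end, name, 0, region.strand),
        ]
    return [BedInterval(region.contig_id, region.start, region.end, name, 0, region.strand)]
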