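"""Site-to-region placement, methylated-gene tables and the ATG-relative
location-enrichment profile.

A classified site lands in every region that contains its methylated base
(multi-assignment: the same base can sit in gene A's regulatory region and
gene B's CDS). Offsets are strand-aware and relative to the A of the gene's
ATG start codon: negative upstream, 0 at the A itself.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation_regions import RegionAssignment
from .site_classification import ClassifiedSite


@dataclass(frozen=True)
class SiteRegionHit:
    site: ClassifiedSite
    region: RegionAssignment
    offset_from_start_codon: Optional[int]  # present for regulatory/CDS regions

    @property
    def gene_id(self) -> Optional[str]:
        return self.region.gene_id


@dataclass
class EnrichmentProfile:
    """Per-offset, per-label site counts across regulatory regions."""

    window: tuple[int, int]  # inclusive offsets, e.g. (-500, 99)
    counts: Counter = field(default_factory=Counter)  # (offset, label) -> count

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"offset": off, "label": lab, "count": n}
            for (off, lab), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["offset", "label", "count"])


def _offset(region: RegionAssignment, position: int) -> Optional[int]:
    if region.anchor is None:
        return None
    if region.strand == "+":
        return position - region.anchor
    return region.anchor - position


def intersect_sites_regions(
    sites: Sequence[ClassifiedSite],
    regions: Sequence[RegionAssignment],
    include_low_coverage: bool = False,
) -> list[SiteRegionHit]:
    """One hit per (site, overlapping region) pair.

    Implemented with a per-contig interval tree over the regions, queried at
    each site's methylated base; low-coverage sites are excluded from
    downstream tallies by default.
    """
    trees: dict[str, IntervalTree] = {}
    wrapped: dict[str, list[RegionAssignment]] = {}
    for region in regions:
        if region.wrap:
            wrapped.setdefault(region.contig_id, []).append(region)
            continue
        trees.setdefault(region.contig_id, IntervalTree()).addi(
            region.start, region.end + 1, region
        )
    hits: list[SiteRegionHit] = []
    for site in sites:
        if site.label == "low_coverage" and not include_low_coverage:
            continue
        pos = site.position
        matched = [iv.data for iv in trees.get(site.contig_id, IntervalTree())[pos]]
        matched += [r for r in wrapped.get(site.contig_id, []) if r.contains(pos)]
        for region in matched:
            hits.append(
                SiteRegionHit(
                    site=site,
                    region=region,
                    offset_from_start_codon=_offset(region, pos),
                )
            )
    hits.sort(
        key=lambda h: (
            h.site.contig_id,
            h.site.position,
            h.site.strand,
            h.region.kind,
            h.region.gene_id or "",
            h.region.start,
        )
    )
    return hits


GENESET_COLUMNS = (
    "contig",
    "gene_id",
    "motif",
    "label",
    "position",
    "strand",
    "offset",
    "region_kind",
    "qv",
    "fraction",
    "coverage",
)


def methylated_geneset_table(hits: Iterable[SiteRegionHit]) -> pd.DataFrame:
    """One row per site-region hit, deterministically sorted."""
    rows = []
    for h in hits:
        rows.append(
            {
                "contig": h.site.contig_id,
                "gene_id": h.region.gene_id or "",
                "motif": h.site.motif,
                "label": h.site.label,
                "position": h.site.position,
                "strand": h.site.strand,
                "offset": h.offset_from_start_codon,
                "region_kind": h.region.kind,
                "qv": h.site.qv,
                "fraction": h.site.fraction,
                "coverage": h.site.coverage,
            }
        )
    df = pd.DataFrame(rows, columns=list(GENESET_COLUMNS))
    if len(df):
        df = df.sort_values(["contig", "position", "gene_id", "region_kind", "strand"])
        df = df.reset_index(drop=True)
    return df


def enrichment_profile(
    hits: Iterable[SiteRegionHit], window: tuple[int, int] = (-500, 99)
) -> EnrichmentProfile:
    """Tally regulatory-region hits by start-codon offset and label.

    Offsets outside ``window`` are dropped; low-coverage sites never reach
    this tally (filtered at intersection time).
    """
    lo, hi = window
    profile = EnrichmentProfile(window=window)
    for h in hits:
        if h.region.kind != "regulatory" or h.offset_from_start_codon is None:
            continue
        if h.site.label == "low_coverage":
            continue
        off = h.offset_from_start_codon
        if lo <= off <= hi:
            profile.counts[(off, h.site.label)] += 1
    return profile


def overlap_with_deg(
    rtmg_gene_ids: set[str], deg_gene_ids: set[str]
) -> tuple[set[str], dict[str, int]]:
    """Set overlap between RTMG genes and differentially expressed genes."""
    inter = set(rtmg_gene_ids) & set(deg_gene_ids)
    return inter, {
        "n_rtmg": len(set(rtmg_gene_ids)),
        "n_deg": len(set(deg_gene_ids)),
        "n_overlap": len(inter),
    }
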