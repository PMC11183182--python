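"""End-to-end orchestration: files in, report bundle out.

Thin glue over the library modules; the CLI calls straight into
:func:`run_pipeline`, and tests drive it on generated fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import annotation_regions, io_formats, reporting, site_classification, tfbs
from .annotation_regions import RegionConfig, RegionAssignment, region_bed_rows
from .io_formats import BedInterval, GenomeSequence
from .region_intersection import (
    SiteRegionHit,
    intersect_sites_regions,
    overlap_with_deg,
)
from .site_classification import ClassThresholds, ClassifiedSite, MotifOccurrence
from .tfbs import BackgroundModel, RegionSequence, RtmgRecord, TfbsHit


@dataclass
class PipelineResult:
    genomes: dict[str, GenomeSequence]
    genes: list
    regions: list[RegionAssignment]
    occurrences_by_motif: dict[str, list[MotifOccurrence]]
    sites_by_motif: dict[str, list[ClassifiedSite]]
    hits: list[SiteRegionHit]
    tfbs_hits: list[TfbsHit]
    rtmg: list[RtmgRecord]
    manifest: reporting.RunManifest
    deg_overlap: Optional[tuple[set[str], dict[str, int]]] = None
    outputs: dict[str, Path] = field(default_factory=dict)


def _site_bed_rows(sites: Sequence[ClassifiedSite]) -> list[BedInterval]:
    return [
        BedInterval(
            contig=s.contig_id,
            start=s.position,
            end=s.position,
            name=s.motif,
            score=s.qv if s.qv is not None else 0.0,
            strand=s.strand,
        )
        for s in sorted(sites, key=lambda s: (s.contig_id, s.position, s.strand))
    ]


def run_pipeline(
    genome_fasta: str | Path,
    basemods_gff: str | Path,
    motifs_csv: str | Path,
    annotation_gff: str | Path,
    pfm_paths: Sequence[str | Path] = (),
    outdir: str | Path = "methyreg_out",
    sample: str = "sample",
    thresholds: ClassThresholds = ClassThresholds(),
    region_config: RegionConfig = RegionConfig(),
    background: str = "genome",
    pseudocount: float = 0.1,
    alpha: float = 1e-4,
    deg_path: Optional[str | Path] = None,
    all_regions: bool = False,
    circular: bool = False,
    write_circos: bool = True,
) -> PipelineResult:
    """Run classification, region assignment, intersection, TFBS scanning and
    RTMG detection, writing the full report bundle under ``outdir``.

    ``background`` selects the scanning null model: ``"genome"`` (0-order
    genome base frequencies) or ``"uniform"``. By default TFBS scanning is
    restricted to regulatory regions holding at least one (under)methylated
    site; ``all_regions`` scans every regulatory region instead.
    """
    outdir = Path(outdir)
    (outdir / "beds").mkdir(parents=True, exist_ok=True)
    (outdir / "fasta").mkdir(parents=True, exist_ok=True)

    genomes = {g.contig_id: g for g in io_formats.read_fasta(genome_fasta, circular=circular)}
    calls = io_formats.read_basemods_gff(basemods_gff)
    call_index = site_classification.index_calls(calls)
    summaries = io_formats.read_motifs_csv(motifs_csv)
    genes = io_formats.read_annotation_gff(annotation_gff)
    contig_lengths = {cid: g.length for cid, g in genomes.items()}

    regions: list[RegionAssignment] = []
    for genome in genomes.values():
        regions.extend(annotation_regions.derive_all_regions(genes, genome, region_config))

    occurrences_by_motif: dict[str, list[MotifOccurrence]] = {}
    sites_by_motif: dict[str, list[ClassifiedSite]] = {}
    for summary in summaries:
        occs: list[MotifOccurrence] = []
        for genome in genomes.values():
            occs.extend(
                site_classification.find_motif_occurrences(
                    genome, summary.motif, summary.center_index
                )
            )
        occurrences_by_motif[summary.motif] = occs
        sites_by_motif[summary.motif] = site_classification.classify_sites(
            occs, call_index, thresholds, motif=summary.motif,
            expected_mod_type=summary.mod_type,
        )

    all_sites = [s for sites in sites_by_motif.values() for s in sites]
    hits = intersect_sites_regions(all_sites, regions)

    # region BED exports
    window = (-region_config.upstream_bp, region_config.downstream_bp - 1)
    for kind in ("regulatory", "CDS", "intergenic"):
        rows = []
        for r in regions:
            if r.kind == kind:
                rows.extend(region_bed_rows(r, contig_lengths[r.contig_id]))
        io_formats.write_bed(rows, outdir / "beds" / f"{sample}_{kind}.bed", contig_lengths)
    for label, fname in (
        ("methylated", "Target_methylation.bed"),
        ("unmethylated", "Target_unmethylation.bed"),
        ("undermethylated", "Target_undermethylation.bed"),
    ):
        io_formats.write_bed(
            _site_bed_rows([s for s in all_sites if s.label == label]),
            outdir / "beds" / fname,
            contig_lengths,
        )

    # regulatory regions of genes with at least one methylated site
    genes_with_meth = {
        h.region.gene_id
        for h in hits
        if h.region.kind == "regulatory" and h.site.label == "methylated"
    }
    genes_with_any_meth = {
        h.region.gene_id
        for h in hits
        if h.region.kind == "regulatory"
        and h.site.label in ("methylated", "undermethylated")
    }
    rr_by_gene = {r.gene_id: r for r in regions if r.kind == "regulatory"}
    meth_regions = [rr_by_gene[g] for g in sorted(genes_with_meth) if g in rr_by_gene]
    io_formats.write_region_fasta(
        meth_regions, genomes, outdir / "fasta" / "Methylated_region.fasta"
    )

    # TFBS scanning
    bg = (
        BackgroundModel.uniform()
        if background == "uniform"
        else BackgroundModel.from_genome(genomes.values())
    )
    scan_gene_ids = (
        sorted(g for g in rr_by_gene if g is not None)
        if all_regions
        else sorted(g for g in genes_with_any_meth if g is not None)
    )
    scan_regions_seq = []
    for gid in scan_gene_ids:
        r = rr_by_gene.get(gid)
        if r is None or r.wrap:
            continue
        scan_regions_seq.append(
            RegionSequence(
                gene_id=gid,
                contig_id=r.contig_id,
                start=r.start,
                end=r.end,
                strand=r.strand,
                sequence=genomes[r.contig_id].sequence[r.start - 1 : r.end],
            )
        )
    tfbs_hits: list[TfbsHit] = []
    for pfm_path in pfm_paths:
        for pfm in io_formats.read_pfm(pfm_path):
            ppm = tfbs.pfm_to_ppm(pfm, pseudocount=pseudocount, background=bg)
            pwm = tfbs.ppm_to_pwm(ppm, bg)
            tfbs_hits.extend(tfbs.scan_regions(pwm, scan_regions_seq, bg, alpha=alpha))
    rtmg = tfbs.find_rtmg(tfbs_hits, hits)

    rtmg_regions = [rr_by_gene[r.gene_id] for r in rtmg if r.gene_id in rr_by_gene]
    io_formats.write_region_fasta(
        rtmg_regions, genomes, outdir / "fasta" / "RTMG_region.fasta"
    )

    manifest = reporting.RunManifest(
        sample=sample,
        input_digests={
            "genome_fasta": reporting.file_digest(genome_fasta),
            "basemods_gff": reporting.file_digest(basemods_gff),
            "motifs_csv": reporting.file_digest(motifs_csv),
            "annotation_gff": reporting.file_digest(annotation_gff),
        },
        thresholds={
            "qv_cut": thresholds.qv_cut,
            "fraction_cut": thresholds.fraction_cut,
            "coverage_cut": thresholds.coverage_cut,
            "upstream_bp": region_config.upstream_bp,
            "downstream_bp": region_config.downstream_bp,
            "pvalue_threshold": alpha,
            "pseudocount": pseudocount,
            "background": bg.source,
        },
        stage_counts={
            "contigs": len(genomes),
            "genes": len(genes),
            "regions": len(regions),
            "modification_calls": len(calls),
            "motifs": len(summaries),
            "occurrences": sum(len(v) for v in occurrences_by_motif.values()),
            "classified_sites": len(all_sites),
            "tfbs_hits": len(tfbs_hits),
        },
    )
    outputs = reporting.build_summary(
        outdir, sites_by_motif, hits, rtmg, manifest, window=window
    )
    if write_circos:
        all_occ = [o for occs in occurrences_by_motif.values() for o in occs]
        reporting.circos_tracks(
            list(genomes.values()), genes, all_sites, all_occ, outdir / "circos"
        )

    deg_overlap = None
    if deg_path is not None:
        deg_ids = io_formats.read_gene_list(deg_path)
        rtmg_ids = {r.gene_id for r in rtmg}
        deg_overlap = overlap_with_deg(rtmg_ids, deg_ids)
        inter, stats = deg_overlap
        io_formats.write_table(
            [
                {"gene_id": g, "in_rtmg": True, "in_deg": True}
                for g in sorted(inter)
            ],
            outdir / "tables" / "deg_overlap.tsv",
        )

    return PipelineResult(
        genomes=genomes,
        genes=genes,
        regions=regions,
        occurrences_by_motif=occurrences_by_motif,
        sites_by_motif=sites_by_motif,
        hits=hits,
        tfbs_hits=tfbs_hits,
        rtmg=rtmg,
        manifest=manifest,
        deg_overlap=deg_overlap,
        outputs=outputs,
    )
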