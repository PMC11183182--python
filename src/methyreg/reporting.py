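"""Human-facing report bundle: summary tables, plot-ready data and Circos
track files.

Every figure the pipeline supports is backed by an exact data table (the
tested artifact); rendering is optional. Output layout under the run
directory: ``tables/`` (TSV), ``beds/`` (BED6), ``fasta/``, ``circos/`` and
a flat key-value ``manifest.txt``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__
from .io_formats import GeneRecord, GenomeSequence, write_table
from .region_intersection import SiteRegionHit, enrichment_profile, methylated_geneset_table
from .site_classification import ClassifiedSite, MotifOccurrence, fraction_bins
from .tfbs import RtmgRecord


@dataclass
class RunManifest:
    """Flat run record: inputs, thresholds and per-stage record counts."""

    sample: str
    input_digests: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, object] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""  # optional run label; empty by default so re-runs are byte-identical
    stage_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"sample\t{self.sample}\n")
            fh.write(f"version\t{self.version}\n")
            fh.write(f"timestamp\t{self.timestamp}\n")
            for name in sorted(self.input_digests):
                fh.write(f"input.{name}\t{self.input_digests[name]}\n")
            for name in sorted(self.thresholds):
                fh.write(f"threshold.{name}\t{self.thresholds[name]}\n")
            for name in sorted(self.stage_counts):
                fh.write(f"count.{name}\t{self.stage_counts[name]}\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def fraction_bin_table(sites_by_motif: dict[str, Sequence[ClassifiedSite]]) -> pd.DataFrame:
    """Per-motif counts over the four methylation-fraction bins."""
    rows = []
    for motif in sorted(sites_by_motif):
        counts, n_missing = fraction_bins(
            [s for s in sites_by_motif[motif] if s.label != "low_coverage"]
        )
        for bin_name in counts:
            rows.append({"motif": motif, "bin": bin_name, "count": counts[bin_name]})
        rows.append({"motif": motif, "bin": "missing", "count": n_missing})
    return pd.DataFrame(rows, columns=["motif", "bin", "count"])


def site_metrics_table(sites_by_motif: dict[str, Sequence[ClassifiedSite]]) -> pd.DataFrame:
    """Scatter-plot data: one row per classified, adequately covered site."""
    rows = []
    for motif in sorted(sites_by_motif):
        for s in sites_by_motif[motif]:
            if s.label == "low_coverage":
                continue
            rows.append(
                {
                    "motif": motif,
                    "contig": s.contig_id,
                    "position": s.position,
                    "strand": s.strand,
                    "label": s.label,
                    "qv": s.qv,
                    "coverage": s.coverage,
                    "fraction": s.fraction,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["motif", "contig", "position", "strand", "label", "qv", "coverage", "fraction"],
    )
    if len(df):
        df = df.sort_values(["motif", "contig", "position", "strand"]).reset_index(drop=True)
    return df


def label_summary_table(sites_by_motif: dict[str, Sequence[ClassifiedSite]]) -> pd.DataFrame:
    rows = []
    for motif in sorted(sites_by_motif):
        sites = sites_by_motif[motif]
        row = {"motif": motif, "n_occurrences": len(sites)}
        for label in ("methylated", "undermethylated", "unmethylated", "low_coverage"):
            row[f"n_{label}"] = sum(1 for s in sites if s.label == label)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "motif", "n_occurrences", "n_methylated", "n_undermethylated",
            "n_unmethylated", "n_low_coverage",
        ],
    )


def rtmg_table(records: Iterable[RtmgRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for s in r.methylation_sites:
            for t in r.tfbs_hits:
                rows.append(
                    {
                        "gene_id": r.gene_id,
                        "motif": s.motif,
                        "site_position": s.position,
                        "site_strand": s.strand,
                        "label": s.label,
                        "fraction": s.fraction,
                        "tf": t.tf_name,
                        "tfbs_start": t.hit_start,
                        "tfbs_end": t.hit_end,
                        "tfbs_strand": t.strand,
                        "score": round(t.score, 4),
                        "p_value": t.p_value,
                        "min_distance_bp": r.min_distance_bp,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "motif", "site_position", "site_strand", "label", "fraction",
            "tf", "tfbs_start", "tfbs_end", "tfbs_strand", "score", "p_value",
            "min_distance_bp",
        ],
    )
    if len(df):
        df = df.sort_values(["gene_id", "site_position", "tf", "tfbs_start"]).reset_index(drop=True)
    return df


def build_summary(
    outdir: str | Path,
    sites_by_motif: dict[str, Sequence[ClassifiedSite]],
    hits: Sequence[SiteRegionHit],
    rtmg: Sequence[RtmgRecord],
    manifest: RunManifest,
    window: tuple[int, int] = (-500, 99),
) -> dict[str, Path]:
    """Write the full table bundle; returns {table name: path}.

    Re-running on identical inputs produces a byte-identical bundle.
    """
    outdir = Path(outdir)
    tables = outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    artifacts = {
        "fraction_bins": fraction_bin_table(sites_by_motif),
        "site_metrics": site_metrics_table(sites_by_motif),
        "label_summary": label_summary_table(sites_by_motif),
        "enrichment_profile": enrichment_profile(hits, window).to_frame(),
        "Methylated_geneset_table": methylated_geneset_table(
            [h for h in hits if h.site.label == "methylated"]
        ),
        "Undermethylated_geneset_table": methylated_geneset_table(
            [h for h in hits if h.site.label == "undermethylated"]
        ),
        "Unmethylated_geneset_table": methylated_geneset_table(
            [h for h in hits if h.site.label == "unmethylated"]
        ),
        "RTMG_list": rtmg_table(rtmg),
    }
    for name, df in artifacts.items():
        path = tables / f"{name}.tsv"
        write_table(df, path)
        written[name] = path

    manifest.stage_counts.setdefault("site_region_hits", len(hits))
    manifest.stage_counts.setdefault("rtmg_genes", len(rtmg))
    manifest_path = outdir / "manifest.txt"
    manifest.write(manifest_path)
    written["manifest"] = manifest_path
    return written


# ---------------------------------------------------------------------------
# Circos tracks
# ---------------------------------------------------------------------------

def circos_tracks(
    genomes: Sequence[GenomeSequence],
    genes: Sequence[GeneRecord],
    sites: Sequence[ClassifiedSite],
    occurrences: Sequence[MotifOccurrence],
    outdir: str | Path,
    density_window: int = 1000,
) -> dict[str, Path]:
    """Emit plain-text Circos data tracks (0-based half-open, space-separated).

    Rings, outer to inner: karyotype; genes on + and -; methylated sites on
    +; un/undermethylated sites (with a link file, one link per site); and
    methylated sites on -; plus an all-motif density track.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, lines: list[str]) -> None:
        p = outdir / name
        p.write_text("".join(line + "\n" for line in lines))
        paths[name.removesuffix(".txt")] = p

    emit("karyotype.txt", [f"chr - {g.contig_id} {g.contig_id} 0 {g.length} grey" for g in genomes])
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        emit(
            f"genes_{suffix}.txt",
            [f"{g.contig_id} {g.start - 1} {g.end}" for g in genes if g.strand == strand],
        )
        emit(
            f"sites_methylated_{suffix}.txt",
            [
                f"{s.contig_id} {s.position - 1} {s.position}"
                for s in sites
                if s.label == "methylated" and s.strand == strand
            ],
        )
    under = [s for s in sites if s.label in ("undermethylated", "unmethylated")]
    emit(
        "sites_under_unmethylated.txt",
        [f"{s.contig_id} {s.position - 1} {s.position} label={s.label}" for s in under],
    )
    # Interpretive link track: one self-anchored link per un(der)methylated site.
    emit(
        "links_under_unmethylated.txt",
        [
            f"{s.contig_id} {s.position - 1} {s.position} {s.contig_id} {s.position - 1} {s.position}"
            for s in under
        ],
    )
    density: dict[tuple[str, int], int] = {}
    for o in occurrences:
        key = (o.contig_id, (o.match_start - 1) // density_window)
        density[key] = density.get(key, 0) + 1
    lengths = {g.contig_id: g.length for g in genomes}
    emit(
        "motif_density.txt",
        [
            f"{contig} {b * density_window} {min((b + 1) * density_window, lengths.get(contig, (b + 1) * density_window))} {n}"
            for (contig, b), n in sorted(density.items())
        ],
    )
    return paths


def render_fraction_plot(
    fraction_bin_df: pd.DataFrame, path: str | Path
) -> Optional[Path]:
    """Optional bar-chart rendering of the fraction-bin table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    motifs = sorted(fraction_bin_df["motif"].unique())
    fig, axes = plt.subplots(1, max(len(motifs), 1), figsize=(4 * max(len(motifs), 1), 3.5))
    if len(motifs) <= 1:
        axes = [axes]
    colors = {"0-60%": "tab:red", "60-75%": "tab:gray", "75-90%": "tab:blue",
              "90-100%": "tab:green", "missing": "black"}
    for ax, motif in zip(axes, motifs):
        sub = fraction_bin_df[fraction_bin_df["motif"] == motif]
        ax.bar(sub["bin"], sub["count"], color=[colors.get(b, "gray") for b in sub["bin"]])
        ax.set_title(motif)
        ax.set_ylabel("sites")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
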