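"""Ground-truthed synthetic input generation.

Builds a random bacterial-style genome with implanted genes, motif
occurrences with assigned truth classes, a matching base-modification GFF
and motif-summary CSV, a TF position matrix with consensus implants, and a
differential-expression gene list — everything the pipeline consumes, with
complete per-site truth, so every stage is testable without downloads.

Default class metric ranges sit strictly inside each label's threshold
region (methylated QV 45-70 / fraction 0.80-1.0; undermethylated QV 45-70 /
fraction 0.10-0.70; unmethylated either no call or QV 5-35; low-coverage
coverage 5-25), so truth recovery by the classifier is exact, not
statistical. Incidental motif occurrences that arise by chance in the random
background are detected post hoc and carried in the truth as unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import annotation_regions, site_classification, tfbs
from .annotation_regions import RegionConfig
from .io_formats import GeneRecord, GenomeSequence, PositionMatrix, write_genome_fasta
from .tfbs import BackgroundModel

_BASES = np.array(list("ACGT"))
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    genome_length: int = 100_000
    gc_content: float = 0.5
    n_genes: int = 60
    motif: str = "GATC"
    center_index: int = 1
    mod_type: str = "m6A"
    n_occurrences: int = 400
    # target proportions over (methylated, undermethylated, unmethylated, low_coverage)
    class_mix: tuple[float, float, float, float] = (0.5, 0.2, 0.2, 0.1)
    n_rtmg_genes: int = 5
    tf_consensus: str = "TTGACATCGTAC"
    tf_name: str = "SynTF"
    qv_range_methylated: tuple[float, float] = (45.0, 70.0)
    qv_range_undermethylated: tuple[float, float] = (45.0, 70.0)
    qv_range_unmethylated: tuple[float, float] = (5.0, 35.0)
    fraction_range_methylated: tuple[float, float] = (0.80, 1.0)
    fraction_range_undermethylated: tuple[float, float] = (0.10, 0.70)
    coverage_range: tuple[int, int] = (35, 120)
    low_coverage_range: tuple[int, int] = (5, 25)
    min_gene_length: int = 600
    max_gene_length: int = 1000
    contig_id: str = "contig_1"

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0,1)")
        if self.n_rtmg_genes > self.n_genes:
            raise ValueError("n_rtmg_genes exceeds n_genes")
        if set(self.tf_consensus) - set("ACGT"):
            raise ValueError("tf_consensus must be over ACGT")


@dataclass
class FixtureTruth:
    """By-construction ground truth for a generated fixture."""

    # (strand, methylated_position) -> label, for every motif occurrence
    site_labels: dict[tuple[str, int], str]
    implanted_keys: set[tuple[str, int]]
    rr_spans: dict[str, tuple[int, int]]
    gene_strands: dict[str, str]
    tf_implants: dict[str, tuple[int, int]]  # gene -> consensus span (1-based)
    expected_rtmg: set[str]
    files: dict[str, Path] = field(default_factory=dict)


_CLASS_NAMES = ("methylated", "undermethylated", "unmethylated", "low_coverage")


def generate_pfm_from_consensus(
    consensus: str, sharpness: float = 1.0, tf_name: str = "SynTF", total: float = 100.0
) -> PositionMatrix:
    """Counts matrix whose per-column consensus base carries ``sharpness`` of
    the probability mass; sharpness 0.25 is fully uninformative."""
    if not (0.0 < sharpness <= 1.0):
        raise ValueError("sharpness must lie in (0, 1]")
    L = len(consensus)
    values = np.full((4, L), total * (1.0 - sharpness) / 3.0)
    for j, base in enumerate(consensus):
        values["ACGT".index(base), j] = total * sharpness
    return PositionMatrix(tf_name=tf_name, form="counts", values=values)


def _write_pfm(matrix: PositionMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{matrix.tf_name}\n")
        for base, row in zip("ACGT", matrix.values):
            fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


class _Occupancy:
    """Non-overlapping interval bookkeeping for implants (1-based inclusive)."""

    def __init__(self) -> None:
        self.intervals: list[tuple[int, int]] = []

    def free(self, start: int, end: int) -> bool:
        return all(e < start or s > end for s, e in self.intervals)

    def add(self, start: int, end: int) -> None:
        self.intervals.append((start, end))


def _resolve_motif(rng: np.random.Generator, motif: str) -> str:
    return "".join(
        b if len(_IUPAC[b]) == 1 else str(rng.choice(list(_IUPAC[b]))) for b in motif
    )


def generate_fixture(
    spec: FixtureSpec, outdir: str | Path, background: str = "uniform"
) -> FixtureTruth:
    """Generate the full fixture file set under ``outdir`` and return truth.

    Deterministic given ``spec.seed``: running twice writes byte-identical
    files. ``background`` selects the null model used when deriving the
    expected RTMG set (must match the background the pipeline run will use).
    Raises before writing anything if the genes cannot fit.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    motif_len = len(spec.motif)
    cons_len = len(spec.tf_consensus)

    block = L // spec.n_genes
    upstream_gap = 600  # keeps every RR full-length (no same-strand truncation)
    if block < upstream_gap + spec.max_gene_length + 1:
        raise ValueError(
            f"genome_length {L} too small for {spec.n_genes} genes of up to "
            f"{spec.max_gene_length} bp with {upstream_gap} bp upstream gaps"
        )

    # --- random genome at the stated GC content ---
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = rng.choice(np.arange(4), size=L, p=probs)
    seq = np.array(list("ACGT"))[genome]  # mutable char array

    occupancy = _Occupancy()

    # --- genes, one per block, both strands, ATG implanted at the start ---
    genes: list[GeneRecord] = []
    for i in range(spec.n_genes):
        glen = int(rng.integers(spec.min_gene_length, spec.max_gene_length + 1))
        start = i * block + 1 + upstream_gap
        end = start + glen - 1
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"GENE_{i + 1:04d}"
        if strand == "+":
            seq[start - 1 : start + 2] = list("ATG")
            occupancy.add(start, start + 2)
        else:
            seq[end - 3 : end] = list("CAT")  # ATG on the minus strand
            occupancy.add(end - 2, end)
        genes.append(
            GeneRecord(gene_id=gid, contig_id=spec.contig_id, start=start, end=end,
                       strand=strand, product="hypothetical protein")
        )

    config = RegionConfig()
    rr_spans: dict[str, tuple[int, int]] = {}
    anchors: dict[str, tuple[str, int]] = {}
    for g in genes:
        rr = annotation_regions.assign_regulatory_region(g, genes, config, L)
        rr_spans[g.gene_id] = (rr.start, rr.end)
        anchors[g.gene_id] = (g.strand, rr.anchor)

    def implant(start0: int, instance: str, strand: str) -> tuple[str, int]:
        """Write a motif instance (1-based start) and return its truth key."""
        if strand == "+":
            seq[start0 - 1 : start0 - 1 + motif_len] = list(instance)
            key_pos = start0 + spec.center_index
        else:
            seq[start0 - 1 : start0 - 1 + motif_len] = list(_revcomp(instance))
            key_pos = start0 + (motif_len - 1 - spec.center_index)
        occupancy.add(start0, start0 + motif_len - 1)
        return (strand, key_pos)

    def place_in(lo: int, hi: int, length: int, max_tries: int = 200) -> int:
        for _ in range(max_tries):
            s = int(rng.integers(lo, hi - length + 2))
            if occupancy.free(s, s + length - 1):
                return s
        raise RuntimeError("could not place implant; spec too dense")

    implanted: dict[tuple[str, int], str] = {}

    # --- RTMG genes: a methylated motif + the TF consensus in the RR upstream part ---
    rtmg_gene_idx = sorted(rng.choice(spec.n_genes, size=spec.n_rtmg_genes, replace=False))
    rtmg_genes = [genes[i] for i in rtmg_gene_idx]
    tf_implants: dict[str, tuple[int, int]] = {}
    for g in rtmg_genes:
        r1, r2 = rr_spans[g.gene_id]
        if g.strand == "+":
            up_lo, up_hi = r1, g.start - 1
        else:
            up_lo, up_hi = g.end + 1, r2
        m_start = place_in(up_lo, up_hi, motif_len)
        strand = "+" if rng.random() < 0.5 else "-"
        key = implant(m_start, _resolve_motif(rng, spec.motif), strand)
        implanted[key] = "methylated"
        c_start = place_in(up_lo, up_hi, cons_len)
        c_strand = "+" if rng.random() < 0.5 else "-"
        cons = spec.tf_consensus if c_strand == "+" else _revcomp(spec.tf_consensus)
        seq[c_start - 1 : c_start - 1 + cons_len] = list(cons)
        occupancy.add(c_start, c_start + cons_len - 1)
        tf_implants[g.gene_id] = (c_start, c_start + cons_len - 1)

    # --- remaining occurrences anywhere, classes from the target mix ---
    n_rand = max(spec.n_occurrences - spec.n_rtmg_genes, 0)
    labels = rng.choice(4, size=n_rand, p=list(spec.class_mix))
    for lab_idx in labels:
        m_start = place_in(1, L - motif_len + 1, motif_len)
        strand = "+" if rng.random() < 0.5 else "-"
        key = implant(m_start, _resolve_motif(rng, spec.motif), strand)
        implanted[key] = _CLASS_NAMES[lab_idx]

    genome_str = "".join(seq)
    genome_obj = GenomeSequence(contig_id=spec.contig_id, sequence=genome_str)

    # --- full truth: every occurrence in the final genome ---
    occurrences = site_classification.find_motif_occurrences(
        genome_obj, spec.motif, spec.center_index
    )
    occ_keys = {(o.strand, o.methylated_position) for o in occurrences}
    missing = set(implanted) - occ_keys
    if missing:
        raise RuntimeError(f"implanted occurrences destroyed: {sorted(missing)[:5]}")
    site_labels = {key: "unmethylated" for key in occ_keys}
    site_labels.update(implanted)

    # --- modification calls per implanted class ---
    def _u(rng, lo, hi):
        return float(rng.uniform(lo, hi))

    call_rows = []
    for (strand, pos), label in sorted(implanted.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if label == "methylated":
            qv = _u(rng, *spec.qv_range_methylated)
            frac = _u(rng, *spec.fraction_range_methylated)
            cov = int(rng.integers(*spec.coverage_range))
        elif label == "undermethylated":
            qv = _u(rng, *spec.qv_range_undermethylated)
            frac = _u(rng, *spec.fraction_range_undermethylated)
            cov = int(rng.integers(*spec.coverage_range))
        elif label == "low_coverage":
            qv = _u(rng, *spec.qv_range_methylated)
            frac = _u(rng, *spec.fraction_range_methylated)
            cov = int(rng.integers(*spec.low_coverage_range))
        else:  # unmethylated: half get a low-QV call, half no call at all
            if rng.random() < 0.5:
                continue
            qv = _u(rng, *spec.qv_range_unmethylated)
            frac = _u(rng, 0.0, 1.0)
            cov = int(rng.integers(*spec.coverage_range))
        ctx_lo = max(pos - 11, 0)
        context = genome_str[ctx_lo : pos + 10]
        if strand == "-":
            context = _revcomp(context)
        ipd = round(_u(rng, 2.0, 6.0), 2)
        call_rows.append(
            (pos, strand, int(round(qv)), cov, round(min(frac, 0.9999), 4), context, ipd)
        )

    # --- write files ---
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["genome"] = outdir / "genome.fasta"
    write_genome_fasta([genome_obj], files["genome"])

    files["genes"] = outdir / "genes.gff"
    with open(files["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {spec.contig_id} 1 {L}\n")
        for g in genes:
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id};product={g.product}"
            fh.write(
                f"{spec.contig_id}\tsynthetic\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )

    files["basemods"] = outdir / "motifs.gff"
    with open(files["basemods"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##source synthetic fixture seed={spec.seed}\n")
        for pos, strand, qv, cov, frac, context, ipd in call_rows:
            attrs = f"coverage={cov};context={context};IPDRatio={ipd};frac={frac:.4f}"
            fh.write(
                f"{spec.contig_id}\tkinModCall\t{spec.mod_type}\t{pos}\t{pos}\t{qv}\t{strand}\t.\t{attrs}\n"
            )

    files["motifs_csv"] = outdir / "motifs.csv"
    n_detected = len(call_rows)
    n_genome = len(occ_keys)
    mean_qv = round(float(np.mean([r[2] for r in call_rows])), 2) if call_rows else 0.0
    mean_cov = round(float(np.mean([r[3] for r in call_rows])), 2) if call_rows else 0.0
    with open(files["motifs_csv"], "w") as fh:
        fh.write("motifString,centerPos,modificationType,fraction,nDetected,nGenome,meanScore,meanCoverage\n")
        frac_all = round(n_detected / n_genome, 4) if n_genome else 0.0
        fh.write(
            f"{spec.motif},{spec.center_index},{spec.mod_type},{frac_all},"
            f"{n_detected},{n_genome},{mean_qv},{mean_cov}\n"
        )

    files["pfm"] = outdir / "tf.pfm"
    pfm = generate_pfm_from_consensus(spec.tf_consensus, sharpness=1.0, tf_name=spec.tf_name)
    _write_pfm(pfm, files["pfm"])

    # --- expected RTMG set, by construction + brute window scoring ---
    bg = (
        BackgroundModel.uniform()
        if background == "uniform"
        else BackgroundModel.from_genome([genome_obj])
    )
    ppm = tfbs.pfm_to_ppm(pfm, pseudocount=0.1, background=bg)
    pwm = tfbs.ppm_to_pwm(ppm, bg)
    dist = tfbs.score_distribution(pwm, bg)
    threshold = tfbs.pvalue_threshold_score(dist, alpha=1e-4)
    lod = pwm.values  # 4 x Lc

    def _brute_has_hit(r1: int, r2: int) -> bool:
        region = genome_str[r1 - 1 : r2]
        rc = _revcomp(region)
        for s in (region, rc):
            for i in range(len(s) - cons_len + 1):
                window = s[i : i + cons_len]
                if "N" in window:
                    continue
                score = sum(lod["ACGT".index(b), j] for j, b in enumerate(window))
                if score >= threshold:
                    return True
        return False

    genes_with_meth_rr = set()
    meth_keys = [
        (strand, pos)
        for (strand, pos), label in implanted.items()
        if label in ("methylated", "undermethylated")
    ]
    for gid, (r1, r2) in rr_spans.items():
        if any(r1 <= pos <= r2 for _, pos in meth_keys):
            genes_with_meth_rr.add(gid)
    expected_rtmg = {gid for gid in genes_with_meth_rr if _brute_has_hit(*rr_spans[gid])}
    if not set(g.gene_id for g in rtmg_genes) <= expected_rtmg:
        raise RuntimeError("RTMG implant failed its own construction check")

    files["deg"] = outdir / "deg.txt"
    deg_extra_idx = sorted(rng.choice(spec.n_genes, size=min(5, spec.n_genes), replace=False))
    deg_ids = sorted({g.gene_id for g in rtmg_genes} | {genes[i].gene_id for i in deg_extra_idx})
    files["deg"].write_text("".join(g + "\n" for g in deg_ids))

    files["truth"] = outdir / "truth.tsv"
    with open(files["truth"], "w") as fh:
        fh.write("strand\tposition\tmotif\tlabel\timplanted\n")
        for (strand, pos) in sorted(site_labels, key=lambda k: (k[1], k[0])):
            fh.write(
                f"{strand}\t{pos}\t{spec.motif}\t{site_labels[(strand, pos)]}\t"
                f"{(strand, pos) in implanted}\n"
            )

    return FixtureTruth(
        site_labels=site_labels,
        implanted_keys=set(implanted),
        rr_spans=rr_spans,
        gene_strands={g.gene_id: g.strand for g in genes},
        tf_implants=tf_implants,
        expected_rtmg=expected_rtmg,
        files=files,
    )
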