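"""Readers and writers for the external formats the pipeline touches.

Covers: genome FASTA, SMRT-seq base-modification GFF ("motifs.gff" dialect),
the motif-summary CSV ("motifs.csv"), gene-annotation GFF3 (PROKKA-style),
JASPAR-style position frequency matrices, BED6, region FASTA export and
tab-separated tables.

Coordinate convention: 1-based inclusive everywhere in memory; the single
conversion to 0-based half-open happens at the BED boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from urllib.parse import unquote

logger = logging.getLogger(__name__)

BASE_ORDER = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """A contig: uppercase sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_raw(cls, contig_id: str, raw: str, circular: bool = False) -> "GenomeSequence":
        """Normalize a raw sequence: strip whitespace, uppercase, map
        ambiguity codes other than N to N (with a logged warning)."""
        seq = re.sub(r"\s+", "", raw).upper()
        bad = sorted(set(seq) - set("ACGTN"))
        if bad:
            logger.warning(
                "contig %s: mapping non-ACGTN characters %s to N", contig_id, bad
            )
            seq = re.sub(r"[^ACGTN]", "N", seq)
        return cls(contig_id=contig_id, sequence=seq, circular=circular)


@dataclass(frozen=True)
class ModificationCall:
    """One per-position base-modification record from SMRT-seq kinetics."""

    contig_id: str
    position: int  # 1-based genomic coordinate of the modified base
    strand: str  # '+' or '-'
    mod_type: str  # m6A / m4C / m5C / modified_base
    qv: float  # Phred-scaled modification QV
    coverage: Optional[int] = None
    fraction: Optional[float] = None
    context: Optional[str] = None
    ipd_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.qv < 0:
            raise ValueError(f"QV must be non-negative, got {self.qv}")
        if self.fraction is not None and not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction must lie in [0,1], got {self.fraction}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class MotifSummary:
    """Per-motif summary row from motifs.csv."""

    motif: str
    center_index: int  # 0-based offset of the methylated base within the motif
    mod_type: str
    n_detected: Optional[int] = None
    n_in_genome: Optional[int] = None
    mean_qv: Optional[float] = None
    mean_coverage: Optional[float] = None
    partner_motif: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.center_index < len(self.motif)):
            raise ValueError(
                f"center_index {self.center_index} outside motif {self.motif!r}"
            )
        if (
            self.n_detected is not None
            and self.n_in_genome is not None
            and self.n_detected > self.n_in_genome
        ):
            raise ValueError("n_detected exceeds n_in_genome")


@dataclass(frozen=True)
class GeneRecord:
    """A gene (CDS) feature with 1-based inclusive coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class PositionMatrix:
    """A TF specificity matrix in counts, probabilities or log-odds form.

    ``values`` is a 4xL array with rows in A,C,G,T order.
    """

    tf_name: str
    form: str  # counts | probabilities | log_odds
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 2 or arr.shape[0] != 4 or arr.shape[1] < 1:
            raise ValueError(f"matrix must be 4xL with L>=1, got shape {arr.shape}")
        if self.form == "counts":
            if (arr < 0).any():
                raise ValueError("counts matrix has negative entries")
        elif self.form == "probabilities":
            if (arr < 0).any():
                raise ValueError("probability matrix has negative entries")
            col = arr.sum(axis=0)
            if not np.allclose(col, 1.0, atol=1e-9):
                raise ValueError("probability columns must sum to 1 within 1e-9")
        elif self.form != "log_odds":
            raise ValueError(f"unknown matrix form {self.form!r}")

    @property
    def length(self) -> int:
        return self.values.shape[1]


class BedInterval(NamedTuple):
    """A BED6 row held in internal 1-based inclusive coordinates."""

    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    name: str
    score: float
    strand: str  # '+', '-' or '.'


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeSequence]:
    """Read a multi-FASTA file into normalized :class:`GenomeSequence` records."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found (empty file or missing '>' header)")
    return [GenomeSequence.from_raw(r.id, str(r.seq), circular=circular) for r in records]


_MOD_TYPES = {"m6A", "m4C", "m5C", "modified_base"}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, val = chunk.partition("=")
        else:  # tolerate space-separated GTF-ish attributes
            key, _, val = chunk.partition(" ")
        out[key.strip()] = unquote(val.strip().strip('"'))
    return out


def read_basemods_gff(path: str | Path) -> list[ModificationCall]:
    """Parse a SMRTLink-style base-modification GFF.

    Dialect: the score column holds the modification QV; attribute keys
    ``coverage``, ``frac`` (fraction), ``context``, ``IPDRatio`` are honored;
    ``identificationQv``, when present, overrides the score column as the QV.
    ``fracLow``/``fracUp`` are tolerated and ignored.
    """
    path = Path(path)
    calls: list[ModificationCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            contig, _source, mod_type, start_s, end_s, score_s, strand, _frame, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer start/end") from None
            if start != end:
                raise FormatError(
                    f"{path}:{lineno}: per-base record must have start == end "
                    f"(got {start}..{end})"
                )
            attrs = _parse_gff_attributes(attr_s)
            try:
                qv = float(attrs["identificationQv"]) if "identificationQv" in attrs else float(score_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score/identificationQv") from None
            coverage: Optional[int] = None
            if "coverage" in attrs:
                try:
                    coverage = int(float(attrs["coverage"]))
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric coverage") from None
            fraction = float(attrs["frac"]) if "frac" in attrs else None
            ipd = float(attrs["IPDRatio"]) if "IPDRatio" in attrs else None
            if mod_type not in _MOD_TYPES:
                logger.warning(
                    "%s:%d: unknown modification type %r, keeping as modified_base",
                    path, lineno, mod_type,
                )
                mod_type = "modified_base"
            calls.append(
                ModificationCall(
                    contig_id=contig,
                    position=start,
                    strand=strand,
                    mod_type=mod_type,
                    qv=qv,
                    coverage=coverage,
                    fraction=fraction,
                    context=attrs.get("context"),
                    ipd_ratio=ipd,
                )
            )
    return calls


_MOTIF_CSV_MANDATORY = ("motifString", "centerPos", "modificationType")


def read_motifs_csv(path: str | Path) -> list[MotifSummary]:
    """Parse the SMRTLink motif-summary CSV (motifs.csv)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in _MOTIF_CSV_MANDATORY:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    def _opt(row, col, cast):
        if col in df.columns and pd.notna(row[col]):
            return cast(row[col])
        return None

    out = []
    for _, row in df.iterrows():
        out.append(
            MotifSummary(
                motif=str(row["motifString"]).strip(),
                center_index=int(row["centerPos"]),
                mod_type=str(row["modificationType"]).strip(),
                n_detected=_opt(row, "nDetected", int),
                n_in_genome=_opt(row, "nGenome", int),
                mean_qv=_opt(row, "meanScore", float),
                mean_coverage=_opt(row, "meanCoverage", float),
                partner_motif=_opt(row, "partnerMotifString", str),
            )
        )
    return out


def read_annotation_gff(
    path: str | Path, feature_types: Sequence[str] = ("CDS",)
) -> list[GeneRecord]:
    """Extract gene records from a GFF3 annotation (e.g. PROKKA output).

    Identifier precedence: ``locus_tag`` then ``ID``. Features without either
    are skipped with a warning. Duplicate identifiers are disambiguated with
    deterministic ``_1``, ``_2`` suffixes in file order.
    """
    path = Path(path)
    wanted = set(feature_types)
    raw: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # PROKKA appends the genome FASTA
                break
            fields = line.split("\t")
            if len(fields) != 9:
                continue
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            if ftype not in wanted:
                continue
            attrs = _parse_gff_attributes(attr_s)
            gene_id = attrs.get("locus_tag") or attrs.get("ID")
            if not gene_id:
                logger.warning("%s:%d: %s feature without locus_tag/ID skipped", path, lineno, ftype)
                continue
            if strand not in ("+", "-"):
                logger.warning("%s:%d: feature with strand %r skipped", path, lineno, strand)
                continue
            raw.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=int(start_s),
                    end=int(end_s),
                    strand=strand,
                    product=attrs.get("product"),
                )
            )
    counts: dict[str, int] = {}
    for g in raw:
        counts[g.gene_id] = counts.get(g.gene_id, 0) + 1
    seen: dict[str, int] = {}
    out: list[GeneRecord] = []
    for g in raw:
        if counts[g.gene_id] > 1:
            seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
            g = GeneRecord(
                gene_id=f"{g.gene_id}_{seen[g.gene_id]}",
                contig_id=g.contig_id,
                start=g.start,
                end=g.end,
                strand=g.strand,
                product=g.product,
            )
        out.append(g)
    return out


_PFM_ROW_LABEL = re.compile(r"^\s*([ACGTacgt])\s*[:|\[]?\s*(.*?)\s*\]?\s*$")


def read_pfm(path: str | Path) -> list[PositionMatrix]:
    """Read JASPAR-style PFMs: ``>name`` header then four rows (A/C/G/T),
    optionally labeled and in any label order; or a bare 4-row matrix.
    """
    path = Path(path)
    entries: list[tuple[str, list[str]]] = []
    name = path.stem
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if rows:
                    entries.append((name, rows))
                    rows = []
                name = line[1:].split()[0] or path.stem
            else:
                rows.append(line)
    if rows:
        entries.append((name, rows))
    if not entries:
        raise FormatError(f"{path}: no matrix rows found")

    matrices = []
    for tf_name, lines in entries:
        if len(lines) != 4:
            raise FormatError(f"{path}: matrix {tf_name!r} has {len(lines)} rows, expected 4")
        labeled: dict[str, list[float]] = {}
        unlabeled: list[list[float]] = []
        for line in lines:
            m = _PFM_ROW_LABEL.match(line)
            if m and m.group(2):
                base, body = m.group(1).upper(), m.group(2)
            else:
                base, body = "", line
            body = body.replace("[", " ").replace("]", " ").replace(",", " ")
            try:
                nums = [float(x) for x in body.split()]
            except ValueError:
                raise FormatError(f"{path}: non-numeric matrix entry in {tf_name!r}") from None
            if base:
                labeled[base] = nums
            else:
                unlabeled.append(nums)
        if labeled and len(labeled) == 4:
            ordered = [labeled[b] for b in BASE_ORDER]
        elif not labeled and len(unlabeled) == 4:
            ordered = unlabeled  # assumed already in A,C,G,T order
        else:
            raise FormatError(f"{path}: matrix {tf_name!r} mixes labeled and unlabeled rows")
        lens = {len(r) for r in ordered}
        if len(lens) != 1:
            raise FormatError(f"{path}: matrix {tf_name!r} has rows of unequal length")
        matrices.append(PositionMatrix(tf_name=tf_name, form="counts", values=np.array(ordered)))
    return matrices


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list, one locus tag per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Iterable[BedInterval],
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write BED6 (0-based half-open) from internal 1-based inclusive intervals."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.start < 1 or iv.start > iv.end:
                raise ValueError(f"invalid interval {iv}")
            if contig_lengths is not None:
                clen = contig_lengths.get(iv.contig)
                if clen is not None and iv.end > clen:
                    raise ValueError(f"interval {iv} extends past contig length {clen}")
            fh.write(
                f"{iv.contig}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[BedInterval]:
    """Read BED6 back into 1-based inclusive :class:`BedInterval` rows."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            out.append(
                BedInterval(
                    contig=fields[0],
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                    name=fields[3],
                    score=float(fields[4]),
                    strand=fields[5],
                )
            )
    return out


def extract_sequence(genome: GenomeSequence, start: int, end: int, strand: str = "+") -> str:
    """Slice [start, end] (1-based inclusive); reverse-complement for '-'."""
    if start < 1 or end > genome.length or start > end:
        raise ValueError(
            f"interval {start}..{end} outside contig {genome.contig_id} (length {genome.length})"
        )
    seq = genome.sequence[start - 1 : end]
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def write_region_fasta(regions: Iterable, genomes: dict[str, GenomeSequence], path: str | Path) -> None:
    """Export region sequences; minus-strand regions are reverse-complemented.

    Each region must expose contig_id, kind, start, end, strand and gene_id.
    Header: ``>{gene_id}|{kind}|{contig}:{start}-{end}({strand})``.
    """
    with open(path, "w") as fh:
        for region in regions:
            genome = genomes[region.contig_id]
            strand = region.strand if region.strand in ("+", "-") else "+"
            seq = extract_sequence(genome, region.start, region.end, strand)
            gid = region.gene_id or "intergenic"
            fh.write(
                f">{gid}|{region.kind}|{region.contig_id}:{region.start}-{region.end}({region.strand})\n"
            )
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_genome_fasta(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.contig_id}\n")
            for i in range(0, g.length, 60):
                fh.write(g.sequence[i : i + 60] + "\n")


def write_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write a tab-separated table with a header row."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)
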