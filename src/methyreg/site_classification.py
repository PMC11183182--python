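"""Motif-occurrence enumeration and methylation-state classification.

Every genomic occurrence of a methyltransferase recognition motif (IUPAC
degenerate string with a designated methylated-base offset) is located on
both strands, then matched to the SMRT-seq per-position modification call at
its methylated base and labeled:

* ``low_coverage``  — coverage present and below the coverage cutoff (gate
  applied first; such sites are excluded from downstream tallies),
* ``unmethylated``  — no call at the position, or modification QV below the
  QV cutoff,
* ``methylated``    — QV at/above cutoff and fraction at/above the fraction
  cutoff (a missing fraction with passing QV is labeled methylated and
  flagged ``fraction_missing``),
* ``undermethylated`` — QV at/above cutoff but fraction below the cutoff,
  the signature of TF competition or population heterogeneity.

Defaults: QV 40 (probability 0.9999), fraction 0.75, coverage 30.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .io_formats import GenomeSequence, ModificationCall

LABELS = ("methylated", "undermethylated", "unmethylated", "low_coverage")

#: Fig-style methylation-fraction bins: left-closed, right-open, last closed.
FRACTION_BIN_EDGES = (0.0, 0.60, 0.75, 0.90, 1.0)
FRACTION_BIN_NAMES = ("0-60%", "60-75%", "75-90%", "90-100%")


@dataclass(frozen=True)
class ClassThresholds:
    qv_cut: float = 40.0
    fraction_cut: float = 0.75
    coverage_cut: int = 30

    def __post_init__(self) -> None:
        if self.qv_cut < 0 or self.fraction_cut < 0 or self.coverage_cut < 0:
            raise ValueError("thresholds must be non-negative")
        if self.fraction_cut > 1:
            raise ValueError("fraction_cut must lie in [0,1]")


@dataclass(frozen=True)
class MotifOccurrence:
    """One genomic match of a motif; coordinates on the + coordinate system."""

    contig_id: str
    strand: str
    match_start: int  # 1-based inclusive start of the match on + coordinates
    matched_seq: str  # strand-oriented matched sequence
    methylated_position: int  # 1-based genomic coordinate of the methylated base


@dataclass(frozen=True)
class ClassifiedSite:
    occurrence: MotifOccurrence
    motif: str
    label: str
    qv: Optional[float] = None
    coverage: Optional[int] = None
    fraction: Optional[float] = None
    flags: tuple[str, ...] = ()

    @property
    def position(self) -> int:
        return self.occurrence.methylated_position

    @property
    def strand(self) -> str:
        return self.occurrence.strand

    @property
    def contig_id(self) -> str:
        return self.occurrence.contig_id


def _motif_regex(motif: str) -> re.Pattern[str]:
    """Compile an IUPAC motif to an overlapping-match regex.

    Genome N never matches: each motif letter expands to its concrete base
    set only, so the character classes exclude N by construction.
    """
    classes = []
    for letter in motif.upper():
        bases = ambiguous_dna_values.get(letter)
        if bases is None or letter not in "ACGTRYSWKMBDHVN":
            raise ValueError(f"invalid IUPAC letter {letter!r} in motif {motif!r}")
        classes.append(f"[{bases}]" if len(bases) > 1 else bases)
    return re.compile("(?=(" + "".join(classes) + "))")


def find_motif_occurrences(
    genome: GenomeSequence, motif: str, center_index: int
) -> list[MotifOccurrence]:
    """All occurrences of ``motif`` on both strands, overlapping included.

    A minus-strand occurrence is a match of the motif's reverse complement on
    the plus sequence; its methylated base maps to plus coordinate
    ``match_start + (L - 1 - center_index)``. Palindromic motifs therefore
    yield one occurrence per strand at the same match interval, matching the
    strand-specific nature of SMRT modification calls.
    """
    L = len(motif)
    if not (0 <= center_index < L):
        raise ValueError(f"center_index {center_index} outside motif of length {L}")
    seq = genome.sequence
    out: list[MotifOccurrence] = []
    for m in _motif_regex(motif).finditer(seq):
        i = m.start()
        out.append(
            MotifOccurrence(
                contig_id=genome.contig_id,
                strand="+",
                match_start=i + 1,
                matched_seq=m.group(1),
                methylated_position=i + 1 + center_index,
            )
        )
    rc_motif = str(Seq(motif).reverse_complement())
    for m in _motif_regex(rc_motif).finditer(seq):
        i = m.start()
        out.append(
            MotifOccurrence(
                contig_id=genome.contig_id,
                strand="-",
                match_start=i + 1,
                matched_seq=str(Seq(m.group(1)).reverse_complement()),
                methylated_position=i + 1 + (L - 1 - center_index),
            )
        )
    out.sort(key=lambda o: (o.match_start, o.strand))
    return out


def index_calls(
    calls: Iterable[ModificationCall],
) -> dict[tuple[str, int, str], ModificationCall]:
    return {(c.contig_id, c.position, c.strand): c for c in calls}


def classify_sites(
    occurrences: Sequence[MotifOccurrence],
    calls: Iterable[ModificationCall] | dict[tuple[str, int, str], ModificationCall],
    thresholds: ClassThresholds = ClassThresholds(),
    motif: str = "",
    expected_mod_type: Optional[str] = None,
    strict: bool = False,
) -> list[ClassifiedSite]:
    """Label each occurrence from the call at its methylated base.

    The coverage gate runs first; a covered-but-shallow call is labeled
    ``low_coverage`` regardless of QV and fraction so the site stays
    auditable instead of silently vanishing. An occurrence with no call at
    all is ``unmethylated`` with absent metrics. In ``strict`` mode a passing
    QV with a missing fraction raises instead of flagging.
    """
    index = calls if isinstance(calls, dict) else index_calls(calls)
    out: list[ClassifiedSite] = []
    for occ in occurrences:
        call = index.get((occ.contig_id, occ.methylated_position, occ.strand))
        if call is None:
            out.append(ClassifiedSite(occurrence=occ, motif=motif, label="unmethylated"))
            continue
        flags: list[str] = []
        if expected_mod_type and call.mod_type not in (expected_mod_type, "modified_base"):
            flags.append("mod_type_mismatch")
        if call.coverage is not None and call.coverage < thresholds.coverage_cut:
            label = "low_coverage"
        elif call.qv < thresholds.qv_cut:
            label = "unmethylated"
        elif call.fraction is None:
            if strict:
                raise ValueError(
                    f"site {occ.contig_id}:{occ.methylated_position}{occ.strand} has "
                    "QV above cutoff but no methylation fraction (strict mode)"
                )
            label = "methylated"
            flags.append("fraction_missing")
        elif call.fraction >= thresholds.fraction_cut:
            label = "methylated"
        else:
            label = "undermethylated"
        out.append(
            ClassifiedSite(
                occurrence=occ,
                motif=motif,
                label=label,
                qv=call.qv,
                coverage=call.coverage,
                fraction=call.fraction,
                flags=tuple(flags),
            )
        )
    return out


def qv_to_probability(qv: float) -> float:
    """Phred-scaled modification QV to modification probability.

    ``p = 1 - 10^(-qv/10)``; the default cutoff QV 40 corresponds to 0.9999.
    """
    if qv < 0:
        raise ValueError(f"QV must be non-negative, got {qv}")
    return 1.0 - 10.0 ** (-qv / 10.0)


def fraction_from_counts(n_modified: int, n_unmodified: int) -> float:
    """Methylation fraction: modified reads over total reads at the site."""
    total = n_modified + n_unmodified
    if total <= 0:
        raise ValueError("total read count must be positive")
    return n_modified / total


def fraction_bins(sites: Iterable[ClassifiedSite]) -> tuple[dict[str, int], int]:
    """Histogram of methylation fractions over the standard four bins.

    Bins are left-closed/right-open with the last bin closed; sites with an
    absent fraction are counted separately and returned as the second value.
    """
    counts: Counter[str] = Counter({name: 0 for name in FRACTION_BIN_NAMES})
    n_missing = 0
    edges = FRACTION_BIN_EDGES
    for site in sites:
        f = site.fraction
        if f is None:
            n_missing += 1
            continue
        for i, name in enumerate(FRACTION_BIN_NAMES):
            lo, hi = edges[i], edges[i + 1]
            if (lo <= f < hi) or (i == len(FRACTION_BIN_NAMES) - 1 and f == hi):
                counts[name] += 1
                break
    return dict(counts), n_missing


def off_motif_calls(
    calls: Iterable[ModificationCall],
    occurrences: Iterable[MotifOccurrence],
) -> list[ModificationCall]:
    """Modification calls not enclosed by any motif occurrence.

    These are reported separately rather than classified: the classification
    contract covers motif sites only.
    """
    keyed = {
        (o.contig_id, o.methylated_position, o.strand) for o in occurrences
    }
    return [c for c in calls if (c.contig_id, c.position, c.strand) not in keyed]
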