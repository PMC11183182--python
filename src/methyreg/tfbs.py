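"""TF binding-site scanning of methylated regulatory regions.

A position frequency matrix (counts) is converted to a probability matrix
with a background-weighted pseudocount, then to a log2-odds weight matrix.
The null score distribution under the background model is computed exactly
by dynamic-programming convolution of the discretized per-column score
distributions, which yields exact p-values and the score threshold
equivalent to a FIMO-style p-value cutoff (default 1e-4). Regions are
scanned on both strands; genes whose regulatory region carries both a
methylation site and a TFBS hit become RTMG records ("regulated by
transcriptional factor and methylation" genes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import GenomeSequence, PositionMatrix
from .region_intersection import SiteRegionHit
from .site_classification import ClassifiedSite

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class BackgroundModel:
    """Zero-order background base composition (A, C, G, T)."""

    probabilities: tuple[float, float, float, float]
    source: str = "uniform"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must be > 0 and sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls((0.25, 0.25, 0.25, 0.25), source="uniform")

    @classmethod
    def from_genome(cls, genomes: Iterable[GenomeSequence]) -> "BackgroundModel":
        counts = np.ones(4)  # Laplace smoothing keeps every base > 0
        for g in genomes:
            for base, idx in _BASE_INDEX.items():
                counts[idx] += g.sequence.count(base)
        p = counts / counts.sum()
        return cls(tuple(p), source="genome_frequencies")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probabilities)


@dataclass(frozen=True)
class TfbsHit:
    tf_name: str
    gene_id: str
    contig_id: str
    region_start: int
    region_end: int
    hit_start: int  # 1-based genome coordinate of the leftmost matched base
    strand: str
    score: float  # log2-odds
    p_value: float
    matched_seq: str  # strand-oriented

    @property
    def hit_end(self) -> int:
        return self.hit_start + len(self.matched_seq) - 1


@dataclass(frozen=True)
class RtmgRecord:
    """A gene co-targeted by methylation and a TF in its regulatory region."""

    gene_id: str
    methylation_sites: tuple[ClassifiedSite, ...]
    tfbs_hits: tuple[TfbsHit, ...]
    min_distance_bp: int

    def __post_init__(self) -> None:
        if not self.methylation_sites or not self.tfbs_hits:
            raise ValueError("RTMG record requires both methylation sites and TFBS hits")


# ---------------------------------------------------------------------------
# matrix transforms
# ---------------------------------------------------------------------------

def pfm_to_ppm(
    matrix: PositionMatrix,
    pseudocount: float = 0.1,
    background: Optional[BackgroundModel] = None,
) -> PositionMatrix:
    """Counts to probabilities: (count + pc*bg_b) / (column_total + pc)."""
    if matrix.form != "counts":
        raise ValueError(f"expected counts form, got {matrix.form}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    bg = (background or BackgroundModel.uniform()).array
    counts = matrix.values
    totals = counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("all-zero column with zero pseudocount; supply a pseudocount")
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    return PositionMatrix(tf_name=matrix.tf_name, form="probabilities", values=probs)


def ppm_to_pwm(matrix: PositionMatrix, background: BackgroundModel) -> PositionMatrix:
    """Probabilities to log2-odds against the background model."""
    if matrix.form != "probabilities":
        raise ValueError(f"expected probabilities form, got {matrix.form}")
    if (matrix.values <= 0).any():
        raise ValueError(
            "probability matrix has zero cells; rebuild the PPM with a positive pseudocount"
        )
    lod = np.log2(matrix.values / background.array[:, None])
    return PositionMatrix(tf_name=matrix.tf_name, form="log_odds", values=lod)


# ---------------------------------------------------------------------------
# exact score distribution
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Discretized exact distribution of PWM scores under the background.

    Scores are binned at width ``delta``; ``probs[k]`` is the probability of
    integer bin ``k + offset`` (score ~ (k + offset) * delta).
    """

    delta: float
    offset: int
    probs: np.ndarray = field(repr=False)
    _tail: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._tail is None:
            self._tail = np.cumsum(self.probs[::-1])[::-1]

    def _bin(self, score: float) -> int:
        return int(round(score / self.delta)) - self.offset

    def tail(self, score: float) -> float:
        """P(score' >= score) under the background model."""
        k = self._bin(score)
        if k <= 0:
            return 1.0
        if k >= len(self.probs):
            return 0.0
        return float(self._tail[k])

    def support(self) -> np.ndarray:
        """Achievable (binned) scores with positive mass."""
        ks = np.nonzero(self.probs > 0)[0]
        return (ks + self.offset) * self.delta


def score_distribution(
    pwm: PositionMatrix,
    background: BackgroundModel,
    granularity: int = 1000,
) -> ScoreDistribution:
    """Exact null score distribution by column-wise DP convolution.

    Each column contributes four score atoms weighted by the background;
    scores are discretized to ``granularity`` bins per (largest) column
    range and the per-column distributions convolved across columns.
    """
    if pwm.form != "log_odds":
        raise ValueError(f"expected log_odds form, got {pwm.form}")
    if granularity < 100:
        raise ValueError("granularity must be >= 100")
    values = pwm.values  # 4 x L
    bg = background.array
    col_ranges = values.max(axis=0) - values.min(axis=0)
    max_range = float(col_ranges.max())
    if max_range == 0.0:
        # Degenerate matrix: every sequence scores the same.
        total = float(values[0].sum())
        delta = 1.0
        k = int(round(total / delta))
        return ScoreDistribution(delta=delta, offset=k, probs=np.array([1.0]))
    delta = max_range / granularity

    keys = np.round(values / delta).astype(np.int64)  # 4 x L
    lo = int(keys.min(axis=0).sum())
    hi = int(keys.max(axis=0).sum())
    probs = np.zeros(hi - lo + 1)
    probs[0] = 1.0  # running distribution over (sum - running_lo)
    run_lo = 0
    run_len = 1
    for j in range(values.shape[1]):
        col_lo = int(keys[:, j].min())
        col_hi = int(keys[:, j].max())
        new_len = run_len + (col_hi - col_lo)
        new = np.zeros(new_len)
        for b in range(4):
            shift = int(keys[b, j]) - col_lo
            new[shift : shift + run_len] += bg[b] * probs[:run_len]
        probs[:new_len] = new
        probs[new_len:] = 0.0
        run_lo += col_lo
        run_len = new_len
    return ScoreDistribution(delta=delta, offset=run_lo, probs=probs[:run_len].copy())


def pvalue_threshold_score(dist: ScoreDistribution, alpha: float = 1e-4) -> float:
    """Minimal achievable score s* with P(score >= s*) <= alpha."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    ks = np.nonzero(dist.probs > 0)[0]
    tails = dist._tail[ks]
    ok = ks[tails <= alpha + 1e-15]
    if len(ok) == 0:
        logger.warning("no achievable score has tail probability <= %g", alpha)
        return math.inf
    return float((ok[0] + dist.offset) * dist.delta)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSequence:
    """A region's plus-strand sequence with its genome placement."""

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # strand of the owning gene
    sequence: str  # always the + genome strand


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> -1."""
    arr = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _window_scores(codes: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N score NaN."""
    L = values.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        vw = windows[valid]
        scores[valid] = values.T[np.arange(L)[None, :], vw].sum(axis=1)
    return scores


def scan_regions(
    pwm: PositionMatrix,
    regions: Sequence[RegionSequence],
    background: BackgroundModel,
    alpha: float = 1e-4,
    dist: Optional[ScoreDistribution] = None,
    granularity: int = 1000,
) -> list[TfbsHit]:
    """Scan region sequences on both strands; report hits with p <= alpha.

    Minus-strand windows are scored with the reverse-complemented matrix on
    the plus sequence, so reported coordinates stay on the plus axis with
    ``matched_seq`` strand-oriented.
    """
    if pwm.form != "log_odds":
        raise ValueError(f"expected log_odds form, got {pwm.form}")
    if dist is None:
        dist = score_distribution(pwm, background, granularity=granularity)
    threshold = pvalue_threshold_score(dist, alpha)
    L = pwm.length
    values_fwd = pwm.values
    values_rev = values_fwd[::-1, ::-1]  # complement rows, reverse columns
    hits: list[TfbsHit] = []
    for region in regions:
        if len(region.sequence) < L:
            logger.warning(
                "region %s (%d bp) shorter than matrix %s (%d bp); skipped",
                region.gene_id, len(region.sequence), pwm.tf_name, L,
            )
            continue
        codes = encode(region.sequence)
        for strand, values in (("+", values_fwd), ("-", values_rev)):
            scores = _window_scores(codes, values)
            idx = np.nonzero(np.nan_to_num(scores, nan=-np.inf) >= threshold)[0]
            for i in idx:
                window = region.sequence[i : i + L]
                hits.append(
                    TfbsHit(
                        tf_name=pwm.tf_name,
                        gene_id=region.gene_id,
                        contig_id=region.contig_id,
                        region_start=region.start,
                        region_end=region.end,
                        hit_start=region.start + int(i),
                        strand=strand,
                        score=float(scores[i]),
                        p_value=dist.tail(float(scores[i])),
                        matched_seq=window if strand == "+" else _revcomp(window),
                    )
                )
    hits.sort(key=lambda h: (h.contig_id, h.hit_start, h.strand, h.gene_id, h.tf_name))
    return hits


def find_rtmg(
    tfbs_hits: Iterable[TfbsHit],
    site_hits: Iterable[SiteRegionHit],
) -> list[RtmgRecord]:
    """Genes with >=1 (under)methylated regulatory-region site and >=1 TFBS hit.

    ``min_distance_bp`` is the smallest distance from any methylated base to
    the nearest edge of any TFBS interval, zero when the base lies inside.
    Undermethylated sites count toward membership: a confidently detected but
    partially protected site is exactly the TF-competition signature.
    """
    meth_by_gene: dict[str, list[ClassifiedSite]] = {}
    for h in site_hits:
        if h.region.kind != "regulatory" or h.region.gene_id is None:
            continue
        if h.site.label in ("methylated", "undermethylated"):
            meth_by_gene.setdefault(h.region.gene_id, []).append(h.site)
    tf_by_gene: dict[str, list[TfbsHit]] = {}
    for t in tfbs_hits:
        tf_by_gene.setdefault(t.gene_id, []).append(t)

    records = []
    for gene_id in sorted(set(meth_by_gene) & set(tf_by_gene)):
        sites = meth_by_gene[gene_id]
        tfs = tf_by_gene[gene_id]
        dmin = min(
            0
            if t.hit_start <= s.position <= t.hit_end
            else min(abs(s.position - t.hit_start), abs(s.position - t.hit_end))
            for s in sites
            for t in tfs
        )
        records.append(
            RtmgRecord(
                gene_id=gene_id,
                methylation_sites=tuple(sites),
                tfbs_hits=tuple(tfs),
                min_distance_bp=dmin,
            )
        )
    return records
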