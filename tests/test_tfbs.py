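"""PWM transforms, exact p-value DP, region scanning and RTMG detection."""

import itertools
import math

import numpy as np
import pytest

from methyreg.annotation_regions import RegionAssignment
from methyreg.io_formats import PositionMatrix
from methyreg.region_intersection import intersect_sites_regions
from methyreg.site_classification import ClassifiedSite, MotifOccurrence
from methyreg.tfbs import (
    BackgroundModel,
    RegionSequence,
    find_rtmg,
    pfm_to_ppm,
    ppm_to_pwm,
    pvalue_threshold_score,
    scan_regions,
    score_distribution,
)

UNI = BackgroundModel.uniform()


def counts(cols):
    """Column-major convenience constructor: cols is a list of (A,C,G,T)."""
    return PositionMatrix(tf_name="t", form="counts", values=np.array(cols, dtype=float).T)


# ------------------------------------------------------------------- transforms

def test_pfm_to_ppm_pure_column():
    ppm = pfm_to_ppm(counts([(8, 0, 0, 0)]), pseudocount=0)
    assert list(ppm.values[:, 0]) == [1, 0, 0, 0]


def test_pfm_to_ppm_uniform_column_stays_uniform():
    ppm = pfm_to_ppm(counts([(2, 2, 2, 2)]), pseudocount=3.7)
    assert np.allclose(ppm.values[:, 0], 0.25)


def test_pfm_to_ppm_pseudocount_formula():
    # (count + pc*bg) / (total + pc) with pc=1, uniform background
    ppm = pfm_to_ppm(counts([(3, 1, 0, 0)]), pseudocount=1)
    assert np.allclose(ppm.values[:, 0], [3.25 / 5, 1.25 / 5, 0.25 / 5, 0.25 / 5])
    assert abs(ppm.values[:, 0].sum() - 1.0) < 1e-12


def test_pfm_to_ppm_zero_column_zero_pseudocount_errors():
    with pytest.raises(ValueError, match="pseudocount"):
        pfm_to_ppm(counts([(0, 0, 0, 0)]), pseudocount=0)


def test_ppm_to_pwm_log_odds():
    ppm = PositionMatrix(tf_name="t", form="probabilities",
                         values=np.array([[0.25], [0.5], [0.125], [0.125]]))
    pwm = ppm_to_pwm(ppm, UNI)
    assert pwm.values[0, 0] == 0.0
    assert pwm.values[1, 0] == 1.0  # one bit for p=0.5 vs 0.25
    assert np.allclose(pwm.values[2:, 0], -1.0)


def test_ppm_to_pwm_zero_cell_errors():
    ppm = pfm_to_ppm(counts([(8, 0, 0, 0)]), pseudocount=0)
    with pytest.raises(ValueError, match="pseudocount"):
        ppm_to_pwm(ppm, UNI)


def test_ppm_to_pwm_full_matrix_hand_computed():
    ppm = pfm_to_ppm(counts([(3, 1, 0, 0), (0, 0, 2, 2)]), pseudocount=1)
    pwm = ppm_to_pwm(ppm, UNI)
    for j in range(2):
        for b in range(4):
            assert pwm.values[b, j] == pytest.approx(math.log2(ppm.values[b, j] / 0.25))


# -------------------------------------------------------------- exact p-values

def _pwm(cols, pc=0.1, bg=UNI):
    return ppm_to_pwm(pfm_to_ppm(counts(cols), pseudocount=pc, background=bg), bg)


def enumerate_tail(pwm, bg, threshold):
    """Oracle: exact tail mass over all 4^L sequences."""
    L = pwm.length
    p = 0.0
    for word in itertools.product(range(4), repeat=L):
        score = sum(pwm.values[b, j] for j, b in enumerate(word))
        if score >= threshold:
            p += math.prod(bg.array[b] for b in word)
    return p


def test_single_column_distribution_is_four_atoms():
    dist = score_distribution(_pwm([(5, 1, 1, 1)]), UNI)
    support = dist.support()
    assert len(support) <= 4
    masses = dist.probs[dist.probs > 0]
    assert np.allclose(sorted(masses), [0.25, 0.75]) or np.allclose(masses, 0.25)
    assert abs(dist.probs.sum() - 1.0) < 1e-9


def test_two_identical_columns_self_convolution():
    one = score_distribution(_pwm([(5, 1, 1, 1)]), UNI)
    two = score_distribution(_pwm([(5, 1, 1, 1)] * 2), UNI)
    conv = np.convolve(one.probs, one.probs)
    assert np.allclose(np.trim_zeros(two.probs, "b"), np.trim_zeros(conv, "b"), atol=1e-12)


@pytest.mark.parametrize("L", [2, 4, 6])
def test_dp_matches_exhaustive_enumeration(rng, L):
    """DP tail probabilities bracket the 4^L enumeration within rounding slack."""
    for bg in (UNI, BackgroundModel((0.2, 0.3, 0.3, 0.2), source="uniform")):
        cols = [tuple(rng.integers(0, 20, size=4)) for _ in range(L)]
        pwm = _pwm(cols, bg=bg)
        dist = score_distribution(pwm, bg)
        slack = dist.delta * (L / 2 + 1)
        for q in (0.05, 0.25, 0.5, 0.9):
            t = float(np.quantile(dist.support(), q))
            p_dp = dist.tail(t)
            assert enumerate_tail(pwm, bg, t + slack) - 1e-12 <= p_dp
            assert p_dp <= enumerate_tail(pwm, bg, t - slack) + 1e-12


def test_threshold_alpha_one_is_minimum_achievable_score():
    pwm = _pwm([(5, 1, 1, 1), (1, 5, 1, 1)])
    dist = score_distribution(pwm, UNI)
    assert pvalue_threshold_score(dist, alpha=1.0) == pytest.approx(min(dist.support()))


def test_threshold_one_column_top_quarter():
    pwm = _pwm([(5, 1, 1, 1)])
    dist = score_distribution(pwm, UNI)
    assert pvalue_threshold_score(dist, alpha=0.25) == pytest.approx(max(dist.support()))


def test_threshold_matches_enumeration_tail(rng):
    pwm = _pwm([tuple(rng.integers(0, 15, size=4)) for _ in range(4)])
    dist = score_distribution(pwm, UNI)
    for alpha in (0.5, 0.1, 0.01):
        s_star = pvalue_threshold_score(dist, alpha)
        slack = dist.delta * 3
        assert enumerate_tail(pwm, UNI, s_star + slack) <= alpha + 1e-12


def test_threshold_alpha_validation_and_infeasible():
    pwm = _pwm([(5, 1, 1, 1)])
    dist = score_distribution(pwm, UNI)
    with pytest.raises(ValueError):
        pvalue_threshold_score(dist, alpha=0.0)
    with pytest.raises(ValueError):
        pvalue_threshold_score(dist, alpha=1.5)
    assert pvalue_threshold_score(dist, alpha=1e-9) == math.inf


# -------------------------------------------------------------------- scanning

CONS = "TTGACA"


def sharp_pwm(consensus=CONS):
    cols = []
    for b in consensus:
        col = [0.0] * 4
        col["ACGT".index(b)] = 100.0
        cols.append(tuple(col))
    return _pwm(cols)


def _region(seq, gene_id="g1", start=1_001):
    return RegionSequence(gene_id=gene_id, contig_id="c1", start=start,
                          end=start + len(seq) - 1, strand="+", sequence=seq)


def revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def test_consensus_region_maximal_hit_at_position_one():
    pwm = sharp_pwm()
    hits = scan_regions(pwm, [_region(CONS)], UNI, alpha=1e-3)
    plus = [h for h in hits if h.strand == "+"]
    assert len(plus) == 1
    h = plus[0]
    assert h.hit_start == 1_001 and h.matched_seq == CONS
    assert h.score == pytest.approx(float(pwm.values.max(axis=0).sum()), abs=1e-6)
    assert h.p_value <= 1e-3


def test_reverse_complement_consensus_hits_minus_strand():
    pwm = sharp_pwm()
    fwd = scan_regions(pwm, [_region(CONS + "AAAA")], UNI, alpha=1e-3)
    rev = scan_regions(pwm, [_region(revcomp(CONS + "AAAA"))], UNI, alpha=1e-3)
    f = next(h for h in fwd if h.matched_seq == CONS)
    r = next(h for h in rev if h.matched_seq == CONS)
    assert (f.strand, r.strand) == ("+", "-")
    assert f.score == pytest.approx(r.score)


def test_scan_region_shorter_than_matrix_skipped():
    assert scan_regions(sharp_pwm(), [_region("ACG")], UNI) == []


def test_scan_skips_windows_containing_n():
    pwm = sharp_pwm()
    region = _region("TTGNCA" + CONS)
    hits = scan_regions(pwm, [region], UNI, alpha=1e-3)
    assert all("N" not in h.matched_seq for h in hits)
    assert any(h.matched_seq == CONS for h in hits)


def test_shrinking_alpha_never_adds_hits(rng):
    seq = "".join(rng.choice(list("ACGT"), size=400))
    cols = [tuple(rng.integers(0, 12, size=4)) for _ in range(5)]
    pwm = _pwm(cols)
    prev = None
    for alpha in (0.5, 0.1, 0.01, 1e-3):
        hits = {(h.hit_start, h.strand) for h in scan_regions(pwm, [_region(seq)], UNI, alpha)}
        if prev is not None:
            assert hits <= prev
        prev = hits


def test_implanted_consensus_recovered_false_positives_bounded(rng):
    """All implants found; chance hits stay near alpha * windows scanned."""
    pwm = sharp_pwm("TTGACAGGTACC")  # 12-mer, alpha 1e-4 feasible
    alpha = 1e-4
    offsets = (50, 200, 371)
    seq = list("".join(rng.choice(list("ACGT"), size=500)))
    for off in offsets:
        seq[off : off + 12] = "TTGACAGGTACC"
    region = _region("".join(seq))
    hits = scan_regions(pwm, [region], UNI, alpha=alpha)
    starts = {h.hit_start - region.start for h in hits if h.strand == "+"}
    assert set(offsets) <= starts
    n_windows = 2 * (500 - 12 + 1)
    assert len(hits) - len(offsets) <= max(5, 10 * alpha * n_windows)


# ------------------------------------------------------------------------ RTMG

def _site_hit(gene_id, pos, label="methylated"):
    occ = MotifOccurrence(contig_id="c1", strand="+", match_start=pos - 1,
                          matched_seq="GATC", methylated_position=pos)
    site = ClassifiedSite(occurrence=occ, motif="GATC", label=label, qv=50.0,
                          coverage=40, fraction=0.9)
    rr = RegionAssignment(contig_id="c1", kind="regulatory", start=pos - 500,
                          end=pos + 99, strand="+", gene_id=gene_id, anchor=pos + 400)
    return intersect_sites_regions([site], [rr])[0]


def _tf_hit(gene_id, start, end):
    from methyreg.tfbs import TfbsHit

    return TfbsHit(tf_name="TF", gene_id=gene_id, contig_id="c1", region_start=1,
                   region_end=10_000, hit_start=start, strand="+", score=10.0,
                   p_value=1e-5, matched_seq="A" * (end - start + 1))


def test_rtmg_containment_gives_zero_distance():
    rec, = find_rtmg([_tf_hit("g1", 9_980, 9_995)], [_site_hit("g1", 9_990)])
    assert rec.gene_id == "g1" and rec.min_distance_bp == 0


def test_rtmg_distance_to_nearest_edge():
    rec, = find_rtmg([_tf_hit("g1", 10_000, 10_010)], [_site_hit("g1", 9_990)])
    assert rec.min_distance_bp == 10


def test_gene_with_only_unmethylated_sites_excluded():
    assert find_rtmg([_tf_hit("g1", 1, 10)], [_site_hit("g1", 5, label="unmethylated")]) == []


def test_undermethylated_sites_count_toward_membership():
    rec, = find_rtmg([_tf_hit("g1", 1, 10)], [_site_hit("g1", 5, label="undermethylated")])
    assert rec.gene_id == "g1"


def test_rtmg_subset_of_both_inputs():
    tf_hits = [_tf_hit("g1", 1, 10), _tf_hit("g2", 1, 10)]
    site_hits = [_site_hit("g2", 5), _site_hit("g3", 5)]
    recs = find_rtmg(tf_hits, site_hits)
    assert {r.gene_id for r in recs} == {"g2"}
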