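"""Motif occurrence enumeration and methylation-state classification."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methyreg.io_formats import GenomeSequence, ModificationCall
from methyreg.site_classification import (
    ClassThresholds,
    classify_sites,
    find_motif_occurrences,
    fraction_bins,
    fraction_from_counts,
    index_calls,
    off_motif_calls,
    qv_to_probability,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_motif(motif):
    return motif.translate(COMP)[::-1]


def revcomp_seq(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def naive_scan(seq, motif, center):
    """Oracle: regex over the sequence and over its reverse complement."""
    L, Lg = len(motif), len(seq)
    pat = re.compile("(?=(" + "".join(f"[{IUPAC[b]}]" for b in motif) + "))")
    occs = set()
    for m in pat.finditer(seq):
        i = m.start()
        occs.add(("+", i + 1, i + 1 + center, m.group(1)))
    for m in pat.finditer(revcomp_seq(seq)):
        j = m.start()
        occs.add(("-", Lg - j - L + 1, Lg - j - center, m.group(1)))
    return occs


def as_set(occs):
    return {(o.strand, o.match_start, o.methylated_position, o.matched_seq) for o in occs}


# ------------------------------------------------------------ motif occurrences

def test_palindromic_motif_reported_once_per_strand():
    g = GenomeSequence(contig_id="c", sequence="TTGATCAA")
    occs = find_motif_occurrences(g, "GATC", 1)
    assert as_set(occs) == {("+", 3, 4, "GATC"), ("-", 3, 5, "GATC")}


def test_degenerate_motif_wildcard_semantics():
    g = GenomeSequence(contig_id="c", sequence="AGACTCA")
    plus = [o for o in find_motif_occurrences(g, "GANTC", 1) if o.strand == "+"]
    assert len(plus) == 1 and plus[0].match_start == 2
    assert plus[0].methylated_position == 3 and plus[0].matched_seq == "GACTC"


def test_no_match_returns_empty():
    g = GenomeSequence(contig_id="c", sequence="GGGG")
    assert find_motif_occurrences(g, "GATC", 1) == []


def test_genome_n_matches_no_motif_letter():
    g = GenomeSequence(contig_id="c", sequence="GANCGNTC")
    assert find_motif_occurrences(g, "GANC", 0) == []  # N in genome blocks even motif N


def test_invalid_iupac_letter_errors():
    g = GenomeSequence(contig_id="c", sequence="ACGT")
    with pytest.raises(ValueError, match="Z"):
        find_motif_occurrences(g, "GAZC", 1)


@given(st.data())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_occurrences_match_naive_oracle(data):
    seq = data.draw(st.text(alphabet="ACGTN", min_size=10, max_size=300))
    motif = data.draw(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=2, max_size=8))
    center = data.draw(st.integers(min_value=0, max_value=len(motif) - 1))
    g = GenomeSequence(contig_id="c", sequence=seq)
    assert as_set(find_motif_occurrences(g, motif, center)) == naive_scan(seq, motif, center)


@given(st.data())
@settings(max_examples=40, derandomize=True, deadline=None)
def test_strand_symmetry_under_genome_reverse_complement(data):
    """Scanning the revcomp genome swaps strands with x -> L-x+1 coordinates."""
    seq = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=200))
    motif = data.draw(st.sampled_from(["GATC", "GANTC", "CCWGG", "AGG"]))
    center = 1
    L = len(seq)
    fwd = find_motif_occurrences(GenomeSequence(contig_id="c", sequence=seq), motif, center)
    rev = find_motif_occurrences(
        GenomeSequence(contig_id="c", sequence=revcomp_seq(seq)), motif, center
    )
    flip = {"+": "-", "-": "+"}
    mapped = {(flip[o.strand], L - o.methylated_position + 1) for o in rev}
    assert {(o.strand, o.methylated_position) for o in fwd} == mapped


# ---------------------------------------------------------------- QV / fraction

def test_qv_probability_values():
    assert abs(qv_to_probability(40) - 0.9999) < 1e-12
    assert qv_to_probability(0) == 0.0
    assert abs(qv_to_probability(10) - 0.9) < 1e-12
    with pytest.raises(ValueError):
        qv_to_probability(-1)


@given(st.floats(min_value=0, max_value=100, allow_nan=False))
@settings(max_examples=50, derandomize=True)
def test_qv_probability_increasing_and_bounded(qv):
    p = qv_to_probability(qv)
    assert 0.0 <= p < 1.0
    assert qv_to_probability(qv + 1) > p


def test_fraction_from_counts():
    assert fraction_from_counts(75, 25) == 0.75
    assert fraction_from_counts(0, 10) == 0.0
    assert fraction_from_counts(30, 10) == 0.75
    with pytest.raises(ValueError):
        fraction_from_counts(0, 0)


# ----------------------------------------------------------------- class labels

def _call(pos=4, strand="+", qv=50.0, coverage=40, fraction=0.9):
    return ModificationCall(contig_id="c", position=pos, strand=strand,
                            mod_type="m6A", qv=qv, coverage=coverage, fraction=fraction)


def _occs():
    g = GenomeSequence(contig_id="c", sequence="TTGATCAA")
    return [o for o in find_motif_occurrences(g, "GATC", 1) if o.strand == "+"]


@pytest.mark.parametrize(
    "qv,fraction,coverage,expected",
    [
        (50, 0.9, 40, "methylated"),
        (50, 0.5, 40, "undermethylated"),
        (20, 0.9, 40, "unmethylated"),
        (50, 0.9, 10, "low_coverage"),
        (40, 0.75, 30, "methylated"),  # boundaries are inclusive per the cutoffs
        (39.9, 0.75, 30, "unmethylated"),
        (40, 0.7499, 30, "undermethylated"),
        (40, 0.75, 29, "low_coverage"),
    ],
)
def test_classification_thresholds(qv, fraction, coverage, expected):
    (site,) = classify_sites(_occs(), [_call(qv=qv, coverage=coverage, fraction=fraction)],
                             ClassThresholds(), motif="GATC")
    assert site.label == expected


def test_no_call_is_unmethylated_with_absent_metrics():
    (site,) = classify_sites(_occs(), [], ClassThresholds(), motif="GATC")
    assert site.label == "unmethylated"
    assert site.qv is None and site.coverage is None and site.fraction is None


def test_missing_fraction_with_passing_qv_flags_and_strict_raises():
    call = _call(fraction=None)
    (site,) = classify_sites(_occs(), [call], motif="GATC")
    assert site.label == "methylated" and "fraction_missing" in site.flags
    with pytest.raises(ValueError, match="strict"):
        classify_sites(_occs(), [call], strict=True)


def test_mod_type_mismatch_flagged_not_dropped():
    call = ModificationCall(contig_id="c", position=4, strand="+", mod_type="m4C",
                            qv=50, coverage=40, fraction=0.9)
    (site,) = classify_sites(_occs(), [call], motif="GATC", expected_mod_type="m6A")
    assert site.label == "methylated" and "mod_type_mismatch" in site.flags


def test_partition_every_occurrence_gets_exactly_one_label(rng):
    """Labels partition the occurrence set regardless of call availability."""
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    g = GenomeSequence(contig_id="c", sequence=seq)
    occs = find_motif_occurrences(g, "GATC", 1)
    calls = []
    for o in occs[::2]:  # calls at half the sites
        calls.append(ModificationCall(
            contig_id="c", position=o.methylated_position, strand=o.strand,
            mod_type="m6A", qv=float(rng.uniform(0, 80)),
            coverage=int(rng.integers(1, 100)), fraction=float(rng.uniform(0, 1)),
        ))
    sites = classify_sites(occs, calls, motif="GATC")
    assert len(sites) == len(occs)
    from collections import Counter
    counts = Counter(s.label for s in sites)
    assert sum(counts.values()) == len(occs)
    assert set(counts) <= {"methylated", "undermethylated", "unmethylated", "low_coverage"}


def test_raising_fraction_cut_never_promotes_to_methylated(rng):
    occs = _occs()
    call = _call(fraction=0.8)
    lo = classify_sites(occs, [call], ClassThresholds(fraction_cut=0.75))[0]
    hi = classify_sites(occs, [call], ClassThresholds(fraction_cut=0.9))[0]
    assert lo.label == "methylated" and hi.label == "undermethylated"


def test_off_motif_calls_reported_separately():
    occs = _occs()
    on = _call(pos=4)
    off = _call(pos=2)
    assert off_motif_calls([on, off], occs) == [off]


# ------------------------------------------------------------------ fraction bins

def test_fraction_bins_edges():
    def site(frac):
        g = GenomeSequence(contig_id="c", sequence="TTGATCAA")
        occ = find_motif_occurrences(g, "GATC", 1)[0]
        call = _call(fraction=frac)
        return classify_sites([occ], [call], motif="GATC")[0]

    counts, missing = fraction_bins([site(f) for f in (0.5, 0.7, 0.8, 0.95)])
    assert counts == {"0-60%": 1, "60-75%": 1, "75-90%": 1, "90-100%": 1}
    counts, _ = fraction_bins([site(0.75)])
    assert counts["75-90%"] == 1  # left-closed convention
    counts, _ = fraction_bins([site(1.0)])
    assert counts["90-100%"] == 1  # last bin closed
    counts, missing = fraction_bins([])
    assert sum(counts.values()) == 0 and missing == 0
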