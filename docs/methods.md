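# Methods

## Model and procedure

The pipeline treats a bacterial methylome as a set of methyltransferase
(MTase) recognition-motif occurrences, each carrying at most one
per-position, per-strand SMRT-seq modification call at its methylated base.
Three call metrics drive classification:

* **modification QV** — Phred-scaled confidence that the base is modified,
  `p = 1 − 10^(−QV/10)`; the default cutoff QV ≥ 40 corresponds to p =
  0.9999;
* **methylation fraction** — modified reads over total reads covering the
  site (75 modified + 25 unmodified reads → 0.75);
* **coverage** — reads used to make the call.

Classification is a strict decision list: coverage < `coverage_cut` (30) →
`low_coverage`; else QV < `qv_cut` (40) → `unmethylated`; else fraction ≥
`fraction_cut` (0.75) → `methylated`, otherwise `undermethylated`. An
occurrence with no call at all is `unmethylated` with absent metrics, and
bypasses the coverage gate (there is no coverage to test). A passing QV with
a missing fraction is labeled `methylated` and flagged `fraction_missing`;
`strict` mode raises instead. Low-coverage sites keep an explicit label
rather than being dropped, so every occurrence remains auditable, but they
are excluded from all downstream tallies.

Occurrence enumeration expands the IUPAC motif to concrete base sets (N in
the genome matches nothing, including motif N) and scans the plus sequence
with the motif and with its reverse complement; a palindromic motif such as
GATC therefore yields one occurrence per strand at the same interval,
matching the strand-specificity of SMRT calls.

### Regions

The regulatory region (RR) of a gene runs from `upstream_bp` (500) before
the A of the ATG start codon to `downstream_bp` (100) after it. The
downstream window counts the A as position 1, so the RR of a plus-strand
gene starting at s is [s−500, s+99]; this puts offset 0 of the enrichment
profile at the A itself (the alternative reading — the window beginning
after the ATG triplet — would shift everything by 3 bp and can be obtained
by passing `downstream_bp` against a shifted anchor; we fixed one convention
and document it rather than exposing a confusing toggle). If the nearest
same-strand upstream gene ends at e ≥ s−500 the RR starts at e+1; if that
gene overlaps the start codon (e ≥ s) the RR collapses to the downstream
window alone, since the stated rule would otherwise invert the interval.
Opposite-strand genes never truncate. On circular contigs RRs wrap the
origin and are emitted as two BED rows sharing a name; the default is
linear with clamping at the contig bounds.

Intergenic regions are the complement of CDS ∪ RR (configurable to
complement-of-CDS-only), so the three kinds jointly cover the contig and a
base is never unaccounted for. Regions may overlap; intersection is
multi-assignment — a site in two genes' RRs is reported under both — and
offsets use the site's methylated base, not the motif match start, because
the methylated base is the biological signal position.

### TFBS scanning

PFM → PPM: `(count + pc·bg_b) / (col_total + pc)` with pseudocount pc = 0.1
distributed by background composition; PPM → PWM: `log2(p / bg_b)`.
Background defaults to 0-order genome base frequencies (Laplace-smoothed so
every base has positive mass), uniform by flag. The null distribution of
window scores is computed exactly: per-column scores are discretized to
`granularity` (1000) bins per largest column range and convolved across
columns under the background; enumeration over all 4^L sequences pins the
discretization error in tests. The scan threshold is the minimal achievable
score whose exact tail probability is ≤ α (default 1e-4, matching the
conventional scanner cutoff); hits report their exact p-value. Both strands
are scanned by scoring the plus sequence with the matrix and its
reverse-complement; windows containing N are skipped; overlapping hits are
all reported (no merging — downstream RTMG membership only needs
existence). P-values are raw, matching the fixed-threshold convention; a
Benjamini–Hochberg column could be layered on but is deliberately absent by
default.

Scanning is restricted to RRs holding at least one methylated or
undermethylated site (`--all-regions` overrides). Undermethylated sites
count toward RTMG membership: partial protection of a site is precisely the
TF-competition signature the co-location analysis looks for. Each RTMG
record carries `min_distance_bp`, the distance from any (under)methylated
base to the nearest TFBS edge (0 inside), making "adjacent" quantitative
and filterable.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| qv_cut | 40 | Phred | unmethylated below, (under)methylated at/above |
| fraction_cut | 0.75 | — | methylated at/above, undermethylated below |
| coverage_cut | 30 | reads | low_coverage below |
| upstream_bp / downstream_bp | 500 / 100 | bp | RR extent around the ATG |
| pvalue_threshold (α) | 1e-4 | — | exact-p cutoff for TFBS hits |
| pseudocount | 0.1 | counts | PPM regularization, background-weighted |
| background | genome | — | 0-order null composition (or uniform) |
| granularity | 1000 | bins | score discretization per column range |

Fraction-bin edges for the ratio table are [0, 0.60), [0.60, 0.75),
[0.75, 0.90), [0.90, 1.0] — left-closed, last bin closed, chosen so the
touching printed ranges partition [0, 1] unambiguously.

## The synthetic generator

`methyreg.fixtures` emulates the full input set: a random genome at a
stated GC content; non-overlapping genes (one per equal-length block, ≥600
bp upstream gaps so every RR is full-length, ATG implanted at each start);
motif occurrences implanted at non-overlapping positions with classes drawn
from a target mix; a basemods GFF whose QV/fraction/coverage are drawn
strictly inside each class's threshold region (methylated QV 45–70,
fraction 0.80–1.0; undermethylated fraction 0.10–0.70; unmethylated QV 5–35
for half the sites and no call for the other half, exercising both
unmethylated pathways; low-coverage coverage 5–25), so label recovery is
exact by construction, not statistical; and, for the designated RTMG genes,
a methylated motif plus the TF consensus implanted in the RR's upstream
half. Incidental motif occurrences arising by chance in the background are
detected post hoc and enter the truth as unmethylated (no call emitted).

The expected RTMG set is computed at generation time: genes with an
implanted (under)methylated site inside their derived RR, intersected with
genes whose RR contains a window passing the scan threshold — the latter
checked by brute per-window log-odds scoring on both strands, a code path
independent of the sliding-window scanner under test. With sharpness-1
consensus implants and α = 1e-4 this includes the implanted genes and any
chance near-consensus co-locations, so fixture tests assert set equality,
not just recall of the implants.

What the generator does **not** emulate: read-level kinetics (IPD ratios
are decorative), operon structure, RR truncation (gene spacing prevents
it — the truncation rule is unit-tested directly), overlapping genes,
multi-contig assemblies (single contig by default; contig handling is
exercised in I/O tests), and realistic base composition beyond 0-order GC
content. Passing fixture tests therefore demonstrate the pipeline's logic,
coordinate arithmetic and threshold behavior — not robustness to the noise
structure of real SMRT-seq calls.

## Numerical choices and determinism

* Coordinates are 1-based inclusive internally; the single 0-based
  half-open conversion happens at the BED boundary (and in Circos tracks).
* Score discretization: rounding to the nearest bin bounds the per-window
  score error by L·δ/2; the enumeration oracle tests bracket DP tails
  between enumeration tails shifted by that slack.
* A degenerate (all-columns-constant) PWM yields a point-mass distribution.
* If no achievable score meets α, the threshold is +∞ with a warning and
  the scan returns no hits.
* Ties: duplicate locus tags get `_1`, `_2` suffixes in file order; all
  tables sort deterministically; the run manifest's timestamp field is left
  empty by default so re-runs are byte-identical (a run label can be set
  explicitly when provenance matters more than reproducibility).
* Genome ambiguity codes other than N are normalized to N with a warning
  rather than rejected, since real assemblies contain them; N never matches
  a motif letter.

## Problem sizes

Default test and acceptance workloads use a 100 kb single-contig genome
with 60 genes and ~400 implanted GATC occurrences (~1.6 k total with
background matches), a 12-bp TF consensus and 5 RTMG implants; the shared
unit-test fixture is 30 kb / 18 genes / 120 occurrences. Oracle suites run
200 random motif-scan pairs (≤5 kb), 100 random intersection fixtures
(≤500 sites × ≤100 regions) and full 4^L enumeration for matrices up to
L = 6. The whole suite completes in well under a minute.

## Known limitations

* No statistical test on the positional enrichment profile — it is a
  histogram, as in standard practice for this analysis.
* No operon inference: a site upstream of the first gene of an operon is
  attributed to that gene only.
* m5C detection reliability depends on much deeper coverage than m6A/m4C;
  the classifier treats all types identically and leaves coverage judgment
  to the coverage gate.
* Off-motif modification calls are reported, not classified.
* Only cis co-location is modeled; trans effects of methylation on
  regulators are out of scope.
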