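# Methods

## Repeat detection

Tandem arrays of period 1–6 bp are found in three stages. (1) *Seeding*:
positions where `seq[i] == seq[i+p]` are collected into maximal runs; a run
repeating at least one full period becomes a seed, provided its unit is
primitive (a homopolymer is a period-1 repeat, not a degenerate period-4
one). Candidate regions never span an N. (2) *Joining*: neighbouring seeds
with the same canonical unit are chained when bridging the gap pays off
under the scan's alignment weights (+2 per matched position, −7 per gap
base), i.e. maximal positive-scoring chains in the Kadane sense. This is
the package's maximality criterion: a candidate is extended exactly while
the alignment score increases. Match-percentage maximality was considered
and rejected — one mismatch amortised over a long perfect array keeps the
percentage high, so any threshold-based extension rule would absorb
arbitrary random flank; score maximality returns a planted perfect array
with its exact boundaries. (3) *Re-scoring*: each candidate is aligned
against its repeat unit by wraparound dynamic programming (free start and
end phase, pattern wraps modulo the unit) with the same +2/−7/−7 weights.

Reported statistics: `copy_number` = array length / period (partial
trailing copies count fractionally); `match_pct` = matched columns /
aligned columns × 100 (the indel-inclusive reading of "match percentage" —
the alternative, indel-excluded reading is noted as ambiguous and not
used); `longest_perfect_run` = the longest run of exact unit copies at any
phase. Overlapping calls with one canonical unit are merged and re-scored;
across units the higher-scoring call wins, ties broken by smaller period,
then leftmost start. Canonical units are the lexicographically smallest
rotation with two field-convention overrides (GAAA rather than AAAG, CAG
rather than AGC).

Screen thresholds are strict as stated: copies ≥ 12 inclusive, match
percentage > 90 exclusive. Inside `screen_candidates` the detector runs
with relaxed discovery thresholds (copies ≥ 5, match > 75) so that
near-miss loci are still emitted, with criterion (i) applied afterwards as
an auditable pass/fail — the screen's output is a provenance table, not
just the accepted subset.

## CpG islands and restriction sites

Islands may be supplied as an annotated BED track (preferred) or computed
with the classic composition rule: sliding windows of `min_length` (200 bp,
step 1) with GC ≥ 0.50 and observed/expected CpG ≥ 0.60, where obs/exp =
(#CpG × L)/(#C × #G). Qualifying windows are merged; a merged island that
no longer satisfies the thresholds is trimmed from its edges until it does,
so every reported island re-tests positive under its own definition.

Restriction sites are matched under IUPAC semantics on both strands
(palindromic sites reported once); the built-in table covers AciI (CCGC),
BstUI (CGCG), FauI (CCCGC, non-palindromic — both strands scanned;
cleavage-offset chemistry is irrelevant to the screen and ignored), HhaI
(GCGC) and HpaII (CCGG). Sites of different enzymes whose CpG dinucleotides
coincide are cross-flagged, because methylation of a shared CpG can block
the neighbouring enzyme and make per-enzyme ratios disagree.

## Distance conventions

Intervals are 0-based half-open internally; BED I/O keeps that convention,
GFF3 and printed coordinates are 1-based inclusive. Two repeat-to-feature
distances are exposed: `start_to_start` (|Δstart|, the convention that
reproduces browser-style printed offsets such as the 230 bp between the
tetranucleotide repeat at chrX:46695765-46695834 and the CpG island at
chrX:46695995-46696984) and `edge_gap` (bases strictly between the
intervals, 0 when touching or overlapping). The proximity filters use
`edge_gap` with a strict `< 300` test, so a gap of exactly 300 bp fails and
a repeat inside an island trivially passes; reporting defaults to
`start_to_start`. The gene behind an island is assigned by nearest
annotated TSS within a 2 kb window; with escape filtering enabled, an
island that cannot be linked to any gene cannot be cleared and the
escape sub-criterion fails, while a locus with no nearby island at all is
judged only by the proximity sub-criterion.

## XCI quantification

Allele sizes are always called from the undigested run (digestion can
abolish a peak entirely); digested peaks are matched to those sizes within
±1 bp. A peak one repeat unit below a taller peak is treated as stutter
and excluded from allele calling unless its area exceeds half the taller
peak's — a genuine one-unit-shorter allele is comparable in area to its
neighbour, a stutter product is not.

Stutter correction uses a single-position proportional model: the
artifact sits one repeat unit below a true allele with expected area
`stutter_fraction ×` the true-allele area. When the two alleles are
exactly one unit apart the shorter allele's observed area contains the
longer allele's stutter and is corrected by subtraction (floored at zero;
a subtraction overshooting by more than 5 % of the observed area raises a
`stutter_overcorrection` flag). Default fractions are 0.026 for the
tetranucleotide GAAA locus and 0.176 for the trinucleotide CAG locus;
`estimate_stutter_fraction` re-estimates them as the mean stutter/true
ratio over single-allele (hemizygous) samples, with absent stutter
contributing zero. More elaborate cascade models (stutter of stutter,
n−2 positions) are deliberately out of scope.

The Xi fraction of allele 1 is `(d1/u1)/(d1/u1 + d2/u2)`; dividing each
digested area by its undigested companion cancels per-allele amplification
bias, so equal digested and undigested profiles give exactly 0.5 and
swapping allele labels maps r to 1−r. Classification is two-class —
random for a main inactive allele ≤ 80 %, non-random above — with an
additional `extremely_skewed` reporting flag at ≥ 90 % (a phrase used in
practice without a standard threshold; the flag does not change the
class). Results from different enzymes are reported separately, never
averaged, with a discordance warning when they differ by more than 15
percentage points. Digestion QC on single-X (male) controls passes when
residual digested/undigested signal is ≤ 5 %.

Population statistics: observed heterozygosity is the direct count over
typed females (males are hemizygous and excluded from the denominator but
contribute alleles to the frequencies); expected heterozygosity 1 − Σp²
is computed alongside, observed being the default report. Combined
informativeness of a multi-locus panel is either empirical (fraction of
samples heterozygous at ≥ 1 locus) or the independence approximation
1 − Π(1 − H), averaged with equal weight over population subsets.
Concordance between loci is the Spearman rank correlation (ties
mid-ranked) with a 95 % CI from the Fisher z transform, half-width
1.96/√(n−3) — the conventional choice when only the statistic, not the
method, is prescribed. Trio phasing calls the child's Xi maternal when the
Xi-bearing allele occurs in the mother only, paternal when in the
(hemizygous) father only, ambiguous when in both, and raises a Mendelian
inconsistency when in neither.

## Synthetic data

The genome generator writes planted features onto a seeded random
background from which every CpG has been rewritten, so all islands and
methylation-sensitive sites exist only where planted. Planted CpG islands
hit their GC/obs-exp targets with every CpG embedded in an A·CG·T motif,
which provably cannot form any of the five enzyme recognition sites —
site placement stays fully spec-controlled. Planted repeats are flanked by
phase-breaking bases so the detector recovers their exact coordinates, and
arrays below 100 % purity are built as equal chunks separated by single-C
interruptions, giving a predictable match percentage of
matches/(matches + interruptions). Feature overlaps and out-of-bounds
placements are spec errors. Everything is emitted to a truth TSV and
regeneration from the same spec and seed is bit-identical.

The cohort generator draws per-haplotype Hardy–Weinberg genotypes (males
hemizygous) and one Xi-skew parameter per female shared by all loci (both
marker loci ride the same X haplotypes, which is what makes two-locus
readouts concordant). The default skew distribution is a mixture: 70 %
random XCI with the Xi fraction drawn from Beta(14, 14) (main inactive
allele mostly 50–80 %) and 30 % skewed at 85/90/95/99 % with random
orientation. The Xi allele is modelled as fully methylated (uncut) and the
Xa allele fully unmethylated, cut with a digestion-efficiency scalar
(default 1.0); overlapping-site cleavage interference is *not* modelled
beyond that scalar. Peak areas get multiplicative log-normal noise
parameterised by a coefficient of variation; the default CV is 0.05,
chosen as a realistic replicate CV for capillary peak areas and consistent
with the package's calibration conditions (mean recovered skew within 3
percentage points of truth at n = 50 per stratum, two-locus concordance
r ≥ 0.9 at 5 % noise). Stutter peaks are added one unit below each true
allele at the locus fraction. Amplimer size is a constant locus offset
plus unit-length × unit-count, so unit counts and sizes interconvert in
tests. With zero noise and full digestion the simulate → quantify loop
returns the planted Xi fractions exactly.

What the simulations do **not** emulate: raw electropherogram traces
(baseline, size calling), PCR competition between loci in a biplex,
tissue differences, partial or heterogeneous CpG methylation, and
chimerism (relevant to marmoset hematopoiesis). Passing tests therefore
demonstrate the correctness of the arithmetic and the screen's decision
logic under the stated generative model, not robustness to every artifact
of real capillary data.

## Problem sizes and numerics

The planted-grid analyses use one locus per condition on a single
chromosome (about 3.2 kb per block; the 501-gap grid is a 1.6 Mb
chromosome and screens in about a second). Monte-Carlo checks use 50–60
samples per condition with fixed seeds. Stutter-conservation and ratio
identities are asserted to 1e−9 relative; interval coordinates and
threshold boundaries are exact integers. Degenerate inputs are errors,
not silent results: empty units, invalid alphabet characters (reported
with their offset), allele dropout (undigested area 0), complete digestion
of both alleles, fathers with two alleles, and Mendelian-inconsistent
trios all raise typed exceptions.

## Known limitations

* The repeat finder is a deterministic seeded scanner, not a probabilistic
  model; arrays whose interruptions are dense enough to leave no
  full-period seed (no stretch of ≥ 2 exact copies) are invisible to it.
* The stutter model is single-position and proportional; loci with heavy
  multi-step stutter (dinucleotides) would need a cascade model.
* Escape-gene status is an input list; the screen does not infer it.
* CGI→gene linkage by nearest TSS within 2 kb is a heuristic; promoters
  shared by divergent gene pairs will link to the closer TSS only.
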