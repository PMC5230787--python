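# Methods

This note documents the models, conventions and numerical choices behind
`kevtools`, and what the synthetic-data tests do and do not establish.

## The KEV model

A translatome experiment measures, per gene, four quantities × replicates:
intensity in the free and the polysomal RNA fraction, in an untreated and
a drug-treated culture. The per-replicate translational efficiency (TE)
is the polysomal/free quotient; it is undefined (recorded as missing,
never as zero) when either intensity is missing, zero or negative.

**Aggregation.** The drug effect is the ratio of *condition means* of TE,
not the mean of per-replicate ratios: replicates are independent cultures
and are not paired across conditions, so a per-replicate treated/untreated
ratio has no experimental meaning.

**Normalization.** Channel scalings of microarray-style intensities are
arbitrary, so only the relative drug effect across genes is identified.
We subtract the median of raw log2 ratios from every gene, making the
median log2 KEV exactly 0: "KEV = 1" *means* the average drug effect.
The median is preferred over the mean because the effect distribution has
heavy tails (the sensitive/resistant genes themselves). Consequence:
KEVs are invariant under any global rescaling of either condition's
intensities (tested).

**Outlier screen.** Visual removal of "obvious outliers" at high CV is
formalized as: if CV = sd/mean ≥ `cv_threshold` (0.60) and n ≥ 4, remove
the single value whose removal most reduces the CV, provided it lies more
than `outlier_k` (2.0) sample standard deviations from the mean of the
others; applied at most once, and never when removal would leave fewer
than two values for both the filter (n ≥ 4 guard) and a defined sd.
The rule is checked against a brute-force leave-one-out search.

**Classification.** Sensitive iff KEV ≤ 0.5, resistant iff KEV ≥ 2.0,
both boundaries inclusive; otherwise average. Genes failing the
replicate filter (fewer than `min_replicates` = 3 usable TEs in either
condition) are "excluded" with a reason, and every input gene appears in
the output exactly once.

**Per-gene test.** Two-sided Welch (unequal-variance) t-test on log2 TEs.
Log scale because TEs are strictly positive ratios; Welch because the
outlier screen and dropout make replicate counts and variances unequal
between conditions. Caveat, measured precisely during development: at
five-vs-five replicates the Welch test is conservative — its true type-I
error at α = 0.05 is 0.0443 ± 0.0001, not 0.050. Student's t would be
nominally calibrated at equal n and equal variance (size 0.051) but
degrades badly exactly where this pipeline lives (size 0.06–0.07 at
variance ratios 2–4, size 0.032 at 3-vs-5 replicates), so Welch is kept
deliberately. P-values are reported raw; with a handful of planned
contrasts and an exploratory per-gene table, no multiplicity adjustment
is applied.

**Histogram.** log2 KEVs binned at 0.25 log2 units on a grid aligned to 0
(the bin width is a presentation choice, configurable).

## Start regions and SD detection

Windows cover 40 nt upstream of the start codon and the first 37 nt of
the ORF; the 3-nt codon is removed, so position labels run −40..−1 and
+4..+40. Reverse-strand genes are reverse-complemented first; windows
running off a contig end are N-padded and flagged. Coordinates are
1-based inclusive in all reports, 0-based half-open internally.

The SD detector scans candidate 8-mers whose 3' ends lie 2–12 nt upstream
of the codon, scores each position-wise (ungapped) against `TAAGGAGG`
(N never matches), keeps the candidate maximizing (total matches, longest
run, smaller distance), and calls the motif present iff total ≥ 5 or run
≥ 4. This criterion is not from first principles: it is the simplest
rule that reproduces all 19 expert yes/no calls in the bundled reference
set of experimentally mapped 5' ends, and it is fully configurable.
The "distance to AUG" counts nucleotides strictly between the site's 3'
end and the first codon base. The register aligning printed site
sequences to the consensus is taken as ungapped at offset 0; mutating any
site position toward the consensus can never flip a present call to
absent (tested as a monotonicity property).

Leaderless calls: strict iff 5'-UTR ≤ 4 nt, relaxed iff ≤ 7 nt. Two
mapped 5' ends within `end_tolerance` (3 nt) count as the same
transcription start.

## Structure logos

Per position, I = Σ_b q_b log2(q_b/p_b) bits, with 0·log 0 ≡ 0, where p
is the *gene set's own* pooled composition — so a logo shows deviation
from that set's expectation, not from a genome-wide or uniform model.
Letter heights are sign(q_b − p_b) · q_b · I (ties treated as
over-represented), which satisfies the conservation law Σ_b|height_b| = I
and reduces to the Shannon logo height (2 − H) under a uniform
background. An alternative |q_b − p_b|-proportional convention exists in
the logo literature; this one was chosen for the conservation law and the
upright/inverted semantics. A pseudocount of 0.5 per base is added to
per-position and background counts (gene sets of ~100 windows routinely
have empty cells); N bases are excluded from all counts. Published bit
values from a specific gene set are not reproduced here — that requires
the original gene lists and genome — but on simulated sets with planted
SD motifs the information maximum lands in the SD region (−12..−7) at
0.2–0.5 bit, the same order as real translatome gene sets.

## Feature enrichment

Intergenic distance = (annotated start) − (upstream same-strand gene's
annotated end) − 1 in 1-based inclusive coordinates; overlaps are
negative and count as "< 15 nt" (overlap is the strongest evidence of
operonic continuity, e.g. overlapping stop/start codons in
translationally coupled pairs). Operon-position percentages use the
genes listed in the external operon annotation as denominator; the
intergenic-distance criterion uses the whole group. Percentages are
rounded half-up to integers. The association test is the two-sided
Fisher exact test (hypergeometric tail summation), with the sample odds
ratio a·d/(b·c), Haldane-Anscombe 0.5 correction when a cell is zero;
the p-value is verified against an exact rational-arithmetic enumeration
oracle.

## The synthetic world

Defaults state the emulated experiment: 2801 genes, 5 replicates (two
carrying dye-swap metadata with no value effect — the schema matches a
real experiment; no dye-specific correction is modeled), ~3.6% planted
sensitive and ~4.9% planted resistant genes at ±2 log2 units.

* **True effects**: average genes draw log2 KEV ~ N(0, `log2_kev_sd`);
  the default 0.55 makes the Gaussian tails beyond ±1 log2 roughly match
  the observed sensitive/resistant fractions of a real Kasugamycin
  translatome. Planted genes sit at exactly ±`effect_log2`. Truths are
  median-centered at generation, so ground truth lives on the same
  normalized scale as the estimates and noiseless recovery is exact
  rather than exact-up-to-a-constant. Class labels in the ground truth
  come from the thresholds applied to the centered truth, so a wide
  "average" draw past a threshold is labeled by its value.
* **Noise**: log-normal multiplicative, per measurement, with
  σ = sqrt(ln(1+cv²)); default `noise_cv` 0.20 (a free parameter — the
  source experiment reports no replicate dispersion to calibrate
  against). Expectations about ratios hold in the geometric-mean sense.
* **Outliers**: with probability 0.01 a measurement is multiplied or
  divided by 8 — the gross, visually obvious kind the CV screen targets.
* **Dropout**: each measurement is independently missing with
  probability 0.05; a missing intensity kills that replicate's TE.
* **Sequences**: windows drawn i.i.d. from `base_composition`
  (A 0.29, C 0.22, G 0.23, T 0.26, matching measured start-region
  fractions); SD consensus planted in 55% of genes at a uniform 3–7 nt
  spacer. The planted site is the exact consensus by default
  (`sd_plant_mismatches` mutates it).
* **Annotation**: operon position multinomial (35/35/30%
  single/first/distal by default); distal genes draw short intergenic
  distances (geometric, shifted to allow overlaps), first genes long
  ones; 5'-UTR lengths log-normal with median ~60 nt plus a 2%
  explicitly leaderless fraction; per-class distal rates can be planted
  for power studies.

What a green test does *not* establish: real microarray data have
correlated probe effects, intensity-dependent (nonlinear) biases, dye
bias, and non-log-normal error tails; sequences are not i.i.d. draws.
The simulator validates the statistical machinery and its bookkeeping,
not robustness to those artifacts.

One enumeration subtlety: the SD false-positive rate under a uniform
background is verified against exhaustive 4^8 enumeration with the scan
restricted to a single register, because overlapping candidate windows in
the full 2–12 scan are statistically dependent and admit no closed form
from the single-window law.

## Degenerate inputs and tie-breaks

* TE undefined (≤ 0 or missing intensity) → replicate dropped with
  reason, never coerced to 0.
* Outlier screen with n < 4, or candidate failing the `outlier_k`
  criterion → nothing removed; the summary keeps a high-CV flag.
* compute_kevs with a zero/invalid mean TE → gene excluded with reason.
* SD scan on sequences shorter than one candidate → absent with reason
  "too short" (leaderless inputs are legitimate).
* Logo maximum ties → most upstream position.
* Annotated start codon outside {ATG, GTG, TTG} → warning, not error
  (real annotations contain rare non-canonical starts).
* Percentage rounding: half-up (floor(x+0.5)), matching how published
  feature tables round.

## Known limitations

* No dye-bias or background correction; the pipeline starts from
  summarized intensities.
* The SD criterion is a reverse-engineered surrogate for expert calls on
  19 transcripts; other consensus lengths/registers need re-tuning.
* Logos are sequence-only; the original "structure logo" method also
  annotates base pairing, which is out of scope here.
* The Welch p-values are conservative at n = 5 (see above); downstream
  consumers should treat them as screening values, as the source design
  does.
* `simulate_annotation` draws features per gene independently; it does
  not lay out a physically consistent genome (no shared operon objects
  linking neighbours' distances).
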