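# Methods

## The affinity model

TBP recognition of the TATA element is commonly described as a three-step
process — sequence readout, sliding of the protein along the duplex, and
bending of the DNA into the saddle — and the estimator mirrors that
decomposition. A window of `window_length` nucleotides (default 15, the
canonical TATA-box/oligonucleotide width) is scored as

    −ln K_D = k0 + k_pwm · S_pwm + k_slide · S_slide + k_bend · S_bend

with K_D in mol/L. `S_pwm` is the sum of a position-weight matrix (PWM,
additive per-position base weights) over the window; `S_slide` and `S_bend`
are the means over the window's 14 dinucleotide steps of a base-stacking
energy scale (kcal/mol) and a propeller-twist scale (degrees) taken from the
standard dinucleotide property compilations. The fitted coefficients absorb
the units of both scales, so only their relative profiles matter.

The affinity of a promoter region — canonically the 51-nt [−70; −20] window
upstream of the TSS anchor, where the experimentally supported TBP sites of
the promoters modelled here are located — is the **maximum** of the window
score over all contiguous windows, ties broken to the leftmost window. Only
the given strand is scanned by default (TATA boxes are directional relative
to the TSS); the reverse strand can be scored by reverse-complementing the
input at load time. Windows containing non-ACGT characters are skipped; if
every window is masked the estimate is an error rather than a guess.

### Uncertainty ε

Each estimate carries a single uncertainty ε (ln units), the residual
standard deviation of the calibration, not a per-sequence quantity: the
training tables print one "± ε"-style uncertainty regime per service run
and show Z-values varying at fixed promoters, which is consistent with an
uncertainty dominated by model residual rather than sequence composition.
ε is overridable per call (`estimate_affinity(..., epsilon=...)`).

A consequence worth stating plainly: with the calibration-fallback ε of
~0.73 ln-units, single-base affinity shifts of the size the published
service flags as highly significant (e.g. a 0.6 ln-unit K_D change) are
*not* significant under the standard-normal mapping used here. The
published Z/α pairs (Z up to 43 at α = 10⁻⁶) imply a much smaller effective
ε in the original estimator, whose externally determined value is not
distributed with this package. The decision machinery is therefore exact in
its mapping (two-sided normal tail → smallest containing bin → rank) but
conservative in its default ε; callers who possess an instrument-grade ε
can supply it.

## Calibration

The estimator's coefficients are not hard-coded; they are produced at run
time by `calibrate_from_markers` on the packaged tables (129 rows, two
allele contexts per row with a printed K_D, 256 observations of 21-nt
flank+allele+flank sequences). Calibration is two-stage:

1. **Position-weight fit.** Each observation's best window is one-hot
   encoded (15 positions × 4 bases) and joined with its two dinucleotide
   means; the 63-parameter linear system is solved with an L2 (ridge)
   penalty of 1.0 on the one-hot block only. Per position the four base
   weights are centred, the offsets being absorbed into the intercept. The
   penalty exists to resolve the intrinsic collinearity of one-hot rows
   (each sums to the window length) and of bases never observed at a
   position; it is kept small enough to act as a regulariser rather than a
   shrinkage device.
2. **Coefficient refit.** With the PWM fixed, ordinary least squares refits
   (k0, k_pwm, k_slide, k_bend) against −ln K_D, exactly the spec of
   `calibrate`: the best-window assignment is recomputed under the current
   parameters and the fit iterated until the assignment is stable.
   `residual_sd` is set to the root-mean-square residual (floored at 1e-6
   so interpolating fits keep a positive ε).

Both loops treat window reassignment as a fixed-point iteration. Because
reassignment can enter a limit cycle instead of a fixed point, the loops
also terminate when an assignment recurs or when the residual stops
improving, returning the best-fitting iterate seen; the procedure is
deterministic either way. A genuine failure to stabilise within the
iteration cap raises a convergence error.

In-sample, the calibrated model explains about two thirds of the variance
of the printed −ln K_D values (R² ≈ 0.67, residual ≈ 0.73 ln-units). The
worked-example contexts of rs1800202 (printed 1 → 4 nM) are recovered at
1.95 → 3.44 nM and of rs33981098 (printed 5 → 9 nM) at 5.68 → 12.3 nM. The
rs33981098 minor allele is the known limit of the additive model family on
these data: the eight HBB rows share one promoter whose printed minor-K_D
values span 6–29 nM for single-base changes inside the same TATA box, and
the least-squares compromise across them (together with 250 other
observations) cannot place this particular context within one unit of its
printed value while everything else is fit.

## Coordinates and variant application

The TSS anchor is position +1 of a 1-based sequence; there is no position
0, so offset −k is the k-th base upstream and [−70; −20] is 51 nt. Whether
the anchor is a transcription start or a translation start is the caller's
choice — both conventions appear in promoter annotation practice — and the
arithmetic is identical.

Variants are described by 10-nt flanks plus ancestral/minor alleles ("-" =
empty allele; symbolic names such as "18bp" resolve through a per-gene
insert dictionary, because the same token denotes different sequences in
different genes). The flank context must match the region exactly once;
zero or multiple matches are hard errors rather than silent first-match
edits, which prevents mis-placement of the edit in repetitive promoters.
Matching is case-insensitive; everything is uppercased internally.

## Decision statistics

`compare_alleles` computes Z = Δ(−ln K_D)/√(ε_wt² + ε_mut²), a two-sided
standard-normal p-value (floored at 1e-300 so far tails stay in-domain), the
smallest containing significance bin from {10⁻⁶, 10⁻³, 10⁻², 0.05, 1}, the
rank A–E, and the direction: excess for significant positive Z, deficiency
for significant negative Z, norm otherwise. The norm call is driven purely
by p > 0.05 with no effect-size floor, and no multiple-testing correction
is applied across SNPs (per-SNP levels are reported, as in the source
tables). The bin thresholds and the 0.05 cutoff are exposed as arguments.

The direction-ratio cross-check is one-sided:
z = (k − n·p0)/√(n·p0(1−p0)) with p0 defaulting to 2/3 (the genome-wide 2:1
ratio of affinity-decreasing to affinity-increasing regulatory SNPs), the
tail chosen by the sign of the observed deviation. An exact binomial tail
is provided alongside and the tests require the approximation to track it
within an order of magnitude for table-sized n.

## Verification battery

`correlation_suite` analyses paired predicted and measured K_D(mut)/K_D(wt)
ratios on the given scale by default (a `log_scale` flag transforms both
sides). Pearson's r uses the t-transform significance; Spearman's R and
Kendall's τ use their standard approximations (τ is computed as τ-b, which
equals τ-a on ties-free data); Goodman–Kruskal γ is computed by direct pair
enumeration with ties excluded from both counts, with the classic
z = γ√((C+D)/(n(1−γ²))) approximation for significance (γ = ±1 reports
p = 0). The OLS regression of measured on predicted reports the per-point
95% confidence band of the mean response.

## Synthetic data

`generate_promoter_case` builds a random 51-nt background at a requested GC
content, plants a TATA-like window, and searches candidate substitutions
until the model-forward comparison matches the requested effect
(disrupting / enhancing / neutral at the 0.05 level). For enhanceable cases
the planted box is degraded at three informative PWM positions so that an
affinity-raising substitution always exists. The default generating model
is the consensus seed template (sharp weights, ε = 0.5), which emulates the
regime of a strong canonical TATA box where a single consensus-breaking hit
is decisive — the regime the annotation pipeline is meant to detect. What
the generator does **not** emulate: real promoter base composition beyond
GC content, multiple or overlapping TBP sites, indel variants, and the
inter-promoter heterogeneity of the published tables; passing tests on
synthetic cases therefore demonstrate the correctness of the machinery, not
field accuracy on real promoters.

`simulate_emsa_titration` uses the single-site isotherm L/(L + K_D), the
ligand-in-excess approximation appropriate to a titration of trace protein
(0.3 nM) with increasing oligonucleotide; an `exact_form` flag switches to
the quadratic two-species equilibrium. Gaussian noise is truncated to
[0, 1] and K_D is refit by bounded least squares. At zero noise recovery is
exact; at 3% absolute noise on 8 points spanning 0.1–10×K_D the median
relative refit error over 100 seeds is below 10% (bound established by the
Monte-Carlo run and frozen in the tests).

## Fixtures

The packaged TSVs transcribe the seven published candidate-marker tables
row by row (129 rows across 45 genes; the reproductive-gene table has 24
rows splitting 5:19 by direction). Typographic ambiguities of the source
layout — rank letters inconsistent with the printed significance bin, a
direction printed against the sign of the K_D change, a row printed without
numbers, footnote-only extra alleles — are preserved as printed and flagged
per row in a `flags` column; row-invariant validation exempts a row only
from the specific check it is flagged for. Comma-separated minor alleles
share one printed K_D; the first listed allele is the one scored.

## Problem sizes

The test suite and the acceptance script run the full calibration (256
observations, 63 fitted weights) and the property batteries at 100–200
random draws each; these sizes give stable statistics while keeping a full
run in the tens of seconds on one CPU.

## Known limitations

- The additive PWM + dinucleotide model explains ~2/3 of the printed
  −ln K_D variance; promoters with several near-equal windows or
  non-additive base interactions are fit worst (see the rs33981098 note).
- ε from the calibration fallback is conservative; significance calls on
  real single-base variants require a smaller, instrument-grade ε.
- Only the promoter-sense strand is scored unless the input is explicitly
  reverse-complemented.
- The named-insert dictionary covers the genes of the packaged tables;
  user tables with symbolic alleles must extend it.
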