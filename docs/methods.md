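# Methods

## Poisson quantification

A ddPCR well partitions the reaction into `n_total` droplets; with template
distributed Poisson, the negative fraction estimates `exp(-λ)` and
`λ̂ = -ln(n_neg/n_total)`. Concentration is `λ/V_d` with `V_d` the droplet
volume in µl. `V_d` defaults to **0.85 nl**, the accepted volume for QX200
EvaGreen droplets; it is exposed everywhere because instrument generations
differ by a few percent, and all planning numbers in the test-suite and
acceptance script are stated under this default. Concentrations are per µl
of *assembled reaction*; a `dilution_factor` converts to per-µl of input
DNA.

**Confidence intervals.** A Wilson score interval on the binomial negative
fraction, transformed through the monotone map `λ = -ln p`. Wilson was
chosen over Wald/Clopper–Pearson because it is well behaved as occupancy
approaches 0 or 1 — exactly the edges of the usable dynamic range — without
the conservatism of exact intervals. No claim of bit-compatibility with
vendor software is made. Saturated wells (zero negatives) are *censored*:
they carry a finite lower concentration bound (from the Wilson upper bound
on p at 0 successes) and an infinite upper bound, never a point estimate.

**Ratios.** For `r = c_A/c_B`, each λ's standard error is recovered from
its interval width, relative variances add to first order, and the interval
is `r·exp(±z·σ_log)` so it stays positive. In a duplex well the two
per-target negative counts (fail + other-target singles) have zero
covariance under independent Poisson occupancy, so no covariance term is
needed.

**Gating-discrepancy error.** The expected gate occupancy is computed from
the Poisson model, `d` droplets are moved from the positive to the negative
gate and vice versa, λ is re-estimated each way, and the *mean of the two
absolute fractional changes* is reported. The two directions are asymmetric
at high occupancy (removing negatives matters more than adding them), and
the symmetric mean is the definition under which the standard planning
values (≈3% at 3000 copies/µl and ≈11% at 5000 copies/µl for a 100-droplet
discrepancy; ≈18% at 2 copies/µl and ≈6% at 6 copies/µl for 5 droplets)
are reproduced; a one-directional definition does not reproduce them.

**Dynamic-range planning.** The reference-concentration ceiling is
`cap · ploidy · ref_copies_per_genome / mCN` with the mitochondrial target
capped at 3000 copies/µl by default, below the ~4000 copies/µl inflection
beyond which partition statistics degrade rapidly.

## Calibration model and duplex design

Mean positive-droplet intensity versus primer concentration is fitted as
`I = plateau·(1 − e^{−k·c})` through the origin, with the plateau fixed at
30,000 fluorescence units by default (free on request, needing ≥3 distinct
concentrations). The rate constant is modelled as `k = (L/(a·E))²`; the
detector constant `a` defaults to 1235, an empirical value for the QX200
EvaGreen configuration, and inverting the square law gives a primer-quality
diagnostic `E = L/(a·√k)`. Fitting uses `lmfit` least squares seeded from
the algebraic single-point solution, so noiseless curves round-trip to
numerical precision.

Duplex concentration selection minimises the separation between the two
predicted single-positive means subject to a floor of
`separation_multiple · (sd_A + sd_B)` — minimal sufficient separation keeps
the brighter single positives clear of the double-positive band. A dense
grid (default 10–500 nM at 1 nM) locates the feasible optimum (the
objective is cheap and non-convex in the constrained region) and an exact
inversion then places the gap on the constraint boundary, tie-breaking
toward lower total primer. Population SDs default to empirical estimates
from gated droplets when available.

## Gating

Automated gating fits a seeded diagonal-covariance Gaussian mixture in
(Ch1, Ch2). Component means are initialised from the bands delimited by the
largest gaps in sorted Ch1 amplitude: ddPCR populations are extremely
unbalanced (a reference band of tens of droplets against ~14,000
positives), and an uninformed mixture reliably splits the dominant band
instead of finding the sparse one. Components are ordered by mean intensity
and labelled `fail < posB < posA < double`. Each population is summarised
as a Ch1 interval (±5 component SDs, clipped at midpoints between
neighbouring means) and counts are taken from those intervals, so cluster
and manual-threshold gating treat between-gate droplets ("rain")
identically. Rain is excluded from both gates by default (conservative), or
folded into negatives via `rain_to="negative"`. Per-target negatives in a
duplex well are `fail + other-target singles`; double positives are
positive for both.

Degenerate wells (all amplitudes identical) fall back to a single `fail`
population with a warning rather than failing.

## Copy-number statistics

`mCN = ratio · ploidy · (1 + pseudogenes)`; ploidy defaults to 2.
Reference copy number is inferred by rounding the multi:single-copy ratio
to the nearest integer within a tolerance (default 0.2); anything farther
raises rather than guessing. Gel-band heteroplasmy length-normalises each
band's fluorescence before taking the molar fraction. Depletion
detectability uses one-way ANOVA plus Scheffé pairwise contrasts at
group-wise α = 0.05, assuming homoscedastic groups (no Welch correction);
the Scheffé critical value is `(k−1)·F_{1−α}(k−1, N−k)`, which controls
the family-wise rate over all contrasts and is therefore conservative for
many titration levels.

## Quantal imaging model

The batch histogram of puncta intensities (Freedman–Diaconis bins by
default; binning is configurable since no canonical choice exists) is
fitted by `Σₙ Aₙ·N(n·q, σ₁√n)`, `n = 1..10`. `q` and `σ₁` are shared
across the batch — fixation and imaging conditions are constant within a
batch — while weights are per-cell. For fixed `(q, σ₁)` the model is linear
in the weights, so they are profiled out by non-negative least squares and
only `(q, σ₁)` are searched (Nelder–Mead in log space). The search starts
from `q` at the histogram mode and at 1/2 and 1/3 of it: the model is
degenerate under `q → q/m` relabelling, so among near-tied residuals the
*largest* q (most parsimonious multiplicity assignment) wins. Components
whose Gaussian lies essentially outside the histogram range are pinned to
zero weight, since their near-zero basis columns could otherwise absorb
unbounded weight invisibly. Weights are continuous ≥ 0, reported as
expected puncta counts. An optional constant baseline term (off by
default) accommodates a diffuse background of spurious puncta.

Cell-level mCN is `Σ intensities / q` — invariant to punctum merging, the
reason intensity-summing is preferred over punctum counting.
`batch_mcn_stats` reports mean, SD, a Shapiro–Wilk normality diagnostic,
and accepts a calibration scale for anchoring optical estimates to a
ddPCR-measured batch mean, the recommended way to make the optical assay
absolute.

## Synthetic data

The generators define the study conditions for all simulation-based tests.

*Droplets*: independent Poisson occupancy per target
(`λᵢ = cᵢ·V_d`); occupancy beyond one copy does not change the amplitude
class (end-point saturation). Default intensity geometry: fail 2000 ± 250,
posB 10000 ± 600, posA 18000 ± 600, double at the brighter single mean
+6000 (± 700) — the double band is a declared convention, not additivity,
since end-point co-amplification is not additive. Ch2 reads the same dye at
gain 0.55 plus noise. Rain is drawn uniformly between the fail ceiling and
the positive floor at a configurable rate (default 0).

*Puncta*: 36 cells, between-cell mCN Normal(970, 280) truncated positive,
nucleoid multiplicities truncated-geometric on 1..10 with p = 0.24 (mean
≈ 3.5 genomes/nucleoid, hence ≈ 275 puncta/cell), q = 1000, σ₁ = 150;
multiplicities are accumulated until the cell's genome target is reached
and their realised sum is the recorded truth.

*Titration*: expected ratio interpolates linearly between an untreated and
a depleted stock (default 135 → 85, a 37% depletion); technical replicates
(default 4) get multiplicative pipetting noise (CV 2% by default).
Droplet-partition sampling noise can be added by simulating binomial
negative counts at a stated reference concentration; it is off by default,
the merged-well regime in which pipetting error dominates replicate
variance.

These generators emulate partition statistics, population geometry and
quantal structure — not PCR kinetics, droplet-volume dispersion, true rain
mechanisms, optical segmentation artefacts, or NUMT cross-amplification.
Passing tests therefore validate the estimators under their stated
statistical model, not instrument-specific behaviour.

## Problem sizes and numerical choices

Simulation-based tests use 16,000-droplet wells, 10⁴ replicate wells for
interval-coverage checks, 20 batches for quantal parameter recovery, 60
seeded runs for end-to-end pipeline coverage and 300 replicates for
variance-ordering comparisons — sizes chosen to make binomial sampling
error small relative to the margins being asserted. Fits are deterministic
given seeds; Nelder–Mead tolerances are 1e-6 (parameters, log scale) and
1e-9 (objective).

## Known limitations

- Automated gating assumes well-separated bands; heavily overlapping
  populations (e.g. excessive rain) need manual thresholds.
- The ratio CI is first-order; at very low positive counts (< ~10) its
  coverage degrades together with the underlying binomial approximation.
- The quantal model's degeneracy under `q → q/m` is broken only by the
  parsimony tie-break; data genuinely lacking a unimer peak can still fit
  ambiguously, which is why calibration against ddPCR is recommended.
- The Scheffé procedure's conservatism understates detectability relative
  to less stringent post-hoc corrections.
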