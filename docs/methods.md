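# Methods

This note documents the models implemented in `xenospot`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generators do and do not emulate.

## Species assignment

Each sequenced template (read pair = one cfDNA molecule) carries a best and
optionally a next-best alignment score per genome. The decision rule is:

* `human_specific` iff a human best score exists, strictly exceeds the
  mouse best score (or mouse is unmapped), and strictly exceeds the human
  next-best score (or none is reported);
* `mouse_specific` symmetrically;
* `unmapped` iff neither genome has a best score;
* `unresolved` otherwise — cross-genome ties and within-genome
  multi-mapping ties.

Design choices: multi-mapping categories are collapsed into `unresolved`
because only species-specific fragments enter any downstream count; a
missing next-best score is treated as unique (conservative and
deterministic); fragments are counted once per template, never per mate,
since the tumour fraction is a molecule fraction. Classification is
deterministic, order-invariant, and symmetric under swapping the genomes.

The SAM adapter merges two name-sorted per-genome streams, reading best /
next-best scores from `AS` / `XS` tags and the fragment length from the
template length of the properly paired alignment. A template absent from
one stream counts as unmapped in that genome; orphaned mates and unsorted
input raise format errors naming the offending template.

## xTF

For a sample, with a strict length floor (default 30 bp, exposed as a
parameter):

    xTF = #human_specific(len > 30) / #(human_specific + mouse_specific)(len > 30)

Fragments of exactly 30 bp are excluded (the strict reading of the length
rule). Blacklist filtering removes any fragment overlapping a blacklisted
interval of its assigned genome by ≥ 1 bp; coordinates follow the BED
0-based half-open convention throughout. A zero denominator is an error
state, never a silent 0.

Time series are normalised per mouse by the day-1 value (a zero or missing
baseline excludes the mouse from slope fits, with a report entry). The
group-level change rate is a single pooled OLS of normalised xTF on day
over all mouse-timepoints of a patient-line × arm group — not a mean of
per-mouse slopes — matching how a single line is fitted across all mice of
a group. Fitting on raw rather than normalised values is exposed as an
option.

## In-silico dilution

Human patient pools are downsampled without replacement into a mouse
background at target fractions (default 1, 2, 5, 7, 10, 15, 25%), one
sample per (fraction, human pool) cell; pools are reused across samples,
mirroring the reuse of a fixed set of patients. The human draw is
`round(f·total)` and the mouse draw fills the total exactly. Linearity is
scored by Spearman rank correlation (midranks for ties); a constant
measured series reports NaN. Because the mixture operates on classified
fragment records rather than raw reads, re-alignment is skipped — a
fidelity limitation: alignment-stage artefacts cannot re-enter the mixed
sample. With error-free classification each sample's measured xTF is
binomially distributed around its expected fraction, which the tests
verify with exact 99.9% binomial envelopes.

## Absolute copy number

1. **Binning** — human-specific fragments are assigned to fixed-width bins
   (30 kb default, 500 kb for cross-sample comparison) by fragment
   midpoint; a midpoint exactly on a boundary goes to the higher bin.
2. **Bias correction** — bins are stratified into GC deciles ×
   mappability quintiles (quantile edges over usable bins); each count is
   divided by its stratum's median, with strata under 10 usable bins
   falling back to the global median, then rescaled to genome mean 1.
   Stratified median ratios were chosen over two-dimensional LOESS for
   determinism and a minimal tunable surface; correctness is asserted
   behaviourally (an injected multiplicative GC bias must at least halve
   the coefficient of variation after correction). Bins below a
   mappability floor (default 0.5) are unusable and excluded everywhere.
3. **Segmentation** — per chromosome, optimal partitioning minimising
   within-segment sum of squares plus a per-breakpoint penalty
   `10·σ̂²·log n`, with σ̂ estimated robustly from first differences
   (MAD / √2). The constant is stiffer than the classic SIC factor 2:
   copy-number steps at these depths are large relative to bin noise, and
   the stiffer penalty keeps pure noise from splitting while a height-1.0
   step at σ = 0.1 is still localised within ±2 bins in ≥ 19/20 seeded
   replicates. A zero-noise constant signal collapses to one segment via a
   penalty floor.
4. **ACN fitting** — grid search over ploidy ψ ∈ [1.5, 5.5] step 0.05 and
   cellularity c ∈ [0.1, 1.0] step 0.01, scoring each candidate by the
   segment-length-weighted mean absolute deviation of
   `absolute(r) = (r·D − 2(1−c))/c`, `D = cψ + 2(1−c)`, from the nearest
   integers. Ties break toward lower ψ, then higher c, so flat
   (ploidy-unidentifiable) profiles resolve deterministically to the
   diploid fit. For PDX blood spots cellularity defaults to a fixed 1.0 —
   the human-specific compartment is purely tumour-derived — with the full
   grid available. A guide ploidy (e.g. from the matched tumour tissue of
   the same patient line) restricts ψ to ±0.5 around the guide. Samples
   under 500,000 human-specific fragments are refused unless forced,
   reflecting the assay's operating floor.
5. **Driver calls** — gene-level total copy number is the
   overlap-length-weighted mean of segment values across the gene region
   (the summarisation rule is this package's choice); COSMIC rules:
   gain iff (ψ ≤ 2.7 and TCN ≥ 5) or (ψ > 2.7 and TCN ≥ 9); loss iff
   (ψ ≤ 2.7 and TCN = 0) or (ψ > 2.7 and TCN < ψ − 2.7).
6. **Profile comparison** — both profiles are projected onto a shared
   500 kb grid (overlap-weighted) and correlated bin-wise by Pearson;
   zero-variance profiles report NaN.

## Growth kinetics

Calliper volumes `V = π/6·h·w·d` (mm³) are modelled on the cube-root
scale, where subcutaneous growth is near-linear. For one patient line:

* fixed effects: shared intercept α; control arm slope β_c; treated arm
  continuous piecewise-linear with slopes β1 (pre-treatment-effect),
  β2 on [t1, t2), β3 (regrowth) — "point-wise" is read as continuous
  piecewise-linear, which is what an inflection-point analysis needs;
* random intercept per mouse ~ N(0, τ²);
* independent Gaussian residuals with arm-specific variances (treated
  responses are visibly noisier than controls).

Estimation maximises the marginal likelihood, profiling fixed effects out
by GLS (per-mouse Sherman–Morrison inversion of σ²I + τ²J) and optimising
the three log-variances with L-BFGS-B (ftol 1e-8 on the profiled
log-likelihood, ≤ 500 iterations). The blockwise likelihood is verified in
tests against a dense multivariate-normal density. Noiseless data take an
exact OLS path with zero variances. Designs with fewer than two mice in an
arm raise an identifiability error.

**Knots.** (t1, t2) are estimated by joint grid search over candidate
days — by default the interior observed treated measurement days (weekly
grid; the outermost days would make a hinge column collinear). Each
candidate pair is fitted and scored by the RSS of treated observations
around the population (fixed-effects) expectation, random effects zeroed.
Ties resolve to the earliest t1 then earliest t2; a flat RSS surface (no
treatment effect) is flagged non-identifiable.

**Inference.** Slope contrasts (regrowth vs pre-treatment β3 − β1;
treated vs control baseline β1 − β_c) are Wald tests with a small-sample
treatment: variance components are re-estimated by REML for the test, the
contrast variance receives a first-order Kackar–Harville inflation for
variance-parameter uncertainty, and the reference distribution is Student
t with Satterthwaite degrees of freedom — the lmerTest-style recipe. A
plain z-reference Wald on the ML fit is measurably anticonservative at
five mice per arm (~10% empirical size at nominal 5%); the adjusted test
simulates at ~6–7%, within the tolerated calibration band. Point
estimation remains ML. Families of within-line tests are Holm-adjusted
(family-wise control without independence assumptions).

**Outcome.** Time to endpoint is the first observed day with volume ≥
1,500 mm³ (censored mice report their censoring day), or the closed-form
crossing of the fixed-effects trajectory when extrapolation is requested.
Group mean xTF slopes are Pearson-correlated with t2 (treated groups
only — t2 is undefined for controls) and with mean time to endpoint.

## Synthetic data

The generators define the study conditions for all tests; truth is always
read from the emitted manifest, never re-derived.

* **Fragment lengths** are drawn from discretised unimodal pmfs: a narrow
  exponential core (scale 3 bp — the sharp nucleosomal peak, which also
  pins the empirical mode at the configured value for n ≥ 10,000) over
  asymmetric exponential shoulders (left scale 0.4·spread, right scale
  spread = 25 bp). Modes default to 146 bp (ctDNA) and 166 bp (cfDNA).
  The 10.4 bp nucleosomal periodicity is not modelled — only the modes and
  the sub-50 bp spurious class are load-bearing.
* **Scores**: genuine alignments get a cross-genome gap ≥ 5 and a unique
  within-genome best, so an error-free classifier recovers truth exactly.
  The spurious channel (rate 5×10⁻⁴ per mouse fragment) emits short
  human-only alignments, 85% below the 50 bp cap — reproducing the
  sub-0.1% false-positive human-call rate of tumour-free samples with
  mostly sub-50 bp lengths.
* **Coordinates** live on miniature two-chromosome toy layouts
  (30 Mb + 20 Mb per genome) so binning and segmentation stay desk-scale
  while exercising the same code paths; human positions are drawn
  proportional to an integer copy-number profile with optional
  multiplicative GC bias.
* **Cohorts** follow the piecewise mixed model exactly (defaults:
  α = 500^⅓, β1 = β_c = β3 = 0.12, β2 = −0.08 per day on the cube-root
  scale, τ = 0.3, σ_treated = 0.3, σ_control = 0.15, t1 = 8, t2 = 29,
  five mice per arm, weekly callipering from three weeks before dosing —
  tumours are measured from engraftment, which is what identifies the
  pre-treatment slope — blood spots on days 1/16/29). xTF at sampling days
  is the baseline xTF (5%) scaled by relative latent tumour volume with
  multiplicative log-normal noise (σ = 0.1), truncated to [0, 1]; in the
  noiseless limit xTF is exactly proportional to volume.

What the generators do **not** emulate: base-level sequence, alignment
errors beyond score gaps, mouse attrition/dropout, inter-mouse xTF
baseline heterogeneity, or the fragment-length periodicity. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical structure, not robustness to every artefact of real
sequencing data.

## Problem sizes

Simulation-based checks run at desk scale chosen for statistical
resolution: dilution series at 6.5×10⁵ fragments per sample (composition
counts verified at the full 6.5×10⁶), specificity at 0.5–1×10⁶ fragments,
segmentation over 20 seeded replicates of 100 bins, knot recovery over
100 cohorts, and test calibration over 500 replicates.

## Known limitations

* Segmentation is a least-squares changepoint fit, not CBS; equivalence
  with any specific external tool is not claimed — behaviour is specified
  by the contract tests above.
* The dilution module mixes classified fragments, not raw reads.
* Gene-level TCN summarisation over multiple segments (length-weighted
  mean) is a package choice; a breakpoint inside a small gene can dilute
  a focal amplification.
* The growth model has no dropout mechanism: mice are observed on the full
  day grid, whereas real endpoint rules truncate trajectories.
* Exact numerical equivalence with external mixed-model software is not
  claimed; the likelihood itself is oracle-tested and parameter recovery
  is verified by simulation.
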