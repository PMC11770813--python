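# Methods

## The assay in brief

An IP bolus of [6,6-²H₂]glucose (0.5 g/kg lean mass), alone (GTT) or
co-injected with insulin at 0.75 U/kg lean mass (ITT), is followed over
50 min with glucometer readings and LC-MS/MS glucose isotopologue areas
at 0/10/15/30/40/50 min. The tracer is assumed (i) not to recirculate
once taken up by tissue, and (ii) not to provoke an insulin response
when given IP. Under these assumptions labeled glucose in blood is
entirely exogenous and unlabeled glucose entirely endogenous, so the
measured molar enrichment partitions the glucometer total into the two
components.

## Natural-abundance and purity correction

The measured ion defaults to deprotonated glucose **C₆H₁₁O₆** (charge
−1). The exact species and any derivatization are configurable via
`IonFormula`; the correction algebra is formula-generic and uses only
integer nominal mass shifts.

For the species carrying *j* tracer labels, the predicted mass-shift
envelope is the convolution of

* the natural-abundance envelope of the formula with *j* hydrogens
  removed — per element the *n*-fold convolution of the single-atom
  shift distribution (pinned IUPAC 2013 representative values,
  overridable), computed by binary exponentiation of the generating
  polynomial; and
* the label distribution Binomial(*j*, purity): each labeled position
  is ²H with probability `tracer_purity` (default 0.99, a typical
  commercial specification), so impurity feeds shift *j−1* etc.

Columns are truncated at the largest recorded shift K (default 2) and
**not renormalized**: renormalization would bias the recovered
fractions, whereas the lost mass surfaces in the inversion residual,
which is the better QC signal. Inversion is by **non-negative least
squares** on the sum-normalized spectrum (plain matrix inversion can
return negative fractions under noise); the residual norm is reported
per sample and samples above `residual_threshold` (default 0.05) are
QC-flagged, never dropped silently. Enrichment is the corrected
fraction at the tracer's shift, clipped to [0, 1] with the raw value
retained for QC. A correction-off mode (raw M+2 share of total area)
exists for sensitivity analyses because some laboratories report the
uncorrected ratio.

## Partitioning and AOC

Partitioning requires the MS and glucometer grids to agree exactly —
both come from the same tail bleed, so a mismatch indicates a data
error and raises rather than interpolating. The glucometer is assumed
to respond identically to labeled and unlabeled glucose (²H₂
substitution does not measurably affect glucose-oxidase chemistry),
and mass fractions are treated as molar fractions (the 182/180 Da
difference is ~1% and cancels almost entirely in the ratio).

The AOC is the **signed** trapezoidal integral of the
baseline-subtracted curve in mg/dL·min; below-baseline excursions
subtract. Total and endogenous curves use their own t = 0 values as
baseline; the exogenous baseline is 0 by construction, which makes
`aoc_total = aoc_exogenous + aoc_endogenous` an exact identity (the
trapezoid is linear). Both raw and baseline-subtracted endogenous
curves are emitted, since either convention may be wanted for plotting.
Unsorted time grids raise rather than sort silently.

## Statistics

The design is a 2×2 mixed factorial: diet between animals, insulin
(GTT vs ITT, one week apart in the same animals) within animals. Each
AOC outcome gets a mixed-design two-way ANOVA (diet and insulin main
effects, interaction), six pairwise cell contrasts (paired t within
diet across modes, Welch t across diets) with Holm adjustment, and a
compact letter display computed as the maximal cliques of the
non-significance graph (cells not sharing a letter differ at α,
default 0.05). Per-timepoint comparisons are Welch t-tests at each
post-baseline time with Holm adjustment across the five timepoints.
The ANOVA flavor and post-hoc procedure are conventions of this
package, chosen to match the main-effect/interaction/letters style of
presentation; normality is probed with a logged Shapiro flag only.

## The synthetic-cohort generator

Two glucose species share one compartment and one fractional uptake
rate:

    dG_L/dt = ka·(D/Vd)·e^(−ka·t) − (k0 + kI·I(t))·G_L
    dG_U/dt = EGP0·e^(−sI·I(t) − sG·(G_L+G_U−Gb)) − (k0 + kI·I(t))·G_U

with G_L(0) = 0, G_U(0) = Gb. I(t) is the insulin excursion above basal
in units of the administered dose per kg lean mass: identically 0 in
GTT mode, and a first-order absorbed/cleared (Bateman) profile with
amplitude 0.75 in ITT mode. Writing the kinetics in excursion units
makes the fasted steady state exact with EGP0 = k0·Gb (the
construction default) in both modes. EGP produces unlabeled glucose
only and uptaken tracer never returns — the tracer's defining
assumptions — and the exponential suppression form keeps EGP positive
without clamping. Because dose (g/kg lean) and distribution volume
(dL/kg lean) are both lean-normalized, simulated concentrations are
independent of lean mass, mirroring the dosing rationale. Integration
is adaptive RK45 at tolerance 1e-8 sampled on the protocol schedule;
the system is smooth and non-stiff at these rates.

Default parameters (per minute unless noted): ka_depot 0.12, Vd 2.5
dL/kg lean, ka_ins 0.20, ke_ins 0.035, glucometer CV 5%, MS area CV 5%,
insulin CV 10%. The LFD-like preset uses Gb 150 mg/dL, k0 0.025, kI
0.15, sI 3.5, sG 0.004; the HFD-like preset Gb 185, k0 0.016, kI 0.07,
sI 1.6, sG 0.002 (hyperglycemic, impaired glucose handling, blunted
insulin action). These values were chosen once to produce realistic
murine curves and to reproduce the assay's *qualitative* orderings —
fasting hyperglycemia under high-fat feeding, augmented EGP in the GTT,
faster early EGP suppression in the insulin-sensitive group, and an ITT
total curve that tracks its endogenous component — never to match any
quantitative figure value. Between-animal variability applies lognormal
multipliers (CV 15%) to the rate parameters and 5% to Gb; lean mass is
Normal(20, 1.5²) g.

The measurement model produces glucometer totals with multiplicative
normal noise, MS areas by forward convolution of the true label
fractions with the same correction matrix the analysis inverts (scaled
to ~10⁶ counts, multiplicative noise, clipped at 0), and noisy insulin
in the GTT only (the reported plasma insulin is
`basal·(1 + excursion)` µg/L — an arbitrary-unit conversion hook, since
the assay's absolute insulin scale is not modeled).

What the generator does **not** emulate: counter-regulatory responses
to hypoglycemia, tracer recirculation (assumed absent), glucometer
bias/quantization, chromatographic interference or detector
saturation, within-animal correlation between the GTT and ITT sessions
beyond shared kinetic parameters, and circadian or stress effects.
Passing tests therefore demonstrate correctness of the *analysis* under
the assay's stated assumptions, not robustness to violations of them.

## Operating characteristics and problem sizes

Replicate studies (in `deutg.studies`) run the full measured-data path
(NNLS correction → partition → AOC → mixed ANOVA) on simulated
cohorts. Type-I error uses two groups sharing one generator **with the
insulin dose set to zero**, making the test-mode factor null as well,
so all three reported effects are true nulls; 200 replicates at n = 10
per cell. Power and pattern-reproduction studies use the default
presets at the study's sample sizes (14 vs 15) with 200 replicates.
These sizes give Monte-Carlo standard errors of ~1.5 percentage points
on a 5% rate, adequate for the [0.02, 0.08] calibration band. The
monotonicity checks run noiseless kinetics on parameter grids so strict
inequalities are meaningful.

## Numerical choices and degenerate inputs

* CSVs are written with `%.17g` so floats round-trip exactly and
  identical seeds give byte-identical files.
* All-zero spectra, non-positive glucose, unsorted or mismatched grids,
  empty factorial cells, groups of n < 2, and animals absent from the
  manifest raise immediately with the offending sample/cell/animal
  named; high NNLS residuals flag rather than fail.
* Enrichment clipping to [0, 1] guarantees non-negative partitioned
  curves; the raw value is kept so QC can see, e.g., slightly negative
  baseline enrichments.
* All randomness flows from explicit seeds (`numpy.random.Generator`);
  the pipeline itself is deterministic given its inputs.

## Known limitations

* The correction uses nominal (unit) mass shifts; fine isotope
  structure and resolution-dependent overlap are out of scope.
* Only H-label tracers are wired through the enrichment extraction
  (the matrix builder itself is element-generic).
* No Steele-style rate-of-appearance modeling: the assay reports
  concentrations and AOCs, and so does the package.
* The mixed ANOVA assumes approximate normality of cell residuals;
  with n ≈ 14 per cell it is robust to the mild skew the generator
  produces, but heavy-tailed real data may warrant rank-based
  alternatives.
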