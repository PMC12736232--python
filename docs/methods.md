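# Methods

## Problem and model chain

`pdtdepth` is a virtual-experiment pipeline for estimating how deep
5-ALA photodynamic therapy (PDT) remains biologically effective when
630 nm light must first traverse brain tissue. The physical experiment
it emulates irradiates glioblastoma spheroids through optical phantom
plates matched to porcine white and gray matter, reads ATP luminescence
as a viability surrogate, and classifies each condition into response
zones. The pipeline chains five stages:

1. **Attenuation fit.** Measured irradiance E(d) behind plates of
   thickness d is modelled as a single exponential with a free
   intercept, E(d) = E0·exp(−μ_eff·d), fitted by unweighted ordinary
   least squares of ln E on d. Two parameters, not one: the intercept
   E0 sits well below the nominal 42.25 mW/cm² source (8.79 mW/cm² for
   gray matter, 4.69 for white) and absorbs the large near-surface
   coupling/interface loss already visible at 1 mm. Fitting in the log
   domain encodes a multiplicative error assumption and has an exact
   analytic solution. Duplicate thicknesses are rejected rather than
   averaged. Fitted decay constants (0.4008 /mm gray, 0.6141 /mm
   white) are cross-checked against the diffusion-approximation
   prediction μ_eff = √(3 μ_a (μ_a + μ_s′)) computed from the packaged
   tissue coefficients (0.4313 and 0.6859 /mm); agreement within 15%
   is asserted in the tests. Coefficients for 405 nm are packaged too,
   but no transmission data exist at that wavelength, so a 405 nm fit
   requires user data.

2. **Dosimetry.** Radiant exposure H = irradiance × time / 1000
   (mW·s = mJ), so the default 42.25 mW/cm² × 3600 s protocol delivers
   152.1 J/cm². Dose at depth composes the fitted model with the
   protocol: H(d) = E(d)·t. Plated arms use the fitted intercept (that
   is what the measurements support); the 0 mm direct-irradiation arm
   has no phantom interface and uses the nominal source irradiance.

3. **Synthetic study.** The generator emits plate-level luminescence
   for 6 cell lines × 2 tissues × the tested thickness grids (white
   0–6 mm in 1 mm steps; gray 0,1,2,3,5,7,9 mm) × assay days 5/7/11 ×
   3 replicates, plus dark, light-only and ALA-only control arms.
   Mean luminescence is baseline × exp(growth_rate·(day−4)) × V/100,
   with V the viability model below; replicate noise is multiplicative
   lognormal with unit mean and coefficient of variation `noise_cv`
   (default 0.10 — a typical plate-reader replicate spread; the
   luminescence scale is positive and heteroscedastic, which rules out
   additive Gaussian noise). Identical seeds give identical record
   lists; `noise_cv = 0` gives the deterministic mean model.

4. **Viability model.** Dose response is a two-parameter Hill curve on
   radiant exposure, V(H) = 100/(1 + (H/ED50)^h) — the minimal
   monotone sigmoid, since no functional form is published. Sublethal
   damage recovers: if the day-5 viability exceeds a permanence
   threshold V_perm, the deficit relaxes as
   V(t) = 100 − (100 − V5)·exp(−r·(t−5)); below V_perm the kill is
   permanent. This first-order mechanism is invented to reproduce the
   observed direction of change — treatment-effect depths shallow, and
   never deepen, between days 5 and 11.

5. **Zones and decisions.** Viability is normalized per cell line and
   day to the mean of the same-day dark control (the published figures
   normalize to the untreated control; whether the same day or the
   pre-irradiation baseline was the denominator is unstated — same-day
   is used here, and light-only/ALA-only arms are reported but never
   the denominator). The replicate mean is classified: Effect < 50%,
   Consider 50–70% inclusive, NoEffect > 70%. Boundary values land in
   Consider because the outer zones are defined by strict
   inequalities; this matters because floating-point means can land
   exactly on a boundary. Classification uses the replicate mean, not
   individual replicates, matching how the zone membership of mean ±
   SD bars is reported; per-replicate conventions exist only in the
   decision framework. Depth profiles are functions on the tested grid
   only — the gray grid's untested 4 and 6 mm are never interpolated —
   and censoring is first-class: `">max"` when even the deepest plate
   is still Effect, `"none"` when a zone is never reached.

## Calibration of the cell-line profiles

Per-cell-line dose–response parameters are not published; the packaged
profiles are calibrated stand-ins. The PC38 profile (ED50 = 3.0 J/cm²,
h = 1.5) is pinned by a closed-form check: with the fitted gray model
the day-5 doses at 1,2,3,5,7,9 mm are 21.2, 14.2, 9.5, 4.27, 1.91,
0.86 J/cm², giving viabilities 5.1, 8.9, 15.1, 37.1, 66.2, 86.7% and
hence the zone sequence Effect×4, Consider, NoEffect — deepest Effect
depth 5 mm, NoEffect onset 9 mm, the reference pattern for this cell
line. Its permanence threshold of 40% keeps the 37% point at 5 mm
permanent, so the deepest Effect depth stays at 5 mm through day 11,
matching the reported stability of this line. The other ED50s (SC38
0.6, SC40 0.7, U251 0.8, T98G 1.7, PC40 5.0 J/cm², all h = 1.5) follow
the observed sensitivity ranking — stem-like SC38/SC40 and U251 most
sensitive, PC40 least — and reproduce the qualitative day-5 gray
pattern (SC38/SC40/U251 effective beyond the 9 mm grid, T98G to 7 mm,
PC40 to 3 mm); they are illustrative, not inferred from data. Growth
rate defaults to 0.35 /day (untreated luminescence roughly doubles
every two days, consistent with exponential-phase spheroids);
recovery rate r defaults to 0.12 /day, which moves a 60%-viable
condition to ≈80.5% by day 11 — enough to shift zone calls by one or
two grid steps over the observation window.

## Decision framework

Assumed truth is an untruncated normal N(mean, sd) on the percent
scale with n replicates — mean and sd are all the published scenarios
specify, and leaving the distribution untruncated keeps the closed
forms exact (truncation at [0,100] would change the base-case numbers
in the fourth decimal at most). Because "probability of correct
classification" is undefined until the classified statistic is named,
three conventions are enumerated and every result is labelled with
its convention: mean rule (closed form via the normal CDF),
all-replicates rule (closed form via an independence product), and a
one-sided 95% t-confidence-bound rule (Monte Carlo only). "Correct"
is read strictly: the Consider band counts as incorrect for both Go
and NoGo targets. For the packaged base case (20 ± 10%, n = 3, target
Go) and worst case (90 ± 10%, n = 3, target NoGo) the conventions give
P(correct) ≈ 1.000/0.9997 (mean rule) and 0.9960/0.9333
(all-replicates). The study's printed headline figures of 98% and 96%
fall between these conventions and are reproduced exactly by none of
them; since the computation behind the printed values is unspecified,
the report tabulates the conventions side by side and carries a
footnote instead of claiming agreement. Monte Carlo defaults to
100,000 draws with a mandatory seed and returns the binomial standard
error; internal consistency (closed form vs Monte Carlo within 3
standard errors, P(correct)+P(incorrect)=1) is what the tests assert.

## Numerical and serialization choices

Units are fixed internally — mm, mW/cm², J/cm², 1/mm — with
conversions only at I/O boundaries. CSV outputs are UTF-8 with LF
endings; thickness prints with one decimal, viability with two, doses
with three. Every pipeline output starts with a comment line carrying
the package version, the SHA-256 of the canonical config text and the
seed, and a rerun with an identical config is byte-identical. Seeds
feed `numpy.random.default_rng`; the generator refuses `noise_cv > 0`
without a seed.

## What the synthetic data do and do not show

The generator reproduces the *statistical shape* of the experiment —
monotone dose response, replicate noise, growth, partial regrowth,
censored grids, control arms — so every downstream stage is testable
offline, and the noise-free defaults reproduce the reference PC38
gray-matter zone pattern end to end. It does not model PpIX
photochemistry, oxygen depletion, intra-spheroid dose gradients,
morphology, or real inter-experiment variability, so passing tests
validate the pipeline's arithmetic and classification logic, not the
biology of any particular cell line. The wet-lab per-condition
viability values themselves were never deposited; the synthetic
profiles stand in for them by construction. The qualitative
microscopy adjudication of Consider-zone cases is out of scope;
Consider calls are reported as-is.

## Problem sizes

The default virtual study is 756 treated + 162 control records
(6 lines × 14 conditions × 3 days × 3 replicates, plus 3 control arms);
the noise-stability check reruns it 200 times at CV 0.10, and Monte
Carlo decision estimates use 100,000 draws.
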