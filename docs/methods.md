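# Methods

This note documents the models and procedures implemented in `ramclav`,
the defaults and why they were chosen, what the synthetic cohorts do and
do not emulate, and the numerical conventions that matter for
reproducing results.

## Preprocessing

Each spectrum is cropped to the closed interval [594, 1704] cm⁻¹ (the
working range of the acquisition being modelled), baseline-corrected,
and scaled to unit Euclidean norm, in that fixed order.

**Baseline model.** Fluorescence background is removed with an iterative
modified polynomial fit: an order-7 polynomial is least-squares fitted
on the wavenumber axis affinely rescaled to [−1, 1] (for conditioning);
intensities of the *original* spectrum lying above the fit are replaced
by the fit; the fit is repeated until the baseline's maximum absolute
change falls below `rel_tol` (default 10⁻⁶, relative to the baseline's
maximum magnitude) or `max_iter` (default 100) passes.  Because Raman
bands only add intensity above the background, the clipping makes the
polynomial track the background rather than the band envelope.  Two
conventions deserve note:

* The clip compares the **original** spectrum against the current fit
  each pass, rather than accumulating clips on a working copy.  The two
  variants converge to similar baselines for moderate peaks, but the
  accumulating variant permanently burns the first iteration's
  least-squares side-lobes into the data; for a narrow peak 100× the
  background scale the non-accumulating variant roughly halves the
  residual at the peak centre.  The test suite pins the implementation
  against an independent plain-`numpy` reimplementation of the loop.
* Residual error at a peak centre scales with peak amplitude (the
  clipped fixed point sits slightly above the true background under
  strong bands) and, more importantly, a band whose flank is truncated
  by the edge of the spectral range leaves the polynomial with no
  background anchor beyond it, so the fit climbs into the band.  The
  order of the polynomial cannot fix this; it is a property of
  single-polynomial baseline correction on a finite window.  The
  generator's default amide I band is therefore parameterised to return
  close to background before 1704 cm⁻¹ (see below), mirroring the
  practical advice to acquire past the last band of interest.

Negative post-correction intensities are retained (clipping them would
bias the normalization).  `poly_order` is configurable; "a polynomial of
7" is read as polynomial *order* 7 (8 coefficients).  An optional median
despike filter exists but is off by default, since the modelled
acquisition chain applies none.

**Vector normalization** divides by the Euclidean norm over the cropped
grid.  It makes every downstream intensity a relative quantity: all
band-height *ratios* are invariant to it (and to any global intensity
scaling of the raw input), while individual normalized heights are
coupled — if one strong band grows, every other normalized height
shrinks.  This coupling matters for interpreting loadings (below).

## Band metrics

Bands are measured inside fixed windows, symmetric around the field's
standard centres and wide enough to absorb apex drift: proline 830–870,
phosphate 930–990, carbonate 1040–1100, amide III 1220–1300 (covering
both the ~1250 and ~1270 conventions), CH₂ 1420–1480, amide I
1620–1700 cm⁻¹.  The apex is the highest interior local maximum in the
window, refined by a parabola through its grid triplet (sub-grid
position and height); a window with no interior maximum returns its edge
point flagged `at_edge`.

*True peak height* is apex intensity minus the baseline reference at the
apex: zero in `global` mode (the default — spectra are already
baseline-corrected) or the chord joining the window endpoints in
`local_chord` mode (retained for overlapping-band robustness).  FWHM is
measured between the two half-height crossings nearest the apex, each
linearly interpolated between bracketing grid points, referenced to the
same baseline as the height; it is reported missing with a reason
(`no_crossing`, `non_positive_height`) when undefined.  On a 1 cm⁻¹ grid
this reproduces the analytic widths of Gaussian (2√(2 ln 2)·σ) and
Lorentzian (2γ) lines to better than 0.1 cm⁻¹.

Interpretation convention: smaller phosphate FWHM ⇒ more ordered, more
mature apatite.  Maturity rankings sort group-mean FWHM ascending; exact
ties share lexicographic label order and are flagged.

## PCA-LDA

Spectra (rows) are mean-centred and decomposed by PCA without variance
scaling; 10 components are retained by default (capped at n−1), a common
chemometrics default that keeps the discriminant problem well-posed at
tens of samples per class.  A cumulative-variance retention policy is
available.  LDA is fitted in the retained score space by the generalized
symmetric eigenproblem of between-class scatter against pooled
within-class scatter with a ridge ε = 10⁻⁸·trace(S_w)/p, giving
deterministic behaviour for near-singular scatter; C classes yield C−1
unit-norm discriminants ordered by eigenvalue.  Wavenumber-space
loadings are the PC loadings composed with the discriminant directions,
sign-fixed so each loading's maximum-absolute coefficient is positive.
Band attribution scores each window by its maximum |loading| and ranks
bands per discriminant; an all-zero loading yields an empty ranking
flagged degenerate.

Two caveats that shaped the package's test constructions:

* A discriminant is a *precision-weighted* contrast: directions with
  small within-class variance get large coefficients even when their
  class-mean difference is modest.  Loading peaks therefore do not
  simply rank effect sizes.
* Through vector normalization, a change in one strong band induces
  anti-correlated apparent changes at every other band.  A "only band X
  differs" construction consequently guarantees a loading maximum in
  X's window only when X does not dominate the spectral norm.

## Cohort designs and trend flags

The five designs subset and label a preprocessed cohort: `by_age` (3 age
classes, all spectra); `by_age_within_side` (per side); the medial vs
lateral contrast per side (middle-region spectra excluded, 3 ages × 2
regions = 6 classes); left vs right per region (3 ages × 2 sides); and
along-bone position per (age, side) (15 position classes).  Each design
re-fits its own PCA-LDA on the subset.  Sub-analyses with fewer than 2
classes or any class under 2 spectra are skipped with a logged reason.
Age-group labels use the overlapping boundary convention: ages 18 and 30
belong to the younger-labelled group.

`trend_summary` reports group means over an ordered key (age groups
youngest→oldest; positions 1→15; regions lateral→medial) with a
direction flag per metric.  Means and standard errors are computed over
*individuals* (each individual's spectra are averaged first) so repeated
measurements of one clavicle do not masquerade as independent evidence.
A metric is flagged `increasing`/`decreasing` only when the group means
are strictly ordered **and** every adjacent gap exceeds one standard
error of that gap; otherwise `non-monotone`.  Bare tables without
replication fall back to strict ordering.  The guard exists because
strict ordering of three group means occurs with probability 1/3 under
pure noise; with the guard, effect-free cohorts produce a false monotone
flag in about 1% of replicates while the default effect sizes are
detected essentially always.  Threshold: 1 standard error, chosen a
priori from that power analysis.  No hypothesis tests are reported — the
pipeline is descriptive, matching the analyses it reproduces.

## The synthetic cohort generator

A measurement is Σ_b A_b·mult_b(meta)·ε_ind,b·ε_meas,b·PV(ν; c_b, w_b,
η_b) + background(ν) + N(0, σ²).  Bands are pseudo-Voigt (η-weighted
Gaussian/Lorentzian, η defaults 0.7); the background is a degree-3
polynomial plus one broad Gaussian hump (FWHM 600 cm⁻¹), smooth enough
for the order-7 baseline class; ε factors are mean-1 log-normal, drawn
once per (individual, band) and once per (measurement, band).  Per-band
rather than per-spectrum factors are essential: a scalar per spectrum
would cancel in every ratio and make recovery tests vacuous.

**Layout.** 12 individuals — 10 with both clavicles, one left-only, one
right-only (both unpaired ones in the oldest group) — 4/4/4 across the
age groups 13–18, 18–30, 30–40; 15 measurements per clavicle (positions
1–5 lateral, 6–10 middle, 11–15 medial); 330 spectra.  The emulated
assemblage reports 336 collected spectra against 22×15 = 330; the
generator produces 330 and the discrepancy is left unresolved.  The
4/4/4 split is a declared assumption; per-group counts are unpublished.

**Default bands** (centre / FWHM / η / amplitude in counts): proline
850/20/0.7/250, phosphate 960/17/0.7/calibrated (≈1666), carbonate
1070/22/0.7/320, amide III 1270/60/0.7/280, CH₂ 1450/45/0.7/200, amide I
1665/55/0.9/700.  Amide I is deliberately mostly Gaussian and ends near
background before the 1704 cm⁻¹ edge so the baseline-recovery problem
stays well-posed (a broad Lorentzian flank truncated at the range edge
makes the polynomial climb into the band and degrades every band
measurement).

**Group effects** (multipliers on band amplitude): phosphate age
1.00/1.06/1.18 (oldest clearly highest, middle slightly above young),
side right 1.03, region middle 1.008 / medial 1.015; carbonate age
1.000/0.995/1.125 and side right 1.015 — the raw old-group boost is
large so that *after* normalization (which drifts upward with the
phosphate increase) the observable carbonate ordering is old > young >
middle; amide III age 1.00/0.985/0.970 and region middle 0.97 / medial
0.93, so the medial mineral-to-protein ratio exceeds the lateral;
proline 1.00/0.998/0.996 and amide I 1.00/0.985/0.960, weak protein
declines.  Phosphate FWHM is scaled by age 1.000/1.015/0.975: the oldest
group's mineral is the most mature (narrowest band), the middle group's
the least — slight differences, consistent with maturity differences
being negligible in the emulated cohort.  One known fidelity trade-off:
the reported subtle rise-then-fall of P:C over age is not reproduced
(the default effects give a mild monotone rise); bending P:C would
require a carbonate effect strong enough to displace phosphate from the
top of the LD1 attribution, and the P:C pattern is described as minor in
the source analyses while the attribution is a headline finding.

**Variability and noise.** Between-individual CV 0.0075 and
per-measurement CV 0.03 per band, additive noise SD 3 counts.  These
emulate a tightly controlled benchtop acquisition (long accumulation,
single anatomical surface, one assemblage) and were fixed a priori by a
power analysis so that the generative orderings are recoverable from 4
individuals per group at the stated replicate rates while effect-free
cohorts stay flat.  They are optimistic relative to field instruments:
passing recovery tests here says the *pipeline* recovers structure under
its stated conditions, not that 22 clavicles suffice under noisier
acquisition.

**Calibration.** The phosphate amplitude is set in two stages: a
fixed-point iteration drives the noiseless, layout-weighted
population-mean 960:1450 true-peak-height ratio (through the full
preprocessing chain) to 8.01; then one rescale against the measured
pipeline on four internal fixed-seed cohorts centres the *measured*
cohort mean on 8.01, absorbing the small (<1%) systematic response of
in-window apex search to noise at the broad CH₂ band.  The calibrated
amplitude is a deterministic number computed at first use and cached.

**What the generator does not emulate:** taphonomic degradation
gradients, iron staining, cosmic-ray spikes, detector etaloning or
wavenumber miscalibration, spatial correlation along the bone beyond the
three-region means, and any within-individual left–right asymmetry
beyond the fixed side multipliers.  Conclusions from passing tests are
about the analysis chain, not about archaeological bone.

## Numerical conventions

* Wavenumber axes are strictly ascending internally, whatever the file
  order; windows are closed intervals [lo, hi].
* Missing numeric outputs serialize as `NA`; tables are written with 8
  significant digits and are byte-identical for identical input.
* Metadata joins use filename stem = the `file` column.
* All randomness flows from a single integer seed per cohort through
  `numpy.random.default_rng`; replicate studies use consecutive seeds.
* Replicate studies (parameter recovery, negative control) run 100
  cohorts of 330 spectra each; one cohort takes ~2 s end-to-end on a
  single CPU, sizes chosen to keep the full suite within a few minutes.

## Known limitations

* Single-polynomial baselines leave amplitude-proportional residuals
  under strong bands and are unreliable within ~half a bandwidth of the
  range edges; heights of bands near the edge (amide I) absorb part of
  this error.
* Attribution by maximum |loading| inherits LDA's precision weighting;
  with strongly heteroscedastic within-class structure it can rank a
  low-variance minor band above the chemically dominant one.  The
  scores/loadings tables are exported so users can inspect rather than
  trust the single top-band summary.
* The FWHM estimator assumes an isolated peak within its window; heavily
  overlapped bands return `no_crossing` rather than a deconvolved width.
  Multi-peak fitting is out of scope.
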