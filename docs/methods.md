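# Methods

`fretquant` implements a complete quantification and characterization chain
for ratiometric FRET kinase biosensors, built around a near-infrared ERK
reporter pair (miRFP670nano3-like donor, miRFP720-like acceptor) imaged with
a single shared excitation band, and the classic two-filter CFP/YFP
configuration it is compared against.

## Measurement model

The readout is EfA, the product of the FRET efficiency `E` of the associated
(phosphorylated, intramolecularly bound) sensor configuration and the
fraction `f_A` of molecules in that configuration. The two factors are not
separately identifiable from intensities, so only the product is modeled.

For the red pair, donor- and FRET-channel intensities are described by
excitation products `X_c^f = source x ex-filter_c x eps_f x absorption_f`
and emission products `M_c^f = QY_f x emission_f x em-filter_c` (channel
`c` in {D, F}, fluorophore `f` in {D, A}). A channel's signal contribution
factorizes into `(int X_c^f dl) * (int M_c^f dl)`: excitation and emission
passbands are separated by a dichroic, so a pointwise product of the two
curves would be identically zero, and the single-integral notation used in
the field is shorthand for this factorized form. Three dimensionless
calibration constants follow:

    R_XT   = [X_F^D M_F^D] / [X_D^D M_D^D]     donor bleed-through
    R_Chan = [X_F^A M_F^A] / [X_D^D M_D^D]     direct acceptor excitation
    R_FRET = [X_F^D M_F^A] / [X_D^D M_D^D]     sensitized emission gain

With the power/exposure-normalized intensity ratio
`NIR = (I_F / I_D) / (P_F t_F / P_D t_D)` and concentration ratio
`k = C_A / C_D` (default 1 for a single-chain sensor):

    NIR = (R_XT (1 - EfA) + R_FRET EfA + k R_Chan) / (1 - EfA)   (forward)
    EfA = (NIR - R_XT - k R_Chan) / (NIR - R_XT + R_FRET)        (inverse)

These are exact algebraic inverses; the test suite verifies the round trip
to 1e-12 over a dense EfA grid and random ratio sets. The model neglects
acceptor emission collected in the donor channel (`M_D^A`, of order 0.1 of
`M_D^D` or less for this pair). `forward_nir_full` retains those terms so
the bias of the simplified inversion can be audited; on synthetic products
with the term at 10% it stays below 0.15 EfA units across the range and is
far smaller at realistic operating points.

For the CFP/YFP configuration, `EfA = 1 - (I_CFP / I_YFP) / R_P`, with
`R_P` the donor-channel gain over the acceptor-channel gain; each gain is
the product of relative power, exposure, extinction coefficient, quantum
yield, and the factorized source/filter/spectrum integrals.

Out-of-[0, 1] EfA values are flagged, never clipped: clipping would bias the
downstream noise-variance estimate. Frames whose inversion denominator is
within `1e-9 * (1 + |NIR|)` of zero become missing values rather than
aborting the track.

### Calibration

All ratios are computed by 1-nm trapezoidal integration on a common grid
spanning the union of spectral supports (linear interpolation inside each
support, zero outside; boundary points carry a 1e-6 nm tolerance so grid
round-off cannot zero a tabulated edge value). Absolute units cancel in
every ratio, so spectra are accepted in arbitrary units.

Because `R_XT` is dominated by spectral tails, where small tabulation errors
stack multiplicatively, the package supports a direct calibration: imaging
the donor alone through both filter sets and averaging the normalized
intensity ratio. A measured `R_XT` takes precedence over the computed one.
The synthetic reference instrument in `fretquant.reference` demonstrates the
workflow: its "true" hardware carries a donor emission tail 2.5% longer than
the tabulated model (a few-percent tail error of the kind vendor spectra
exhibit), and the directly measured crosstalk ratio comes out ~3% above the
computed 0.488 — within the <5% agreement expected of a sound calibration.

Integration accuracy: trapezoid error on a ratio scales with the squared
log-slope of the integrand, so it is the steep emission tails that limit
1-nm accuracy (~1e-3 relative for tails decaying on a 20 nm scale, ~5e-5
for gentle 55 nm Gaussians). The convergence check therefore uses broad
Gaussian fixtures, and `spectral_products` accepts an arbitrary step for
users who need finer grids.

## Synthetic single-cell data

The generator emulates live-cell experiments in epithelial cells: frames
every 6 min over a 540-min movie, EGF stimulation at 60 min, MEK/EGFR
inhibition at 240 min. The deterministic activity profile (0-1 scale) is
piecewise:

* baseline `b` (default 0.10) until EGF;
* a logistic rise, renormalized to start exactly at `b` and peak exactly at
  `b + amplitude` 30 min after EGF (default peak activity 0.95);
* exponential relaxation toward an elevated plateau (default halfway
  between baseline and peak, rate 0.02/min) — stimulated cells settle above
  baseline rather than returning to it;
* after the inhibitor, exponential decay (tau = 3 min) clamped to its
  target after five time constants, so the sampled minimum is attained
  within 20 min;
* optionally a gamma-shaped undershoot (default depth 0.05 of activity for
  the red sensors) that dips below baseline and recovers over ~60 min —
  a sensor-level artifact of the red pair, not a property of the kinase;
* T/A (phospho-dead) variants are constant at baseline regardless of
  treatments.

The exact functional forms are a modeling choice: the kinetics are
constrained only by their landmarks (peak time, suppression time, undershoot
recovery), so smooth parametric pieces with interpretable rates were chosen
and every rate is configurable.

Activity maps affinely onto each sensor's EfA operating range (defaults:
CFP/YFP sensor 0.30-0.65, red sensors 0.15-0.40). Per-cell heterogeneity is
lognormal on expression (sigma 0.5, the spread typical of polyclonal
lentiviral populations) and on peak amplitude (sigma 0.15); lognormal
multipliers are strictly positive and right-skewed with one parameter each.
Frames drop out independently with probability 0.01 (segmentation loss,
applied to all channels of a cell at once).

Noise is placed on channel intensities by default (Gaussian, sd 0.01 in
unit-expression donor-intensity units per channel per frame), because the
shared-excitation configuration makes intensity noise the physical source;
the resulting EfA noise scales as 1/expression. A post-ratio mode adds
Gaussian noise directly to EfA (default sd 0.012) for estimator-calibration
studies where the generating variance must be exact; the 1/expression
scaling is retained. Every population is generated from per-cell RNG
streams keyed by (seed, sensor index, cell index), so output is
byte-identical under a fixed seed and any subset of cells is reproducible.

What the generator does not emulate: photobleaching and chromophore
(biliverdin) maturation kinetics (only implicitly present through the
expression multiplier), temporally autocorrelated noise, cell division and
tracking errors, spatial (subcellular) signal structure, and illumination
drift. Passing tests on synthetic data therefore validate the algebra,
bookkeeping and statistical machinery of the pipeline — not robustness to
every artifact of real microscopy data.

## Track processing

A track is one cell's EfA series for one sensor. Processing for
cross-sensor comparison follows four steps: (1) remove tracks present in
<= 85% of the movie's frames (movie length is the experiment's full frame
span, not any single track's) or showing any frame outside the sensor's
expected range — the strictest reading of "signals outside of expected
ranges"; a mean-based mode is available; (2) 3-point centered moving
average, window shrinking at the edges, missing frames excluded from each
window and never interpolated; (3) subtract each track's minimum smoothed
value; (4) multiply by the red-to-CFP/YFP scaling factor and a per-sensor
normalizing value (defaults 1.5679 x 5 and 3.0042 x 3 for the two red
sensors, 1 x 4 for the CFP/YFP sensor) to place all sensors on a common
0-1 display scale.

The scaling factor is estimated from dual-sensor cells as the mean over
cells of the framewise CFP/YFP-to-red signal ratio, restricted to frames
where the red signal exceeds 5% of that cell's CFP/YFP maximum (guarding
against 0/0 near the re-zeroed baseline; how near-zero frames are handled
is otherwise unconstrained). Orientation is CFP/YFP over red: the published
factors exceed 1 and must up-scale the red sensor, whose dynamic range is
smaller.

## Characterization

Per cell: **Signal** is the dynamic range, max minus min EfA over the full
retained, unsmoothed trace (smoothing is part of the display-normalization
recipe, not of the dynamic-range definition). **Noise** is the unbiased
(n-1) sample variance over the closed window 2-5 h after the inhibitor
(31 frames at 6-min sampling; with ~31 frames the n vs n-1 choice shifts
the estimate by ~3%, so it is fixed and documented); a first-difference
variance mode is provided for drift-contaminated baselines. **SNR** is each
cell's Signal divided by its own Noise.

Noise may be reported on a per-sensor display scale `k` (Noise is
multiplied by `k^2`; variance is offset-invariant, so baseline subtraction
is immaterial) while Signal stays on raw EfA. This scale split is
deliberate: the published characterization magnitudes for this sensor class
(functional dynamic range ~0.1-0.2, phospho-dead dynamic range < 0.05,
post-inhibition variance ~0.007-0.009) are mutually consistent only if the
variance refers to the display-normalized signal — a per-frame sd of
sqrt(0.009) ~ 0.095 on the raw scale would force the max-min range of even
a flat trace above 0.3. With Noise on the display scale (k ~ 7.8-9.0) the
implied raw per-frame sd is ~0.012, which reproduces all the printed
magnitudes simultaneously, including the near-cancellation that makes the
two red sensors' SNRs statistically indistinguishable while their Signals
and Noises differ.

Statistics follow the replicate structure: metrics are averaged per
technical replicate, technical-replicate means are pooled across
experimental replicates, and groups are compared by one-way ANOVA followed
by a Tukey-Kramer post-hoc test (studentized range with unequal group sizes
supported; it reduces to Tukey's HSD for balanced designs). All pairwise
comparisons are computed; reporting is filterable. The implementation uses
`statsmodels`' `pairwise_tukeyhsd`; the test suite cross-checks its adjusted
p-values against `scipy.stats.tukey_hsd` as an independent oracle.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes that keep every
statistical check well-powered: 50 dual-sensor cells for zero-noise
recovery; 1,000 single-replicate cells for noise-estimator calibration
(mean window variance within 5% of the generating 0.009, per-cell estimates
chi-square with 30 d.f.); 20 seeded runs of 2 groups x 8 technical x 3
experimental replicates x 50 cells for ordering recovery at the published
operating points (Signal 0.13 vs 0.10, Noise 0.009 vs 0.007 on the display
scale); 100-track fixtures for the filter audit; 60 cells x 9 replicates
per arm for the phospho-dead null.

Other fixed choices: trapezoidal integration at 1 nm by default (vendor
spectra are tabulated at >= 1 nm); spectral interpolation is linear with
zero outside the support; inversion denominator tolerance
`1e-9 * (1 + |NIR|)`; all randomness flows from a single seed through named
`SeedSequence` streams; ties in the filter log record every rule that fired
for a track.

## Known limitations

* The spectral ratios of the bundled reference instrument are synthetic;
  real analyses must supply measured spectra via the manifest, and should
  prefer a direct donor-only `R_XT` calibration.
* The noise model is white per frame; real baselines show slow drifts, for
  which the first-difference Noise mode is a partial remedy.
* The scaling-factor estimator assumes dual-sensor cells share one
  underlying activity; sensor-specific kinetic artifacts (the red sensors'
  post-inhibition undershoot) bias the framewise ratio slightly, which is
  why it is restricted to frames well above baseline.
* FLIM readouts, pH sensitivity, and Förster-radius/dipole-orientation
  physics are out of scope; the model operates at the EfA product level.
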