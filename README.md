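# fretquant

Quantification and single-cell characterization of ratiometric FRET kinase
biosensors, built for red/far-red ERK reporters (miRFP670nano3/miRFP720-class
FRET pairs such as REKAR67 and REKAR76) imaged with a single shared
excitation band, alongside the classic CFP/YFP configuration (EKAREN4).
It is aimed at people building or benchmarking live-cell kinase activity
reporters: it turns two-channel intensity tracks into crosstalk-corrected
activity time series and into the per-cell figures of merit — dynamic range
("Signal"), post-inhibition variance ("Noise") and their ratio (SNR) — with
replicate-level statistics.

## The model

The readout is EfA: FRET efficiency `E` times the fraction `f_A` of sensor
molecules in the high-FRET (phosphorylated) configuration. For the red pair,
with spectral calibration ratios `R_XT` (donor bleed-through into the FRET
channel), `R_Chan` (direct acceptor excitation) and `R_FRET` (sensitized
emission), and the power/exposure-normalized intensity ratio
`NIR = (I_FRET / I_Donor) / (P_F t_F / P_D t_D)`:

    EfA = (NIR − R_XT − k·R_Chan) / (NIR − R_XT + R_FRET),   k = C_A/C_D (1 for single-chain)

which exactly inverts the forward model
`NIR = (R_XT(1−EfA) + R_FRET·EfA + k·R_Chan) / (1−EfA)`. The ratios are
computed from light-source, filter and fluorophore spectra (and `R_XT` can
be measured directly by imaging the donor alone through both filter sets —
preferred, since crosstalk lives on error-prone spectral tails). For the
CFP/YFP pair, `EfA = 1 − (I_CFP/I_YFP)/R_P` with `R_P` the donor/acceptor
channel gain ratio.

Downstream, tracks are filtered (>85% presence, in-range signal), smoothed
(3-point), baseline-subtracted, scaled across sensors and normalized for
display; characterization computes per-cell Signal = max−min EfA,
Noise = variance in the 2–5 h window after MEK/EGFR inhibition, SNR =
Signal/Noise, then compares sensors on technical-replicate means with
one-way ANOVA + Tukey–Kramer. A seeded simulator generates realistic
single-cell populations (EGF peak ~30 min post-stimulus, suppression within
20 min of inhibition, red-sensor undershoot, T/A null mutants, lognormal
cell heterogeneity, intensity-level noise) with ground truth for validation.
See `docs/methods.md` for the full account.

## Worked example

Simulate a small dual-sensor experiment, quantify it, and characterize it:

```sh
$ fretquant simulate --n-cells 10 --seed 42 --out tracks.csv --truth-out truth.csv
wrote 32484 rows (180 tracks) to tracks.csv

$ fretquant quantify tracks.csv --out efa.csv
quantified 16242 frames to efa.csv

$ fretquant characterize efa.csv --out-prefix char
per-cell metrics for 180 tracks -> char_per_cell.csv
18 replicate means -> char_replicates.csv
group comparisons -> char_stats.json
```

The per-cell table averages to:

```
         signal   noise       snr
sensor
EKAREN4  0.3639  0.0008  989.8669
REKAR67  0.2741  0.0007  990.5766
```

The simulated CFP/YFP sensor spans a wider EfA range (0.30–0.65) than the
red sensor (0.15–0.40), so its dynamic range (signal) is larger; at the
default 1% intensity noise both sensors resolve their dynamic range
hundreds of times over (snr = signal / noise-variance per cell). With a
spectra manifest, `fretquant calibrate manifest.yaml --out ratios.json`
computes the spectral ratios — on the bundled synthetic reference
instrument `R_XT = 0.4876`, `R_Chan = 0.0462`, `R_FRET = 0.4513`, and a
simulated donor-only calibration measures `R_XT = 0.5028`, 3.1% above the
computed value — and `fretquant pipeline run.yaml` drives the whole chain
from a YAML run configuration with seeded, hash-stamped outputs.

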