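# Methods

`cardiorqa` implements a proof-of-concept protocol for characterising
cardiac and autonomic dynamics in single-lead ECG: a synthetic rat-ECG
generator for four reference conditions, standard time-domain HRV and
Poincaré descriptors, a full recurrence-quantification pipeline, and a PCA
projection that scores how close a recording's nonlinear signature lies to
each simulated condition. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Synthetic ECG model

### Tachogram synthesis

The RR series is generated in the spectral domain. A target power spectrum

S(f) = r · G(f; f_LF, σ_LF) + G(f; f_HF, σ_HF)

is sampled on the beat-frequency grid (the series is beat-indexed; physical
frequencies are mapped through the mean beat rate, 350 bpm → 5.83 Hz).
`r` is the LF/HF ratio: it multiplies the LF Gaussian while the HF weight
is fixed at 1, so r = 0 leaves pure high-frequency (fast, decorrelating)
modulation and r = 1.5 yields a slowly wandering, autocorrelated heart
rate. Random spectral phases are drawn from a seeded generator, an inverse
real FFT produces a fluctuation series, and an affine rescale pins the
instantaneous-HR series to exactly the requested sample mean and SD
(defaults 350 and 50 bpm, the standard awake-rat values). RR (ms) is then
60000/HR.

Rat LF/HF band locations are not standardised; the defaults are
f_LF = 0.35 Hz (σ 0.1) and f_HF = 1.5 Hz (σ 0.3), conventional values for
rat HRV, and both are exposed on `TachogramSpec`. HR excursions that would
imply RR ≤ 0 are clipped (floor 15 bpm / RR cap 4 s) with a warning; a hard
RR floor of 40 ms — far below any physiologic rat RR — guards positivity
after noising.

Tachogram "measurement noise" at levels {0, 0.33, 0.66, 0.99} is additive
zero-mean Gaussian with SD = level × peak-to-peak range of the clean RR
series. For a constant tachogram the range is zero; the generator then
falls back to SD = level × mean(RR) × 0.01 and warns.

### PQRST rendering

Each RR interval is rendered as one beat cycle θ ∈ [−π, π) stretched to
RR_k ms, with voltage Σ_w a_w · exp(−Δθ_w² / 2b_w²) summed over the five
waves (template-sequencing rather than integrating a limit-cycle ODE; at
rat rates the difference is invisible and the sequencing is exactly
reproducible). Beat boundaries come from cumulative rounding of the RR
partial sums so no duration drift accumulates. The four conditions:

| condition | θ (deg) P,Q,R,S,T | a | b | extras |
|---|---|---|---|---|
| DET | −70, −15, 0, 15, 100 | 1.2, −5, 30, −7.5, 0.75 | 0.25, 0.1, 0.1, 0.1, 0.4 | 1% trace noise |
| LQT | as DET | as DET | b_T = 0.6 | widened T wave |
| AF | as DET | a_P = 0.2 | b_P = 0.125 | + PQ-segment white noise |
| NSE | as DET | as DET | as DET | trace noise fraction 1.00 |

Trace noise is additive Gaussian with SD = fraction × max|clean signal|
(the additive reading for NSE; a multiplicative reading would erase the
visible QRS that defines the condition). The Q wave is kept (a_Q = −5) as
the parameter set prescribes. AF implements both printed mechanisms: the
suppressed/narrowed P wave in the template and white noise (SD 0.2 template
units, configurable) laid over the PQ segment, taken as θ ∈ [−90°, −20°].
The noise is added on top of the residual P rather than replacing the
segment so that both mechanisms remain active; their relative weighting is
an open modelling choice.

The templates store their ground-truth R-peak sample indices, which the
tests use to validate the detector.

## HRV and Poincaré descriptors

SDNN (sample SD of RR), RMSSD (RMS of successive differences), and the
return-map dispersions SD1/SD2 (sample SDs of (x−y)/√2 and (x+y)/√2 for
x = RR_t, y = RR_{t+lag}). Everything uses the n−1 convention, so the
identities SD1 = RMSSD/√2 and SD1² + SD2² = 2·SDNN² hold to O(1/n) and are
asserted with 1% tolerance at n = 1000 rather than exactly. No NN/ectopy
filtering is applied by default (synthetic data has no artifacts); a filter
callable can be injected.

## R-peak detection and complexes

The detector takes local maxima above an adaptive threshold
(median + 0.4 × (max − median)) with a 60 ms refractory period — rat rates
up to ~500 bpm leave ≥ 120 ms between beats, and the synthetic R amplitude
(30) dwarfs every other wave, so nothing fancier is warranted. A flat trace
returns an empty index set. Complexes are cut ±18 ms around each R
(truncating ms→samples; 37 columns at 1 kHz); boundary beats are dropped
without affecting interior rows. Waveform PCA reuses `cohort.pca_fit` on
the complex matrix.

## Recurrence quantification

- **Delay τ**: first lag where the average mutual information falls to
  AMI(0)/e. Histograms use Sturges bins (⌈1 + log₂ n⌉) with shared edges on
  both axes, so AMI(0) equals the binned Shannon entropy. Per recording, τ
  is the median over the epoch windows. If the curve never crosses (pure
  deterministic signals can stay high at all lags) the argmin is used with
  a warning.
- **Dimension m**: first dimension with Kennel false-nearest-neighbour
  fraction < 0.1, with r_tol = 10 and a_tol = 2 (FNN fractions averaged
  over the same windows at the selected τ). Neighbour pairs at numerically
  zero distance — exact repeats in noiseless periodic data — are excluded
  from the criterion; their stretch ratio is 0/0. If nothing qualifies,
  m_max (default 8) is used with a warning.
- **Threshold ε**: 9% of the maximum phase-space diameter, applied per
  epoch after per-epoch normalization of the distance matrix (every epoch
  is described at the same scale).
- **Theiler window 1**: the line of identity is excluded from diagonal-line
  statistics (but kept in the stored matrix and in vertical statistics).
  Without this, determinism saturates at 1 for any signal.
- **l_min = 3** for both diagonal and vertical lines.

The ten factors: RecR (off-LOI recurrence density), DTM (fraction of
recurrence points on diagonals ≥ l_min, denominator over all diagonal
recurrence points), ⟨D⟩/Dmax/ENTR (mean, max, and Shannon entropy of the
diagonal length distribution restricted to d ≥ l_min), LAM/TT (the vertical
analogues of DTM and ⟨D⟩), Vmax (longest vertical run, no length
restriction), and the return times T1 (mean gap between successive
recurrence indices down each column, sojourn points included) and T2 (same
after collapsing each vertical run to its onset). T1 is included alongside
the defined T2 so the factor vector has the ten entries the protocol's
factor matrix expects. A factor with no qualifying structure is reported as
0 and flagged in `RQAFactorVector.undefined`.

All ten factors are verified exactly against a brute-force oracle that
enumerates every maximal diagonal/vertical run and return time in pure
Python, over hundreds of random symmetric binary matrices (N ≤ 40),
including varied Theiler windows and l_min.

One boundary fact worth knowing: a saturated all-ones plot does **not**
give DTM = 1 — the corner diagonals of any finite plot have lengths 1 and
2, below l_min, so DTM peaks at 1 − O(1/N).

## Cohort analysis

`pca_fit` z-scores each factor column (they span orders of magnitude:
RecR ∈ [0,1] vs Dmax in the hundreds) and eigendecomposes the covariance.
Signs follow a deterministic convention (largest-|loading| entry positive);
zero-variance columns are dropped with a warning. `pca_project` applies the
*fitted* standardization and loadings to new rows — no refit — which is
what makes projecting real recordings onto the simulated factor space
meaningful. Centroid distances are Euclidean in the PC1–PC2 plane by
default (the protocol uses only the first two components; full-space
distances are available via `n_components`).

The clustergram uses scipy average-linkage agglomeration with Euclidean
distance on the standardized matrix, rows and columns independently, with
scipy's deterministic leaf order.

Group statistics: KS normality screen per group (against a normal with the
sample's own moments — a pragmatic screen, not a size-corrected Lilliefors
test), Mann-Whitney U (exact for small samples) for two groups,
Kruskal-Wallis for more, followed by Tukey-Kramer on joint-rank means with
studentized-range p-values. The post hoc mirrors the classical stats-toolbox
behaviour and is an approximation, not an exact rank test.

## Epoching and problem sizes

The protocol's epoch bookkeeping is configurable (`epoch_s`, `n_epochs`);
library defaults are 20 s × 15 epochs at 1 kHz. The grid analyses shipped
in the tests and in `scripts/acceptance.py` run at fs = 250 Hz with 4 s
epochs (1000 phase-space points per epoch, ~1300 epochs over the full
4 conditions × 4 noise × 4 LF/HF grid), a desk-scale choice that keeps
distance matrices at 10⁶ entries while preserving ~43 samples per beat —
enough to resolve the QRS complex (width b = 0.1 rad ≈ 2.7 ms needs
fs ≳ 200 Hz). Epoch length and rate are ordinary parameters; nothing in the
factor definitions depends on them beyond the usual finite-size effects.

## What the generator does and does not emulate

It emulates: rat-range heart rate and variability, LF/HF-shaped autonomic
modulation, tachogram measurement noise, four PQRST morphologies, 1%
trace noise, and two rat-like presets ("pd-like": bradycardic 280 bpm,
reduced SD 15 bpm, AF morphology; "sham-like": 350/50 bpm DET) standing in
for real lesioned/control recordings. Both presets are synthetic.

It does not emulate: ectopic beats or arrhythmic RR dynamics, baseline
wander, electrode artifacts, respiration coupling, morphology drift, or any
beat-to-beat coupling between morphology and RR beyond the time stretch.
Passing tests therefore demonstrate the pipeline's correctness and its
ability to separate these idealised conditions — not performance on real
ECG, where detector robustness and artifact filtering dominate.

## Numerical details and degenerate inputs

- All stochastic stages take explicit seeds; composite operations spawn
  independent child streams (`numpy` `SeedSequence`), so every pipeline
  stage is reproducible bit-for-bit.
- Constant series: AMI ≡ 0, FNN ≡ 0 (warned), SDNN/RMSSD/SD1/SD2 = 0,
  degenerate zero-diameter phase spaces yield the zero distance matrix with
  a warning.
- Beats shorter than the template support are compressed with a warning;
  beat rendering floors at 2 samples.
- RR·fs need not be an integer, so consecutive beats can differ by one
  sample; exact periodicity tests use 300 bpm where RR is a whole number of
  samples at 1 kHz.
- ECG CSV I/O round-trips bit-exactly (`repr` floats on write,
  `float_precision="round_trip"` on read). WFDB input is not supported;
  ECG travels as CSV and tachograms as one-RR-per-line text.

## Known limitations

- DET, AF and LQT differ only in P/T-wave details that contribute little
  to phase-space geometry at ε = 9%; their recurrence signatures are
  similar and separability at zero noise, while positive, is driven mainly
  by the NSE contrast plus the subtler morphology shifts. The waveform PCA
  view separates them much more sharply.
- The LF/HF ratio enters as a spectral weight on a beat-indexed series; it
  is a modulation model, not a physiological transfer function.
- T1/T2 depend on epoch length through the available return horizon.
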