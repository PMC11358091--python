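# Methods

## Scope

`ecognet` implements a complete complexity-and-connectivity analysis for
paired two-condition multichannel ECoG: preprocessing, permutation entropy
(PE), permutation Lempel-Ziv complexity (PLZC), band coherence, histogram
mutual information (MI), phase transfer entropy (PTE) with surrogate
significance and region-flow hub analysis, and gated group statistics.
Because no recordings for this design are publicly deposited, the package
is exercised end-to-end on a synthetic cohort generator whose ground truth
encodes the qualitative group-level findings the analysis is meant to
detect. The estimators themselves are generic and accept any CSV cohort in
the documented format.

## Preprocessing

Order: decimate → notch → band-pass → artifact mask, each per channel.

- **Decimation** 1,000 → 256 Hz is the rational factor 32/125, applied in a
  single polyphase stage (`scipy.signal.resample_poly`, Kaiser-windowed
  anti-aliasing). One stage avoids the rounding error of cascaded integer
  stages.
- **Notch**: second-order IIR notches (Q = 30) at 50 Hz and 100 Hz, applied
  forward-backward (zero phase). Both frequencies sit below the 128 Hz
  Nyquist after decimation.
- **Band-pass**: 4th-order Butterworth, 55–95 Hz, `sosfiltfilt`
  (zero phase; the phase contract matters because PTE consumes Hilbert
  phases).
- **Artifact mask**: visual screening is replaced by a deterministic rule —
  a sample is unusable when any channel deviates from its median by more
  than z = 6 robust standard deviations (1.4826 × MAD); epochs with > 20 %
  flagged samples are excluded. Complexity estimation symbolizes within
  contiguous usable runs only (no ordinal pattern spans a masked gap);
  spectral and phase estimators use non-excluded epochs whole, since Welch
  averaging and the Hilbert transform require contiguous data.

Swapping decimation and notch changes 55–95 Hz band power by < 1 % on
band-limited test signals (regression-tested), so the chosen order is not
load-bearing.

## Ordinal complexity

Delay vectors use embedding dimension m = 4 and delay τ = 1 by default.
m = 4 gives 24 patterns, well sampled by the ≈ 2,557 symbols of a 10-s
epoch at 256 Hz (a warning is emitted whenever the symbol count falls below
5·m!). Ties are broken by earlier position (stable argsort), making the map
deterministic. PE uses natural-log entropy normalized by ln(m!).

The LZ76 parser scans the symbol sequence with the classic S/Q scheme: the
candidate phrase Q grows while it occurs inside SQv (everything seen so far
minus Q's final symbol); each failure closes a phrase; a trailing
incomplete phrase counts once (so a constant sequence has exactly c = 2
phrases). The normalization is PLZC = c(n)·(log_{m!} n + 1)/n, the
finite-length version of c(n)/(n/log_{m!} n). Truly i.i.d. *symbol*
sequences normalize slightly above 1 at finite n; ordinal symbol sequences
of i.i.d. *signals* are serially dependent (overlapping windows), so their
PLZC plateaus lower — about 0.74 at m = 3, n = 10⁴ (Monte-Carlo, frozen in
the tests). Complexity is computed per epoch and then averaged (whole-brain
= mean over the 10 channels; region = mean over region channels).

## Functional connectivity

Coherence uses Welch averaging with a Hann window, 256-sample (1 s)
segments, 50 % overlap — ≥ 19 segments per 10-s epoch, which bounds the
no-coupling bias near 1/segments ≈ 0.05 — and reduces COH(f) to its
arithmetic mean over 55–95 Hz. The all-pairs matrix is computed from one
broadcast cross-spectral pass and is regression-tested against the scalar
pair estimator. MI uses 16 equal-width bins per margin over the observed
range, log base 2, clipped at zero (the plug-in estimate can go
infinitesimally negative). Region summaries average unique channel pairs:
within F/P/O (6/6/1 pairs) and between F–P/F–O/P–O (16/8/8 pairs),
diagonal excluded. Per-epoch pair values are computed first and averaged
afterwards.

## Phase transfer entropy

Phases come from the analytic signal of the band-passed series, with 5 %
trimmed at each end against Hilbert edge artifacts. PTE is estimated by
joint histograms over 8 equal-width phase bins on (−π, π]; 8³ = 512 joint
cells are adequately sampled by the ≥ 10⁴ samples pooled per
subject-condition. The prediction delay defaults to a quarter cycle of the
75 Hz band centre, δ = max(1, round(fs/(4·75))) = 1 sample at 256 Hz, and
is configurable; all reported PTE values are tied to their δ.

Significance uses circular-shift surrogates of the source phase series
(shift drawn uniformly, at least δ+1 samples, independently per pooled
epoch segment): shifting preserves the source's marginal distribution and
autocorrelation while destroying cross-predictability. Full permutation
would destroy the phase autocorrelation too and inflate false positives.
The p-value is the add-one rank (1 + #{surrogate ≥ observed}) /
(1 + n_surrogates); 200 surrogates by default for pair-level calls, 100 per
ordered pair in the cohort pipeline (90 pairs × 20 subject-conditions).
Pooling is capped at 24,000 samples per subject-condition; beyond that the
estimate is bias-dominated rather than variance-dominated, and the cap
keeps the full-design run inside a few minutes. Epoch boundaries are
respected — no (t, t−δ) pair spans two epochs.

Region flows sum PTE over cross-region ordered channel pairs: outflow(R) =
Σ PTE(i→j), i∈R, j∉R; inflow symmetric; net = inflow − outflow. Nets sum
to zero by construction (asserted). The hub verdict names every region
whose net inflow exceeds 5 % (configurable) of total cross-region flow; an
empty set reads "no clear hub". A set-valued verdict is used because the
design's ground truth makes two regions (parietal and occipital)
comparably strong inflow targets, which a winner-takes-all rule cannot
express.

## Group statistics

The unit of observation for group tests is the subject-level mean (10
pairs), avoiding pseudoreplication across the 40 epochs; epoch-level
analysis remains available through the tables. Each comparison runs
Shapiro–Wilk on both samples and Levene across them at a 0.05 gate; the
paired t-test is used only if all three pass, otherwise the Wilcoxon
signed-rank test on paired differences. A rank-sum variant (which ignores
pairing) is available behind `literal_rank_sum` for fidelity runs. A
degenerate (constant) sample is treated as failing normality. No
multiple-testing correction is applied by default. Correlations are Pearson
r over matched (subject, condition, day, epoch, region) observations:
region-mean PE/PLZC against within-region mean coherence/MI, all four
metric pairs, per region and condition.

## The synthetic cohort generator

Per epoch, each region r has a driver d_r of resonant band-limited
Gaussian noise — a 2nd-order Butterworth sub-band centred at 75 Hz with
±8 Hz half-width, inside the 55–95 Hz analysis band. A spectrally *peaked*
oscillator matters: after band-passing, ordinal entropy differences
between conditions come from in-band spectral shape, and a flat-spectrum
oscillator would erase the complexity contrast. Directed influence is an
explicit lagged linear term on the drivers; channels mix their region
driver with private band noise (weight `coupling_strength`), then admix
broadband white noise (weight `irregularity`, the epoch-level latent
severity jitters it), split into a globally shared part
(`shared_noise_fraction`) and a local part that is region-shared or
channel-private (`noise_scope`). A small channel-private sensor-noise term
completes the channel.

Condition ground truth (defaults, fixed as the package's study
conditions):

| parameter | normal | scz |
|---|---|---|
| coupling_strength | 1.0 | 0.65 |
| irregularity (jitter) | 0.15 (0.06) | 0.55 (0.12) |
| shared_noise_fraction | 0.10 | 0.75 |
| noise_scope | region | channel |
| sensor_noise | 0.001 | 0.03 |
| directed edges | F→P, F→O, lag 13, gain 1.1 | all 6 region pairs, lag 4, gain 3.0 |

Design reasoning, in brief:

- *Normal* regions behave as single coherent sources observed by several
  electrodes (region-scoped noise, full coupling): within-region pairs are
  near-copies, so their conditional phase-predictive information is
  genuinely ≈ 0 and the significant directed graph is carried by the true
  F→P/F→O edges — frontal outflow, parietal/occipital inflow hubs. The
  normal edge lag is one full cycle of the 75 Hz band centre (13 samples at
  1 kHz), so the inflow copy is positively correlated with its source at
  zero lag and the between-region MI sits clearly above the scz level.
- *Scz* channels individuate (channel-private noise, reduced coupling),
  and every region pair is coupled bidirectionally with equal gains:
  couplings are dense but directionally ambiguous, nets ≈ 0, no hub. The
  broadband admixture raises ordinal entropy (flat in-band spectrum), and
  its large shared fraction makes the epoch-level severity raise
  complexity and connectivity *together*, producing the positive
  complexity–connectivity correlation in this cohort only.
- Subjects carry small paired trait offsets (shared across conditions);
  the coupling offset is scaled by c(1−c) so boundary-pinned conditions
  stay pinned.

What the generator does **not** emulate: volume conduction and reference
effects, 1/f background spectra outside the analysis band, non-stationary
artifacts (the artifact rule is exercised by injected spikes in tests),
pharmacokinetics, or the 4 unassigned electrode sites. Passing tests
demonstrate that the estimator stack recovers planted effects of realistic
size under in-band Gaussian dynamics — not that real cortical data carry
those effects.

## Numerical choices and degenerate inputs

- Ordinal ties: earlier index first (stable sort); a constant series is a
  single pattern, PE = 0 by convention rather than an error.
- MI and PTE clip at zero; a constant margin yields MI = 0; constant input
  to the Hilbert phase is rejected (undefined phase).
- Coherence requires ≥ 2 Welch segments (a single segment degenerates to
  coherence 1 identically).
- Surrogate counts below ⌈1/α⌉−1 are rejected (p could never reach α).
- Identical samples in a paired test return p = 1 ("no difference") rather
  than propagating the undefined t statistic.
- All randomness flows through `numpy` `SeedSequence` spawning; a single
  master seed makes generation, surrogate draws and hence every report
  byte-reproducible (regression-tested).

## Problem sizes

Unit and property tests run on reduced cohorts (2–3 subjects, 2–6 epochs)
and short series; the acceptance test and `scripts/acceptance.py` run the
full study design (10 subjects × 2 conditions × 40 epochs, ≈ 1.5 min on
one CPU) plus calibration experiments at the sizes stated in the tests
(50-seed nulls, 200-run surrogate calibration, 100-seed direction
recovery). The PTE pooling cap and per-pair surrogate count in the cohort
pipeline are the package defaults described above.

## Known limitations

- The plug-in PTE estimator is bias-dominated at large pooled n; p-values
  are calibrated (surrogate-based), but raw PTE magnitudes are not
  bias-corrected and should be compared only within a fixed (n, bins, δ).
- Histogram MI with equal-width bins is not invariant under monotone
  transforms (a quantile-binned cross-check mode would be; not
  implemented).
- The epoch-level correlation analysis treats epochs as exchangeable
  within subject; a mixed model would be more conservative.
- Binary EDF input/output is not supported; the on-disk format is the
  documented CSV dialect.
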