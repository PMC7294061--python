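# Methods

This note documents the models, estimators and numerical choices behind
`bindnet`, in the order the pipeline applies them.

## Paradigm and behavioral model

The trial generator crosses the three S2 features (orientation, location,
color; 2 levels each) with the repetition/alternation of each feature and
of the response — 2⁷ = 128 cells, each repeated `n_repeats` times (the
canonical session uses 3 repeats, 384 trials). S1 is derived from S2 and
the repetition flags; the feature-overlap level of a trial is the number of
repeated features, so overlap 0 and 3 occur in 48 trials each and overlap 1
and 2 in 144 each. Trial order is shuffled by the seed. Nominal trial
timing (cue 1500 ms, blank 1000 ms, S1 500 ms, blank 2000 ms, S2 up to
2000 ms, ITI uniform in 1500–2000 ms) is carried as metadata; only
S2-locked epochs are simulated because only those are analyzed.

Behavior uses a logistic model for accuracy and a Gaussian model for RT,
each containing a single systematic term — the overlap × response
interaction that defines event-file binding. With the centred overlap
covariate z ∈ [−1, 1] and response sign s (+1 repeat, −1 alternate):

* logit P(correct) = logit(0.93) + 0.5·z·s
* RT = 450 − 20·z·s + N(0, 100²) ms, clipped to [150, 2000] ms.

The baseline accuracy and RT sit in the range typical of healthy adults in
this task; the interaction sizes produce a clear crossover (≈ ±6% accuracy
between extreme cells) that a 28-subject cohort detects with essentially
full power while remaining small enough that single subjects do not. Any
monotone link would serve; the logistic/Gaussian pair was chosen for
closed-form cell expectations.

## Synthetic EEG

Each epoch (60 channels by default, 256 Hz, −1000…1000 ms around S2) is the
sum of:

* **S component** — Gaussian bump, peak 180 ms, SD 50 ms, 6 µV, posterior
  topography (Gaussian in angular distance on the scalp sphere).
* **C component** — peak 550 ms, SD 120 ms, base 8 µV, vertex (Cz)
  topography. Its amplitude is scaled by 1 − 0.3·z·s (smallest for
  full-overlap/repeat) and its single-trial latency jitters by
  N(0, 50 ms), truncated at ±150 ms.
* **R component** — peak 40 ms before the keypress, SD 60 ms, 4 µV,
  bilateral central topography, placed at each trial's RT.
* **1/f noise** — per-channel Gaussian noise with a 1/f power spectrum
  (exponent 1, 10 µV RMS), matching the broadband character of resting
  EEG.
* **Oscillatory coupling** — for each edge of a condition-specific graph an
  independent 4–8 Hz band-limited signal (6 µV RMS) is added to one
  endpoint channel and its 90°-shifted (quadrature) copy to the other.
  The quadrature lag makes the coupling maximally visible to the imaginary
  part of coherency and invisible to zero-lag (volume-conduction-like)
  measures, which is precisely the contrast the analysis statistic is
  designed around. The graph is a ring lattice (k = 2 neighbours per side)
  for conditions meant to show regular organization, a fully rewired
  Watts–Strogatz graph for random-like conditions, and a β = 0.1
  small-world graph elsewhere; the default condition map gives
  overlap-0/repeat and overlap-3/alternate random coupling and the other
  two cells lattice coupling, mirroring the crossover observed in the ω
  statistic.

The per-edge coupling strength was set so that the imaginary coherence on a
true edge (≈ 0.2, bounded above by 1/degree because every channel carries
several independent edge signals) clearly exceeds the finite-trial null
floor (≈ 0.07 at 60 trials). Everything injected — per-trial C latencies
and amplitude factors, component templates, condition topologies — is
returned as `GroundTruth` for recovery tests.

What the generator does *not* emulate: eye/muscle artifacts (and hence the
ICA step of human pipelines), realistic volume conduction from dipolar
sources, cross-frequency structure, autocorrelated behavior (fatigue,
learning), or between-subject topography variability. Passing tests
demonstrate that the estimators recover the structure they assume, not that
the assumptions hold in human data.

## Preprocessing

Order: band-pass → average reference → artifact rejection → CSD → baseline
→ segmentation. Rejection runs on potential (pre-CSD) data.

* **Band-pass.** The target response is the squared magnitude of an
  order-8 Butterworth (0.5–20 Hz), i.e. the response that zero-phase
  forward–backward filtering would have. It is applied spectrally
  (multiplying the epoch's rFFT) rather than recursively: a recursive
  0.5 Hz high-pass rings for most of a 2 s epoch (≈ 8% leakage of a 50 Hz
  probe even with generous padding), whereas the spectral application
  attenuates stop-band probes to < 0.1% with identical pass-band response.
  The cost is circular wrap-around leakage for signals with strongly
  mismatched epoch endpoints, which is negligible for baseline-scale EEG.
* **Rejection.** A trial is dropped if any channel exceeds ±150 µV
  anywhere, or if any channel's peak-to-peak stays below 0.5 µV within any
  sliding 100 ms window (the "flatline" reading of an activity criterion).
* **CSD.** Spherical-spline surface Laplacian with stiffness m = 4, ridge
  λ = 1e−5, 50 Legendre terms, head radius 10 cm; output in µV/m² with the
  source sign convention (−∇², so a positive potential peak keeps a
  positive CSD peak). The implementation was validated against the
  spherical-harmonic oracle: zonal harmonics are reproduced as
  eigenfunctions with eigenvalue ≈ +l(l+1) (attenuated at high l by the
  ridge, e.g. ×0.96 at l = 3). The "channel sum ≈ 0" property of the
  surface Laplacian holds only for spline-representable (spatially smooth)
  fields on a closed sphere sampling and is tested as such, at 2% relative
  tolerance, on a full-sphere Fibonacci montage.
* **Montage.** Simulated caps use a golden-angle spiral over polar angles
  ≤ 100°, an idealization of an equidistant 60-channel cap, with Cz at the
  vertex.

## ERP measures and electrode validation

Condition averages are plain means; the P3 measure is the mean amplitude in
400–700 ms at Cz (window endpoints inclusive). Electrode validation
compares each electrode's window amplitude against the mean of the
remaining electrodes with a paired two-sided *t*-test across subjects,
keeps electrodes with p below α/n_electrodes (0.05/60 ≈ .0008) and the
matching polarity, and is run on the grand mean across conditions (a
per-condition run is a caller choice). Under an exchangeable null the
family-wise selection rate stays below α (verified by simulation).

## RIDE

Single trials are modelled as S(t) + C(t − τᵢ) + R(t − RTᵢ) + noise. Each
cluster is estimated inside its window (S: −200…700 ms post-S2, R:
±300 ms around the response, C: 150…800 ms post-S2; 100 ms cosine tapers)
as the pointwise **median** over trials of the residuals after subtracting
the other two clusters at their latencies — the L1 estimate that makes the
procedure robust to imperfectly removed overlap. C latencies are
re-estimated every iteration by a multichannel matched filter: the lag in
±200 ms maximizing the summed per-channel cross-correlation between the
residual (S and R removed) and the mean-centred C template, ties broken
toward zero lag. Because the model is invariant to a common shift of the C
template and all latencies, latencies are re-centred to zero median each
iteration; without this the latency origin drifts by tens of ms. The outer
loop stops when the relative L2 change of the C waveform is ≤ 1e−3 or
after 10 iterations; integer-sample latency flicker typically keeps the
change near 0.3–1%, so results at the iteration cap are returned flagged
(`converged=False`) rather than treated as errors.

Known identifiability limit: inside the S∩C window overlap a
stimulus-locked S and a jitter-free C are observationally equivalent, so
when the data contain no latency-variable activity the S/C split there is
arbitrary (the stimulus-locked-median initialization assigns it mostly to
C). Outside the overlap, and whenever C actually jitters, recovery is
accurate (C-waveform correlation ≈ 0.98, latency correlation ≈ 0.93 at
2 µV noise on the generator's data).

## Connectivity and small-world ω

Spectra are estimated per trial from the Hann-tapered full epoch; cross-
and auto-spectra are averaged across trials, coherency formed per bin, and
|Im(coherency)| averaged over the band's bins (theta 4–8 Hz, alpha
8–12 Hz). The magnitude of the imaginary part is used because only
coupling strength matters for thresholding. Adjacency keeps the strongest
(100 − P)% of pairs, P ∈ {85, 90}; the quota is round-half-even of the
pair count and ties at the cut break by lexicographic pair order, making
the graph deterministic.

Graph metrics follow the Watts–Strogatz definitions: average local
clustering (degree-<2 nodes contribute 0) and mean shortest path over
connected ordered pairs, with the count of disconnected pairs reported
(percentile thresholding can disconnect nodes). References are
Watts–Strogatz models with k = round(mean degree / 2): C_latt from the
β = 0 ring lattice (closed form 3(k−1)/(2(2k−1))), L_rand and C_rand from
20 β = 1 realizations (seeded). ω = L_rand/L − C/C_latt; values outside
[−1, 1] are flagged, never clipped. If the thresholded graph is so sparse
that k = 1 (C_latt = 0), ω is undefined and the pipeline raises — with 60
channels both thresholds give k = 3, but 90% thresholding below ~40
channels crosses this limit, which is why scaled-down analyses use the 85%
threshold.

## Statistics

The two-way fully-within ANOVA uses the standard balanced decomposition
with effect-specific error terms (subject × effect interactions);
F = MS_effect/MS_error, partial η² = SS_effect/(SS_effect + SS_error).
Two-level factors need no sphericity correction. Degenerate inputs are
defined: zero effect SS gives F = 0, p = 1, η² = 0; zero error SS with
positive effect SS gives F = ∞, p = 0. Post-hoc paired *t*-tests
(two-sided by default) multiply p by the number of comparisons, capped at
1; Cohen's d is the within-subject d_z and zero-variance differences are
flagged as degenerate. Optional extras: a 90% CI for partial η² by
noncentral-F inversion, and a BIC-approximation Bayes factor that is
explicitly *not* equivalent to a default-prior JZS Bayes factor.

## Pipeline scale choices

The default `RunConfig` reflects the canonical study (28 subjects, 384
trials, 60 channels, both bands, both thresholds). The test suite runs
scaled-down versions as its own design choice — 24–30 channels, one
factorial pass or the overlap-0/3 subset, theta band, 85% threshold —
which preserves every qualitative property being tested (interaction
detection, topology discrimination, ω behaviour) at a few seconds per
subject. The end-to-end discrimination test uses 50 simulated subjects and
verifies both the per-subject ω ordering (random-coupled > lattice-coupled
in ≥ 90%) and the group-level 2×2 interaction.

All randomness flows from per-run seeds through `numpy` Generators; fixed
seeds give bit-identical tables.

## Limitations

* The generator's coupling injects field-free quadrature signals; real EEG
  mixes sources through a head model, so absolute coherence levels are not
  comparable to human data.
* RIDE is implemented per the published procedure but is not a numerical
  clone of the reference MATLAB toolbox (different latency estimator
  details, tapering and convergence bookkeeping).
* EDF import of continuous recordings is out of scope; the epoch container
  (HDF5) and TSV metadata are the supported interchange formats.
* The 4-level overlap factor is supported by the general a×2 ANOVA, but
  the neurophysiological pipeline restricts itself to the overlap-{0,3}
  cells, as the downstream analyses do.
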