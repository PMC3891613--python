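# Methods

This document specifies the signal model, the estimators, and every
default parameter of `ehgcv`, with the rationale for each choice and the
known limitations.

## 1. Signal model

An 8×8 monopolar electrode grid (interelectrode distance d, default
0.5 cm) records the uterine electrical activity; one bipolar channel is
used only for contraction timing. Within a contraction, action-potential
activity is modeled as a **plane wave**: every channel (r, c) records the
same reference shape s(n) delayed linearly in row and column index plus
independent white Gaussian noise,

    x_rc(n) = s(n − (r−1)·τ_r − (c−1)·τ_c) + w_rc(n),          (model)

where τ_r and τ_c are the inter-row and inter-column delays. A wave of
speed CV hitting the grid at incidence angle θ (measured from the
vertical/row axis, positive counter-clockwise, rows increasing downward)
produces

    τ_r = d·cosθ / CV,     τ_c = d·sinθ / CV,                  (geometry)

inverted as CV = d/√(τ_r² + τ_c²), θ = atan2(τ_c, τ_r).

## 2. Contraction detection

**eIUP surrogate.** The bipolar channel's spectrogram ρ(n, f) is computed
with a Hann window of 20 s, hop 5 s, zero-padded to 0.025 Hz bin spacing
(≥ 20 bins across the band of interest), density-scaled so each frame's
band integral approximates its variance. The estimated-intrauterine-
pressure surrogate is the unnormalized first spectral moment over the
contraction band [0.3, 0.8] Hz (inclusive bounds):

    Ψ(n) = Σ_{f ∈ [0.3, 0.8] Hz} f · ρ(n, f).

Ψ is used for timing only; no pressure-amplitude calibration is
attempted.

**Adaptive threshold.** In overlapping 60 s windows (50% overlap), a
frame is active when Ψ exceeds the window median + k·spread, with k = 3
and spread = max(1.4826·MAD, 5% of the global Ψ range) — the floor
prevents zero-spread pathologies on flat stretches. Active frames are
unioned across windows; runs separated by less than one frame hop are
merged.

**Edge refinement.** The adaptive threshold sits well above the burst
edges, so each run is extended outward to a low edge boundary — global
baseline (median Ψ) plus max(5% of the run's peak excursion, k·global MAD
spread) — and onset/offset take the midpoint between the last sub-edge
and first supra-edge frame, removing the half-hop quantization bias of
frame-centered timestamps. Runs shorter than 20 s are dropped; output
segments are disjoint and time-ordered (asserted).

**Confirmation.** A detection is kept iff it overlaps a tocodynamometer
interval (any nonzero intersection) or a maternal-perception instant
falls within the segment ± 30 s slack; `confirmed_by` records which
criteria fired. The 30 s slack is roughly half a typical contraction —
perception marks are instants and need a tolerance.

## 3. Delay and CV estimation

**Windowing.** Each confirmed contraction is cut into windows of 10 s
advancing by 5 s (5 s overlap); a trailing partial window is dropped.
10 s holds many action potentials at physiological firing rates yet is
short enough to track CV changes within a burst.

**Pre-filtering.** Grid channels are band-passed 0.3–5 Hz (4th-order
Butterworth, zero-phase forward-backward), removing drift below and
broadband noise above the action-potential band; zero-phase filtering
leaves inter-channel delays untouched.

**Channel weights.** Under the model, maximum-likelihood estimation
weights each channel inversely to its noise variance. The noise is first
read from the > 10 Hz band (white-noise floor, corrected by the band
fraction), and optionally refined as the residual variance after
subtracting the re-aligned reference shape once delays are available.
Dead channels (zero variance) get weight 0; weights are normalized to
mean 1 over live channels.

**Cost function.** With X_rc(f) and S(f) the Fourier transforms of
channel (r, c) and of the reference shape,

    E²(τ_r, τ_c) = Σ_rc w_rc Σ_f p_f |X_rc(f) − S(f)·e^{−j2πf[(r−1)τ_r + (c−1)τ_c]}|² / N,

using one-sided Parseval bin weights p_f (1 at DC/Nyquist, 2 elsewhere),
so E² equals the time-domain weighted sum of squared residuals exactly.
For any candidate delay pair the least-squares-optimal shape is the
weighted mean of the re-aligned channel spectra,

    S_opt(f) = Σ_rc w_rc X_rc(f)·e^{+j2πf[(r−1)τ_r + (c−1)τ_c]} / Σ w,

and substituting it yields the **concentrated (profile) cost**

    E²(τ) = Σ_rc w_rc‖x_rc‖² − (Σw)·Σ_f p_f |S_opt(f)|²/N,

a smooth 2-D function of (τ_r, τ_c) alone. Minimizing the concentrated
cost converges directly to the joint (shape, delay) optimum; an
alternating scheme (fix shape, refine delays, re-estimate shape) was
evaluated and converged only linearly, orders of magnitude slower and
less precise, so the concentrated form is used throughout.

**Search.** (i) A coarse exhaustive search over ±τ_max at half-sample
steps, where τ_max = d/CV_min with CV_min = 1 cm/s (slower propagation is
treated as non-propagating). The concentrated objective expands into
pairwise channel cross-correlations grouped by (row offset, column
offset), evaluated on the candidate grid by band-limited interpolation —
O(grid²) without per-candidate FFTs. (ii) Nelder-Mead refinement of the
concentrated cost from the coarse optimum (relative function tolerance;
an absolute zero target is unattainable in floating point). (iii) A few
Newton steps via central differences polish the optimum to machine
precision. Frequency-domain delays are continuous parameters: resolution
is not limited by the sampling grid. Non-converged windows are flagged
and excluded from averaging.

**Physiological exclusion.** Windows with estimated CV strictly above
30 cm/s are marked excluded (`supra-physiological`); exactly 30 cm/s is
retained. A zero delay vector (infinite velocity) is excluded as
`zero-delay`.

## 4. Group statistics

Window vectors are averaged per contraction and per patient as **vector
(Cartesian-component) means**; a scalar amplitude mean is available via a
config switch (`use_vector_mean: false`) since the literature does not
fix which average enters the test. Opposing directions that cancel to
(numerically) zero yield a degenerate, excluded mean. Patients delivering
within 24 h of the measurement form the labor group. Per-patient
amplitudes are tested with Shapiro-Wilk per group (reported as 1.0 for
groups of fewer than 3, where the test is undefined), Levene across
groups, and a pooled-variance two-sided t-test at α = 0.05.

## 5. Synthetic generator

The simulator is the package's acceptance surface; it obeys the model of
§1 exactly:

- **Action potential**: first derivative of a Gaussian (biphasic,
  zero-mean, band-limited), default width 300 ms (σ = width/6, spectral
  centroid ≈ 3.2 Hz). The width keeps the pulse inside the 0.3–5 Hz
  analysis band; 100 ms pulses would center near 9.5 Hz, outside it.
- **Bursts**: jittered near-regular spike trains (default 1.5 Hz) whose
  amplitudes follow a Tukey(0.25) rise-plateau-release envelope; the
  envelope shape matters because Ψ is quadratic in it — too peaky an
  envelope spends little time above threshold.
- **Delays**: exact fractional (sub-sample) delays via frequency-domain
  phase multiplication; full recordings use zero-padded buffers to
  suppress wrap-around, single-window fixtures use circular shifts with
  the Nyquist bin zeroed (a populated Nyquist bin cannot carry a
  fractional phase shift through a real inverse transform).
- **Noise**: independent white Gaussian noise per channel; snr_db is the
  ratio of within-contraction clean signal power to noise power.
  Empirical SNR of generated recordings is within 0.5 dB of the request.
- **Bipolar channel**: the difference of two virtual electrodes sharing
  a common-mode term, carrying the burst envelope modulating
  0.3–0.8 Hz band-limited activity — sufficient for timing, with no
  claim of morphological fidelity.
- **Annotations**: tocodynamometer marks replicate the schedule;
  perception marks sit at contraction midpoints.

Defaults fs = 200 Hz and d = 0.5 cm give inter-electrode delays of
1.7–50 ms for physiological CVs (2–30 cm/s), resolvable with sub-sample
frequency-domain estimation; both are configuration, not assumptions.

The simulator does **not** model volume conduction or tissue layers,
maternal/fetal ECG or respiration artifacts, electrode-skin impedance,
curved or point-source wavefronts, or IUP amplitude in physical units.

## 6. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| fs_hz | 200 Hz | resolves ms-scale delays; configurable |
| electrode_spacing_cm | 0.5 cm | physiological delays 1.7–50 ms across the CV range |
| ap_width_s | 0.3 s | pulse centered in the 0.3–5 Hz analysis band |
| spike_rate_hz | 1.5 Hz | several APs per 10 s window |
| STFT window / hop | 20 s / 5 s | ≥ 20 bins across 0.3–0.8 Hz after padding |
| threshold window | 60 s, 50% overlap, k = 3 | adaptive median + MAD with 5%-range floor |
| min contraction | 20 s | rejects transient Ψ bursts |
| perception slack | ± 30 s | half a typical contraction |
| CV window / overlap | 10 s / 5 s | multiple APs per window; tracks within-burst change |
| f_band_hz | 0.3–5 Hz | AP energy band; removes drift and HF noise |
| cv_min_cm_s / cv_max_cm_s | 1 / 30 cm/s | coarse-search range; physiological exclusion |
| tol_s, max_iter | 1e-5 s, 20 | delay tolerance; iteration budget |
| alpha | 0.05 | significance level of the group test |

## 7. Limitations

- The plane-wave model assumes one dominant wavefront per window;
  colliding or curved fronts bias the estimate rather than failing it.
- Ψ-based detection needs the contraction band to dominate the bipolar
  channel; broadband artifacts (motion, ECG residue) are not rejected.
- The 30 cm/s rule is a proxy for non-propagating activity, not a
  physical bound.
- Vector averaging attenuates amplitude when propagation direction
  varies strongly between contractions of the same patient; the scalar
  mean switch exists for that regime.
- Synthetic validation covers the model the estimator assumes; agreement
  on clinical data is a separate, unvalidated question.
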