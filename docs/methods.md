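# Methods

## The Windkessel simulator

The generator integrates the four-element Windkessel (WK4) system

    dq/dt   = (p_c − p_p) / L
    dp_c/dt = (q_in − q) / C1(t)
    dp_p/dt = (q − p_p / R) / C2

on a fixed 50 Hz output grid with 5 RK4 substeps per sample (effective step
4 ms); inflow and time-varying parameters are linearly interpolated at
substep times. The system is non-stiff at physiological parameters; the
fixed-step integrator agrees with the periodic steady state's DC balance
(mean p_p = R · mean q_in) to well below 0.1%. A pressure magnitude above
10⁴ mmHg aborts integration with the offending parameter set named. The
first 10 s are treated as transient and discarded by every downstream
analysis.

**Inflow.** The heart is a current source: each beat ejects a half-sine
pulse over the systolic fraction (default 0.35) of the cycle, renormalized
sample-wise so the discrete beat integral equals the stroke volume exactly.
Beat onsets follow the instantaneous heart rate.

**Parameter drift.** R, C1, stroke volume and heart rate are modulated by
stationary Ornstein–Uhlenbeck processes with exact discretization
(x_{k+1} = μ + a(x_k − μ) + s√(1−a²) z, a = e^{−Δt/τ}), specified by a
relative σ and a correlation time τ, and clipped to [0.2, 5]× the base
value. An OU process was chosen because it is seedable, stationary, and has
a single timescale knob matching the use of a standard deviation σ as the
fluctuation measure.

**Defaults** (units: mmHg, mL, s): R0 = 1.0 mmHg·s/mL, C1 = 1.5 mL/mmHg,
C2 = 0.1 mL/mmHg, L = 0.005 mmHg·s²/mL, HR 60 bpm, SV 70 mL. These give
MAP ≈ 82 mmHg at CO 4.95 L/min and pulse pressure ≈ 30 mmHg. L sits at the
low end of reported lumped-model inertances; at 50 Hz it keeps the
pressure-foot delay after inflow onset within two samples, which is what a
foot detector can in principle resolve at this rate.

**Optical surrogate.** The PPG is modelled as transduction of the distal
distension volume v = C1(t)·p_p. Transmission-mode PPG is exponential in
absorber volume (Beer–Lambert), so the surrogate is
ppg = gain · v̄ · exp((v − v̄)/s) with curvature scale s = 60 volume-units
(`optical_scale=None` restores the linear map). The curvature matters for
realism: it produces the solidly positive waveform skewness (≈ 0.4) that
the skewness-based quality rule presumes, while preserving the properties
estimation relies on — AC/PP tracks C1(t) (trend correlation > 0.95 in
validation) and the map is affine to first order.

**Observation noise.** Additive 1/f^β Gaussian noise (FFT-shaped, β ∈
[0, 2]) plus white measurement noise. The colored noise is scaled by the
local 10 s pulsatile amplitude relative to a fixed reference sd of 25
signal units: optical noise in reflective/transmissive PPG scales with
perfusion, and this choice makes the fractal power *fraction*
amplitude-neutral — slow stroke-volume drift moves signal and noise power
together instead of inducing a spurious amplitude-driven fraction change.
Optionally the noise amplitude is modulated by exp(g·Δp(t−δ)/5 mmHg), where
Δp is the deviation of the 10 s-smoothed peripheral pressure from its
record mean, g the coupling gain and δ = 15 s the delay. This is the
mechanism by which the synthetic cohort embeds a genuine, lagged,
hemodynamics → fractal-power causal link.

## Preprocessing

Foot detection uses a slope-sum transform (trailing 128 ms sum of positive
slopes) with peak picking under a 0.3 s refractory period and a *sequential
adaptive threshold*: a candidate peak is accepted at ≥ 45% of an
exponential moving average (weight 0.25) of previously accepted peak
heights, seeded from the 75th percentile of the earliest candidates. The
EMA tracks slow amplitude modulation (stroke-volume drift) while rejecting
noise and dicrotic slope-sum bumps, which sit well below half a true
upstroke. The foot is the last sample attaining the signal minimum in the
0.35 s before each accepted peak. Detrending draws straight lines through
the feet; AC is the per-beat peak-to-peak of the detrended signal, DC the
per-beat mean of the baseline.

Per-beat quality rules, applied in the fixed order that also resolves the
recorded rejection reason: pulse pressure < 15 mmHg; beat-wise PPG–ABP
waveform correlation < 0.8 (both resampled to 50 points); beat interval
outside [0.5, 1.5] s; Fisher–Pearson skewness of the raw PPG negative in
any analysis window (all beats overlapping such a window are flagged).
Analysis windows are 100 s long with a 5 s hop (half-open, 0-based), or
runs of 100 consecutive valid beats for per-beat series; a window with more
than 10 s not covered by valid beats is discarded. Counting uncovered time
as corrupt (rather than only flagged-beat time) makes usability monotone
under additional corruption.

Subject-level inclusion: age > 18 y, weight > 40 kg, height > 145 cm,
16 ≤ BMI ≤ 35, and no analysis window with median SBP below 80 mmHg.

## Hemodynamic estimation

Two stages, in the order R and C1 first, then C2 and L with the first two
held fixed. R = MAP/CO per beat (mmHg·min/L); C1 = AC/PP per beat, in
PPG-units/mmHg — deliberately uncalibrated, so only intrasubject trends are
meaningful. The (C2, L) fit reconstructs the inflow as per-beat half-sines
(integral = CO·interval/60), truncates it to its first 10 cardiac harmonics
and pushes it through the WK4 transfer function

    H(ω) = 1 / [(1 + (jω)² L C1)(jω C2 + 1/R) + jω C1],   H(0) = R,

minimizing RMS = √(SSE/(N−1)) against the measured p_p over a 24×24
log-spaced grid (C2 ∈ [0.01, 10]·C1, L ∈ [10⁻⁴, 1]) followed by Nelder–Mead
refinement on the log-parameters (≤ 200 iterations; on failure the grid
optimum is returned flagged). Ten harmonics follow the convention of
frequency-domain Windkessel fitting; the grid-first strategy guards against
the multimodality of the two-parameter RMS surface. A fit with RMS above
10% of the pulse pressure is flagged poor. Fits are evaluated per 100 s
window. Fluctuation is summarized as the within-window sample standard
deviation σ of each per-beat parameter.

## Spectral separation (IRASA) and wavelets

Resampling factors h ∈ {1.1, 1.15, …, 1.9} (the original IRASA set), each
applied as a rational polyphase resample (anti-aliased) up and down; PSDs by
Welch with 10 s Hann segments and 50% overlap at the nominal rate; fractal
PSD = median over h of √(S_h·S_{1/h}); oscillatory PSD = total − fractal,
not clipped pointwise. Analysis band 0.5–10 Hz for 50 Hz PPG (the upper
edge must stay below Nyquist/max(h) ≈ 13 Hz; violating bands raise an error
naming the feasible limit). The fractal fraction integrates trapezoidally
and clips only at the fraction stage to [0, 100]%. The power-law exponent β
is −slope of the OLS fit of log₁₀S on log₁₀f over positive fractal bins
(≥ 10 required), with 100·SE(slope)/|slope| as relative uncertainty.

Wavelet components use a generalized Morse wavelet (symmetry γ = 3,
time–bandwidth P² = 60) implemented as frequency-domain filtering; the
component at each center frequency is the real part of the analytic CWT at
the scale whose peak frequency matches. Center frequencies are √2-spaced
from 11.63 Hz down to 0.4 Hz. Correctness is defined by energy
localization (a pure tone concentrates ≥ 80% of summed component variance
at the nearest center frequency), not by coefficient identity with any
particular CWT implementation.

On simulated records the Higuchi fit uncertainty of wavelet components is
strongly frequency-dependent (rising toward oscillation-dominated bands);
only the fractal-dominated low-frequency components fit more cleanly than
the raw signal. Narrowband components of the smooth WK4 surrogate behave
like modulated tones, which curves their Higuchi log–log plots; real PPG
has more broadband texture at all scales.

## Complexity measures

Higuchi FD: normalized curve lengths L(k), k = 1…k_max = 10, averaged over
offsets; HFD = OLS slope of ln⟨L(k)⟩ on ln(1/k), with the slope's relative
standard error reported as fit uncertainty; a constant series returns 1.
Katz FD is computed on the amplitude-range-normalized polyline with unit
index spacing — this keeps the straight-line value exactly 1, keeps the
measure finite on maximally jagged series, and makes it exactly scale
invariant.

Entropies use Chebyshev distance and tolerance r = 0.2·sd recomputed per
window. SampEn: n−m templates at both lengths, self-matches excluded,
−ln(A/B); when no (m+1)-length pair matches, the value is capped at
ln(B) + ln 2 and flagged. ApEn includes self-matches (Φ_m − Φ_{m+1}).
FuzzEn uses mean-subtracted templates and exponential membership
exp(−(d/r)^2). RQA ENTR: delay embedding (m = 4, τ = 1), recurrence
threshold 10% of the attractor's Chebyshev diameter, Shannon entropy (nats)
of diagonal-line lengths ≥ 2 from the upper triangle. All four are verified
against independent O(n²) brute-force implementations to 10⁻¹².

FNN (Kennel): rtol = 10, atol = 2, nearest neighbours searched with a
Theiler window (default 10 samples) excluding temporally adjacent points —
without it, oversampled flows nominate their own trajectory neighbours and
the false-neighbour fraction collapses prematurely. The embedding dimension
is the smallest m with FNN fraction < 5%, or the argmin when the fraction
never drops (irregular noise). The m = 4 default for entropies matches the
FNN outcome on PPG-like signals; the Rössler x-coordinate sampled with a
delay of a quarter orbital period embeds at 3, the canonical check.

HRV LF/HF: foot-to-foot intervals cubic-interpolated to 4 Hz, Welch PSD,
LF = 0.04–0.15 Hz over HF = 0.15–0.40 Hz band power. Per-beat series use
the beat index as abscissa; the uneven physical spacing of beat-sampled
series is acknowledged, not corrected.

## Association statistics

Intrasubject Pearson r across usable windows with the t-distribution
p-value; pairs with missing values dropped pairwise, ≥ 10 pairs required.
Sensitivities ∂Feature/∂Target are within-subject OLS slopes across
windows, annotated with the subject's σ values — the sensitivity functions
are represented empirically, as regression slopes conditioned on σ, which
is also how such sensitivities are reported in practice. Cohort comparisons
use median ± STD and the Wilcoxon rank-sum test; the median split on σ_CO
assigns ties to the low group.

Granger causality runs on per-window series (feature and hemodynamic values
share the 100 s / 5 s-hop grid). Both series are first-differenced if an
augmented Dickey–Fuller test fails to reject a unit root in either. Both
F-tests are evaluated at the full lag cap of 10 (50 s at the 5 s hop). A
data-driven order choice was rejected after calibration: BIC/HQIC collapse
these heavily smoothed, overlapping-window series to order 1 and miss
multi-hop delayed coupling, while AIC's post-selection bias inflates the
null false-positive rate beyond its nominal level; fixed-lag testing
measures a 7.5% null non-NONE rate (two tests per pair at α = 0.05,
theoretical ≈ 9.75%) with 95/100 unidirectional and 100/100 bidirectional
recovery on simulated VAR systems. The two tests per pair are deliberately
not multiplicity-corrected, matching the single stated α = 0.05. Categories
partition every subject: both p < α → bidirectional; exactly one → the
corresponding unidirectional; neither → none.

## The synthetic cohort study

Twenty subjects, 800 s each at 50 Hz (141 analysis windows — enough to
satisfy the 100-paired-window requirement of the Granger stage with margin
even when quality rules remove windows). Heart rate ~ U(55, 85) bpm, stroke
volume ~ U(60, 80) mL; OU fluctuation of stroke volume with relative σ
spanning 0.02–0.15 (τ = 30 s) sets a within-cohort gradient of σ_CO, plus
C1 (σ = 0.05, τ = 60 s) and heart-rate (σ = 0.03, τ = 20 s) drift.
Observation noise: perfusion-scaled 1/f noise at amplitude 6 (≈ 6% of the
pulsatile amplitude) and 0.2 units of white noise. In a randomly chosen
half of the cohort the noise amplitude is additionally modulated by the
exponential pressure envelope (gain 0.5, delay 15 s), embedding a lagged
hemodynamics → fractal-power causal link whose strength grows with the
subject's absolute pressure fluctuation.

Running the full pipeline on this cohort recovers, by construction and in
validation: (i) a positive across-subject correlation between mean fractal
fraction and σ_CO in the coupled half, with the uncoupled half flat
(amplitude-neutral noise); and (ii) a strongly elevated non-NONE Granger
rate in the coupled half (80% vs 20% in a reference run). The 15 s coupling
delay is resolvable at the 5 s window hop yet short against the 100 s
smoothing window; delays much beyond 50 s would exceed the lag cap and
become undetectable by design.

**What the synthetic validation does and does not show.** The generator
reproduces the *structure* real analyses face — pulsatile waveforms with
realistic skewness and foot geometry, slow correlated hemodynamic drift,
amplitude-coupled broadband noise, beat-quality failures — but not real
PPG's multiscale texture, reflected-wave morphology, motion artifacts,
respiratory modulation, or measurement nonstationarities. Passing the
synthetic study shows the pipeline recovers known effects of the stated
kind at the stated sizes; it does not certify effect sizes or significance
levels on clinical recordings.

## Numerical and degenerate-input conventions

Flat signals raise a no-beats error in detection; constant series return
FD = 1 and entropy 0 with flags rather than NaN where a limit exists;
entropy windows with unmatched templates are capped and flagged, and
flagged windows are excluded from association statistics. Welch segment
length is 10 s (resolving the 0.5 Hz band edge within a 100 s window). The
per-beat PPG–ABP correlation resamples both waveforms to 50 points so
unequal beat lengths compare. Window counts follow
floor((T − 100)/5) + 1. All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence`; reruns are bitwise reproducible.

Problem sizes used by the test-suite and the acceptance script — 5000-point
complexity fixtures, 10–50 seed medians, 100–200 seed calibrations, a
20-subject 800 s cohort — were chosen as the smallest sizes at which the
checked quantities are stable against seed choice.

## Known limitations

C1 (and hence the C2 grid anchored to it) carries arbitrary optical units;
absolute compliance values are not meaningful, only trends. The WK4 fit
assumes the reconstructed half-sine inflow shape; real ejection profiles
differ, biasing C2/L. The skewness quality rule is evaluated on the
analysis window (the alternative — a separate quality window — is noted but
not implemented). Granger causality on overlapping-window series inherits
moving-average autocorrelation; the fixed-lag F-test is calibrated for it
in simulation, but contemporaneous confounding can still produce verdicts
in either direction on real data, and no claim of true causation is made.
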