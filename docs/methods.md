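# Methods

This note documents the models, estimators, defaults and numerical
choices behind `cbtdcs`, and what the synthetic benchmark does and does
not establish about real recordings.

## Field law and its calibration

The intracranial field imposed by a transcranial current of intensity
`I` (µA) at depth `d` (mm below the cortical surface, under the active
electrode) is modeled as

    E(d, I) = I · (α − β · ln((d + d₀)/d₀)),  clamped at 0,

i.e. linear in intensity and logarithmically decaying in depth. The
offset `d₀` keeps the logarithm finite at the surface. Defaults
(`α = 0.4527 V·m⁻¹·µA⁻¹`, `β = 0.2169`, `d₀ = 0.5663 mm`, recorded in
`GeneratorConfig`) were chosen so that, at 200 µA, the mean field over
the first millimetre is 64.8 V/m and the field at a deep (2.3 mm)
recording site is 20.2 V/m, with the field reaching zero at 4 mm, the
deepest calibrated depth. A single log law cannot simultaneously satisfy
every printed anchor of a quadratic-surface description of real data;
the first-millimetre mean was treated as primary and the shallow
(0.3 mm) field is consequently ~72 V/m under this law. The clamp at
zero is handled analytically in `field_integral` (closed-form
antiderivative up to the zero-crossing depth).

Simulated tACS LFPs at depth `d` are sinusoids whose peak-to-peak
amplitude is the surface amplitude minus the accumulated potential drop
`∫₀ᵈ E dz` (mV), so consecutive-depth peak-to-peak differences equal the
segment-mean field exactly. The surface amplitude is the total 0–4 mm
drop plus a 10% margin (keeps the deepest trace positive). Amplitude
noise is one multiplicative Gaussian draw per stimulation cycle
(default SD 5%).

## Spike-train generator

Simple-spike trains are refractory-thinned inhomogeneous Poisson
processes. The target rate is

    r(t) = r₀ · max(0, 1 + m(t)),
    m(t) = polarity · g · E(d, |I(t)|) · cos θ    during pulses,

with `g = gain_per_Vm` (default 0.01 per V/m: a mid-depth, perfectly
aligned cell modulates ~46% at 200 µA, and vermis-scale folded
modulations of ~60% arise at shallower depths), and the trapezoidal
current making `m(t)` ramp linearly through ramp-in/ramp-out. After
ramp-out, `m(t)` flips sign and decays exponentially (rebound); the
rebound amplitude fraction (0.3) and time constant (2 s) are qualitative
placeholders — the phenomenon is reported qualitatively in vivo and no
published magnitude constrains them — and are flagged as such in the
config. The generating hazard is dead-time corrected,
`h = r/(1 − r·t_ref)` with `t_ref = 1.5 ms`, so the realized rate equals
the target rate despite the absolute refractory period (rates are capped
at `0.95/t_ref`). The process is thinned from a homogeneous candidate
stream; refractoriness is enforced by a vectorized greedy scan proven
equivalent to the sequential rule in the tests.

Complex spikes are homogeneous Poisson (default 1 Hz) and unmodulated by
default, matching the observation that CS rates do not change under
stimulation; a config switch (`cs_modulated`) applies the SS law to CS
for robustness experiments. Each CS silences SS for a pause drawn
uniformly from 10–40 ms, and **SS firing resumes at pause end** (a spike
is placed there unless a survivor follows within the refractory period).
This makes the realized CS→next-SS latency equal the drawn pause; with
deletion alone the latency would be pause plus a residual renewal wait
(~1/r₀), systematically overshooting the 10–40 ms identification band.
The SS process is a refractory-thinned Poisson rather than a gamma
renewal — adequate for rate statistics, not for fine ISI-shape studies.

Non-PC units use the same machinery without CS. Their anodal modulation
fraction is drawn once per unit from N(0, 0.5²) and the cathodal
fraction from a negatively correlated draw (correlation −0.6, same
marginal SD; both truncated at −0.95 so rates stay nonnegative). This
reproduces the qualitative population picture: wider dispersion than the
PC cosine law at a matched orientation spread, with a loose negative
anodal/cathodal relationship.

Default session structure: blocks of 5 trials per polarity per
intensity (anodal first), 5 s ramps, 5 s plateau, 10 s rest, one rest
interval of lead-in so every trial has a full 5 s baseline window.
Vermis PCs draw θ near 0° or 180° (SD 15°), crus PCs near 90°/270°,
encoding the opposite orientation of adjacent vermis layers versus the
oblique crus geometry. Locomotion flags each trial independently
(default p = 0.1) and covers the flagged pulse with a running interval.

## Estimators

**Field.** Peak-to-peak amplitudes are averaged over whole stimulation
cycles (trailing partial cycle discarded). Field per segment is
`(p2p_i − p2p_{i+1})/Δd` in V/m, assigned to the segment midpoint (the
plotting convention for the log fit; midpoints keep the fit symmetric).
The log fit is ordinary least squares of field on ln(depth); R is the
Pearson correlation between fitted and observed values (defined as 1 for
an exact constant fit, where Pearson is degenerate). The interpolation
surface fits all monomials `depth^i·intensity^j`, i, j ∈ {0, 1, 2}, by
OLS with 95% coefficient bounds from the linear-model covariance; a
`force_zero_intensity` variant drops the j = 0 terms. Evaluations
outside the fitted bounding rectangle are returned with an extrapolation
flag and a warning. Negative estimated fields (noise) are retained, not
clamped. Two-depth profiles yield one segment and skip the log fit with
a warning.

**Spike curation.** "DC remove" is exponential-moving-average
subtraction (single-pole high-pass), τ default 0.7 ms, the midpoint of
the 0.4–1 ms range used in acquisition software. Detection thresholds
default to 4× the robust SD (1.4826·MAD; plain SD optional); events are
local extrema of supra-threshold excursions of |x| with a 1.5 ms dead
time. Amplitude curation finds stable periods by breaking the recording
wherever the windowed mean amplitude drifts more than 15% between
consecutive populated 60 s windows (both values are config, unstated in
the experimental description), then drops events deviating more than ⅓
from the period mean — invariant to uniform rescaling by construction.
Refractory contamination is the fraction of ISIs below 1.5 ms, passed at
≤ 1%.

**PC identification.** The pause statistic is the median CS→next-SS
latency (≤ 100 ms lags). A unit is flagged as pause-positive when the
median falls in 10–40 ms *and* the cross-correlogram rate in the first
10 ms after a CS (the band minimum, where a genuine pause implies
silence) is below half the unit's overall SS rate — an explicit numeric
floor replacing visual correlogram inspection. Classification: PC
requires CS present below 3 Hz, SS above 50 Hz and the pause flag;
no CS ⇒ non-PC; CS present but criteria failed ⇒ rejected. SS and CS
rates are measured over non-stimulation epochs, so strong modulation
cannot push a unit out of its rate band. Autocorrelogram "shoulder"
shape analysis is not attempted. Trials overlapping any locomotion
interval (any overlap, half-open) are dropped, recordings cap at 1 hr,
and a unit is included only with ≥ 3 clean trials per
(intensity, polarity).

**Modulation.** Each trial contributes three half-open 5 s windows:
before `[ramp_in − 5, ramp_in)`, during `[plateau_start,
plateau_start + 5)` (the full plateau for 15 s pulses), after
`[ramp_out_end, ramp_out_end + 5)` — the rebound deliberately lands in
"after" and is assessed only through the omnibus test, with no separate
rebound statistic. PSTHs are counts per 0.1 s bin (1 s for CS),
converted to Hz, averaged over trials *before* the z-transform;
`z = (X − μ)/σ` with μ, σ (sample SD) from the baseline bins. A silent
or constant baseline (σ = 0) yields an undefined z-PSTH: the unit is
flagged and excluded from z-based outputs but retained for window-rate
tests. The omnibus test applies Shapiro–Wilk per condition column
(constant columns fail the gate); all-normal routes to one-way
repeated-measures ANOVA with Tukey HSD pairwise comparisons (studentized
range on the RM error mean square), otherwise Friedman's chi-square
(mid-rank ties; an all-constant-rows matrix returns statistic 0, p = 1)
with Nemenyi pairwise comparisons (mean-rank differences against the
studentized range with infinite df). Units are tested at α = 0.05 with
no multiple-testing correction across units, matching per-neuron
testing practice; a Benjamini–Hochberg option exists but is off by
default. CS-rate and pause-latency comparisons use per-trial window
values through the same omnibus machinery. Normalized modulation is
`100·during/before` (undefined and flagged for a silent baseline);
folded modulation is `|percent − 100|`; both signed and folded values
are emitted. The population scatter fit is OLS of cathodal on anodal
modulation with Pearson R and its two-sided p; region comparisons use a
two-sided Mann–Whitney U, exact by full enumeration for combined
n ≤ 20 (two-sided p = twice the smaller tail, capped at 1) and
tie-corrected normal (no continuity correction) otherwise.

**Orientation.** θ is the signed planar angle from the electrode normal
to the soma→dendritic-centroid vector, counterclockwise positive, in
[0, 360) — 0° means dendrites toward the electrode. The 0–360°
convention follows the polar presentation of orientation data; angles
are computed in the 2-D section plane (3-D reconstruction is out of
scope). The predicted modulation sign is `sign(polarity·cos θ)` with a
dead zone |cos θ| < 0.1 (config) returning 0, motivated by the null
effects observed near 90°/270°. The cosine model
`mod − 100 = A·cos(θ − φ)` is fitted linearly via
`a·cos θ + b·sin θ`; it requires ≥ 4 units spanning ≥ 2 quadrants.

## What the benchmark shows — and does not

Passing tests establish that the estimators recover the generator's
ground truth under its assumptions: a uniform, depth-directed field
acting multiplicatively through cos θ; Poisson-like spiking; stationary
baselines; independent trials; noise that is Gaussian and, for LFPs,
purely multiplicative per cycle. Real recordings violate several of
these (electrode drift, bursting and CS-SS interactions beyond the
pause, non-stationary arousal state, field inhomogeneity across folia),
so green tests here do not certify performance on real data — they
certify the internal consistency and correctness of the analysis chain.
Headline population numbers from in vivo datasets (regional means,
counts of significant neurons, specific R values) depend on those real
data and are not reproduced at desk scale; the benchmark instead checks
recovery errors, calibration of test levels, and parameter recovery.

## Problem sizes and numerical choices

The packaged checks use: 5 depths × 3 intensities with 10 s traces for
noiseless field recovery (600 s with 5% noise, giving the per-segment
precision that pooling animals provides in practice); 200 units for
classification accuracy; 500 null units (20 trials each) for the
false-positive rate and 100 units (50 trials, plateau gain 1.3) for
power; 16 PCs on a 22.5° grid with 50 trials per polarity for cosine
recovery. Monte-Carlo assertions use 3-SEM bands; exact identities use
1e-6–1e-12 tolerances as stated per test. Seeds are fixed in tests and
flow from a single `--seed` in the acceptance script (all generators are
`numpy.random.Generator`-based; identical seeds reproduce byte-identical
exports). The degree-2 surface approximates the out-of-class log law
within 15% over 0.3–2.3 mm (measured ~6%); that tolerance is stated in
the tests. Known limitations: no compartmental biophysics, no synaptic
network, no waveform-shape statistics, no spike-sorting of overlapping
multi-unit traces (rendered-trace tests use isolated units), and the
rebound parameters are placeholders as noted above.
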