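# Methods

This note documents the models, the defaults and why they were chosen, the
synthetic study conditions, and the numerical choices a maintainer needs to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Chromophore inversion (MBLL)

Optical-density change is defined against the mean intensity over a
reference window, by default the protocol's baseline segment (the choice of
reference is open in typical acquisitions; it is configurable). The 2×2
system in (Δ[HbO₂], Δ[Hb]) is solved exactly per sample; with ε in
cm⁻¹·mM⁻¹ and L in cm the solution is in mM and reported in µM.

* Geometry: ρ = 3.0 cm, DPF = 5 at both wavelengths (one DPF value per
  configuration; per-wavelength DPF accepted).
* Extinction coefficients at 695/830 nm are interpolated from the
  Prahl/OMLC compilation of the Gratzer hemoglobin spectra (base-10
  convention, matching the log₁₀ OD definition) and overridable via JSON.
  They enter only as a fixed linear map; every test is a round trip, so no
  result depends on their absolute accuracy.
* The inversion refuses ill-conditioned extinction matrices
  (condition number > 1e6) and names the wavelength pair.
* Channel averaging happens after per-channel inversion, on concentrations:
  averaging raw intensities across channels with different optode couplings
  has no physical meaning.

## Blood-flow-index fitting (DCS)

The semi-infinite correlation-diffusion Green's function with Brownian
dynamics is the forward model; the random-ballistic (flow) variant is not
implemented. The effective reflection coefficient comes from the standard
polynomial approximation in the relative refractive index
(R_eff(1.37) ≈ 0.506); the extrapolated boundary is
z_b = (2/3μ_s′)(1+R_eff)/(1−R_eff).

g₁ is evaluated in the factored form
e^{−(K−K₀)r₁}·[1−(r₁/r_b)e^{−KΔr}]/[1−(r₁/r_b)e^{−K₀Δr}], which yields
g₁(0) = 1 exactly and avoids cancellation between two tiny exponentials at
large lags; g₁ underflows to 0 once (K−K₀)r₁ exceeds ~745 (float64), which
is far below any fittable signal level.

* Optical properties are configuration with logged defaults — μ_a = 0.1,
  μ_s′ = 10 cm⁻¹, n = 1.37, λ = 785 nm, ρ = 2.5 cm — conventional
  adult-head values; results are only meaningful relative to the assumed
  model, which is echoed into every run manifest.
* Nonlinear fit: trust-region least squares over (log₁₀ αD_B, β); bounds
  αD_B ∈ [1e−12, 1e−4] cm²/s, β ∈ (0, 1]; tolerances 1e−12; initialized
  from the linearized estimator. β can be fixed instead (``fix_beta``).
  Standard errors come from the Gauss–Newton covariance (delta method for
  the log-parameterized flow index).
* Linearized estimator: β by linear extrapolation of g₂−1 over the five
  earliest lags to τ = 0; Siegert conversion; degree-N polynomial fit of
  ln g₁ over the contiguous early lags with (g₂−1)/β ≥ 0.3 (nonpositive
  excess values are excluded and counted); the initial slope maps to αD_B
  through the analytic τ = 0 derivative of the forward model. This is one
  member of the family of Nth-order linear inversions; it is cross-validated
  against the nonlinear fit (10% agreement across a parameter sweep) rather
  than against any external implementation.
* Per-frame fits are independent (no temporal regularization); failed
  frames are marked missing, never silently interpolated. rCBF is
  100·αD_B(t)/mean(αD_B over the baseline window), so the baseline mean is
  100 by construction. Both αD_B and rCBF are emitted.
* A flat g₂ curve (max excess < 0.02) raises a no-decay error instead of
  returning an arbitrary fit.

## Signal conditioning

The stated conditioning chain for all hemodynamic variables is a
third-order zero-phase Butterworth filter, then a 5-point centered moving
average, then channel averaging. Zero phase is obtained by
forward–backward application with odd-symmetric edge padding of three times
the realized filter order; cutoffs specify the single-pass design, so the
two-pass −3 dB points sit slightly inside the band (the two-pass magnitude
is the single-pass magnitude squared — verified numerically in the tests).

**Band-pass vs low-pass.** `preprocess.FilterSpec` defaults to the
0.01–0.5 Hz band-pass design, and the acceptance script measures its upper
−3 dB edge. The analysis pipeline, however, defaults to the 0.5 Hz
*low-pass* variant (`filter.low_hz: null`) for one documented reason: a
single block run lasts 160 s, so the task response's fundamental lies near
1/160 ≈ 0.006 Hz — *below* the 0.01 Hz low cut. Applying the band-pass to a
single-block record removes most of the response the phenotype rules must
quantify (measured ≈4× attenuation of task deltas). The band-pass remains
one config key away and is appropriate for long multi-block recordings
where drift removal matters and the response energy sits at the block
repetition frequency. A related consequence: the noiseless
truth-reproduction test runs the inversion chain without the filter stage,
because no implementation can reproduce a single-block truth through a
filter that removes the block's own band; the filtered path is covered by
the label/delta recovery tests instead.

The rCBF series is filtered as its deviation from the 100 % baseline
(filter, then restore the offset), since any high-pass annihilates the DC
that carries the normalization.

Artifact handling: samples are flagged where the absolute first difference
exceeds k = 6 robust SDs (1.4826·MAD) of the channel's differences, or an
optional amplitude ceiling; flagging and exclusion are separate decisions,
and the pipeline excludes a channel from averaging only when more than 5 %
of its samples are flagged (both knobs configurable, both reported).

## Protocol analysis

Timelines are contiguous baseline/task/recovery segments from t = 0; VFT
and HCT default to 30 + 60 + 70 s = 160 s; the VBH task is bounded by the
recorded breath_start/breath_end events (hold durations are
subject-dependent, so VBH timelines are fully event-driven). Segments are
half-open [start, end): a boundary sample belongs to the later segment, and
segmentation is a partition (property-tested).

Summary features per signal: baseline mean; task and recovery deltas
(segment mean − baseline mean); within-segment OLS slope (descriptive
only — the analysis deliberately contains no inferential statistics);
overshoot flag (recovery exceeds baseline after a task-period decline);
task nadir and post-task peak relative to baseline (the breath-hold
landmarks); and a fluctuation index — the SD of the 0.05–0.2 Hz component
during the task divided by the same-band SD during baseline, 0/0 guarded
to 0. Five seconds at each segment edge are excluded from the band SDs:
the band filter is non-causal, so a sharp transient in a neighbouring
segment (e.g. the post-release hyperemic peak) would otherwise leak across
the boundary and inflate the index. The 0.05–0.2 Hz band targets slow
vasogenic oscillations while excluding task-locked trends.

Phenotype rules and defaults (all configurable; rule margins are always
reported so threshold sensitivity is inspectable):

* Oxygenation, cognitive tasks: typical_activation if ΔHbO₂ > 0.2 µM and
  ΔHb < −0.1 µM; task_ischemia if both < −0.2 µM; blunted if both
  amplitudes < 0.1 µM; otherwise unclassified.
* Oxygenation, breath hold: hypoxia_typical if ΔHbO₂ < −0.2 µM and
  ΔHb > +0.1 µM; blunted inside the 0.1 µM ceiling; otherwise
  hypoxia_atypical (e.g. a delayed paradoxical rise of both chromophores).
* Flow: flow_instability if the fluctuation index exceeds 2.0 (checked
  first — instability dominates any delta pattern); for VBH,
  vbh_dip_hyperemia if the task nadir is more than 5 % below baseline and a
  post-task peak exceeds 5 % above it; stable if |task delta| < 5 %;
  otherwise task_increase / task_decrease_recover by sign.

Raising the blunted ceiling can only move labels toward blunted, never away
(monotonicity is property-tested). Repeated runs of the same protocol are
averaged at the summary level, not as raw curves, since no alignment rule
across days is defined.

## Synthetic study conditions

The generator's defaults are the study conditions for every test. The
response kernel is a saturating exponential toward a task plateau
(τ_rise = 10 s) with exponential recovery (τ_rec = 20 s) toward an optional
overshoot level — block trends, not transient HRF convolution, matching the
plateau-like curves the protocols elicit. Archetype amplitudes (fixtures,
declared in `ARCHETYPE_TABLE`): healthy cognition +0.8/−0.3 µM;
vascular-deficit cognition −0.6/−0.3 µM with a +0.2 µM HbO₂ recovery
overshoot; neuron-deficit ≤ ±0.1 µM everywhere; healthy breath hold
−0.5/+0.3 µM; vascular-deficit breath hold +0.4/+0.3 µM with a 10 s onset
delay. Flow: neuron-deficit carries a 0.1 Hz oscillation, ±3 % at rest
gated up to ±15 % during the task and early recovery (autoregulatory
instability is task-provoked); vascular-deficit VFT sustains +10 %, HCT
drops −12 % with fast (5 s) recovery. The breath-hold flow kernel dips to a
nadir, partially recovers during the hold, and shows a post-release
hyperemic hump (width ~6 s): the healthy archetype declines gradually
across the hold (nadir at release, −10 %, hyperemia +20 %), the
vascular-deficit archetype dips rapidly at onset (nadir at 25 % of the
hold, −15 %, hyperemia +12 %). Baseline flow index 1e−8 cm²/s, β = 0.5.

Noise (per channel, independent): white Gaussian (0.10 µM / 3 % rCBF),
1/f by spectral synthesis (0.05 µM / 1 %), and a ~1 Hz cardiac sinusoid
with seeded random phase (0.10 µM / 2 %); g₂ frames carry 1 % multiplicative
Gaussian noise per lag — a lag-independent surrogate for correlator shot
noise, with the fraction as the single knob. Default datasets use 5 fNIRS
channels (montage-scale channel counts are configuration; the 51-channel
default montage is 11 prefrontal + 2×20 temporal) and one DCS channel with
one g₂ frame per 0.5 s — a realistic correlator averaging time that also
keeps the conditioning band below the flow-series Nyquist; the flow truth
itself lives on the 0.1 s grid. Every random element consumes an explicit
seed; a dataset manifest regenerates it bit-identically.

What the generator does *not* emulate — motion artifacts with realistic
morphology, superficial/systemic physiology shared across channels, layered
head geometry, correlated multi-channel noise, true photon-counting
statistics — bounds what passing tests show about real data: they verify
the estimators, the conditioning chain and the rule logic under the stated
noise model, not robustness to every clinical confound.

## Numerical choices and degenerate inputs

* Strictly positive intensities are enforced at construction (the offending
  channel and timestamp are named); NaNs must be handled before filtering.
* Filter application requires more samples than 3× the realized filter
  order; shorter series are rejected, not padded further.
* The moving average uses shrinking windows at the edges (no invented
  values); the window must be odd.
* Fitting tolerances: 1e−12 (ftol/xtol/gtol) on the trust-region fit; the
  no-decay floor is 0.02 on max(g₂−1).
* Noiseless flat series: fluctuation index defined as 0; OLS slope of a
  degenerate single-point segment is 0; segments with fewer than 10 samples
  are rejected.
* Reports are serialized with sorted keys so identical configurations
  produce byte-identical reports.

## Problem sizes used in the checks

The acceptance script and test suite size their simulations for a
single-CPU laptop-class run: 160 s records at 10 Hz (oxygenation) and 2 Hz
(flow frames), 50-lag multi-tau grids, 100 noise draws for the noisy
recovery study, a 200-point brute-force grid for the fit oracle (with the
coherence factor profiled analytically, since it enters linearly), and
label-recovery sweeps over all 9 archetype × protocol pairs across multiple
seeds (10 in the test suite, 3 in the acceptance script).

## Known limitations

* Only the semi-infinite homogeneous geometry; no layered or curved models,
  no absolute calibration of αD_B to physiological flow units, and no
  estimation of μ_a/μ_s′ from data.
* Only relative (Δ-from-reference) oximetry; no partial-volume correction
  or short-separation regression.
* The phenotype rules are deterministic thresholds designed for clean
  archetype separation; on real data the reported margins matter more than
  the labels themselves.
* Channel topology is opaque labels; no spatial co-registration or mapping.
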