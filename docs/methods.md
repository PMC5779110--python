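# Methods

This note documents the models implemented in `magnetherm`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions made where the underlying procedure was open.

## Nanoparticle heating physics

**Dipole interaction and the thermal threshold.** Two identical
superparamagnetic particles with aligned moments m at separation r are
treated as point dipoles, U(r) = (μ₀/4πr³)·2m². The separation at which U
crosses the thermal energy, r* = (2μ₀m²/4πk_BT)^(1/3), is the scale below
which induced dipole aggregation becomes relevant; for the ~12.5 nm
core-shell ferrite particles modeled here (m ≈ 4.8×10⁻¹⁹ A·m²) r* ≈ 22 nm
at body temperature, whereas for ferritin it is below contact distance.

**Relaxation.** The Néel time follows the Arrhenius form
τ = τ₀·exp(KV/k_BT) with attempt time τ₀ = 10⁻⁹ s (standard literature
value for ferrites; configurable through `PhysicalConstants`). Brownian
rotation (τ_B = 3ηV_h/k_BT) is *not* combined by default: membrane-bound
particles cannot rotate freely, so Néel relaxation is the operative loss
channel. `slp(..., combine_brownian=True)` provides the parallel
combination 1/τ = 1/τ_N + 1/τ_B for suspension comparisons. If the
Arrhenius exponent overflows the double range the particle is blocked, not
superparamagnetic, and the function raises rather than returning a silent
infinity.

**Specific loss power.** Linear-response dissipation
P_vol = πμ₀χ₀H₀²f·(2πfτ)/(1+(2πfτ)²), converted to W/g by dividing by the
particle mass density. The equilibrium susceptibility is the *chord*
convention χ₀(H₀,T) = M_s·L(ξ)/H₀ with ξ = μ₀mH₀/k_BT and
L(ξ) = cothξ − 1/ξ, which reduces to the initial susceptibility
μ₀M_s²V/3k_BT in the small-field limit (tested explicitly: P ∝ H₀² there).
Field amplitudes are interpreted as rms unless `FieldSpec(peak=True)`. The
saturation magnetization M_s and anisotropy constant K of a given particle
batch are measurement inputs (`ParticleSpec`), not built-in constants; the
module ships no default particle.

**Calorimetry.** Heating rate vs particle density is fitted by ordinary
least squares with a free intercept (forcing the origin is a deliberate
non-default, since the measured lines are consistent with but not
constrained to zero intercept). The suspension slope (°C·µm³/s per
particle) times the volumetric heat capacity of water at 37 °C
(4.18×10⁻¹² J·µm⁻³·K⁻¹, configurable) gives the power per particle; the
ratio of suspension (volumetric) to membrane (areal) slopes gives the
thickness of the water slab the membrane-bound sheet effectively heats
(≈0.5 µm). Near-membrane dynamics are modeled as Newtonian,
dT/dt = r·𝟙(field on) − (T−T_env)/τ_c, integrated exactly per grid
interval because the forcing is piecewise constant; the plateau is
T_env + r·τ_c. Heating scales as H², so time-to-threshold scales as
(H_ref/H_new)²; the amplitude permissible at a frequency f keeps
H·f = const (the accepted bound on background eddy-current heating in
tissue).

## Thermometry and trace normalization

Processing order: (1) subtract the constant camera dark offset (clipping
at zero only warns, so batch jobs survive a mis-stated offset); (2) if the
fitted baseline decays by more than 2 % over the recording (threshold
configurable), correct photobleaching; (3) normalize to percent ΔF/F about
the mean of a baseline window (default: the first 10 s).

The bleach model is F′_fit(t) = A·e^(−t/τ_b) + C fitted to baseline
samples only, and the corrected trace is F(t) = F′(t) + (F′(0) −
F′_fit(t)): the baseline flattens at the initial intensity while transient
excursions are preserved additively. Baseline samples default to those
within 2 robust standard deviations (1.4826·MAD) of a 5 s rolling median —
a detrending criterion chosen because a simple below-percentile rule
concentrates its samples in the dim late half of a strongly bleached
recording and starves the fit of early support. Non-convergence of the
exponential falls back to a linear baseline with a logged warning. The
correction is idempotent to within 10⁻⁶ relative.

Temperature conversion is linear: ΔT(t) = (ΔF/F)(t) / s with
s = −2.2 %/°C for DyLight 550. Linearity is assumed over the few-degree
range relevant near a membrane; the calibration slope and reference
temperature are fields of `ThermoCalibration`.

## Spike-train reconstruction

GCaMP6f resolves single action potentials (~5 % ΔF/F transients, ~0.1 s
rise, ~0.6 s decay) but not their fine timing within bursts. The
reconstruction poses the inverse problem: find the binary event series on
a 100 Hz grid whose convolution with a single-spike template best explains
the 10 Hz trace.

**Template.** Preferably measured: isolated peaks near the single-spike
amplitude are detected, aligned on their maxima, averaged at the native
rate and linearly interpolated to 100 Hz. With fewer than 3 usable peaks,
`default_template()` supplies a double-exponential
(1−e^(−t/τ_rise))·e^(−t/τ_decay) waveform (τ_rise = 0.1 s,
τ_decay = 0.6 s, 1.5 s support, tapered to zero over the final 0.2 s so
the convolution adds no step).

**Placement.** The event locations are optimized by greedy matching
pursuit: the SSE reduction of adding an event at position p is
2⟨r, c_p⟩ − ‖c_p‖² (r the current residual, c_p the template sampled onto
the trace frames), computed for all positions at once by correlating the
zero-stuffed residual with the template. Events are added while the best
gain exceeds a configurable fraction (default 0.25) of a clean
single-event energy — small enough to pick up strongly overlapping
transients, large enough that noise-level gains (at σ ≤ 1.5 % ΔF/F they
are bounded well below half an event energy) never cross it. Greedy
addition is followed by coordinate-descent sweeps that re-place each event
against the residual of the others until no move improves the SSE (at most
10 sweeps). On short traces this procedure attains the global minimum-SSE
placement, verified in the tests against exhaustive enumeration of all
≤3-event placements.

**Acceptance.** The residual histogram (Freedman–Diaconis bins) is fitted
with a Gaussian; reconstruction succeeds when its σ is below the target
(default 2 % ΔF/F). Failure is reported (`success=False` plus a logged
warning), never silent. Events closer than the template rise time are
representable but intrinsically ambiguous at this indicator speed.

**Statistics.** Rate series use half-open bins (default 5 s; totals are
conserved for any bin origin). First-spike latencies are measured from
field onset, censored when no event follows. The latency histogram (1 s
bins from onset) is fitted by unweighted least squares with a scaled
Poisson pmf evaluated at integer bin indices, returning λ and its standard
error. The temperature dose–response is fitted with the Hill form
R(T) = R_min + (R_max−R_min)/(1+(T₅₀/T)ⁿ); T₅₀ is the half-maximal-rate
temperature. Active fraction is the percent of cells with ≥1 event in a
5 s window, with a binomial standard error.

## Open-field kinematics

Trajectories are marker positions in arena-centered mm (y up, CCW
positive), default 30 samples/s in a 50-mm-radius arena. Linear speed is
frame-to-frame displacement over dt, averaged in a centered 500 ms window
(3 s for freezing analysis, matching the slower paw-track sampling).
Angular kinematics support two references: the unwrapped polar angle about
the arena center (arena circling) and the unwrapped heading of the
velocity vector (body-axis rotation, the default for small off-center
circles). Unwrapping takes the shortest arc per frame — valid because at
30 samples/s no behavioral rotation approaches π per frame. Below a 1 mm/s
speed floor the heading is undefined and held at its last defined value
(flagged), so rest-period jitter cannot wind the angle. Note that the
about-center angle of a closed loop is ±1 revolution per turn only if the
loop encircles the arena center; a 22 mm circle centered further than
22 mm from the origin contributes zero net about-center angle while the
heading mode counts every body turn.

Episode statistics split samples into field-on and field-off conditions
and report per-condition mean, sd, sem, t-based 95 % CI, Welch's unpaired
t-test, and the on/off fold change. Behavioral onset/offset latencies use
a threshold of baseline mean + k·sd (k = 2) sustained for 2 s — detector
constants are exposed and echoed in output because latency values depend
on them. Freezing is classified where the 3 s-averaged speed does not
exceed the fixed-marker apparent speed plus twice its sd (defaults
0.52 + 2·0.11 mm/s). Turn summaries count per-trial net rotation signs,
the fraction contralateral to the injected hemisphere (left injection ↔
clockwise), and flag reversals where the windowed angular rate changes
sign after motion onset.

## Synthetic data

The generators produce, under a single integer seed, every input the
pipeline consumes, with the statistical structure of the corresponding
recordings:

- **GCaMP6f traces** (10 Hz): baseline·e^(−t/τ_b)·(1 + Σtemplate/100) +
  dark offset + Gaussian noise, with the generating spike train returned.
  Transient amplitudes bleach together with the baseline, as they do under
  a shared illumination path.
- **Thermometry traces**: intensity = baseline·(1 + s·ΔT(t)/100) + noise
  with the −2.2 %/°C slope.
- **Heating observations**: rate = slope·density + noise, clipped at 0;
  the default slope is the measured suspension value 5.8×10⁻⁴ °C·µm³/s
  over densities spanning the measured 0.1–0.5 °C/s rate range.
- **Trajectories** (30 Hz): peripheral running (near-wall circle at a set
  speed), body-axis rotation (22 mm circle about a settable center),
  freezing (positional jitter calibrated so the apparent speed equals a
  set floor — |Δp| per frame is Rayleigh, so jitter σ = v/(f_s·√π)), and
  exploration (bounded correlated random walk with near-constant step
  length and diffusing heading, steered inward near the wall; its measured
  mean speed tracks the set value within a few percent). Scenario presets
  (`motor-cortex`, `striatum`, `fog`) chain off/on segments continuously
  around 60 s field windows using the measured condition means
  (83.8/5.3 mm/s, 22 mm radius, 17.7/1.04 mm/s).
- **Latencies**: integer Poisson draws (mean λ, default 2.18 s) plus
  uniform within-bin jitter.

Noise is Gaussian and homoscedastic everywhere — a deliberate
simplification. Real recordings add shot noise with intensity-dependent
variance, slow focus and motion artifacts, tracking dropouts, and
cell-to-cell template variability; passing tests on these generators
therefore demonstrate correctness of the algorithms under their stated
model, not robustness to every instrumental pathology. Tracking dropouts
are handled on the input side (gap-filling up to 0.5 s on read; longer
gaps split the record).

## Problem sizes and tolerances

The test suite and the acceptance script use desk-scale problems chosen to
exercise each estimator's asymptotics without waste: 100 seeded
reconstruction trials of 10 s traces with 5 events at 1 % noise
(recovery ≥ 95 % of trials exact); exhaustive-enumeration cross-checks on
4 s traces with ≤3 events; 10⁴ latency draws for the Poisson fit
(λ recovered within ±0.05); 17 temperature points for the Hill fit
(T₅₀ within ±0.2 °C); 20-point calorimetric fits (slope within 3 SE).
Numerical tolerances: the Newtonian integrator matches the closed form to
10⁻⁶ °C; threshold-distance/dipole-energy inversion holds to 10⁻¹⁰
relative; curve fits use scipy defaults with explicit bounds and raise
with diagnostics on non-convergence.

## Known limitations

- The matching pursuit assumes unit-amplitude events and one shared
  template; amplitude adaptation (e.g. per-event scaling) is out of scope.
- SLP validation against an absolute measured value requires the particle
  batch's M_s and K from magnetometry; the package treats them strictly as
  inputs.
- Whether a quoted field amplitude is rms or peak changes SLP by 2×; the
  `peak` flag must be set by the user when known.
- The freezing detector and latency detector thresholds are conventions,
  not measurements; downstream comparisons should hold them fixed.
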