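# magnetherm

Analysis pipeline for **magnetothermal genetic neurostimulation**
experiments: an alternating magnetic field (AMF) heats superparamagnetic
nanoparticles (MNPs) bound to the membrane of TRPV1-sensitized neurons; the
local temperature rise opens the heat-gated channels, evoking spiking in
vitro and motor behavior in freely moving mice. The package provides the
quantitative analyses such an experiment needs, end to end:

- **physics** — MNP energy transduction: dipole interaction energy
  U(r) = (μ₀/4πr³)·2m², Néel relaxation τ = τ₀·exp(KV/k_BT), specific loss
  power P = πμ₀χ₀H₀²f·2πfτ/(1+(2πfτ)²) with a Langevin chord
  susceptibility χ₀(H₀,T) = M_s·L(ξ)/H₀, calorimetric heating-slope fits,
  the H·f = const tissue-safety scaling, and Newtonian heating/cooling
  dynamics.
- **thermometry** — ROI fluorescence to temperature: dark-noise
  subtraction, exponential photobleaching correction
  F(t) = F′(t) + (F′(0) − F′_fit(t)), ΔF/F normalization, and the DyLight
  550 calibration (−2.2 % intensity per °C).
- **calcium** — spike-train reconstruction from GCaMP6f ΔF/F traces:
  greedy template matching pursuit on a 100 Hz grid with a residual-σ
  acceptance criterion (Gaussian fit to the residual histogram, σ < 2 %),
  plus rate binning, first-spike latencies with a Poisson fit, the Hill
  temperature–rate curve R(T) = R_min + (R_max−R_min)/(1+(T₅₀/T)ⁿ), and
  active-fraction statistics.
- **kinematics** — open-field trajectories (30 samples/s, 50-mm arena):
  windowed linear speed, cumulative rotation about the arena center or of
  the heading vector (CCW positive), field-on/off episode statistics with
  fold changes and Welch t-tests, behavior onset/offset latencies,
  freezing-of-gait detection against a fixed-marker noise floor, and
  turn-direction summaries.
- **synthetic** — seeded generators for every input above, each returning
  its ground truth, so the whole pipeline is testable without recorded
  data.
- **io / cli** — delimited-table readers/writers, run configs, and a thin
  `magnetherm` command with `simulate`, `spikes`, `thermo`, `physics` and
  `behavior` subcommands.

## Worked example

`examples/` contains one narrative script per capability. Reconstructing a
spike train from a noisy, bleaching calcium trace
(`examples/spike_reconstruction.py`):

```text
true spike times: [3.1, 8.4, 14.2, 15.0, 21.0, 27.7]
baseline decayed >2%: applied exponential bleach correction
reconstructed:    [3.1, 8.4, 14.2, 15.0, 21.0, 27.7]
residual sigma:   0.47% DF/F (target < 2.0%) -> success=True
events per 5 s bin: [1, 1, 1, 1, 1, 1, 0] (the rate measure used for temperature dose-response curves)
first spike after a field onset at 5 s: 3.40 s latency
```

All six generating events are recovered at their exact 100 Hz positions;
the residual between the measured trace and the template convolution of the
reconstructed train is Gaussian with σ = 0.47 % ΔF/F, well under the 2 %
acceptance criterion. The other scripts print, among others: the
suspension heating slope (5.8×10⁻⁴ °C·µm³/s) and the 2.42 fW per-particle
power it implies; the 0.53 µm water slab a membrane-bound MNP sheet
effectively heats; a −4.4 % dye dip converting to a +2.0 °C membrane rise;
and the 16-fold linear-speed increase of the motor-cortex stimulation
scenario.

The same analyses run from a shell:

```sh
magnetherm simulate --scenario gcamp --seed 1 --out run1
magnetherm spikes --trace run1/gcamp_trace.csv --dark-noise 100 --out run1
magnetherm behavior --scenario motor-cortex --seed 1 --out run1
```

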