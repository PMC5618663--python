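# rsfpkit

Analysis toolkit for the photoswitching behavior of reversibly switchable
fluorescent proteins (RSFPs), built around the rsGreen family and its
Enhancer-nanobody fusions.

Negative-switching RSFPs are driven to a dark state by the same cyan light
that excites their fluorescence, and back to the bright state by violet
light. Repeated on/off cycling is the basis of RESOLFT and pcSOFI
sub-diffraction imaging, and its two failure modes — incomplete switching
(residual baseline) and switching fatigue (progressive loss of recoverable
signal) — are what this package quantifies.

`rsfpkit` is for spectroscopists and microscopists characterizing such
probes. It implements:

- **Spectroscopy** — pKa from a sigmoidal (Henderson–Hasselbalch) fit to a
  pH titration; extinction coefficients by Ward's denatured-chromophore
  method; extrapolation of the apparent extinction coefficient ε₇.₄ to the
  fully deprotonated chromophore, ε_on = ε₇.₄ · (1 + 10^(pKa − pH));
  quantum yield relative to EGFP (Φ_ref = 0.60); molecular brightness
  ε₇.₄·Φ scaled to 100 for a reference construct.
- **Trace extraction** — threshold/label colony image stacks, per-object
  background-subtracted mean traces, normalization to the point of complete
  on-switching, per-object maximum brightness.
- **Switching kinetics** — every off half-cycle is modeled as two emissive
  species with distinct off-rates, each decaying to its own residual
  plateau:

  F(t) = a·[(1−f_A)e^(−k_A t) + f_A] + b·[(1−f_B)e^(−k_B t) + f_B] + c

  A *global fit* shares (k_A, k_B, f_A, f_B, c) across all cycles of an
  experiment (e.g. 500) while the per-cycle amplitudes (aₙ, bₙ) ≥ 0 are
  profiled out by non-negative linear least squares inside the nonlinear
  iteration. Includes 1-vs-2 species model selection (corrected AIC) and
  thermal-recovery fits F(t) = F∞ − (F∞ − F₀)e^(−k_th t).
- **Population dynamics** — across cycles the fast species A interconverts
  to the slow species B and both are photodestroyed:

  da/dn = −(k_AB + k_dA)·a,  db/dn = k_AB·a − k_dB·b

  with closed-form trajectories, fitting, fatigue/contrast metrics, and the
  photon-dose argument separating speed-based from intrinsic stabilization
  of the fast state.
- **Synthetic data** — a seeded generator producing traces, titrations,
  recovery curves and rendered colony stacks with known ground truth, so
  every stage is testable end to end.

## Worked example

Simulate the reference repeated-switching experiment (a field of 20 cells,
500 cycles of 25 on + 25 off periods of 100 ms), globally fit the decays,
then fit the cycle-scale population dynamics:

```python
import rsfpkit as rk
from rsfpkit.synthetic import reference_field_experiment

exp = reference_field_experiment(seed=1, n_cycles=500)
kin, amps, fit = rk.global_fit(exp)
print(f"k_A = {kin.k_A:.3f} /s   k_B = {kin.k_B:.3f} /s   f_B = {kin.f_B:.3f}")

params, _ = rk.fit_population_dynamics(amps.a, amps.b)
print(f"k_AB = {params.k_AB:.5f}  k_dA = {params.k_dA:.5f}  k_dB = {params.k_dB:.5f}")

report = rk.fatigue_metrics(exp)
print(f"cycles to half on-level: {report.cycles_to_half:.1f}")
```

prints

```
k_A = 5.996 /s   k_B = 0.998 /s   f_B = 0.148
k_AB = 0.00601  k_dA = 0.00398  k_dB = 0.00402
cycles to half on-level: 193.3
```

The generating truth was k_A = 6, k_B = 1 s⁻¹, f_B = 0.15 and per-cycle
rates k_AB = 0.006, k_dA = k_dB = 0.004, so the shared kinetics and the
interconversion/destruction rates are recovered to well under 2% from noisy
data. `amps.b` rises from near zero, peaks mid-experiment (here cycle
~152 = ln(α/k_dB)/(α − k_dB) with α = k_AB + k_dA) and declines — the
slow-species accumulation that explains the rising per-cycle baseline
without invoking a separate non-switching state.

The characterization side works from measured inputs:

```python
from rsfpkit.datasets import published_profiles
from rsfpkit.reporting import characterization_report
print(characterization_report(published_profiles(), "rsGreen1"))
```

which reproduces the published deprotonated-state extinction coefficients
(69, 78, 65, 72 ×10³ L mol⁻¹ cm⁻¹ for rsGreen1, rsGreen1-Enhancer,
rsGreenF, rsGreenF-Enhancer) and scaled molecular brightness values
(104, 100, 123, 73, 88 with EGFP included).

## Command line

`rsfpkit` exposes subcommands `simulate`, `extract`, `spectro`,
`fit-switching`, `fit-recovery`, `fit-populations`, `fatigue`, `run`
(config-driven pipeline with manifest) and `report` (construct
comparison); all take `--seed`/`--out` where applicable. All CSVs are
UTF-8, comma-separated, with a header row and `.` decimal.

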