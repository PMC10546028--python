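# neurohemo

Analysis of task-evoked cerebral hemodynamics measured with two diffuse
optical modalities on the same head:

* **fNIRS** (functional near-infrared spectroscopy) — dual-wavelength
  intensity attenuation converted to changes in oxy- and deoxyhemoglobin
  concentration, Δ[HbO₂] and Δ[Hb], via the modified Beer–Lambert law.
* **DCS** (diffuse correlation spectroscopy) — the temporal decorrelation of
  multiply scattered coherent light converted to a microvascular blood flow
  index αD_B (and relative cerebral blood flow, rCBF) by fitting measured
  intensity-autocorrelation curves with the semi-infinite solution of the
  correlation-diffusion equation.

The package targets block-design stimulus protocols — verbal fluency (VFT),
a high-level cognition task (HCT), and voluntary breath holding (VBH) — and
turns the conditioned Δ[HbO₂]/Δ[Hb]/rCBF time courses into per-run response
summaries and rule-based phenotype labels (typical activation, blunted
response, task ischemia, hypoxia patterns; stable flow, flow instability,
breath-hold dip-and-hyperemia). It is written for researchers prototyping
combined fNIRS+DCS analyses of cerebrovascular reactivity and neurovascular
coupling, e.g. in cerebral small vessel disease, where per-subject curve
phenotypes rather than group statistics are the readout.

Because raw clinical optical recordings are rarely shareable, the package
includes a first-class synthetic generator that emulates three subject
archetypes (healthy; neuron-deficit with blunted oxygenation and unstable
flow; vascular-deficit with ischemic oxygenation and reactive flow) all the
way down to raw dual-wavelength intensities and shot-noisy g₂(τ) frames, so
every stage is verifiable by round-trip and parameter-recovery tests.

## Models

**MBLL.** With effective pathlength L = ρ·DPF (source–detector separation
ρ = 3.0 cm, differential pathlength factor DPF = 5) and extinction
coefficients ε at 695 and 830 nm,

    ΔOD(λ, t) = −log₁₀ I(λ,t)/Ī₀(λ) = L · [ε_HbO₂(λ) Δ[HbO₂] + ε_Hb(λ) Δ[Hb]]

is solved exactly per 0.1 s sample as a 2×2 linear system.

**DCS.** The Siegert relation g₂(τ) = 1 + β·g₁(τ)² links the measured
intensity autocorrelation to the field autocorrelation; for a semi-infinite
medium with Brownian scatterer dynamics (⟨Δr²⟩ = 6 αD_B τ),

    g₁(τ) = [e^{−K(τ)r₁}/r₁ − e^{−K(τ)r_b}/r_b] / [e^{−K₀r₁}/r₁ − e^{−K₀r_b}/r_b],
    K(τ) = √(3 μ_a μ_s′ + 6 μ_s′² k₀² αD_B τ)

with r₁, r_b the source and image-source distances of the extrapolated
boundary condition. `G2Model(frame, optics).fit()` estimates (αD_B, β) by
trust-region least squares with a log-parameterized flow index; a
closed-form Nth-order linearized early-lag estimator (`fit_linear`) is
available both standalone and as the initializer.

**Conditioning.** Third-order zero-phase Butterworth filtering (0.01–0.5 Hz
band-pass design; the analysis pipeline defaults to the 0.5 Hz low-pass
variant — see `docs/methods.md`), 5-point centered moving average, spike
artifact flagging, and unweighted channel averaging after per-channel
inversion.

## Worked example

```python
import json
from neurohemo.pipeline import RunConfig, SimulateConfig, run_pipeline

report = run_pipeline(RunConfig(
    out_dir="demo_run",
    simulate=SimulateConfig(archetype="vascular_deficit", protocol="HCT", seed=11),
))
print(json.dumps(report["labels"]))
```

prints

```
{"oxygenation": "task_ischemia", "flow": "task_decrease_recover"}
```

with the supporting response summary (from `report["summary"]`): Δ[HbO₂]
task delta −0.52 µM and Δ[Hb] task delta −0.25 µM (both chromophores decline
during the cognition task — the ischemic signature), rCBF task delta
−10.3 % with recovery toward baseline, fluctuation index 0.55 (no
instability). The run directory contains the simulated raw data, `oxy.csv`,
`flow.csv`, `report.json` and a checksummed `run_manifest.json` echoing
every defaulted parameter.

Fitting a single noisy g₂ curve directly:

```python
fit = G2Model(frame, optics).fit()
print(fit.summary())
```

```
DCS g2 fit (nls)
----------------------------------------------
blood flow index alpha_Db     1.2479e-08 cm^2/s
s.e.(alpha_Db)                3.38e-10 cm^2/s
coherence factor beta         0.5000
s.e.(beta)                    3.56e-03
sum squared residual          5.261e-03
lags used                     50
converged                     True
```

The same stages are available from the shell:

```bash
neurohemo simulate --archetype healthy --protocol vft --seed 1 --out data/
neurohemo oxy  --intensity data/intensity.csv --timeline data/timeline.json --out oxy.csv
neurohemo flow --g2 data/g2_frames.csv --timeline data/timeline.json --out flow.csv
neurohemo analyze --oxy oxy.csv --flow flow.csv --timeline data/timeline.json --out report.json
neurohemo run --config config.yaml       # all stages, one YAML
```

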