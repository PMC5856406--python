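# rootflow

Post-processing of phase-locked volumetric velocity measurements in the
aortic root, for researchers studying prosthetic-valve hemodynamics in
pulse-duplicator experiments.

After aortic valve replacement, the flow downstream of the prosthesis —
the aortic jet with its shear layer, the starting vortex at valve
opening, retrograde flow (RF) near the wall of the ascending aorta (AAo),
and the washout flow in the sinus of Valsalva (SOV) — carries information
about valve performance, blood damage risk and thrombogenicity.
`rootflow` implements the full analysis chain for such experiments:

* **Parametric aortic-root geometry.** A straight phantom lumen defined
  by the annulus radius *r*ₐ and scale factors *α*ₛ, *α*_co, *α*_stj,
  *β*₁, *β*₂. The widest SOV cross-section is built from three circles of
  radius *r*_sp centred *r*_mc off-axis,

  *r*_mc = *r*ₐ (*α*_co² − *α*ₛ²)/(*α*_co − 2*α*ₛ),  *r*_sp = *r*ₐ (*α*_co *α*ₛ − *α*ₛ² − *α*_co²)/(*α*_co − 2*α*ₛ),

  satisfying *r*_sp + *r*_mc = *α*ₛ*r*ₐ and *r*_sp² = *r*_co² + *r*_mc² −
  *r*_co *r*_mc. Four presets (NS, S, M, L) cover a sinus-less root and
  ±10% size variation around a stenotic-patient geometry.
* **Phase-averaged statistics.** For *N* replicate cycles sampled
  phase-locked at *t*ⱼ = *j*·0.03 s, the ensemble mean ⟨**U**⟩ⱼ, the
  Reynolds decomposition **U** = ⟨**U**⟩ + **u**, and the pooled
  fluctuation magnitude *u*_rms = ⟨**u**·**u**⟩^½.
* **3D shear rate.** γ₃D = ε_max − ε_min, the eigenvalue spread of the
  rate-of-strain tensor **S** = ½(∇**U** + ∇**U**ᵀ), with the planar
  analogue γ₂D (which provably underestimates γ₃D).
* **Integral quantities.** Net and retrograde flow rates through the
  cross-section at *Y* = 0; mean and fluctuating kinetic energies
  E_MK = ρ/2 ∫|⟨**U**⟩|² dV, E_FK = ρ/2 ∫*u*_rms² dV over the domains
  Ω₁, Ω₂ (one and two annulus diameters above the valve tips) and Ω_S
  (the front sinus lobe); windowed metrics Ē_TJ (turbulence intensity,
  0.18–0.36 s), Q̄_RF (mid-systolic RF, 0.15–0.30 s) and Ē_MKS (sinus
  washout, 0.12–0.27 s); normalized diameters δ_SOV = (*r*_co + *r*ₛ)/*d*_jet
  and δ_AAo = 2*r*_stj/*d*_jet with *d*_jet = √(4·A_POA/π).
* **Orifice planimetry.** Projected orifice area from axial valve
  images: affine rectification on three strut landmarks, threshold
  segmentation, multi-pulse phase averaging.
* **Synthetic data.** Since tomographic PIV fields are rarely shareable,
  a generator produces phase-resolved ensembles with the same structure
  (flux-conserving pulsatile jet from a Stokes stream function,
  retrograde near-wall flow, starting vortex ring, sinus swirl, seeded
  fluctuations, pulse-to-pulse jitter) plus rendered orifice images with
  known ground truth — fully deterministic under a master seed.

## Worked example

Run the full pipeline (synthetic planimetry → ensemble generation →
statistics → report) for the medium phantom:

```bash
rootflow report --preset M --seed 1 --out out_m
```

which logs `pipeline complete: 1 phantoms, 208 instantaneous fields`
(13 phases × 16 replicates) and writes `report_M.json` containing

```
E_TJ_mJ     0.0725      mean fluctuating kinetic energy in Omega2, 0.18-0.36 s
Q_RF_lmin   2.2953      mean retrograde flow rate at Y=0, 0.15-0.30 s
E_MKS_mJ    0.0051      mean kinetic energy in the sinus domain, 0.12-0.27 s
delta_SOV   2.1080      (r_co + r_s) / d_jet
delta_AAo   1.8822      2 r_stj / d_jet
d_jet_mm    14.6109     jet diameter from the measured A_POA
Re          6180.4      jet Reynolds number 4 Q_max / (pi d_jet nu)
alpha       13.9323     Womersley number r_a sqrt(2 pi / (T nu))
St          0.9764      tracer Stokes number tau U / d_p
```

The retrograde flow rate of ≈2.3 l/min against a 20 l/min peak forward
flow, and δ_AAo between 1.6 and 2, place this configuration in the
free-shear-layer regime where turbulence intensity and RF grow with the
AAo diameter; running all presets (`rootflow report --seed 1`) shows
Ē_TJ and Q̄_RF increasing monotonically from S through M to L in the
`scatter.csv` summary.

The same objects are available as a library:

```python
from rootflow import PRESETS, Grid, JetFlowParams, PulseWaveform, generate_ensemble
from rootflow.pipeline import analyze_ensemble

geom = PRESETS["M"]
ens = generate_ensemble(geom, JetFlowParams.for_phantom(geom), PulseWaveform(),
                        Grid.for_root(geom, 1.0), n_replicates=16, master_seed=1)
report = analyze_ensemble(ens)
print(report.E_TJ_mJ, report.delta_AAo)
```

## Layout

* `src/rootflow/geometry.py` — parametric lumen, masks, areas, volumes
* `src/rootflow/synth.py` — waveform, jet/RF/ring/swirl generator, ensembles
* `src/rootflow/stats.py` — phase statistics, shear rates, energies, metrics
* `src/rootflow/planimetry.py` — orifice rendering, rectification, segmentation
* `src/rootflow/io.py` — HDF5 field container, VTK/text exports
* `src/rootflow/pipeline.py`, `cli.py`, `config.py` — orchestration
* `docs/methods.md` — model assumptions, parameter choices, limitations
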