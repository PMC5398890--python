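# glicgate

Kinetic simulation and analysis of proton-gated channel gating, built
around the question of how to detect an electrically silent **pre-active
intermediate state** in a pentameric ligand-gated ion channel (pLGIC)
such as GLIC, the proton-gated channel of *Gloeobacter violaceus*.

The experimental logic the package implements: bimane fluorophores
paired with tryptophan/tyrosine quenchers act as short-range
conformational rulers (quenching below ~15 Å / ~10 Å inter-residue
distance), so stopped-flow fluorescence reports protein motion while
voltage-clamp currents and liposome thallium-flux rates report channel
activity.  If the pH dependence of the conformational change (ΔF) and
of channel activity (ΔIf) are separated by more than an order of
magnitude in proton concentration, a conformation exists in which the
extracellular domain has already rearranged while the pore is still
closed — a pre-active state.

## The model

Gating is a four-state continuous-time Markov chain

    R (resting) ⇌ P (pre-active) ⇌ O (open) ⇌ D (desensitized)

with Hill-type proton-dependent forward rates
k(H) = k_max·Hⁿ/(Hⁿ + Kⁿ) and constant backward rates.  Observables:

- **Stopped-flow fluorescence** F(t) = Σ_s b_s·p_s(t) per sensor
  (brightness b_s in denatured-reference units), on a triphasic
  sampling grid with a 2.1 ms mixing dead time, fitted with
  y(t) = F + F₁e^(−k₁t) + F₂e^(−k₂t) + F₃e^(−k₃t) from 5.1 ms,
  amplitudes decomposed into dead-time / fast / intermediate / slow
  phases (log₁₀ τ binning, width 0.4).
- **Activation currents** y(t) = A₁(1−e^(−t/τ₁)) + A₂(1−e^(−t/τ₂)) + C
  with the weighted constant τ_w = (A₁τ₁ + A₂τ₂)/(A₁+A₂).
- **Thallium flux** in ANTS-loaded liposomes: stretched-exponential
  quenching F(t) = F∞ + (F₀−F∞)e^(−(t/τ₀)^β) over the first 100 ms and
  the activity metric k(2 ms) = (β/τ₀)·(2 ms/τ₀)^(β−1).
- **Dose-response** curves fitted with the Hill equation
  y(x) = a·x^nH/(x^nH + EC50^nH) in proton-concentration space,
  pH₅₀ = −log₁₀ EC50.

A structural companion module measures Cβ–Cβ distances (Cα for Gly),
minimal fluorophore–quencher heavy-atom distances, quenching-radius
classification and Kabsch superposition RMSD on PDB coordinate files.

See `docs/methods.md` for assumptions, calibrations and limitations.

## Worked example

```python
from glicgate.pipeline import intermediate_state_run

out = intermediate_state_run(seed=1)
print(out)
```

prints (numbers vary in the last digits with the seed):

```
{'pH50_dF': 5.786, 'pH50_dIf': 4.594, 'delta_pH50': 1.192,
 'flag_intermediate': True, 'nH_dF': 2.494, 'nH_dIf': 2.244}
```

meaning: the fluorescence sensor 136–101 reports a conformational
midpoint at pH 5.79, the flux assay an activity midpoint at pH 4.59.
At pH 5 the conformational change is nearly complete while almost no
channels conduct — the 1.2 pH-unit separation (≥ 1 order of magnitude
in proton concentration) flags the pre-active intermediate.  Running
the same pipeline on the concerted-control scheme (no distinct
pre-active step) gives `delta_pH50 ≈ 0.06` and no flag.

The numbered drivers under `analysis/` tell the full story and write
their tables under `results/`:

```bash
python analysis/01_simulate_dataset.py     # synthetic dataset + manifest
python analysis/02_fit_stopped_flow.py     # multi-exponential phase table
python analysis/03_bin_phases.py           # tau histogram, 3 kinetic clusters
python analysis/04_dose_response.py        # Hill fits + dF/dIf comparison
python analysis/05_flux_delay_profile.py   # desensitization vs pre-mix delay
python analysis/06_structure_distances.py  # distance checks (needs PDB files)
```

`analysis/04_dose_response.py`, for example, prints:

```
          readout  pH50    nH
     dF (136-101) 5.786 2.494
dI (peak current) 5.356 2.251
  dIf (flux rate) 4.594 2.244

dF and dIf midpoints are separated by 1.19 pH units (>= 1 order of magnitude in [H+]):
at intermediate acidity the sensors report a nearly complete conformational
change while the channels conduct almost nothing -> pre-active state detected
```

A `glicgate` console command exposes the individual stages
(`simulate`, `fit-sf`, `fit-current`, `bin-taus`, `dose-response`,
`fit-flux`, `struct-pairs`, `struct-rmsd`, `run`); `glicgate run
--seed 1` executes the whole pipeline and writes a JSON report.

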