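# sensortrace

Quantification of genetically encoded biosensor recordings from live
neurons: calcium transient kinetics (RCaMP-class intensity sensors),
cytosolic ATP concentrations and turnover rates (ATeam-class FRET sensors),
compartment redox potentials (roGFP dual-excitation sensors), relative
mitochondrial membrane potential (TMRM ROI pairs), network-burst synchrony
of spontaneous activity, and NMR chemical-shift-perturbation titration
fitting. It is written for imaging labs that start from per-ROI fluorescence
time series (segmentation already done) and want calibrated physiological
numbers rather than arbitrary-unit traces.

## Models

**Hill intensity sensor.** A calcium indicator with dissociation constant
K_d and Hill coefficient n binds a fraction
f([Ca²⁺]) = [Ca²⁺]ⁿ / (K_dⁿ + [Ca²⁺]ⁿ) of its sites; RCaMP1e presets are
K_d = 1.6 μM, n = 3.4. Transients are reported as ΔF/F₀ with peak, time to
peak, and a mono-exponential decay constant τ.

**FRET ATP sensor.** The emission ratio follows
R = R_min + (R_max − R_min)·[ATP]² / (K_d² + [ATP]²) with K_d = 3.3 mM and
dynamic range R_max/R_min = 2.3 (ATeam1.03). With r = R/R_min the exact
inverse is [ATP] = K_d·√((r − 1)/(R_max/R_min − r)). R_min is calibrated
in-recording from the FCCP depletion plateau; ATP consumption and
production rates come from OLS slopes of the quantified mM trace.

**roGFP redox sensor.** From DTT/H₂O₂ calibration plateaus the fraction of
reduced sensor is R = (F − F_ox)/(F_red − F_ox), and the compartment
potential follows the Nernst equation
E′ = E°′(DTT) − (RT/nF)·ln(K_eq·R/(1 − R)) with K_eq = 0.070, R = 8.315
J K⁻¹ mol⁻¹, T = 303.15 K, n = 2, F = 9.649 × 10⁴ C mol⁻¹. For the
mitochondrial matrix the reference midpoint is shifted by
−60.1 mV·(pH − 7) at pH 7.98.

**Network bursts.** Per-neuron event onsets (robust threshold crossings of
ΔF/F0) are pooled; a burst is a maximal merged cluster of 1-s windows in
which ≥ 20% of active neurons fire. Reported: bursts/min, mean
participation, active fraction.

**NMR titration.** Combined shift perturbation
csp = √(ΔδH² + (ΔδN/5)²); per-residue Δδ-vs-ligand curves are fitted with
the single-site isotherm Δδ(L) = Δδ_max·L/(K_d + L) and per-residue K_d
values are averaged.

## Worked example

All inputs are generated by the seeded synthetic module (the package ships
no experimental data), so the whole analysis chain runs from scratch:

```
python analysis/01_simulate_datasets.py --seed 0
python analysis/02_calcium_excitability.py
python analysis/03_atp_turnover.py
python analysis/04_redox_membrane_potential.py
python analysis/05_network_bursts.py
python analysis/06_nmr_binding.py
```

which prints, among other lines:

```
control: 96% responders (95% CI 90-98%), tau = 2.03 ± 0.14 s
impaired: 63% responders (95% CI 53-72%), tau = 2.03 ± 0.14 s
baseline ATP 2.03 mM (Rmin = 0.498)
FCCP: consumption -0.0397 mM/s, production 0.0297 mM/s
cytosol (pH 7.0): 10.1% oxidized, E' = -316.9 mV
mitochondria (pH 7.98): 10.1% oxidized, E' = -375.8 mV
TMRM: mean mito/cyto ratio 3.97 (SD 0.94) over 30 pairs; 100% respond to FCCP
network_25dpt: 15.7 bursts/min, 81% participation, 100% of 225 neurons active
averaged Kd = 2.01 ± 0.18 mM over 4 residues
```

Reading these numbers: the "impaired" population responds to stimulation a
third less often than control while its calcium clearance kinetics are
unchanged; the FCCP assay recovers the simulated 2 mM resting ATP and the
−0.04 / +0.03 mM/s turnover rates; the redox trace (90% reduced sensor)
maps to ≈ −317 mV in the cytosol and, purely through the pH correction, to
≈ −376 mV in the matrix; and the four-residue titration average lands at
the weak-mM affinity built into the generator. Summary tables are written
under `results/`.

A CLI covers the same pipelines file-to-file
(`sensortrace nernst`, `simulate`, `calcium`, `atp`, `redox`, `tmrm`,
`network`, `csp`); try `sensortrace nernst` to print the sensor midpoint
potential (−0.288 V with the default constants).

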