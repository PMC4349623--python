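# bindspec

Quantitative analysis for protein–ligand binding studies that combine
isothermal titration calorimetry (ITC) with fluorescence spectroscopy —
the kind of multi-technique characterization used for calmodulin (CaM),
CaM/troponin-C chimeras, the hydrophobicity probe ANS, and CaM-binding
peptides such as the Orai1 CaM-binding domain. It is aimed at protein
biophysicists who want a scriptable, testable alternative to vendor fitting
software (Origin/DAS6-style workflows) for:

- **ITC isotherms** — "one set of sites" (N identical independent sites) and
  "sequential two-site" binding models, with perfusion-cell injection
  bookkeeping, dilution-blank correction, weighted least-squares fitting, and
  the thermodynamic linkage ΔG = −RT ln K_a, ΔG = ΔH − TΔS, plus the buffer
  ionization decomposition ΔH_app = ΔH_b + nΔH_i.
- **TCSPC fluorescence lifetimes** — multi-exponential decays
  I(t) = A + Σ αᵢ e^(−t/τᵢ) fitted by reconvolution with a measured
  instrument-response ("prompt") histogram under Poisson weighting; fractional
  intensities fᵢ = αᵢτᵢ/Σαⱼτⱼ, amplitude-average lifetime
  ⟨τ⟩ = Σαᵢτᵢ²/Σαᵢτᵢ, and the reduced-χ² < 1.2 acceptance rule.
- **Stern-Volmer quenching** — F₀/F = 1 + K_sv[Q] (and the lifetime analogue),
  bimolecular quenching constants k_q = K_sv/τ₀, and dynamic-vs-static
  classification from steady-state vs lifetime-resolved K_sv values.
- **Stopped-flow kinetics** — single-exponential dissociation fits for k_off
  with a mono- vs bi-exponential adequacy check.
- **Spectral summaries** — whole-spectrum integral fold enhancements, λ_max
  with parabolic refinement, CD ellipticity ratios θ220/θ209, differential
  spectra and scan averaging.
- **Synthetic data** — seeded generators for every modality (Gaussian heat
  noise + dilution blanks for ITC, Poisson-count histograms with a finite
  Gaussian prompt for TCSPC, etc.), so every fitter is exercisable and
  testable with no instrument data.

## Worked example

Simulate a peptide-into-protein titration (30 µM cell, 1 mM syringe,
25 × 10 µL injections, 1.4 mL cell) from known parameters, blank-correct it
and fit the one-set-of-sites isotherm:

```python
import numpy as np
from bindspec import itc, synth

sched = itc.TitrationSchedule(cell_volume_L=1.4e-3, cell_conc_M=30e-6,
                              syringe_conc_M=1e-3,
                              injection_volumes_L=(10e-6,) * 25)
truth = itc.BindingModel.one_set(2.05, 8.92e5, -5.02)
sample, blank = synth.simulate_itc(sched, truth, noise_sd_ucal=0.2, seed=7)
corrected = itc.dilution_correct(sample, blank)
fit = itc.fit_isotherm(corrected, itc.ONE_SET, sigma_ucal=0.2)
state = itc.thermo_derive(fit.model.k_a, fit.model.dh, sched.temperature_K)
print(f"N  = {fit.model.n_sites:.2f} +/- {fit.stderr['n_sites']:.2f} sites")
print(f"Ka = {fit.model.k_a:.3g} +/- {fit.stderr['k_a']:.2g} M^-1")
print(f"dH = {fit.model.dh:.2f} +/- {fit.stderr['dh']:.2f} kcal/mol")
print(f"dG = {state.dg_kcal:.2f} kcal/mol   dS = {state.ds_cal:.1f} cal/(mol K)")
```

Output:

```
N  = 2.05 +/- 0.00 sites
Ka = 8.69e+05 +/- 2.4e+04 M^-1
dH = -5.02 +/- 0.01 kcal/mol
dG = -8.10 kcal/mol   dS = 10.3 cal/(mol K)
```

The fitted stoichiometry N ≈ 2 identifies a 1:2 protein:peptide complex; the
negative ΔH and positive ΔS say the binding is both enthalpy- and
entropy-driven (the entropic gain reflecting desolvation of hydrophobic
surface). With 0.2 µcal heat noise the association constant comes back within
its asymptotic standard error of the generating value 8.92 × 10⁵ M⁻¹.

The same pattern works from the shell: every modality has a `simulate-*` and
a fitting subcommand under the `bindspec` CLI
(`simulate-itc`, `fit-itc`, `simulate-decay`, `fit-decay`, `simulate-quench`,
`sv-fit`, `simulate-trace`, `fit-koff`, `simulate-spectrum`, `spectra …`,
plus a config-driven `run`). `bindspec run --config pipeline.json --seed 1
--out report.json` executes several stages and writes a deterministic report
with provenance.

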