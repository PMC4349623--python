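# Methods

This note documents the models implemented in `bindspec`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where conventions vary between
laboratories and vendor software.

## ITC

### Injection bookkeeping

A perfusion (overfill) cell of fixed volume V₀ expels liquid as titrant is
injected. After a cumulative injected volume v, the cell concentrations are

    M_t = M₀ (1 − v/2V₀) / (1 + v/2V₀)
    L_t = L_syr (v/V₀) / (1 + v/2V₀)

the standard displaced-volume correction in which, on average, half of each
injection's worth of displaced material has the pre-injection composition.
A soft warning is raised once cumulative injections exceed 20% of V₀, where
the first-order treatment degrades. The cell volume defaults to 1.4 mL
(typical for a VP-ITC-class instrument) and is configurable.

### Binding models

**One set of sites.** N identical, independent sites with association
constant K_a and site enthalpy ΔH. The total heat content of the cell after
reaching equilibrium is the closed-form root of the binding quadratic:

    Q = (N·M_t·ΔH·V₀/2) [X − √(X² − 4L_t/(N·M_t))],
    X = 1 + L_t/(N·M_t) + 1/(N·K_a·M_t)

The discriminant is clamped at zero if it becomes numerically negative
(possible only by rounding at extreme saturation).

**Sequential two-site.** Ordered macroscopic steps K_a1 ≥ K_a2 with step
enthalpies ΔH₁, ΔH₂ and binding polynomial P = 1 + K₁L + K₁K₂L². The free
ligand concentration L solves the mass balance

    L_t = L + M_t (K₁L + 2K₁K₂L²)/P

whose left side is strictly increasing in L, so L is bracketed by [0, L_t].
It is found by Newton iteration safeguarded with bisection to a residual
below 10⁻¹³·L_t. The heat content is Q = M_t·V₀·(F₁ΔH₁ + F₂(ΔH₁+ΔH₂)) with
macrostate fractions F₁ = K₁L/P, F₂ = K₁K₂L²/P.

The two models are linked by an exact statistical-factor identity — two
identical independent sites (N = 2, k) are the same physical system as
sequential steps (2k, k/2) with equal step enthalpies — which the test suite
uses as an independent oracle connecting the two code paths to 10⁻⁹ relative.

**Per-injection heats.** The observable is the finite difference of heat
content with the displaced-heat correction

    ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2,  Q₀ = 0.

Dilution correction subtracts a matched titrant-into-buffer blank
injection-by-injection.

### Fitting

Weighted nonlinear least squares over ΔQᵢ (Levenberg-Marquardt via lmfit)
in transformed coordinates: log₁₀K (positivity), raw ΔH and N. Sequential
fits parameterize K_a2 = r·K_a1 with r ∈ (0, 1], which both enforces
positivity and breaks the label-switching symmetry. Without a user guess the
fit multi-starts over a log-spaced K grid (10²–10⁸) crossed with a few
stoichiometry starts, seeding ΔH from the first-injection heat per mole of
titrant; the lowest-χ² converged fit wins. Asymptotic standard errors are
propagated from the transformed coordinates (σ_K = ln10·K·σ_logK). A
flat-isotherm warning fires when the heat span is within 10× the per-point
noise — the low-c or very-high-c regimes in which the isotherm carries
little shape information. The first injection can optionally be excluded
(a common practice for syringe-diffusion artifacts); the default includes it
since simulated data have no such artifact.

For weak dye binding (apparent K ≈ 10³ M⁻¹, c ≈ 0.5, titration far from
saturation) the model is still identified from noiseless data, but K, N and
ΔH become strongly correlated: at 0.2 µcal heat noise the relative error in
K is several percent even though the heats are measured to better than 1%.

**Thermodynamic linkage.** ΔG = −RT ln K_a with R = 1.9872 cal/(mol K);
ΔS = (ΔH − ΔG)/T reported in cal/(mol K). For K_a = 8.92 × 10⁵ M⁻¹ and
ΔH = −5.02 kcal/mol at 298.15 K this gives ΔS ≈ +10 cal/(mol K).

**Buffer ionization.** ΔH_app measured in buffers of different ionization
enthalpy ΔH_i follows ΔH_app = ΔH_b + nΔH_i; ordinary least squares gives
the proton count n (positive = protonation, i.e. protons taken up from the
buffer) and the intrinsic ΔH_b. At least two buffers with distinct ΔH_i are
required; equal ΔH_app across buffers means n = 0.

## TCSPC lifetimes

The decay law is I(t) = A + Σ αᵢ e^(−t/τᵢ) with 1–4 components. A measured
histogram is modeled as the unit-normalized prompt (IRF) convolved with the
baseline-free decay, discretized on the channel grid (channel times are left
edges, so a delta prompt in channel 0 reproduces the direct decay exactly),
plus the baseline.

Fitting minimizes Poisson-weighted residuals with weights 1/max(counts, 1)
and reports the reduced χ² with dof = fitted channels − parameters; fits
with χ²_red < 1.2 are accepted. Because the weights use observed counts
(Neyman weighting), channels with downward count fluctuations are slightly
over-weighted; at 10⁴ peak counts over 4000 channels this depresses the mean
χ²_red below 1 and biases recovered long lifetimes downward by a few percent
— visible in the replicate studies and well inside the 10% recovery
tolerance. Rescaling all counts by a constant rescales these weights
uniformly (away from the 1-count floor), leaving the fitted lifetimes
unchanged.

Numerically the fit uses variable projection: lifetimes (in log space, so
the search is scale-free) and an optional IRF shift (bounded to ±10
channels, applied to the prompt by linear interpolation) are optimized by
trust-region least squares, while amplitudes and baseline are re-solved at
every step by non-negative linear least squares. This removes the linear
parameters from the nonlinear search, making the fit insensitive to
amplitude starting values; lifetime multi-starts are geometric grids between
twice the channel width and a third of the window. Components are reported
sorted by ascending lifetime. Two lifetimes within 1% are flagged
`degenerate`; lifetimes below twice the channel width are flagged
`at_detection_limit` (the free-dye ~0.3 ns component sits near this limit on
coarser grids and is inherently imprecise under a 1 ns prompt). Tail mode
fits A + Σ αᵢ e^(−(t−t₀)/τᵢ) from just after the peak channel with no IRF.

Component-count selection fits n = 1…max_n and takes the smallest n that is
acceptable (χ²_red < 1.2) and is not improved by more than 5% by n+1 — a
documented heuristic, not an information criterion.

Derived quantities: fᵢ = αᵢτᵢ/Σαⱼτⱼ (fractional intensities, Σfᵢ = 1),
Bᵢ = αᵢ/Σαⱼ (normalized pre-exponentials), and
⟨τ⟩ = Σαᵢτᵢ²/Σαᵢτᵢ = Σfᵢτᵢ, which is always bounded by the extreme
component lifetimes. ⟨τ⟩ is computed strictly from this definition;
published summary tables that renormalize fractions (e.g. to exclude a
free-dye component) will not recompute exactly from rounded entries.

## Stern-Volmer quenching

F₀/F = 1 + K_sv[Q] for steady-state intensities, τ₀/τ = 1 + K_sv[Q] for
purely collisional quenching of lifetimes. F₀ is taken as the [Q] = 0
measurement, not a fitted parameter, matching the law's construction; the
default fit fixes the intercept at 1 (a free-intercept fit is available as a
linearity diagnostic, and upward curvature in the residuals raises a
`nonlinear` flag rather than switching to sphere-of-action or static+dynamic
models, which are out of scope). k_q = K_sv/τ₀ with the ns→s conversion, so
K_sv = 1.4 M⁻¹ at τ₀ = 6.4 ns gives k_q ≈ 2.2 × 10⁸ M⁻¹s⁻¹.

Per-component lifetime series are fitted independently; a component present
at fewer than three quencher levels yields a partial (None) result.
Mechanism classification compares the steady-state K_sv with the range of
lifetime K_sv values widened by combined standard errors: inside → dynamic
(collisional); above → a static component (ground-state complex formation
reduces intensity without shortening lifetimes); below → indeterminate.

## Stopped-flow kinetics

Displacement traces follow F(t) = offset + amplitude·e^(−k_off·t).
Points inside the instrument dead time (default 2 ms, configurable) are
excluded; rate, amplitude and offset are fitted by Levenberg-Marquardt with
the rate seeded from the 1/e crossing. A trace whose fitted amplitude is
within 3 residual SDs of zero is flagged `no_decay`. The fit is exactly
invariant to affine rescaling of the fluorescence. A warning fires when the
observation window is shorter than 3/k_off — note the canonical 2 s window
at k_off ≈ 1.4 s⁻¹ sits just below this threshold, which is why slower
dissociators are recorded over 5 s.

The mono- vs bi-exponential check fits both models and prefers two
exponentials only when the χ² improves by more than 10% and the two rates
are distinguishable (ratio > 1.01); Wald-Wolfowitz runs-test z-scores of the
residual signs are reported as structure diagnostics. Association kinetics
(k_on) are not modeled — under the displacement design they are unresolvably
fast — and no reversible-binding scheme is fitted: the excess-trap
pseudo-first-order assumption is taken as part of the experimental design.

## Spectra

Trapezoidal integration over the recorded grid (or an explicit sub-range —
integration bounds are configurable because "the whole spectrum" depends on
the recorded window). Fold enhancement is the ratio of integrals against a
reference spectrum on an identical grid; λ_max is the argmax refined by
parabolic interpolation through the three surrounding points (optional
boxcar smoothing first — a band tens of nm wide needs a comparably wide
boxcar for ~1 nm localization at a few percent noise), with plateau ties
broken toward shorter wavelength. The CD shape index θ220/θ209 interpolates
linearly to the exact wavelengths and is flagged undefined when θ209 ≈ 0.
Differential spectra are pointwise subtractions whose interpretation (the
spectrum of the remaining component) assumes the subtracted component is
structurally unchanged in the complex; the assumption is recorded in the
result metadata. Operand grids must match exactly — there is no silent
resampling; an explicit `resample` utility exists. CD is handled in raw
ellipticity units; mean-residue-ellipticity conversion is a separate utility
requiring residue count, concentration and path length. Secondary-structure
deconvolution is deliberately not implemented.

## Synthetic data

All generators draw from one explicitly seeded `numpy.random.Generator`
passed down from the caller — no global state — so identical inputs and seed
give byte-identical outputs, and at zero noise each generator is the exact
inverse of its fitter.

Default study conditions: ITC titrations of 30 µM protein vs 1 mM peptide or
5–50 µM protein vs 2–5 mM dye in a 1.4 mL cell with 5–10 µL injections;
additive Gaussian heat noise of 0.2 µcal per injection and a constant
−0.5 µcal dilution blank (plausible VP-ITC magnitudes; real blanks drift).
TCSPC histograms use a 200 ns window in 4000 channels accumulated to 10⁴
peak counts with Poisson noise and a Gaussian prompt of 1.0 ns FWHM centred
10% into the window (plausible for a NanoLED source; prompts of real
instruments have tails and afterpulses). Dye simulations include a ~0.3 ns
free-dye component as a third decay component. Stopped-flow traces are
sampled at 2 or 5 ms; quench series use a 0–0.3 M grid in 7 steps
(practical for acrylamide/KI titrations from 6 M / 1 M stocks); emission
spectra are Gaussian bands, and CD spectra are mixtures of synthetic helix
and coil basis shapes constructed so the all-helix basis has
θ220/θ209 = 1.09 exactly and any target ratio can be dialed in by an exact
linear solve at the two reference wavelengths.

What passing round trips do **not** show: the generators contain no baseline
drift, inner-filter or scatter effects, photobleaching, detector afterpulses
or IRF color shift, injection-to-injection heat artifacts, or model error —
so recovery of generating parameters demonstrates the correctness and
calibration of the estimators under the assumed noise models, not robustness
to the systematic errors of real instruments.

## Problem sizes

The replicate studies in the tests and the acceptance script use 50 Poisson
TCSPC replicates at full instrument size (4000 channels), 200-replicate
confidence-interval coverage and noise studies for the fast fitters, and
titrations of 25–27 injections — sizes chosen so each study runs in seconds
to a couple of minutes on a single CPU while leaving the stochastic
assertions comfortably stable.
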