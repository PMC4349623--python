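"""Synthetic-data generators for every measurement modality.

Each simulator draws from an explicitly seeded :class:`numpy.random.Generator`
(no global state) and, at zero noise, is the exact inverse of the matching
fitter — the generated data equal the model evaluated by the analysis modules.

Default instrument conditions emulate the study design:

* ITC: VP-ITC-style titrations (1.4 mL cell; 5-50 uM protein vs 2-5 mM dye,
  or 30 uM protein vs 1 mM peptide; 5-10 uL injections) with additive Gaussian
  heat noise (default 0.2 ucal) and a constant titrant-dilution blank
  (default -0.5 ucal per injection).
* TCSPC: a 200 ns window in 4000 channels accumulated to 10,000 peak counts,
  Poisson counting noise, and a Gaussian prompt of 1.0 ns FWHM centred 10%
  into the window.  ANS simulations carry a ~0.3 ns free-dye component as a
  third decay component.
* Stopped-flow: single-exponential traces sampled at 2 or 5 ms.
* Spectra: sums of Gaussian bands (emission) or helix/coil basis mixtures
  (CD) with multiplicative Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from . import itc as itc_mod
from .itc import BindingModel, Thermogram, TitrationSchedule
from .kinetics import StoppedFlowTrace
from .lifetimes import IRF, DecayHistogram, MultiExpModel, model_decay
from .quenching import QuenchSeries
from .spectra import CD, EMISSION, Spectrum


@dataclass(frozen=True)
class SimulationConfig:
    """Instrument descriptors and per-modality noise levels.

    A fixed ``seed`` makes every simulator byte-identical between runs.
    """

    seed: int = 0
    heat_noise_ucal: float = 0.2
    dilution_heat_ucal: float = -0.5
    trace_noise_frac: float = 0.02
    spectral_noise_frac: float = 0.02
    channels: int = 4000
    window_ns: float = 200.0
    peak_counts: int = 10000
    irf_fwhm_ns: float = 1.0
    irf_center_frac: float = 0.10
    sampling_interval_s: float = 0.002

    def __post_init__(self):
        for name in ("heat_noise_ucal", "trace_noise_frac", "spectral_noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.channels < 2 or self.peak_counts < 1:
            raise ValueError("channels >= 2 and peak_counts >= 1 required")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def simulate_itc(schedule: TitrationSchedule, model: BindingModel,
                 noise_sd_ucal: float = 0.2, seed=0,
                 dilution_heat_ucal: float = -0.5) -> tuple[Thermogram, Thermogram]:
    """Simulate a titration plus its matched titrant-dilution blank.

    Per-injection heats are the model heats from the ITC module plus
    independent Gaussian noise; the blank (same schedule, no protein in the
    cell) contains a constant dilution heat per injection plus noise, ready
    for :func:`bindspec.itc.dilution_correct`.
    """
    if noise_sd_ucal < 0:
        raise ValueError("noise level must be >= 0")
    rng = _as_rng(seed)
    tg = itc_mod.model_thermogram(schedule, model)
    n = schedule.n_injections
    heats = tg.heats_ucal + dilution_heat_ucal \
        + (rng.normal(0.0, noise_sd_ucal, n) if noise_sd_ucal > 0 else 0.0)
    blank_heats = np.full(n, dilution_heat_ucal) \
        + (rng.normal(0.0, noise_sd_ucal, n) if noise_sd_ucal > 0 else 0.0)
    sample = Thermogram(heats_ucal=heats, molar_ratios=tg.molar_ratios,
                        schedule=schedule,
                        meta={"source": "simulated", "noise_sd_ucal": noise_sd_ucal})
    blank = Thermogram(heats_ucal=blank_heats, molar_ratios=tg.molar_ratios,
                       schedule=schedule,
                       meta={"source": "simulated_blank",
                             "dilution_heat_ucal": dilution_heat_ucal})
    return sample, blank


# ---------------------------------------------------------------------------
# TCSPC
# ---------------------------------------------------------------------------

def gaussian_irf_counts(channels: int, window_ns: float, fwhm_ns: float,
                        center_frac: float = 0.10, peak_counts: int = 10000
                        ) -> np.ndarray:
    """Gaussian prompt histogram; ``fwhm -> 0`` degenerates to a delta in one channel."""
    dt = window_ns / channels
    t = np.arange(channels) * dt
    center = center_frac * window_ns
    if fwhm_ns <= dt / 10.0:
        counts = np.zeros(channels)
        counts[int(round(center / dt))] = peak_counts
        return counts
    sigma = fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return np.round(g / g.max() * peak_counts)


def simulate_decay(model: MultiExpModel, irf_fwhm_ns: float = 1.0,
                   window_ns: float = 200.0, channels: int = 4000,
                   peak_counts: int = 10000, seed=0,
                   irf_center_frac: float = 0.10,
                   expectation_only: bool = False) -> tuple[DecayHistogram, IRF]:
    """Simulate a TCSPC histogram and its prompt.

    The expected counts are the IRF-convolved model scaled so the maximum
    expected channel equals ``peak_counts``; observed counts are independent
    Poisson draws (or the rounded expectation if ``expectation_only``).
    """
    if channels < 2 or peak_counts < 1:
        raise ValueError("channels >= 2 and peak_counts >= 1 required")
    if window_ns < max(model.lifetimes_ns):
        warnings.warn("window shorter than the longest lifetime; expect truncation bias",
                      stacklevel=2)
    rng = _as_rng(seed)
    irf_counts = gaussian_irf_counts(channels, window_ns, irf_fwhm_ns,
                                     irf_center_frac, peak_counts)
    irf = IRF(counts=irf_counts, window_ns=window_ns,
              meta={"fwhm_ns": irf_fwhm_ns, "center_frac": irf_center_frac})

    dt = window_ns / channels
    t = np.arange(channels) * dt
    decay = model_decay(MultiExpModel(model.amplitudes, model.lifetimes_ns), t)
    expected = fftconvolve(irf.normalized(), decay)[:channels]
    expected = np.clip(expected, 0.0, None)
    expected *= peak_counts / expected.max()
    expected += model.baseline
    if expectation_only:
        counts = np.round(expected)
    else:
        counts = rng.poisson(expected)
    hist = DecayHistogram(counts=counts, window_ns=window_ns,
                          meta={"peak_counts_target": peak_counts,
                                "expectation_only": expectation_only})
    return hist, irf


def decay_expectation(model: MultiExpModel, irf_fwhm_ns: float = 1.0,
                      window_ns: float = 200.0, channels: int = 4000,
                      peak_counts: int = 10000,
                      irf_center_frac: float = 0.10) -> np.ndarray:
    """Expectation curve of :func:`simulate_decay` (no rounding, no noise)."""
    irf_counts = gaussian_irf_counts(channels, window_ns, irf_fwhm_ns,
                                     irf_center_frac, peak_counts)
    irf = IRF(counts=irf_counts, window_ns=window_ns)
    dt = window_ns / channels
    t = np.arange(channels) * dt
    decay = model_decay(MultiExpModel(model.amplitudes, model.lifetimes_ns), t)
    expected = np.clip(fftconvolve(irf.normalized(), decay)[:channels], 0.0, None)
    expected *= peak_counts / expected.max()
    return expected + model.baseline


def ans_cam_model(tau1_ns: float = 6.4, f1: float = 0.44,
                  tau2_ns: float = 13.1, f2: float = 0.53,
                  tau_free_ns: float = 0.3) -> MultiExpModel:
    """Three-component ANS model from fractional intensities.

    Converts the two bound-dye fractional intensities (the remainder is
    assigned to the short free-dye component) to pre-exponential amplitudes
    via ``alpha_i ~ f_i / tau_i``, normalised to sum to 1.
    """
    f3 = 1.0 - f1 - f2
    if f3 < 0:
        raise ValueError("fractional intensities exceed 1")
    alphas = np.array([f1 / tau1_ns, f2 / tau2_ns, f3 / tau_free_ns])
    alphas /= alphas.sum()
    return MultiExpModel(amplitudes=tuple(alphas),
                         lifetimes_ns=(tau1_ns, tau2_ns, tau_free_ns))


# ---------------------------------------------------------------------------
# Quenching
# ---------------------------------------------------------------------------

def simulate_quench_series(baseline: float, ksv_Minv: float, q_grid_M,
                           noise_frac: float = 0.0, seed=0,
                           kind: str = "intensity") -> QuenchSeries:
    """Quench series obeying ``F = F0 / (1 + Ksv [Q])`` (or the tau analogue)."""
    q = np.asarray(q_grid_M, dtype=float)
    if np.any(q < 0):
        raise ValueError("quencher concentrations must be nonnegative")
    if np.any(np.diff(q) < 0):
        raise ValueError("quencher grid must be sorted ascending")
    if baseline <= 0:
        raise ValueError("baseline response must be positive")
    rng = _as_rng(seed)
    resp = baseline / (1.0 + ksv_Minv * q)
    if noise_frac > 0:
        resp = resp * (1.0 + rng.normal(0.0, noise_frac, len(q)))
    return QuenchSeries(quencher_M=q, responses=resp, kind=kind,
                        reference=baseline)


DEFAULT_Q_GRID_M = tuple(np.linspace(0.0, 0.3, 7))
"""Default quencher grid: 0-0.3 M in 7 steps."""


# ---------------------------------------------------------------------------
# Stopped flow
# ---------------------------------------------------------------------------

def simulate_stopped_flow(k_off_s: float, amplitude: float, offset: float,
                          duration_s: float = 2.0, dt_s: float = 0.002,
                          noise_frac: float = 0.0, seed=0) -> StoppedFlowTrace:
    """``F(t) = offset + amplitude exp(-k_off t)`` plus additive Gaussian noise.

    Noise SD is ``noise_frac * |amplitude|`` (or ``noise_frac * |offset|``
    for a flat trace).
    """
    if k_off_s <= 0:
        raise ValueError("k_off must be positive")
    if duration_s < 3.0 / k_off_s:
        warnings.warn("duration shorter than 3/k_off; rate poorly identifiable",
                      stacklevel=2)
    rng = _as_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2.0, dt_s)
    f = offset + amplitude * np.exp(-k_off_s * t)
    if noise_frac > 0:
        scale = abs(amplitude) if amplitude != 0 else abs(offset)
        f = f + rng.normal(0.0, noise_frac * scale, len(t))
    return StoppedFlowTrace(time_s=t, fluorescence=f,
                            meta={"k_off_true_s": k_off_s, "dt_s": dt_s})


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def simulate_spectrum(bands, grid_nm, noise_frac: float = 0.0, seed=0) -> Spectrum:
    """Sum of Gaussian emission bands ``(center_nm, width_nm, amplitude)``."""
    grid = np.asarray(grid_nm, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    rng = _as_rng(seed)
    signal = np.zeros_like(grid)
    if not bands:
        warnings.warn("empty band list: returning a zero spectrum", stacklevel=2)
    for center, width, amp in bands:
        signal += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    if noise_frac > 0 and signal.max() > 0:
        signal = signal + rng.normal(0.0, noise_frac * signal.max(), len(grid))
    return Spectrum(wavelength_nm=grid, signal=signal, kind=EMISSION)


def _gauss(x, center, width):
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def cd_helix_basis(grid_nm) -> Spectrum:
    """Synthetic all-helix CD basis with theta(220)/theta(209) = 1.09 exactly.

    Built from a positive band near 193 nm and negative bands at 208 and
    222 nm; the 222 nm amplitude is solved at call time so the 220/209 ratio
    equals the all-helix reference value 1.09.
    """
    grid = np.asarray(grid_nm, dtype=float)
    target = 1.09
    pos_c, pos_w = 193.0, 5.5
    n1_c, n1_w = 208.0, 6.5
    n2_c, n2_w = 222.0, 9.5
    pos_amp, n1_amp = 1.8, 1.0

    def val(wl, b):
        return (pos_amp * _gauss(wl, pos_c, pos_w)
                - n1_amp * _gauss(wl, n1_c, n1_w)
                - b * _gauss(wl, n2_c, n2_w))

    # solve val(220)/val(209) = target for the 222-nm band amplitude b
    a220 = pos_amp * _gauss(220.0, pos_c, pos_w) - n1_amp * _gauss(220.0, n1_c, n1_w)
    a209 = pos_amp * _gauss(209.0, pos_c, pos_w) - n1_amp * _gauss(209.0, n1_c, n1_w)
    g220, g209 = _gauss(220.0, n2_c, n2_w), _gauss(209.0, n2_c, n2_w)
    b = (a220 - target * a209) / (g220 - target * g209)
    return Spectrum(wavelength_nm=grid, signal=val(grid, b), kind=CD,
                    meta={"basis": "helix", "synthetic": True})


def cd_coil_basis(grid_nm) -> Spectrum:
    """Synthetic random-coil CD basis: deep minimum near 198 nm, weak >210 nm."""
    grid = np.asarray(grid_nm, dtype=float)
    signal = -1.2 * _gauss(grid, 198.0, 7.0) + 0.08 * _gauss(grid, 222.0, 12.0)
    return Spectrum(wavelength_nm=grid, signal=signal, kind=CD,
                    meta={"basis": "coil", "synthetic": True})


def simulate_cd_spectrum(target_ratio: float, grid_nm, scale: float = 1.0,
                         noise_frac: float = 0.0, seed=0) -> Spectrum:
    """Helix/coil mixture whose theta(220)/theta(209) equals ``target_ratio``.

    The mixing fraction is the exact linear solution at the two reference
    wavelengths, so the noiseless ratio is dialed in exactly.
    """
    grid = np.asarray(grid_nm, dtype=float)
    helix = cd_helix_basis(grid)
    coil = cd_coil_basis(grid)
    wl = grid

    def at(sp, w):
        return float(np.interp(w, wl, sp.signal))

    h220, h209 = at(helix, 220.0), at(helix, 209.0)
    c220, c209 = at(coil, 220.0), at(coil, 209.0)
    denom = (h220 - c220) - target_ratio * (h209 - c209)
    if denom == 0:
        raise ValueError("target ratio unreachable with these bases")
    x = (target_ratio * c209 - c220) / denom
    rng = _as_rng(seed)
    signal = scale * (x * helix.signal + (1.0 - x) * coil.signal)
    if noise_frac > 0:
        signal = signal + rng.normal(0.0, noise_frac * np.abs(signal).max(), len(grid))
    return Spectrum(wavelength_nm=grid, signal=signal, kind=CD,
                    meta={"helix_fraction": x, "target_ratio": target_ratio,
                          "synthetic": True})
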