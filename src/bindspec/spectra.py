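"""Steady-state emission and circular-dichroism spectral summaries.

Operations: trapezoidal whole-spectrum integration, fold enhancement of one
spectrum over a reference (with peak-position shift), parabolic-refined
``lambda_max`` detection, the helix-sensitive CD ellipticity ratio
theta220/theta209, differential spectra and scan averaging.

Spectra are wavelength-indexed arrays; operand grids must match exactly for
arithmetic (use :func:`resample` for explicit regridding — there is no silent
interpolation).  CD spectra are handled in raw ellipticity units (mdeg or
degrees); mean-residue-ellipticity conversion is a separate utility needing
the residue count, concentration and path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

EMISSION = "emission"
CD = "cd"


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-indexed signal (emission intensity or ellipticity)."""

    wavelength_nm: np.ndarray
    signal: np.ndarray
    kind: str = EMISSION
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "signal", s)
        if wl.shape != s.shape or wl.ndim != 1:
            raise ValueError("wavelength and signal must be equal-length 1-D")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind not in (EMISSION, CD):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")


@dataclass(frozen=True)
class EnhancementResult:
    """Integral fold enhancement over a reference with peak shift."""

    fold: float
    lambda_max_nm: float
    reference_lambda_max_nm: float

    @property
    def shift_nm(self) -> float:
        return self.lambda_max_nm - self.reference_lambda_max_nm


def _check_same_grid(a: Spectrum, b: Spectrum):
    if a.wavelength_nm.shape != b.wavelength_nm.shape or \
            not np.array_equal(a.wavelength_nm, b.wavelength_nm):
        raise ValueError("spectra are on different wavelength grids; resample first")


def integrate_spectrum(spec: Spectrum, wl_range: tuple | None = None) -> float:
    """Trapezoidal integral of the signal over the grid or a sub-range."""
    wl, s = spec.wavelength_nm, spec.signal
    if wl_range is not None:
        lo, hi = wl_range
        mask = (wl >= lo) & (wl <= hi)
        wl, s = wl[mask], s[mask]
    if len(wl) < 2:
        raise ValueError("integration range contains fewer than 2 points")
    return float(np.trapezoid(s, wl))


def fold_enhancement(spec: Spectrum, reference: Spectrum,
                     wl_range: tuple | None = None) -> EnhancementResult:
    """Whole-spectrum integral of ``spec`` relative to ``reference``."""
    _check_same_grid(spec, reference)
    ref_area = integrate_spectrum(reference, wl_range)
    if ref_area == 0:
        raise ValueError("reference spectrum integrates to zero")
    area = integrate_spectrum(spec, wl_range)
    return EnhancementResult(fold=area / ref_area,
                             lambda_max_nm=lambda_max(spec),
                             reference_lambda_max_nm=lambda_max(reference))


def lambda_max(spec: Spectrum, smooth_points: int = 0) -> float:
    """Wavelength of maximum signal, refined by parabolic interpolation.

    Optional boxcar smoothing (odd ``smooth_points``) is applied first.
    Exact plateau ties break toward the shorter wavelength.  At the grid
    edges the raw grid point is returned.
    """
    wl, s = spec.wavelength_nm, spec.signal
    if len(wl) < 5:
        raise ValueError("need at least 5 points")
    if smooth_points:
        if smooth_points % 2 == 0:
            raise ValueError("smooth_points must be odd")
        kernel = np.ones(smooth_points) / smooth_points
        s = np.convolve(s, kernel, mode="same")
    i = int(np.argmax(s))  # argmax takes the first (shortest-wavelength) tie
    if i == 0 or i == len(s) - 1:
        return float(wl[i])
    y0, y1, y2 = s[i - 1], s[i], s[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(wl[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(wl[i] + delta * (wl[i + 1] - wl[i]))


def ellipticity_ratio(spec_cd: Spectrum, wl_num: float = 220.0,
                      wl_den: float = 209.0) -> float:
    """Helix-content shape index theta(220)/theta(209).

    Signals are linearly interpolated to the exact wavelengths.  A
    denominator near zero (relative to the spectrum's scale) is undefined
    and raises.
    """
    wl, s = spec_cd.wavelength_nm, spec_cd.signal
    if not (wl[0] <= wl_den and wl_num <= wl[-1]):
        raise ValueError("CD spectrum must cover both ratio wavelengths")
    num = float(np.interp(wl_num, wl, s))
    den = float(np.interp(wl_den, wl, s))
    if abs(den) < 1e-9 * max(np.max(np.abs(s)), 1e-300):
        raise ValueError("theta(209) is ~0; ellipticity ratio undefined")
    return num / den


def differential_spectrum(complex_spec: Spectrum, component_spec: Spectrum) -> Spectrum:
    """Pointwise ``complex - component``.

    Interpreting the difference as the spectrum of the remaining component
    assumes the subtracted component is structurally unchanged in the
    complex; that assumption is recorded in the metadata.
    """
    _check_same_grid(complex_spec, component_spec)
    meta = dict(complex_spec.meta)
    meta["differential"] = "assumes no structural change in subtracted component"
    return replace(complex_spec, signal=complex_spec.signal - component_spec.signal,
                   meta=meta)


def average_scans(spectra: list) -> tuple[Spectrum, np.ndarray]:
    """Pointwise mean of repeated scans; returns (mean spectrum, per-point SD)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for sp in spectra[1:]:
        _check_same_grid(first, sp)
    stack = np.vstack([sp.signal for sp in spectra])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros_like(mean)
    meta = dict(first.meta)
    meta["n_scans"] = len(spectra)
    return replace(first, signal=mean, meta=meta), sd


def resample(spec: Spectrum, new_grid_nm) -> Spectrum:
    """Explicit linear resampling onto a new (strictly increasing) grid."""
    grid = np.asarray(new_grid_nm, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("new grid must be strictly increasing")
    if grid[0] < spec.wavelength_nm[0] or grid[-1] > spec.wavelength_nm[-1]:
        warnings.warn("resampling extrapolates beyond the recorded range", stacklevel=2)
    sig = np.interp(grid, spec.wavelength_nm, spec.signal)
    return Spectrum(wavelength_nm=grid, signal=sig, kind=spec.kind,
                    meta=dict(spec.meta, resampled=True))


def mean_residue_ellipticity(spec_cd: Spectrum, n_residues: int,
                             conc_M: float, path_cm: float) -> Spectrum:
    """Convert raw ellipticity (mdeg) to mean residue ellipticity.

    ``MRE = theta_mdeg / (10 * path_cm * conc_M * n_residues)`` in
    deg cm^2 dmol^-1.
    """
    if n_residues <= 0 or conc_M <= 0 or path_cm <= 0:
        raise ValueError("residue count, concentration and path must be positive")
    factor = 10.0 * path_cm * conc_M * n_residues
    return replace(spec_cd, signal=spec_cd.signal / factor,
                   meta=dict(spec_cd.meta, units="deg cm^2/dmol"))
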