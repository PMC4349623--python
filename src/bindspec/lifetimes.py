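"""Multi-exponential TCSPC decay models, IRF reconvolution fitting and summaries.

The decay law is ``I(t) = A + sum_i alpha_i exp(-t / tau_i)`` with up to four
components.  Measured histograms are the decay law convolved with the measured
instrument response (the "prompt") and corrupted by Poisson counting noise, so
fits minimise Poisson-weighted residuals (weights ``1 / max(counts, 1)``) and
report the reduced chi-square; fits with reduced chi-square below 1.2 are
accepted.

Derived quantities follow the standard definitions: fractional intensities
``f_i = alpha_i tau_i / sum_j alpha_j tau_j``, normalised pre-exponentials
``B_i = alpha_i / sum_j alpha_j`` and the amplitude-average lifetime
``<tau> = sum alpha_i tau_i^2 / sum alpha_i tau_i`` (equal to ``sum f_i tau_i``).

Fitting uses variable projection: the lifetimes (and optional IRF time shift)
are optimised nonlinearly in log space while the amplitudes and baseline are
re-solved at every step by non-negative linear least squares, which makes the
fit robust to poor amplitude starting values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.signal import fftconvolve

CHI2_ACCEPT = 1.2


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per channel over a fixed time window."""

    counts: np.ndarray
    window_ns: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.counts)
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        if len(c) < 2:
            raise ValueError("need at least 2 channels")
        object.__setattr__(self, "counts", c)

    @property
    def n_channels(self) -> int:
        return len(self.counts)

    @property
    def channel_width_ns(self) -> float:
        return self.window_ns / self.n_channels

    @property
    def times_ns(self) -> np.ndarray:
        """Channel times (left edges), starting at 0."""
        return np.arange(self.n_channels) * self.channel_width_ns

    @property
    def peak_count(self) -> int:
        return int(self.counts.max())


class IRF(DecayHistogram):
    """Measured prompt histogram; same shape contract as :class:`DecayHistogram`."""

    def normalized(self) -> np.ndarray:
        total = float(self.counts.sum())
        if total <= 0:
            raise ValueError("IRF has no counts")
        return self.counts / total


@dataclass(frozen=True)
class MultiExpModel:
    """Baseline plus up to four exponential decay components.

    ``amplitudes`` are the pre-exponential factors alpha_i (counts or
    arbitrary units, >= 0), ``lifetimes_ns`` the tau_i (> 0).  ``shift_ns``
    is an optional IRF time shift used during reconvolution.
    """

    amplitudes: tuple
    lifetimes_ns: tuple
    baseline: float = 0.0
    shift_ns: float = 0.0

    def __post_init__(self):
        a = tuple(float(x) for x in self.amplitudes)
        t = tuple(float(x) for x in self.lifetimes_ns)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "lifetimes_ns", t)
        if len(a) != len(t):
            raise ValueError("amplitudes and lifetimes must pair up")
        if not 1 <= len(t) <= 4:
            raise ValueError("1 to 4 components supported")
        if any(tau <= 0 for tau in t):
            raise ValueError("lifetimes must be positive")
        if any(alpha < 0 for alpha in a):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def n_components(self) -> int:
        return len(self.lifetimes_ns)

    def sorted(self) -> "MultiExpModel":
        order = np.argsort(self.lifetimes_ns)
        return MultiExpModel(
            amplitudes=tuple(self.amplitudes[i] for i in order),
            lifetimes_ns=tuple(self.lifetimes_ns[i] for i in order),
            baseline=self.baseline, shift_ns=self.shift_ns)


@dataclass(frozen=True)
class FitQuality:
    """Reduced chi-square and weighted residuals of a decay fit."""

    redchi: float
    weighted_residuals: np.ndarray
    n_points: int
    n_params: int
    flags: tuple = ()

    @property
    def accepted(self) -> bool:
        return accept_fit(self)


def model_decay(model: MultiExpModel, times_ns) -> np.ndarray:
    """Evaluate ``A + sum alpha_i exp(-t/tau_i)`` at the given times (ns)."""
    t = np.asarray(times_ns, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    out = np.full(t.shape, float(model.baseline))
    for a, tau in zip(model.amplitudes, model.lifetimes_ns):
        out += a * np.exp(-t / tau)
    return out


def _shifted_irf(irf_norm: np.ndarray, shift_channels: float) -> np.ndarray:
    if shift_channels == 0.0:
        return irf_norm
    n = len(irf_norm)
    idx = np.arange(n) - shift_channels
    return np.interp(idx, np.arange(n), irf_norm, left=0.0, right=0.0)


def convolve_irf(model: MultiExpModel, irf: IRF, shift_ns: float | None = None) -> np.ndarray:
    """Expected counts per channel: baseline-free model convolved with the prompt.

    The IRF is unit-normalised (and optionally shifted by linear interpolation)
    before the discrete causal convolution; the baseline is added afterwards.
    A delta IRF (all counts in channel 0) reproduces :func:`model_decay` exactly.
    """
    dt = irf.channel_width_ns
    shift = model.shift_ns if shift_ns is None else shift_ns
    kernel = _shifted_irf(irf.normalized(), shift / dt)
    decay = model_decay(
        MultiExpModel(model.amplitudes, model.lifetimes_ns, baseline=0.0),
        irf.times_ns)
    n = irf.n_channels
    conv = fftconvolve(kernel, decay)[:n]
    return np.clip(conv, 0.0, None) + model.baseline


def fractional_intensities(model: MultiExpModel) -> tuple:
    """Fractional intensities f_i and normalised pre-exponentials B_i."""
    a = np.asarray(model.amplitudes)
    tau = np.asarray(model.lifetimes_ns)
    if a.sum() == 0:
        raise ValueError("all amplitudes are zero")
    at = a * tau
    return tuple(at / at.sum()), tuple(a / a.sum())


def amplitude_average_lifetime(model: MultiExpModel) -> float:
    """``<tau> = sum alpha_i tau_i^2 / sum alpha_i tau_i`` (ns)."""
    a = np.asarray(model.amplitudes)
    tau = np.asarray(model.lifetimes_ns)
    denom = (a * tau).sum()
    if denom == 0:
        raise ValueError("all amplitudes are zero")
    return float((a * tau * tau).sum() / denom)


def accept_fit(quality: FitQuality) -> bool:
    """Acceptance rule: reduced chi-square strictly below 1.2."""
    return quality.redchi < CHI2_ACCEPT


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _default_tau_starts(histogram: DecayHistogram, n_components: int) -> list:
    """Geometric tau grids spanning channel width to about a third of the window."""
    dt = histogram.channel_width_ns
    lo, hi = 2.0 * dt, histogram.window_ns / 3.0
    base = np.geomspace(lo, hi, n_components + 2)[1:-1]
    starts = [tuple(base)]
    if n_components > 1:
        starts.append(tuple(base * 0.3))
        starts.append(tuple(np.minimum(base * 3.0, hi)))
    return starts


def _varpro_residual(taus_ns, shift_ch, counts, weights, basis_builder):
    """Weighted residual with amplitudes/baseline solved by NNLS."""
    basis = basis_builder(taus_ns, shift_ch)  # (n_channels, n_comp + 1)
    wb = basis * weights[:, None]
    wy = counts * weights
    coef, _ = nnls(wb, wy)
    resid = wy - wb @ coef
    return resid, coef


def fit_decay(histogram: DecayHistogram, irf: IRF | None = None,
              n_components: int = 1, mode: str = "reconvolution",
              fit_shift: bool = True, tau_starts: list | None = None
              ) -> tuple[MultiExpModel, FitQuality]:
    """Fit a multi-exponential decay to a photon-count histogram.

    ``mode="reconvolution"`` fits all channels of the IRF-convolved model and
    requires ``irf``; ``mode="tail"`` fits ``A + sum alpha_i exp(-(t-t0)/tau_i)``
    from just after the peak channel and needs no IRF.  Residuals are
    Poisson-weighted (``1/max(counts,1)``); the reduced chi-square uses
    ``dof = fitted channels - parameters``.  Components are returned sorted by
    ascending lifetime; lifetimes closer than 1% are flagged ``degenerate``
    and lifetimes below twice the channel width are flagged
    ``at_detection_limit``.
    """
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be in 1..4")
    if mode not in ("reconvolution", "tail"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "reconvolution" and irf is None:
        raise ValueError("reconvolution mode requires an IRF")

    counts = histogram.counts.astype(float)
    dt = histogram.channel_width_ns
    weights_full = 1.0 / np.sqrt(np.maximum(counts, 1.0))

    if mode == "tail":
        start_ch = int(np.argmax(counts)) + 1
        if histogram.n_channels - start_ch < n_components * 2 + 2:
            raise ValueError("too few channels after the peak for tail fitting")
        t = (np.arange(start_ch, histogram.n_channels) - start_ch) * dt
        y = counts[start_ch:]
        w = weights_full[start_ch:]

        def basis_builder(taus, _shift):
            cols = [np.exp(-t / tau) for tau in taus]
            cols.append(np.ones_like(t))
            return np.column_stack(cols)

        fit_shift = False
    else:
        if irf.n_channels != histogram.n_channels:
            raise ValueError("histogram and IRF channel grids differ")
        y = counts
        w = weights_full
        irf_norm = irf.normalized()
        times = histogram.times_ns
        n = histogram.n_channels

        def basis_builder(taus, shift_ch):
            kernel = _shifted_irf(irf_norm, shift_ch)
            cols = []
            for tau in taus:
                conv = fftconvolve(kernel, np.exp(-times / tau))[:n]
                cols.append(np.clip(conv, 0.0, None))
            cols.append(np.ones(n))
            return np.column_stack(cols)

    if tau_starts is None:
        tau_starts = _default_tau_starts(histogram, n_components)

    def packed_residual(x):
        taus = np.exp(x[:n_components])
        shift = x[n_components] if fit_shift else 0.0
        resid, _ = _varpro_residual(taus, shift, y, w, basis_builder)
        return resid

    best = None
    for taus0 in tau_starts:
        x0 = list(np.log(taus0))
        lb = [np.log(dt * 0.1)] * n_components
        ub = [np.log(histogram.window_ns * 10.0)] * n_components
        if fit_shift:
            x0.append(0.0)
            lb.append(-10.0)  # channels
            ub.append(10.0)
        try:
            sol = least_squares(packed_residual, x0, bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("decay fit failed from every start")

    taus = np.exp(best.x[:n_components])
    shift_ch = best.x[n_components] if fit_shift else 0.0
    resid, coef = _varpro_residual(taus, shift_ch, y, w, basis_builder)
    alphas, baseline = coef[:n_components], coef[n_components]

    model = MultiExpModel(amplitudes=tuple(alphas), lifetimes_ns=tuple(taus),
                          baseline=float(baseline), shift_ns=float(shift_ch * dt)).sorted()

    n_par = n_components * 2 + 1 + (1 if fit_shift else 0)
    dof = max(len(y) - n_par, 1)
    redchi = float(np.sum(resid ** 2) / dof)

    flags = []
    taus_sorted = np.asarray(model.lifetimes_ns)
    if np.any(taus_sorted[1:] / taus_sorted[:-1] < 1.01):
        flags.append("degenerate")
    if np.any(taus_sorted < 2.0 * dt):
        flags.append("at_detection_limit")
    if not best.success:
        flags.append("not_converged")
    quality = FitQuality(redchi=redchi, weighted_residuals=resid,
                         n_points=len(y), n_params=n_par, flags=tuple(flags))
    return model, quality


def select_n_components(histogram: DecayHistogram, irf: IRF | None = None,
                        max_n: int = 4, mode: str = "reconvolution") -> dict:
    """Pick the smallest component count with an acceptable fit.

    Heuristic: the smallest ``n`` whose reduced chi-square is acceptable
    (< 1.2) and is not improved by more than 5% by ``n+1``.  If no ``n`` is
    acceptable the result carries ``flagged=True`` and ``n = max_n``.
    """
    if max_n > 4:
        raise ValueError("max_n must be <= 4")
    fits = {}
    for n in range(1, max_n + 1):
        try:
            fits[n] = fit_decay(histogram, irf, n_components=n, mode=mode)
        except Exception as exc:  # keep scanning; report the failure
            warnings.warn(f"{n}-component fit failed: {exc}", stacklevel=2)
    chi = {n: q.redchi for n, (_, q) in fits.items()}
    chosen, flagged = None, False
    for n in sorted(fits):
        if chi[n] >= CHI2_ACCEPT:
            continue
        nxt = n + 1
        if nxt in chi and chi[nxt] < 0.95 * chi[n]:
            continue
        chosen = n
        break
    if chosen is None:
        chosen, flagged = max(fits), True
    return {"n": chosen, "redchi": chi, "fits": fits, "flagged": flagged}
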