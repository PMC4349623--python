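"""Stern-Volmer quenching analysis.

Collisional (dynamic) quenching of a fluorophore by a diffusing quencher obeys

    F0 / F = 1 + Ksv [Q]        (steady-state intensities)
    tau0 / tau = 1 + Ksv [Q]    (lifetimes, purely collisional case)

where ``Ksv`` (M^-1) is the Stern-Volmer constant and ``[Q]`` the quencher
concentration.  The bimolecular quenching rate constant is
``kq = Ksv / tau0`` (M^-1 s^-1 with tau0 in seconds).

When lifetime-resolved data are available, comparing the steady-state ``Ksv``
with the per-component lifetime ``Ksv`` values classifies the mechanism: a
steady-state value lying within the range of the lifetime values indicates
dynamic (collisional) quenching, while a steady-state value well above them
indicates a static (complex-forming) contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIXED = "fixed_at_1"
FREE = "free"


@dataclass(frozen=True)
class QuenchSeries:
    """Quencher concentrations with intensity or lifetime responses.

    ``responses`` holds steady-state intensities (kind="intensity") or
    lifetimes in ns (kind="lifetime"); the reference (F0 or tau0) is the
    response at [Q] = 0 unless ``reference`` is given explicitly.
    """

    quencher_M: np.ndarray
    responses: np.ndarray
    kind: str = "intensity"
    quencher: str = "acrylamide"
    reference: float | None = None

    def __post_init__(self):
        q = np.asarray(self.quencher_M, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "quencher_M", q)
        object.__setattr__(self, "responses", r)
        if q.shape != r.shape or q.ndim != 1:
            raise ValueError("quencher and response arrays must be equal-length 1-D")
        if np.any(q < 0):
            raise ValueError("quencher concentrations must be nonnegative")
        if np.any(r <= 0):
            raise ValueError("responses must be positive")
        if self.reference is None and not np.any(q == 0):
            raise ValueError("series must include [Q]=0 or an explicit reference")

    @property
    def f0(self) -> float:
        if self.reference is not None:
            return float(self.reference)
        return float(self.responses[np.argmin(self.quencher_M)])


@dataclass(frozen=True)
class SternVolmerResult:
    """Fitted Stern-Volmer constant with diagnostics."""

    ksv_Minv: float
    stderr: float | None
    intercept: float
    r_squared: float
    kq_Minv_s: float | None = None
    flags: tuple = ()


def stern_volmer_fit(series: QuenchSeries, intercept: str = FIXED,
                     tau0_ns: float | None = None) -> SternVolmerResult:
    """Linear Stern-Volmer fit of F0/F (or tau0/tau) against [Q].

    ``intercept="fixed_at_1"`` (default) fits the slope only, matching the
    Stern-Volmer law's construction; ``"free"`` also fits the intercept as a
    linearity diagnostic.  Upward curvature (positive structure in the
    residuals) raises a ``nonlinear`` flag rather than switching models.
    If ``tau0_ns`` is given, ``kq`` is derived.
    """
    if intercept not in (FIXED, FREE):
        raise ValueError(f"unknown intercept mode {intercept!r}")
    q = series.quencher_M
    y = series.f0 / series.responses
    if len(q) < 3:
        raise ValueError("need at least 3 quencher levels")

    if intercept == FIXED:
        denom = float(np.sum(q * q))
        if denom == 0:
            raise ValueError("all quencher concentrations are zero")
        ksv = float(np.sum(q * (y - 1.0)) / denom)
        b = 1.0
        resid = y - (1.0 + ksv * q)
        dof = len(q) - 1
        stderr = float(np.sqrt(np.sum(resid ** 2) / dof / denom)) if dof > 0 else None
    else:
        (ksv, b), cov = np.polyfit(q, y, 1, cov=True)
        resid = y - (b + ksv * q)
        stderr = float(np.sqrt(cov[0, 0]))

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

    flags = []
    # upward curvature: residuals correlate positively with [Q]^2
    if len(q) >= 4 and np.ptp(q) > 0:
        curv = np.polyfit(q, resid, 2)[0]
        scale = max(abs(ksv), 1e-12) / max(np.ptp(q), 1e-12)
        if curv > 0.5 * scale:
            flags.append("nonlinear")

    kq = quenching_rate_constant(ksv, tau0_ns) if tau0_ns else None
    return SternVolmerResult(ksv_Minv=float(ksv), stderr=stderr, intercept=float(b),
                             r_squared=r2, kq_Minv_s=kq, flags=tuple(flags))


def quenching_rate_constant(ksv_Minv: float, tau0_ns: float) -> float:
    """Bimolecular quenching rate constant ``kq = Ksv / tau0`` in M^-1 s^-1."""
    if tau0_ns <= 0:
        raise ValueError("tau0 must be positive")
    return ksv_Minv / (tau0_ns * 1e-9)


def lifetime_stern_volmer(quencher_M, tau_matrix_ns, intercept: str = FIXED) -> list:
    """Independent Stern-Volmer fits per lifetime component.

    ``tau_matrix_ns`` has one column per component tracked across the [Q]
    grid; NaN entries mark component dropout, and a component with fewer than
    3 valid points is returned as None (partial result).
    """
    q = np.asarray(quencher_M, dtype=float)
    taus = np.atleast_2d(np.asarray(tau_matrix_ns, dtype=float))
    if taus.shape[0] != len(q):
        raise ValueError("tau matrix rows must match the quencher grid")
    results = []
    for j in range(taus.shape[1]):
        col = taus[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 3 or not np.any(q[ok] == 0):
            results.append(None)
            continue
        series = QuenchSeries(quencher_M=q[ok], responses=col[ok], kind="lifetime")
        results.append(stern_volmer_fit(series, intercept=intercept))
    return results


def classify_quenching(steady_state: SternVolmerResult,
                       lifetime_results: list) -> str:
    """Classify the mechanism as ``dynamic``, ``static_component`` or ``indeterminate``.

    Dynamic if the steady-state Ksv lies within [min, max] of the lifetime Ksv
    values (widened by combined standard errors); static_component if it
    exceeds the maximum by more than that margin; indeterminate otherwise
    (e.g. steady-state Ksv below every lifetime value).
    """
    life = [r for r in lifetime_results if r is not None]
    if not life:
        raise ValueError("need at least one lifetime Stern-Volmer result")
    vals = np.array([r.ksv_Minv for r in life])
    errs = np.array([r.stderr or 0.0 for r in life])
    ss = steady_state.ksv_Minv
    ss_err = steady_state.stderr or 0.0
    lo = vals.min() - np.hypot(errs[np.argmin(vals)], ss_err)
    hi = vals.max() + np.hypot(errs[np.argmax(vals)], ss_err)
    if lo <= ss <= hi:
        return "dynamic"
    if ss > hi:
        return "static_component"
    return "indeterminate"
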