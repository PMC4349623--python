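"""Isothermal titration calorimetry: binding models, injection bookkeeping and fitting.

Implements the two isotherm models used for protein/peptide and protein/dye
titrations on a perfusion-cell instrument (VP-ITC style):

* **one set of sites** — ``N`` identical, independent sites per macromolecule
  with a single association constant ``K_a`` (M^-1) and molar enthalpy ``dH``
  (kcal/mol).  The bound-ligand concentration is the closed-form root of the
  binding quadratic.
* **sequential two-site** — two ordered macroscopic binding steps with
  constants ``K_a1 >= K_a2`` and step enthalpies ``dH1``, ``dH2``.  The free
  ligand concentration is obtained from the binding-polynomial mass balance by
  a safeguarded Newton/bisection solver.

Heats are expressed in microcalories, enthalpies in kcal/mol, concentrations
in molar and volumes in litres throughout; ``R = 1.9872`` cal/(mol K).

The per-injection observable is the finite difference of the total heat
content with the standard overfill (displaced-volume) correction::

    dQ_i = Q_i - Q_{i-1} + (dV_i / V0) * (Q_i + Q_{i-1}) / 2

Fitting is weighted nonlinear least squares over the per-injection heats with
multi-start over log-spaced ``K`` grids; sequential fits enforce the
``K_a1 >= K_a2`` labelling by parameterizing ``K_a2 = r * K_a1`` with
``r in (0, 1]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

R_CAL = 1.9872
"""Gas constant in cal/(mol K)."""

KCAL_TO_UCAL = 1.0e9

ONE_SET = "one_set_of_sites"
SEQUENTIAL = "sequential_two_site"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationSchedule:
    """Cell/syringe composition and the injection program of one titration."""

    cell_volume_L: float
    cell_conc_M: float
    syringe_conc_M: float
    injection_volumes_L: tuple
    temperature_K: float = 298.15

    def __post_init__(self):
        vols = tuple(float(v) for v in self.injection_volumes_L)
        object.__setattr__(self, "injection_volumes_L", vols)
        if self.cell_volume_L <= 0:
            raise ValueError("cell volume must be positive")
        if self.cell_conc_M < 0 or self.syringe_conc_M <= 0:
            raise ValueError("concentrations must be positive")
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must all be positive")
        if sum(vols) > 0.2 * self.cell_volume_L:
            warnings.warn(
                "cumulative injected volume exceeds 20% of the cell volume; "
                "the displaced-volume correction becomes inaccurate",
                stacklevel=2,
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_L)

    @property
    def cumulative_volumes_L(self) -> np.ndarray:
        return np.cumsum(self.injection_volumes_L)


@dataclass(frozen=True)
class BindingModel:
    """Parameter set for either isotherm model.

    ``kind`` selects which fields are meaningful: ``one_set_of_sites`` uses
    (``n_sites``, ``k_a``, ``dh``), ``sequential_two_site`` uses
    (``k_a1``, ``dh1``, ``k_a2``, ``dh2``).
    """

    kind: str
    n_sites: float | None = None
    k_a: float | None = None
    dh: float | None = None
    k_a1: float | None = None
    dh1: float | None = None
    k_a2: float | None = None
    dh2: float | None = None

    def __post_init__(self):
        if self.kind == ONE_SET:
            if self.n_sites is None or self.k_a is None or self.dh is None:
                raise ValueError("one-set model needs n_sites, k_a, dh")
            if self.k_a <= 0 or self.n_sites <= 0:
                raise ValueError("K_a and N must be positive")
        elif self.kind == SEQUENTIAL:
            if None in (self.k_a1, self.dh1, self.k_a2, self.dh2):
                raise ValueError("sequential model needs k_a1, dh1, k_a2, dh2")
            if self.k_a1 <= 0 or self.k_a2 < 0:
                raise ValueError("association constants must be positive")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @classmethod
    def one_set(cls, n_sites: float, k_a: float, dh: float) -> "BindingModel":
        return cls(kind=ONE_SET, n_sites=n_sites, k_a=k_a, dh=dh)

    @classmethod
    def sequential(cls, k_a1: float, dh1: float, k_a2: float, dh2: float) -> "BindingModel":
        return cls(kind=SEQUENTIAL, k_a1=k_a1, dh1=dh1, k_a2=k_a2, dh2=dh2)


@dataclass(frozen=True)
class Thermogram:
    """Per-injection heats (ucal) with the schedule that produced them."""

    heats_ucal: np.ndarray
    molar_ratios: np.ndarray
    schedule: TitrationSchedule
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        h = np.asarray(self.heats_ucal, dtype=float)
        r = np.asarray(self.molar_ratios, dtype=float)
        object.__setattr__(self, "heats_ucal", h)
        object.__setattr__(self, "molar_ratios", r)
        if h.shape != r.shape:
            raise ValueError("heats and molar ratios must have equal length")
        if len(h) != self.schedule.n_injections:
            raise ValueError("thermogram length must equal the injection count")
        if np.any(np.diff(r) <= 0):
            raise ValueError("molar ratios must be strictly increasing")


@dataclass(frozen=True)
class ThermoState:
    """Free energy / enthalpy / entropy triple at temperature T.

    ``dG`` and ``dH`` in kcal/mol, ``dS`` in cal/(mol K).
    """

    dg_kcal: float
    dh_kcal: float
    ds_cal: float
    temperature_K: float

    def __post_init__(self):
        resid = self.dg_kcal - (self.dh_kcal - self.temperature_K * self.ds_cal / 1000.0)
        if abs(resid) > 1e-9 * max(1.0, abs(self.dg_kcal)):
            raise ValueError("dG = dH - T dS violated")


@dataclass(frozen=True)
class IsothermFit:
    """Result of :func:`fit_isotherm`."""

    model: BindingModel
    stderr: dict
    redchi: float
    residuals: np.ndarray
    success: bool
    message: str
    n_obs: int
    n_params: int
    warnings: tuple = ()


# ---------------------------------------------------------------------------
# Injection bookkeeping
# ---------------------------------------------------------------------------

def concentrations_after_injection(schedule: TitrationSchedule, i: int) -> tuple:
    """Cell macromolecule and titrant concentrations after injection ``i`` (1-based).

    Uses the standard perfusion-cell displacement bookkeeping: with ``v`` the
    cumulative injected volume and ``V0`` the (constant) cell volume,

    ``M_t = M0 (1 - v/2V0) / (1 + v/2V0)`` and
    ``L_t = L_syr (v/V0) / (1 + v/2V0)``.
    """
    if not 1 <= i <= schedule.n_injections:
        raise IndexError(f"injection index {i} out of range 1..{schedule.n_injections}")
    v = float(schedule.cumulative_volumes_L[i - 1])
    v0 = schedule.cell_volume_L
    m_t = schedule.cell_conc_M * (1.0 - v / (2.0 * v0)) / (1.0 + v / (2.0 * v0))
    l_t = schedule.syringe_conc_M * (v / v0) / (1.0 + v / (2.0 * v0))
    return m_t, l_t


def concentration_series(schedule: TitrationSchedule) -> tuple:
    """Vectorized :func:`concentrations_after_injection` over all injections."""
    v = schedule.cumulative_volumes_L
    v0 = schedule.cell_volume_L
    m = schedule.cell_conc_M * (1.0 - v / (2.0 * v0)) / (1.0 + v / (2.0 * v0))
    l = schedule.syringe_conc_M * (v / v0) / (1.0 + v / (2.0 * v0))
    return m, l


# ---------------------------------------------------------------------------
# Heat-content models
# ---------------------------------------------------------------------------

def total_heat_one_set(m_t, l_t, n_sites: float, k_a: float, dh: float, v0: float):
    """Total heat content (ucal) of the cell for N identical independent sites.

    Closed-form root of the binding quadratic; the discriminant is clamped at
    zero if it goes (numerically) negative.
    """
    if k_a <= 0 or n_sites <= 0:
        raise ValueError("K_a and N must be positive")
    m_t = np.asarray(m_t, dtype=float)
    l_t = np.asarray(l_t, dtype=float)
    out = np.zeros(np.broadcast(m_t, l_t).shape)
    m = np.broadcast_to(m_t, out.shape)
    l = np.broadcast_to(l_t, out.shape)
    pos = m > 0
    x = 1.0 + l[pos] / (n_sites * m[pos]) + 1.0 / (n_sites * k_a * m[pos])
    disc = x * x - 4.0 * l[pos] / (n_sites * m[pos])
    if np.any(disc < 0):
        if np.any(disc < -1e-9):
            warnings.warn("binding quadratic discriminant < 0; clamped at zero", stacklevel=2)
        disc = np.clip(disc, 0.0, None)
    out[pos] = (n_sites * m[pos] * dh * v0 / 2.0) * (x - np.sqrt(disc)) * KCAL_TO_UCAL
    # M_t = 0: no macromolecule, no binding heat
    if out.ndim == 0:
        return float(out)
    return out


def free_ligand_sequential(m_t: float, l_t: float, k_a1: float, k_a2: float) -> float:
    """Free-ligand concentration for the sequential two-site binding polynomial.

    Solves ``L_t = L + M_t (K1 L + 2 K1 K2 L^2) / (1 + K1 L + K1 K2 L^2)`` for
    ``L`` on ``[0, L_t]`` by Newton iteration safeguarded with bisection; the
    left side is strictly increasing in ``L`` so the bracket is guaranteed.
    Residual tolerance: ``1e-13 * max(L_t, 1e-12)``.
    """
    if k_a1 <= 0 or k_a2 < 0:
        raise ValueError("association constants must be positive")
    if m_t < 0 or l_t < 0:
        raise ValueError("concentrations must be nonnegative")
    if l_t == 0.0:
        return 0.0
    if m_t == 0.0:
        return l_t

    def g(L):
        p = 1.0 + k_a1 * L + k_a1 * k_a2 * L * L
        bound = m_t * (k_a1 * L + 2.0 * k_a1 * k_a2 * L * L) / p
        return L + bound - l_t

    def gprime(L):
        p = 1.0 + k_a1 * L + k_a1 * k_a2 * L * L
        dp = k_a1 + 2.0 * k_a1 * k_a2 * L
        num = k_a1 * L + 2.0 * k_a1 * k_a2 * L * L
        dnum = k_a1 + 4.0 * k_a1 * k_a2 * L
        return 1.0 + m_t * (dnum * p - num * dp) / (p * p)

    lo, hi = 0.0, l_t
    glo, ghi = g(lo), g(hi)
    if glo > 0 or ghi < 0:  # pragma: no cover - impossible for physical inputs
        raise RuntimeError("free-ligand bracket lost: non-physical inputs")
    tol = 1e-13 * max(l_t, 1e-12)
    L = 0.5 * l_t
    for _ in range(200):
        val = g(L)
        if abs(val) < tol:
            return L
        if val > 0:
            hi = L
        else:
            lo = L
        step = val / gprime(L)
        nxt = L - step
        if not (lo < nxt < hi):
            nxt = 0.5 * (lo + hi)
        L = nxt
    if abs(g(L)) > tol:  # pragma: no cover
        raise RuntimeError("free-ligand solver failed to reach tolerance")
    return L


def total_heat_sequential(m_t, l_free, k_a1: float, dh1: float,
                          k_a2: float, dh2: float, v0: float):
    """Total heat content (ucal) for the sequential two-site model.

    With binding polynomial ``P = 1 + K1 L + K1 K2 L^2`` and macrostate
    fractions ``F1 = K1 L / P``, ``F2 = K1 K2 L^2 / P``::

        Q = M_t V0 (F1 dH1 + F2 (dH1 + dH2))
    """
    m_t = np.asarray(m_t, dtype=float)
    L = np.asarray(l_free, dtype=float)
    p = 1.0 + k_a1 * L + k_a1 * k_a2 * L * L
    f1 = k_a1 * L / p
    f2 = k_a1 * k_a2 * L * L / p
    q = m_t * v0 * (f1 * dh1 + f2 * (dh1 + dh2)) * KCAL_TO_UCAL
    if q.ndim == 0:
        return float(q)
    return q


def heat_per_injection(q_series, injection_volumes_L, v0: float) -> np.ndarray:
    """Per-injection heats from post-injection total heat contents.

    ``dQ_i = Q_i - Q_{i-1} + (dV_i/V0) (Q_i + Q_{i-1}) / 2`` with ``Q_0 = 0``;
    the second term is the heat carried out in the displaced volume.
    """
    q = np.asarray(q_series, dtype=float)
    dv = np.asarray(injection_volumes_L, dtype=float)
    if q.shape != dv.shape:
        raise ValueError("Q series and injection volumes must have equal length")
    qprev = np.concatenate(([0.0], q[:-1]))
    return q - qprev + (dv / v0) * (q + qprev) / 2.0


def model_thermogram(schedule: TitrationSchedule, model: BindingModel) -> Thermogram:
    """Noise-free thermogram predicted by ``model`` under ``schedule``."""
    m, l = concentration_series(schedule)
    v0 = schedule.cell_volume_L
    if model.kind == ONE_SET:
        q = total_heat_one_set(m, l, model.n_sites, model.k_a, model.dh, v0)
    else:
        lf = np.array([free_ligand_sequential(mi, li, model.k_a1, model.k_a2)
                       for mi, li in zip(m, l)])
        q = total_heat_sequential(m, lf, model.k_a1, model.dh1, model.k_a2, model.dh2, v0)
    dq = heat_per_injection(q, schedule.injection_volumes_L, v0)
    with np.errstate(divide="ignore"):
        ratios = np.where(m > 0, l / m, np.inf)
    return Thermogram(heats_ucal=dq, molar_ratios=ratios, schedule=schedule,
                      meta={"model": model.kind, "source": "model"})


def dilution_correct(thermogram: Thermogram, blank: Thermogram) -> Thermogram:
    """Subtract a titrant-into-buffer blank, injection by injection."""
    if thermogram.schedule.n_injections != blank.schedule.n_injections:
        raise ValueError("sample and blank must have matching injection counts")
    if not np.allclose(thermogram.schedule.injection_volumes_L,
                       blank.schedule.injection_volumes_L):
        raise ValueError("sample and blank injection volumes differ")
    meta = dict(thermogram.meta)
    meta["dilution_corrected"] = True
    return replace(thermogram, heats_ucal=thermogram.heats_ucal - blank.heats_ucal,
                   meta=meta)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _model_heats_from_params(params, kind, schedule):
    if kind == ONE_SET:
        model = BindingModel.one_set(params["n_sites"].value,
                                     10.0 ** params["logk"].value,
                                     params["dh"].value)
    else:
        k1 = 10.0 ** params["logk1"].value
        k2 = k1 * 10.0 ** params["logr"].value
        model = BindingModel.sequential(k1, params["dh1"].value, k2, params["dh2"].value)
    return model_thermogram(schedule, model).heats_ucal


def _one_set_starts(thermogram):
    dq = thermogram.heats_ucal
    sched = thermogram.schedule
    dv0 = sched.injection_volumes_L[0]
    # first-injection heat per mole of injected titrant, assuming ~all binds
    dh0 = dq[0] / (sched.syringe_conc_M * dv0 * KCAL_TO_UCAL)
    if not math.isfinite(dh0) or dh0 == 0:
        dh0 = -5.0
    starts = []
    for logk in (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0):
        for n0 in (1.0, 2.0, 5.0):
            starts.append({"logk": logk, "n_sites": n0, "dh": dh0})
    return starts


def _sequential_starts(thermogram):
    dq = thermogram.heats_ucal
    sched = thermogram.schedule
    dv0 = sched.injection_volumes_L[0]
    dh0 = dq[0] / (sched.syringe_conc_M * dv0 * KCAL_TO_UCAL)
    if not math.isfinite(dh0) or dh0 == 0:
        dh0 = -5.0
    starts = []
    for logk1 in (4.0, 5.0, 6.0, 7.0):
        for logr in (-0.5, -1.5, -3.0):
            starts.append({"logk1": logk1, "logr": logr, "dh1": dh0, "dh2": dh0})
    return starts


def _make_params(kind, start):
    params = lmfit.Parameters()
    if kind == ONE_SET:
        params.add("logk", value=start["logk"], min=0.0, max=12.0)
        params.add("n_sites", value=start["n_sites"], min=0.05, max=50.0)
        params.add("dh", value=start["dh"])
    else:
        params.add("logk1", value=start["logk1"], min=0.0, max=12.0)
        # K_a2 = K_a1 * 10**logr with logr <= 0 enforces K_a1 >= K_a2
        params.add("logr", value=start["logr"], min=-8.0, max=0.0)
        params.add("dh1", value=start["dh1"])
        params.add("dh2", value=start["dh2"])
    return params


def fit_isotherm(thermogram: Thermogram, model_kind: str,
                 initial_guess: BindingModel | None = None,
                 sigma_ucal: float | None = None,
                 exclude_first: bool = False) -> IsothermFit:
    """Fit an isotherm model to per-injection heats by weighted least squares.

    Parameters are estimated in transformed coordinates (log10 K, raw dH and N)
    to enforce positivity; sequential fits parameterize ``K_a2 = r K_a1`` with
    ``r in (0, 1]`` so the macroscopic constants cannot label-switch.  Without
    an ``initial_guess`` a multi-start over a log-spaced K grid is used and the
    best converged fit (lowest reduced chi-square) is returned.

    ``sigma_ucal`` sets the per-point heat uncertainty used for weights and
    for scaling the reported asymptotic standard errors (unit weights if None,
    with errors scaled by the residual variance, lmfit's default).
    """
    if model_kind not in (ONE_SET, SEQUENTIAL):
        raise ValueError(f"unknown model kind {model_kind!r}")
    n_inj = thermogram.schedule.n_injections
    mask = np.ones(n_inj, dtype=bool)
    if exclude_first:
        mask[0] = False
    if mask.sum() < 6:
        raise ValueError("need at least 6 informative injections")
    obs = thermogram.heats_ucal

    fit_warnings = []
    span = np.ptp(obs[mask])
    if span < 10.0 * (sigma_ucal or 0.0) or span == 0.0:
        fit_warnings.append("flat isotherm: c-value likely too low or too high")

    def residual(params):
        pred = _model_heats_from_params(params, model_kind, thermogram.schedule)
        r = (pred - obs)[mask]
        if sigma_ucal:
            r = r / sigma_ucal
        return r

    if initial_guess is not None:
        if initial_guess.kind != model_kind:
            raise ValueError("initial guess kind does not match model_kind")
        if model_kind == ONE_SET:
            starts = [{"logk": math.log10(initial_guess.k_a),
                       "n_sites": initial_guess.n_sites, "dh": initial_guess.dh}]
        else:
            starts = [{"logk1": math.log10(initial_guess.k_a1),
                       "logr": min(0.0, math.log10(initial_guess.k_a2 / initial_guess.k_a1)),
                       "dh1": initial_guess.dh1, "dh2": initial_guess.dh2}]
    else:
        starts = (_one_set_starts if model_kind == ONE_SET else _sequential_starts)(thermogram)

    best = None
    for start in starts:
        try:
            res = lmfit.minimize(residual, _make_params(model_kind, start),
                                 method="leastsq", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("isotherm fit failed from every start")

    p = best.params
    if model_kind == ONE_SET:
        k_a = 10.0 ** p["logk"].value
        model = BindingModel.one_set(p["n_sites"].value, k_a, p["dh"].value)
        stderr = {
            "k_a": (math.log(10.0) * k_a * p["logk"].stderr) if p["logk"].stderr else None,
            "n_sites": p["n_sites"].stderr,
            "dh": p["dh"].stderr,
        }
    else:
        k1 = 10.0 ** p["logk1"].value
        r = 10.0 ** p["logr"].value
        model = BindingModel.sequential(k1, p["dh1"].value, k1 * r, p["dh2"].value)
        sl1 = p["logk1"].stderr
        slr = p["logr"].stderr
        stderr = {
            "k_a1": (math.log(10.0) * k1 * sl1) if sl1 else None,
            "k_a2": (math.log(10.0) * k1 * r * math.hypot(sl1 or 0.0, slr or 0.0))
                    if (sl1 is not None and slr is not None) else None,
            "dh1": p["dh1"].stderr,
            "dh2": p["dh2"].stderr,
        }

    success = bool(best.success)
    if not success:
        fit_warnings.append("optimizer did not report convergence; parameters unreliable")
    return IsothermFit(model=model, stderr=stderr, redchi=best.redchi,
                       residuals=np.asarray(best.residual), success=success,
                       message=str(best.message), n_obs=int(mask.sum()),
                       n_params=best.nvarys, warnings=tuple(fit_warnings))


# ---------------------------------------------------------------------------
# Thermodynamic linkage & buffer ionization
# ---------------------------------------------------------------------------

def thermo_derive(k_a: float, dh_kcal: float, temperature_K: float = 298.15) -> ThermoState:
    """Derive ``dG = -RT ln K_a`` (kcal/mol) and ``dS = (dH - dG)/T`` (cal/mol K)."""
    if k_a <= 0:
        raise ValueError("K_a must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    dg = -R_CAL * temperature_K * math.log(k_a) / 1000.0
    ds = (dh_kcal - dg) / temperature_K * 1000.0
    return ThermoState(dg_kcal=dg, dh_kcal=dh_kcal, ds_cal=ds,
                       temperature_K=temperature_K)


def buffer_ionization_decompose(dh_app_kcal, dh_ion_kcal) -> dict:
    """Separate intrinsic binding enthalpy from buffer-protonation heat.

    Ordinary least squares of the apparent enthalpy on the buffer ionization
    enthalpy across buffers: ``dH_app = dH_b + n * dH_i``.  The slope ``n`` is
    the number of protons taken up from the buffer (positive = protonation).
    """
    y = np.asarray(dh_app_kcal, dtype=float)
    x = np.asarray(dh_ion_kcal, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("dH_app and dH_i must be equal-length 1-D sequences")
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 buffers with distinct ionization enthalpies")
    if len(x) == 2:
        n = (y[1] - y[0]) / (x[1] - x[0])
        dh_b = y[0] - n * x[0]
        cov = None
    else:
        coef, cov = np.polyfit(x, y, 1, cov=True)
        n, dh_b = coef
    resid = y - (dh_b + n * x)
    out = {"dh_b": float(dh_b), "n_protons": float(n), "residuals": resid}
    if cov is not None:
        out["stderr"] = {"n_protons": float(np.sqrt(cov[0, 0])),
                         "dh_b": float(np.sqrt(cov[1, 1]))}
    return out
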