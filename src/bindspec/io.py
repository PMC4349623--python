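"""CSV/JSON I/O, schema validation, report assembly and the pipeline driver.

File conventions (fixed): comma-separated UTF-8 CSV with one header line and
``.`` decimals; units are embedded in column names (``_uL``, ``_ucal``,
``_ns``, ``_s``, ``_M``, ``_nm``) so a file can never be read in the wrong
unit silently.  Reports serialize deterministically (sorted keys, fixed float
format) so reruns diff cleanly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import itc as itc_mod
from . import kinetics as kin_mod
from . import lifetimes as lt_mod
from . import quenching as q_mod
from . import spectra as sp_mod
from . import synth

log = logging.getLogger("bindspec")

try:
    __version__ = version("bindspec")
except PackageNotFoundError:  # pragma: no cover - editable edge case
    __version__ = "unknown"


SCHEMAS = {
    "thermogram": {"columns": ["injection_index", "volume_uL", "heat_ucal"],
                   "sorted": "injection_index", "unique": "injection_index"},
    "decay": {"columns": ["channel", "time_ns", "counts"],
              "sorted": "channel", "unique": "channel"},
    "quench": {"columns": ["quencher_M", "response"],
               "sorted": "quencher_M", "unique": "quencher_M"},
    "trace": {"columns": ["time_s", "fluorescence"],
              "sorted": "time_s", "unique": "time_s"},
    "spectrum": {"columns": ["wavelength_nm", "signal"],
                 "sorted": "wavelength_nm", "unique": "wavelength_nm"},
}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Checks the header (required columns, by name), numeric cells (malformed
    rows reported with line numbers), sortedness and uniqueness of the key
    column.  Extra columns (e.g. ``tau2_ns`` in lifetime quench tables) are
    allowed but must be numeric.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; "
                         f"valid: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad_lines = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header + 1-based
        df[col] = coerced
    if bad_lines:
        raise ValueError(f"{path}: non-numeric cells on line(s) {sorted(set(bad_lines))}")
    if df[schema["columns"]].isna().any().any():
        rows = df.index[df[schema["columns"]].isna().any(axis=1)]
        raise ValueError(f"{path}: empty cells on line(s) {[int(i) + 2 for i in rows]}")
    key = schema["sorted"]
    if df[key].duplicated().any():
        dup = df[key][df[key].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated {key} value {dup!r}")
    if not df[key].is_monotonic_increasing:
        raise ValueError(f"{path}: column {key!r} must be sorted ascending")
    return df


# -- typed readers/writers ---------------------------------------------------

def read_thermogram(path, schedule: itc_mod.TitrationSchedule) -> itc_mod.Thermogram:
    df = read_table(path, "thermogram")
    vols = df["volume_uL"].to_numpy() * 1e-6
    if len(vols) != schedule.n_injections or \
            not np.allclose(vols, schedule.injection_volumes_L):
        raise ValueError("CSV injection volumes do not match the schedule")
    m, l = itc_mod.concentration_series(schedule)
    return itc_mod.Thermogram(heats_ucal=df["heat_ucal"].to_numpy(),
                              molar_ratios=l / m, schedule=schedule,
                              meta={"path": str(path)})


def write_thermogram(tg: itc_mod.Thermogram, path) -> None:
    pd.DataFrame({
        "injection_index": np.arange(1, tg.schedule.n_injections + 1),
        "volume_uL": np.asarray(tg.schedule.injection_volumes_L) * 1e6,
        "heat_ucal": tg.heats_ucal,
    }).to_csv(path, index=False)


def read_decay(path, window_ns: float | None = None, cls=lt_mod.DecayHistogram):
    df = read_table(path, "decay")
    if window_ns is None:
        dt = float(df["time_ns"].iloc[1] - df["time_ns"].iloc[0])
        window_ns = dt * len(df)
    return cls(counts=df["counts"].to_numpy(), window_ns=window_ns,
               meta={"path": str(path)})


def read_irf(path, window_ns: float | None = None) -> lt_mod.IRF:
    return read_decay(path, window_ns, cls=lt_mod.IRF)


def write_decay(hist: lt_mod.DecayHistogram, path) -> None:
    pd.DataFrame({"channel": np.arange(hist.n_channels),
                  "time_ns": hist.times_ns,
                  "counts": hist.counts}).to_csv(path, index=False)


def read_quench(path) -> q_mod.QuenchSeries:
    df = read_table(path, "quench")
    return q_mod.QuenchSeries(quencher_M=df["quencher_M"].to_numpy(),
                              responses=df["response"].to_numpy())


def write_quench(series: q_mod.QuenchSeries, path) -> None:
    pd.DataFrame({"quencher_M": series.quencher_M,
                  "response": series.responses}).to_csv(path, index=False)


def read_trace(path) -> kin_mod.StoppedFlowTrace:
    df = read_table(path, "trace")
    return kin_mod.StoppedFlowTrace(time_s=df["time_s"].to_numpy(),
                                    fluorescence=df["fluorescence"].to_numpy(),
                                    meta={"path": str(path)})


def write_trace(trace: kin_mod.StoppedFlowTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time_s,
                  "fluorescence": trace.fluorescence}).to_csv(path, index=False)


def read_spectrum(path, kind: str = sp_mod.EMISSION) -> sp_mod.Spectrum:
    df = read_table(path, "spectrum")
    return sp_mod.Spectrum(wavelength_nm=df["wavelength_nm"].to_numpy(),
                           signal=df["signal"].to_numpy(), kind=kind,
                           meta={"path": str(path)})


def write_spectrum(spec: sp_mod.Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelength_nm,
                  "signal": spec.signal}).to_csv(path, index=False)


# -- report ------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Per-stage results plus provenance (inputs, seeds, version, config)."""

    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, name: str, payload: dict) -> None:
        self.sections[name] = payload


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def strip_arrays(payload: dict) -> dict:
    """Drop bulky per-point arrays (residuals) from a result payload."""
    return {k: v for k, v in payload.items()
            if k not in ("residuals", "weighted_residuals")}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return float(f"{f:.10g}")  # fixed precision for stable diffs
    if isinstance(obj, (np.integer, int, str, bool)) or obj is None:
        return int(obj) if isinstance(obj, np.integer) else obj
    if dataclasses.is_dataclass(obj):
        return _jsonify(dataclasses.asdict(obj))
    return str(obj)


def write_report(report: AnalysisReport, path, fmt: str = "json") -> None:
    """Serialize deterministically; same report twice gives byte-identical files."""
    if fmt not in ("json", "markdown"):
        raise ValueError(f"unknown report format {fmt!r}")
    payload = {"provenance": _jsonify(report.provenance),
               "results": _jsonify(report.sections)}
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
        return
    lines = ["# Analysis report", "", "## Provenance", ""]
    for k in sorted(payload["provenance"]):
        lines.append(f"- **{k}**: {payload['provenance'][k]}")
    for name in sorted(payload["results"]):
        lines += ["", f"## {name}", ""]
        for k in sorted(payload["results"][name]):
            lines.append(f"- **{k}**: {payload['results'][name][k]}")
    path.write_text("\n".join(lines) + "\n")


# -- pipeline ----------------------------------------------------------------

VALID_STAGES = ("itc", "decay", "quench", "kinetics", "spectra")


def _stage_itc(spec: dict, rng: np.random.Generator) -> dict:
    sched = itc_mod.TitrationSchedule(
        cell_volume_L=spec.get("cell_volume_mL", 1.4) * 1e-3,
        cell_conc_M=spec.get("cell_conc_uM", 30.0) * 1e-6,
        syringe_conc_M=spec.get("syringe_conc_uM", 1000.0) * 1e-6,
        injection_volumes_L=tuple([spec.get("injection_uL", 10.0) * 1e-6]
                                  * spec.get("n_injections", 25)),
        temperature_K=spec.get("temperature_C", 25.0) + 273.15)
    kind = spec.get("model", itc_mod.ONE_SET)
    if kind == itc_mod.ONE_SET:
        truth = itc_mod.BindingModel.one_set(spec.get("n_sites", 2.05),
                                             spec.get("k_a", 8.92e5),
                                             spec.get("dh", -5.02))
    else:
        truth = itc_mod.BindingModel.sequential(spec.get("k_a1", 7.57e5),
                                                spec.get("dh1", -4.99),
                                                spec.get("k_a2", 1.70e4),
                                                spec.get("dh2", -3.33))
    noise = spec.get("noise_sd_ucal", 0.2)
    sample, blank = synth.simulate_itc(sched, truth, noise_sd_ucal=noise,
                                       seed=rng)
    corrected = itc_mod.dilution_correct(sample, blank)
    fit = itc_mod.fit_isotherm(corrected, kind, sigma_ucal=noise or None)
    out = {"model": kind, "truth": dataclasses.asdict(truth),
           "fit": dataclasses.asdict(fit.model), "stderr": fit.stderr,
           "redchi": fit.redchi}
    k_main = fit.model.k_a if kind == itc_mod.ONE_SET else fit.model.k_a1
    dh_main = fit.model.dh if kind == itc_mod.ONE_SET else fit.model.dh1
    state = itc_mod.thermo_derive(k_main, dh_main, sched.temperature_K)
    out["thermo"] = dataclasses.asdict(state)
    return out


def _stage_decay(spec: dict, rng: np.random.Generator) -> dict:
    model = synth.ans_cam_model(
        tau1_ns=spec.get("tau1_ns", 6.4), f1=spec.get("f1", 0.44),
        tau2_ns=spec.get("tau2_ns", 13.1), f2=spec.get("f2", 0.53),
        tau_free_ns=spec.get("tau_free_ns", 0.3))
    hist, irf = synth.simulate_decay(model,
                                     irf_fwhm_ns=spec.get("irf_fwhm_ns", 1.0),
                                     window_ns=spec.get("window_ns", 200.0),
                                     channels=spec.get("channels", 4000),
                                     peak_counts=spec.get("peak_counts", 10000),
                                     seed=rng)
    fitted, quality = lt_mod.fit_decay(hist, irf,
                                       n_components=spec.get("n_components", 3))
    f, b = lt_mod.fractional_intensities(fitted)
    return {"truth": dataclasses.asdict(model),
            "fit": dataclasses.asdict(fitted) | {"f": list(f), "B": list(b)},
            "mean_lifetime_ns": lt_mod.amplitude_average_lifetime(fitted),
            "redchi": quality.redchi, "accepted": quality.accepted}


def _stage_quench(spec: dict, rng: np.random.Generator) -> dict:
    ksv = spec.get("ksv", 13.5)
    series = synth.simulate_quench_series(spec.get("f0", 100.0), ksv,
                                          spec.get("q_grid_M", synth.DEFAULT_Q_GRID_M),
                                          noise_frac=spec.get("noise_frac", 0.0),
                                          seed=rng)
    res = q_mod.stern_volmer_fit(series, tau0_ns=spec.get("tau0_ns"))
    return {"ksv_true": ksv, "fit": strip_arrays(dataclasses.asdict(res))}


def _stage_kinetics(spec: dict, rng: np.random.Generator) -> dict:
    k = spec.get("k_off", 1.41)
    trace = synth.simulate_stopped_flow(k, spec.get("amplitude", 1.0),
                                        spec.get("offset", 0.2),
                                        duration_s=spec.get("duration_s", 2.0),
                                        dt_s=spec.get("dt_s", 0.002),
                                        noise_frac=spec.get("noise_frac", 0.0),
                                        seed=rng)
    res = kin_mod.fit_single_exponential(trace,
                                         dead_time_s=spec.get("dead_time_s", 0.002))
    return {"k_off_true": k, "fit": strip_arrays(dataclasses.asdict(res))}


def _stage_spectra(spec: dict, rng: np.random.Generator) -> dict:
    grid = np.arange(*spec.get("grid_nm", (400.0, 651.0, 1.0)))
    apo = synth.simulate_spectrum([(spec.get("apo_center_nm", 520.0),
                                    spec.get("width_nm", 40.0), 1.0)], grid,
                                  noise_frac=spec.get("noise_frac", 0.0), seed=rng)
    holo = synth.simulate_spectrum([(spec.get("holo_center_nm", 480.0),
                                     spec.get("width_nm", 40.0),
                                     spec.get("fold", 3.01))], grid,
                                   noise_frac=spec.get("noise_frac", 0.0), seed=rng)
    enh = sp_mod.fold_enhancement(holo, apo)
    cd_grid = np.arange(190.0, 261.0, 1.0)
    cd = synth.simulate_cd_spectrum(spec.get("cd_ratio", 0.89), cd_grid, seed=rng)
    return {"fold": enh.fold, "lambda_max_nm": enh.lambda_max_nm,
            "shift_nm": enh.shift_nm,
            "cd_ratio": sp_mod.ellipticity_ratio(cd)}


_STAGE_FUNCS = {"itc": _stage_itc, "decay": _stage_decay, "quench": _stage_quench,
                "kinetics": _stage_kinetics, "spectra": _stage_spectra}


def run_pipeline(config: dict) -> AnalysisReport:
    """Run the configured stages in order and assemble a report.

    ``config`` holds a global ``seed`` and a ``stages`` list, each entry a
    dict with a ``stage`` name (one of ``itc, decay, quench, kinetics,
    spectra``) plus stage parameters.  Each stage gets its own child seed
    derived from the global one, so the report is a deterministic function of
    (config, seed).  A stage failure halts the run; the partial report is
    attached to the raised error.
    """
    seed = int(config.get("seed", 0))
    master = np.random.default_rng(seed)
    report = AnalysisReport()
    report.provenance = {"seed": seed, "software": f"bindspec {__version__}",
                         "config": _jsonify(config)}
    for i, stage_spec in enumerate(config.get("stages", [])):
        name = stage_spec.get("stage")
        if name not in _STAGE_FUNCS:
            raise ValueError(f"invalid stage {name!r}; valid stages: "
                             f"{list(VALID_STAGES)}")
        child = np.random.default_rng(master.integers(2 ** 31))
        log.info("running stage %d: %s (params=%s)", i, name, stage_spec)
        try:
            result = _STAGE_FUNCS[name](stage_spec, child)
        except Exception as exc:
            report.sections[f"{i}:{name}"] = {"failed": str(exc)}
            report.provenance["partial"] = True
            err = RuntimeError(f"stage {i} ({name}) failed: {exc}")
            err.partial_report = report
            raise err from exc
        label = stage_spec.get("label", f"{i}:{name}")
        report.add(label, result)
    return report
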