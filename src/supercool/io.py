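"""Table I/O, run configuration, and the end-to-end pipeline.

All tables are plain CSV with unit-suffixed column names (``temperature_K``,
``tau_alpha_s``, ...) and optional ``# key: value`` metadata header lines.
Temperatures are kelvin everywhere inside the package; Celsius conversion is
a CLI-boundary concern only.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crystallization import (CENSORED, DETECTED, OnsetTable, RITimeTrace,
                              coupling_parameter, detect_onset,
                              fit_nucleation_arrhenius)
from .dielectric import DielectricSpectrum, build_relaxation_map, fit_hn_spectrum
from .exceptions import DataValidationError, PipelineStageError
from .mixing import (ComponentThermo, DSCTrace, RITempTrace, ck_divergence,
                     k_from_delta_cp, tg_from_bilinear, tg_from_dsc_step)
from .relaxation import RelaxationMap, fit_vft, fragility_report

logger = logging.getLogger("supercool")

__all__ = [
    "read_table",
    "read_metadata",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_relaxation_map_csv",
    "write_relaxation_map_csv",
    "read_ri_time_csv",
    "write_ri_time_csv",
    "read_ri_scan_csv",
    "write_ri_scan_csv",
    "read_dsc_csv",
    "write_dsc_csv",
    "read_onset_csv",
    "write_onset_csv",
    "read_thermo_config",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# generic validated reader

def read_metadata(path) -> dict:
    """Parse leading ``# key: value`` comment lines of a CSV file."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a CSV and validate it against ``schema``.

    ``schema`` maps column name -> dtype ("float" or "str"). Missing columns,
    non-numeric cells, and unknown layouts raise DataValidationError naming
    the offending column and row.
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"file not found: {path}")
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    for col, dtype in schema.items():
        if col not in df.columns:
            raise DataValidationError(f"{path.name}: missing column '{col}'")
        if dtype == "float":
            converted = pd.to_numeric(df[col], errors="coerce")
            allow_nan = col == "t_onset_s"  # censored rows carry no onset time
            bad = converted.isna() & ~(df[col].isna() if allow_nan else False)
            if not allow_nan and converted.isna().any():
                row = int(converted.isna().idxmax())
                raise DataValidationError(
                    f"{path.name}: non-numeric value in column '{col}' at row {row}"
                )
            df[col] = converted
    return df


def _write_csv(df: pd.DataFrame, path, metadata: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# dielectric spectra

def write_spectra_csv(spectra, path):
    """Write a list of DielectricSpectrum records to long-form CSV."""
    frames = []
    for sp in spectra:
        frames.append(pd.DataFrame({
            "temperature_K": sp.temperature,
            "frequency_Hz": sp.frequencies,
            "eps_real": sp.eps_real if sp.eps_real is not None else np.nan,
            "eps_imag": sp.eps_imag,
        }))
    _write_csv(pd.concat(frames, ignore_index=True), path)


def read_spectra_csv(path) -> list[DielectricSpectrum]:
    df = read_table(path, {"temperature_K": "float", "frequency_Hz": "float",
                           "eps_imag": "float"})
    has_real = "eps_real" in df.columns
    spectra = []
    for temp, grp in df.groupby("temperature_K", sort=True):
        f = grp["frequency_Hz"].to_numpy()
        if np.any(np.diff(f) <= 0):
            row = int(grp.index[np.argmin(np.diff(f) > 0) + 1])
            raise DataValidationError(
                f"{Path(path).name}: frequencies not ascending at row {row} "
                f"(temperature {temp} K)"
            )
        real = grp["eps_real"].to_numpy() if has_real else None
        if real is not None and np.all(np.isnan(real)):
            real = None
        spectra.append(DielectricSpectrum(temperature=float(temp), frequencies=f,
                                          eps_imag=grp["eps_imag"].to_numpy(),
                                          eps_real=real))
    return spectra


# ---------------------------------------------------------------------------
# relaxation map

def write_relaxation_map_csv(rmap: RelaxationMap, path):
    df = pd.DataFrame({
        "temperature_K": rmap.temperatures,
        "tau_alpha_s": rmap.tau_alpha,
        "tau_sd_s": rmap.tau_sd if rmap.tau_sd is not None else np.nan,
    })
    _write_csv(df, path)


def read_relaxation_map_csv(path) -> RelaxationMap:
    df = read_table(path, {"temperature_K": "float", "tau_alpha_s": "float"})
    sd = df["tau_sd_s"].to_numpy() if "tau_sd_s" in df.columns else None
    if sd is not None and np.all(np.isnan(sd)):
        sd = None
    return RelaxationMap(temperatures=df["temperature_K"].to_numpy(),
                         tau_alpha=df["tau_alpha_s"].to_numpy(), tau_sd=sd)


# ---------------------------------------------------------------------------
# refractometry traces

def write_ri_time_csv(trace: RITimeTrace, path):
    _write_csv(pd.DataFrame({"time_s": trace.times, "refractive_index": trace.ri}),
               path, metadata={"temperature_K": trace.temperature})


def read_ri_time_csv(path) -> RITimeTrace:
    meta = read_metadata(path)
    df = read_table(path, {"time_s": "float", "refractive_index": "float"})
    if "temperature_K" in df.columns:
        temp = float(df["temperature_K"].iloc[0])
    elif "temperature_K" in meta:
        temp = float(meta["temperature_K"])
    else:
        raise DataValidationError(
            f"{Path(path).name}: temperature_K missing from both metadata and columns"
        )
    return RITimeTrace(temperature=temp, times=df["time_s"].to_numpy(),
                       ri=df["refractive_index"].to_numpy())


def write_ri_scan_csv(trace: RITempTrace, path):
    _write_csv(pd.DataFrame({"temperature_K": trace.temperatures,
                             "refractive_index": trace.ri}),
               path, metadata={"scan_direction": trace.scan_direction})


def read_ri_scan_csv(path) -> RITempTrace:
    meta = read_metadata(path)
    df = read_table(path, {"temperature_K": "float", "refractive_index": "float"})
    return RITempTrace(temperatures=df["temperature_K"].to_numpy(),
                       ri=df["refractive_index"].to_numpy(),
                       scan_direction=meta.get("scan_direction", "cooling"))


# ---------------------------------------------------------------------------
# DSC

def write_dsc_csv(trace: DSCTrace, path):
    _write_csv(pd.DataFrame({"temperature_K": trace.temperatures,
                             "heat_flow_W_per_g": trace.heat_flow}),
               path, metadata={"heating_rate_K_per_min": trace.heating_rate})


def read_dsc_csv(path) -> DSCTrace:
    meta = read_metadata(path)
    if "heating_rate_K_per_min" not in meta:
        raise DataValidationError(
            f"{Path(path).name}: missing '# heating_rate_K_per_min:' metadata line"
        )
    df = read_table(path, {"temperature_K": "float", "heat_flow_W_per_g": "float"})
    return DSCTrace(heating_rate=float(meta["heating_rate_K_per_min"]),
                    temperatures=df["temperature_K"].to_numpy(),
                    heat_flow=df["heat_flow_W_per_g"].to_numpy())


# ---------------------------------------------------------------------------
# onset tables

def write_onset_csv(table: OnsetTable, path):
    _write_csv(pd.DataFrame({"temperature_K": table.temperatures,
                             "t_onset_s": table.t_onset, "flag": table.flags}), path)


def read_onset_csv(path) -> OnsetTable:
    df = read_table(path, {"temperature_K": "float", "t_onset_s": "float",
                           "flag": "str"})
    flags = [str(f).strip() for f in df["flag"]]
    return OnsetTable(temperatures=df["temperature_K"].to_numpy(),
                      t_onset=df["t_onset_s"].to_numpy(), flags=flags)


# ---------------------------------------------------------------------------
# thermo config

def read_thermo_config(path):
    """Read a YAML mixture-thermodynamics config.

    Layout::

        drug: {name: ETB, tg_K: 330, delta_cp_J_per_gK: 0.347}
        excipient: {name: acMAL, tg_K: 332, delta_cp_J_per_gK: 0.350}
        mixtures:
          - {w_excipient: 0.1, tg_observed_K: 329}

    Returns (drug: ComponentThermo, excipient: ComponentThermo,
    observed: list[(w_excipient, tg_observed_K)]).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        drug = ComponentThermo(name=str(cfg["drug"]["name"]),
                               tg=float(cfg["drug"]["tg_K"]),
                               delta_cp=float(cfg["drug"]["delta_cp_J_per_gK"]))
        excip = ComponentThermo(name=str(cfg["excipient"]["name"]),
                                tg=float(cfg["excipient"]["tg_K"]),
                                delta_cp=float(cfg["excipient"]["delta_cp_J_per_gK"]))
    except (KeyError, TypeError) as exc:
        raise DataValidationError(f"thermo config {path}: missing field {exc}") from exc
    observed = [(float(m["w_excipient"]), float(m["tg_observed_K"]))
                for m in cfg.get("mixtures", []) if "tg_observed_K" in m]
    return drug, excip, observed


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Any subset of inputs may be given; the pipeline executes exactly the
    stages whose inputs are available, in dependency order.
    """

    outdir: str
    seed: int = 0
    spectra: str | None = None  # dielectric spectra CSV
    relaxation_map: str | None = None  # precomputed map CSV (skips HN stage)
    ri_time: list = field(default_factory=list)  # isothermal RI trace CSVs
    ri_scan: str | None = None  # cooling-scan RI CSV
    dsc: str | None = None  # DSC trace CSV
    onset_table: str | None = None  # precomputed onset CSV (skips detection)
    thermo: str | None = None  # mixture thermodynamics YAML
    # stage parameters
    tau_ref: float = 100.0  # s, dielectric Tg convention
    fit_window: tuple | None = None  # Hz, HN fit restriction
    e_alpha_window: tuple | None = None  # K, Arrhenius window for E_alpha
    smooth_width: int = 11
    drop_factor: float = 10.0
    exclusion_halfwidth: float = 2.0  # K, bilinear Tg fit

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fit_window", "e_alpha_window"):
            if raw.get(key) is not None:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all tables plus a summary.

    Stage order: spectra -> HN fits -> relaxation map -> VFT -> Tg/m_p/E_alpha;
    RI traces -> onset table -> Arrhenius nucleation -> coupling; thermo ->
    Couchman–Karasz -> divergence; scans -> refractometric / DSC Tg.
    Any stage failure raises PipelineStageError naming the stage; outputs of
    completed stages are preserved on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "parameters": {
                         "tau_ref_s": config.tau_ref,
                         "fit_window_Hz": config.fit_window,
                         "e_alpha_window_K": config.e_alpha_window,
                         "smooth_width": config.smooth_width,
                         "drop_factor": config.drop_factor,
                         "exclusion_halfwidth_K": config.exclusion_halfwidth,
                     }}
    logger.info("supercool %s starting; seed=%d", __version__, config.seed)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    name = "setup"
    try:
        rmap = None
        if config.spectra is not None:
            name = stage("hn_fit")
            spectra = read_spectra_csv(config.spectra)
            fits = []
            rows = []
            for sp in spectra:
                res = fit_hn_spectrum(sp, fit_window=config.fit_window)
                fits.append((sp.temperature, res))
                p = res.params
                rows.append((sp.temperature, p.sigma0, p.eps_inf, p.delta_eps,
                             p.tau_alpha, res.tau_alpha_sd, p.xi, p.delta,
                             res.residual_norm, res.converged))
            fit_df = pd.DataFrame(rows, columns=[
                "temperature_K", "sigma0_S_per_m", "eps_inf", "delta_eps",
                "tau_alpha_s", "tau_sd_s", "xi", "delta", "residual_norm",
                "converged"])
            _write_csv(fit_df, outdir / "hn_fits.csv")
            name = stage("relaxation_map")
            rmap = build_relaxation_map(fits)
            write_relaxation_map_csv(rmap, outdir / "relaxation_map.csv")
        elif config.relaxation_map is not None:
            name = stage("relaxation_map")
            rmap = read_relaxation_map_csv(config.relaxation_map)

        e_alpha = None
        if rmap is not None:
            name = stage("vft")
            vft = fit_vft(rmap)
            report = fragility_report(vft, tau_ref=config.tau_ref,
                                      e_alpha_window=config.e_alpha_window)
            e_alpha = report.e_alpha
            vft_df = pd.DataFrame([{
                "log10_tau0": vft.log10_tau0, "A_K": vft.A, "T_VFT_K": vft.T_VFT,
                "tg_dielectric_K": report.tg_dielectric, "tg_sd_K": report.tg_sd,
                "tau_ref_s": report.tau_ref, "m_p": report.m_p,
                "fragility_class": report.class_label,
                "e_alpha_kJ_per_mol": report.e_alpha,
            }])
            _write_csv(vft_df, outdir / "vft_report.csv")
            summary["vft"] = {"log10_tau0": vft.log10_tau0, "A_K": vft.A,
                              "T_VFT_K": vft.T_VFT}
            summary["tg_dielectric_K"] = report.tg_dielectric
            summary["m_p"] = report.m_p
            summary["fragility_class"] = report.class_label
            if e_alpha is not None:
                summary["e_alpha_kJ_per_mol"] = e_alpha

        onset = None
        if config.ri_time:
            name = stage("onset_detection")
            temps, onsets, flags = [], [], []
            for trace_path in config.ri_time:
                trace = read_ri_time_csv(trace_path)
                t_on, flag = detect_onset(trace, smooth_width=config.smooth_width,
                                          drop_factor=config.drop_factor)
                temps.append(trace.temperature)
                onsets.append(t_on)
                flags.append(flag)
            onset = OnsetTable(temperatures=np.array(temps),
                               t_onset=np.array(onsets), flags=flags)
            write_onset_csv(onset, outdir / "onset_table.csv")
        elif config.onset_table is not None:
            name = stage("onset_detection")
            onset = read_onset_csv(config.onset_table)

        if onset is not None and sum(f == DETECTED for f in onset.flags) >= 3:
            name = stage("nucleation_fit")
            nucl = fit_nucleation_arrhenius(onset)
            summary["nucleation"] = {"log10_t_onset0": nucl.log10_t_onset0,
                                     "e_nucl_kJ_per_mol": nucl.e_nucl}
            _write_csv(pd.DataFrame([summary["nucleation"]]),
                       outdir / "nucleation_fit.csv")
            if e_alpha is not None and config.e_alpha_window is not None:
                name = stage("coupling")
                rep = coupling_parameter(nucl.e_nucl, e_alpha,
                                         window=config.e_alpha_window)
                summary["s_coupling"] = rep.s_coupling

        if config.thermo is not None:
            name = stage("couchman_karasz")
            drug, excip, observed = read_thermo_config(config.thermo)
            k = k_from_delta_cp(excip.delta_cp, drug.delta_cp)
            summary["ck_k"] = k
            if observed:
                div = ck_divergence(observed, drug.tg, excip.tg, k)
                _write_csv(div.table, outdir / "ck_divergence.csv")
                summary["ck_interior_minimum"] = div.interior_minimum
                summary["ck_max_negative_divergence_K"] = float(
                    div.table["divergence_K"].min())

        if config.ri_scan is not None:
            name = stage("tg_refractometry")
            scan = read_ri_scan_csv(config.ri_scan)
            res = tg_from_bilinear(scan, exclusion_halfwidth=config.exclusion_halfwidth)
            summary["tg_refractometry_K"] = res.tg

        if config.dsc is not None:
            name = stage("tg_dsc")
            dsc = read_dsc_csv(config.dsc)
            tg, step = tg_from_dsc_step(dsc)
            summary["tg_dsc_K"] = tg
            summary["dsc_step_height_W_per_g"] = step
    except PipelineStageError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise PipelineStageError(name, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
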