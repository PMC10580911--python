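"""CSV / YAML / JSON file interfaces.

Schemas (headers mandatory):

* progress curves — ``curve_id, time_s, a410, inhibitor_nM``
* ITC heats — ``injection, volume_uL, heat_uJ`` (+ optional ``blank_heat_uJ``)
* DSF melts — ``temperature_C, fluorescence, replicate_id``

Values are converted to SI on read (nM -> M, uL -> L, uJ -> J).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .progress import ProgressCurve, ProgressFitResult, HendersonResult
from .itc import TitrationDesign, InjectionHeats, BindingFit
from .dsf import MeltCurve, MeltFitResult

__all__ = [
    "read_progress_csv", "write_progress_csv",
    "read_itc_csv", "write_itc_csv", "read_titration_config",
    "read_melt_csv", "write_melt_csv",
    "progress_fits_frame", "henderson_to_dict", "binding_fit_to_dict",
    "melt_fits_to_dict",
]

_PROGRESS_COLS = ["curve_id", "time_s", "a410", "inhibitor_nM"]
_ITC_COLS = ["injection", "volume_uL", "heat_uJ"]
_MELT_COLS = ["temperature_C", "fluorescence", "replicate_id"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")


def read_progress_csv(path) -> list[ProgressCurve]:
    """Read progress curves grouped by curve_id, sorted by time."""
    df = pd.read_csv(path)
    _require_columns(df, _PROGRESS_COLS, path)
    bad = df[_PROGRESS_COLS].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()    # +2: header + 0-based
        raise DataError(f"{path}: NaN/missing values at file row(s) {rows}")
    dup = df.duplicated(subset=["curve_id", "time_s"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise DataError(f"{path}: duplicate (curve_id, time) at row(s) {rows}")
    curves = []
    for cid, grp in df.groupby("curve_id", sort=True):
        grp = grp.sort_values("time_s")
        its = grp["inhibitor_nM"].unique()
        if len(its) != 1:
            raise DataError(f"{path}: curve {cid} has varying inhibitor_nM")
        curves.append(ProgressCurve(
            str(cid), float(its[0]) * 1e-9,
            grp["time_s"].to_numpy(float), grp["a410"].to_numpy(float)))
    return curves


def write_progress_csv(curves: list[ProgressCurve], path) -> None:
    frames = [pd.DataFrame({
        "curve_id": c.curve_id, "time_s": c.times, "a410": c.signal,
        "inhibitor_nM": c.inhibitor_conc * 1e9}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_itc_csv(path) -> InjectionHeats:
    df = pd.read_csv(path)
    _require_columns(df, _ITC_COLS, path)
    df = df.sort_values("injection")
    heats = df["heat_uJ"].to_numpy(float) * 1e-6
    blank = (df["blank_heat_uJ"].to_numpy(float) * 1e-6
             if "blank_heat_uJ" in df.columns else None)
    return InjectionHeats(heats, blank)


def write_itc_csv(heats: InjectionHeats, design: TitrationDesign, path) -> None:
    df = pd.DataFrame({
        "injection": np.arange(1, heats.n_injections + 1),
        "volume_uL": np.asarray(design.injection_volumes) * 1e6,
        "heat_uJ": heats.heats * 1e6})
    if heats.blank_heats is not None:
        df["blank_heat_uJ"] = heats.blank_heats * 1e6
    df.to_csv(path, index=False)


def read_titration_config(path) -> TitrationDesign:
    """YAML/JSON config with cell_volume_uL, cell_conc_uM, syringe_conc_uM,
    injection_volume_uL, n_injections, temperature_C."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return TitrationDesign.uniform(
        cell_volume=doc["cell_volume_uL"] * 1e-6,
        cell_conc=doc["cell_conc_uM"] * 1e-6,
        syringe_conc=doc["syringe_conc_uM"] * 1e-6,
        n_injections=int(doc["n_injections"]),
        injection_volume=doc["injection_volume_uL"] * 1e-6,
        temperature=doc.get("temperature_C", 25.0))


def read_melt_csv(path) -> list[MeltCurve]:
    df = pd.read_csv(path)
    _require_columns(df, _MELT_COLS, path)
    curves = []
    for rid, grp in df.groupby("replicate_id", sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(MeltCurve(grp["temperature_C"].to_numpy(float),
                                grp["fluorescence"].to_numpy(float), str(rid)))
    return curves


def write_melt_csv(curves: list[MeltCurve], path) -> None:
    frames = [pd.DataFrame({
        "temperature_C": c.temperatures, "fluorescence": c.fluorescence,
        "replicate_id": c.replicate_id}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def progress_fits_frame(fits: list[ProgressFitResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "curve_id": f.curve_id, "inhibitor_nM": f.inhibitor_conc * 1e9,
        "v0_abs_per_s": f.v0, "vs_abs_per_s": f.vs, "k_per_s": f.k,
        "A0": f.A0, "gamma": f.gamma, "residual_rms": f.residual_rms,
        "converged": f.converged, "k_identifiable": f.k_identifiable,
        "n_points": f.n_points} for f in fits])


def henderson_to_dict(res: HendersonResult) -> dict:
    return {
        "ki_app_nM": res.ki_app * 1e9,
        "intercept_nM": res.intercept * 1e9,
        "r_squared": res.r_squared,
        "slope_stderr_nM": res.slope_stderr * 1e9,
        "n_curves": res.n_curves,
        "points": res.points,
    }


def binding_fit_to_dict(fit: BindingFit) -> dict:
    return {
        "n_sites": fit.n_sites,
        "kd_nM": fit.kd * 1e9,
        "delta_h_kJ_mol": fit.delta_h / 1e3,
        "c_value": fit.c_value,
        "residual_rms_uJ": fit.residual_rms * 1e6,
        "converged": fit.converged,
        "conditioning_warning": fit.conditioning_warning,
        "no_binding": fit.no_binding,
    }


def melt_fits_to_dict(fits: list[MeltFitResult]) -> dict:
    tms = [f.tm for f in fits if np.isfinite(f.tm)]
    return {
        "replicates": [{
            "tm_C": f.tm, "width_C": f.width, "method": f.method,
            "converged": f.converged} for f in fits],
        "tm_mean_C": float(np.mean(tms)) if tms else None,
        "tm_sd_C": float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0,
    }


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
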