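"""CSV schemas, configuration loading and the end-to-end uptake pipeline.

CSV schemas (comma-separated, UTF-8, header row):

* time course: ``time_s, value, value_type`` (+ optional ``replicate``,
  ``condition``), value_type in {nmol, cpm};
* rate table:  ``conc_mM, rate`` (+ optional ``replicate``);
* dose-response: ``conc_M, signal_cpm, background_cpm``;
* current-voltage: ``voltage_mV, current_pA``.

The pipeline runs geometry -> internal concentration -> fold accumulation
-> phenotype call and reports every intermediate so the whole worked chain
can be audited line by line.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import accumulation as acc
from .accumulation import PhenotypeReport, UptakeTimeCourse
from .electro import IVTable
from .geometry import AssaySpec, GeometryResult, LiposomeSpec, internal_volume
from .kinetics import DoseResponse, RateTable
from .units import NMOL_TO_MOL

REPORT_VERSION = 1


class SchemaError(ValueError):
    """Raised when an input table or config does not match its schema."""


_SCHEMAS = {
    "timecourse": {"required": ["time_s", "value", "value_type"], "optional": ["replicate", "condition"]},
    "rates": {"required": ["conc_mM", "rate"], "optional": ["replicate"]},
    "dose_response": {"required": ["conc_M", "signal_cpm", "background_cpm"], "optional": []},
    "iv": {"required": ["voltage_mV", "current_pA"], "optional": []},
}


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _check_columns(df: pd.DataFrame, schema_name: str, path) -> None:
    schema = _SCHEMAS[schema_name]
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for schema "
            f"{schema_name!r}; found {list(df.columns)}"
        )


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna()].tolist()
    if bad:
        raise SchemaError(f"{path}: non-numeric values in column {col!r} at rows {bad}")
    return vals.to_numpy(dtype=float)


def load_table(path, schema_name: str):
    """Load and validate a CSV table, returning the matching typed container.

    schema_name is one of ``timecourse``, ``rates``, ``dose_response``,
    ``iv``. Errors name the offending columns or rows.
    """
    if schema_name not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; choose from {sorted(_SCHEMAS)}")
    df = _read_csv(path)
    _check_columns(df, schema_name, path)

    if schema_name == "timecourse":
        units = df["value_type"].astype(str).str.strip().unique()
        if len(units) != 1 or units[0] not in ("nmol", "cpm"):
            raise SchemaError(
                f"{path}: value_type must be a single value 'nmol' or 'cpm', got {list(units)}"
            )
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        cond = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
        return UptakeTimeCourse(
            times=_numeric(df, "time_s", path),
            amounts=_numeric(df, "value", path),
            amount_unit=units[0],
            replicate_ids=rep,
            condition=cond,
        )
    if schema_name == "rates":
        return RateTable(
            substrate_conc=_numeric(df, "conc_mM", path),
            rate=_numeric(df, "rate", path),
        )
    if schema_name == "dose_response":
        return DoseResponse(
            ligand_conc=_numeric(df, "conc_M", path),
            signal=_numeric(df, "signal_cpm", path),
            background=_numeric(df, "background_cpm", path),
        )
    return IVTable(
        voltage=_numeric(df, "voltage_mV", path),
        current=_numeric(df, "current_pA", path),
    )


def write_timecourse_csv(tc: UptakeTimeCourse, path) -> None:
    """Write an uptake time course in the ``timecourse`` CSV schema."""
    df = pd.DataFrame({"time_s": tc.times, "value": tc.amounts, "value_type": tc.amount_unit})
    if tc.replicate_ids is not None:
        df["replicate"] = tc.replicate_ids
    if tc.condition:
        df["condition"] = tc.condition
    df.to_csv(path, index=False, float_format="%.12g")


def write_rates_csv(rt: RateTable, path) -> None:
    pd.DataFrame({"conc_mM": rt.substrate_conc, "rate": rt.rate}).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_dose_response_csv(dr: DoseResponse, path) -> None:
    pd.DataFrame(
        {"conc_M": dr.ligand_conc, "signal_cpm": dr.signal, "background_cpm": dr.background}
    ).to_csv(path, index=False, float_format="%.12g")


def write_iv_csv(iv: IVTable, path) -> None:
    pd.DataFrame({"voltage_mV": iv.voltage, "current_pA": iv.current}).to_csv(
        path, index=False, float_format="%.12g"
    )


@dataclass
class PipelineConfig:
    """Validated configuration of one uptake-analysis run."""

    liposome: LiposomeSpec
    assay: AssaySpec
    channel_threshold: float = acc.DEFAULT_CHANNEL_THRESHOLD
    coupled_threshold: float = acc.DEFAULT_COUPLED_THRESHOLD
    plateau_n: int = 2
    coupled_baseline: Optional[float] = None


_LIPOSOME_KEYS = {"r_outer", "m_membrane", "a_headgroup", "lipid_mw"}
_ASSAY_KEYS = {
    "lipid_mass", "assay_volume", "external_conc",
    "specific_activity", "counting_efficiency", "protein_mass",
}
_TOP_KEYS = {"liposome", "assay", "thresholds", "plateau_n", "coupled_baseline"}
_THRESHOLD_KEYS = {"channel", "coupled"}


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain mapping, rejecting unknown keys."""
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config root")
    for section in ("liposome", "assay"):
        if section not in raw:
            raise SchemaError(f"config missing required section {section!r}")
        if not isinstance(raw[section], dict):
            raise SchemaError(f"config section {section!r} must be a mapping")
    _reject_unknown(raw["liposome"], _LIPOSOME_KEYS, "liposome section")
    _reject_unknown(raw["assay"], _ASSAY_KEYS, "assay section")
    thresholds = raw.get("thresholds", {})
    _reject_unknown(thresholds, _THRESHOLD_KEYS, "thresholds section")
    try:
        liposome = LiposomeSpec(**raw["liposome"])
        assay = AssaySpec(**raw["assay"])
    except TypeError as exc:
        raise SchemaError(f"config field error: {exc}") from exc
    return PipelineConfig(
        liposome=liposome,
        assay=assay,
        channel_threshold=float(thresholds.get("channel", acc.DEFAULT_CHANNEL_THRESHOLD)),
        coupled_threshold=float(thresholds.get("coupled", acc.DEFAULT_COUPLED_THRESHOLD)),
        plateau_n=int(raw.get("plateau_n", 2)),
        coupled_baseline=raw.get("coupled_baseline"),
    )


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML (.yml/.yaml) or TOML (.toml) file."""
    path = Path(path)
    if path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    else:
        raw = yaml.safe_load(path.read_text())
    return config_from_dict(raw)


def run_pipeline(config: PipelineConfig, tc: UptakeTimeCourse) -> dict:
    """Geometry -> accumulation -> classification, with all intermediates.

    Returns a versioned report dict; every numeric entry carries a unit
    string. Counts-mode time courses are converted to moles first (this is
    where missing radiochemistry configuration surfaces as an error).
    """
    geom = internal_volume(config.assay, config.liposome)
    peak, plateau, peak_time, peak_sem, plateau_sem = acc.summarize_time_course(
        tc, plateau_n=config.plateau_n
    )
    if tc.amount_unit == "cpm":
        peak_mol = acc.counts_to_moles(peak, config.assay)
        plateau_mol = acc.counts_to_moles(plateau, config.assay)
    else:
        peak_mol = peak * NMOL_TO_MOL
        plateau_mol = plateau * NMOL_TO_MOL
    c_peak = acc.internal_concentration(peak_mol, geom.v_internal)
    c_plateau = acc.internal_concentration(plateau_mol, geom.v_internal)
    report = acc.classify_phenotype(
        c_peak, c_plateau, config.assay.external_conc,
        channel_threshold=config.channel_threshold,
        coupled_threshold=config.coupled_threshold,
        coupled_baseline=config.coupled_baseline,
        peak_time=peak_time, peak_sem=peak_sem, plateau_sem=plateau_sem,
    )
    return {
        "report_version": REPORT_VERSION,
        "geometry": geom.as_dict(),
        "uptake": {
            "peak_amount": {"value": peak, "unit": tc.amount_unit},
            "plateau_amount": {"value": plateau, "unit": tc.amount_unit},
            "peak_time": {"value": peak_time, "unit": "s"},
            "peak_sem": {"value": peak_sem, "unit": tc.amount_unit},
            "plateau_sem": {"value": plateau_sem, "unit": tc.amount_unit},
            "external_conc": {"value": config.assay.external_conc, "unit": "mM"},
        },
        "phenotype": report.as_dict(),
    }
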