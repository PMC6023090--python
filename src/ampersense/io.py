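"""File formats and run configuration.

CSV dialect: comma-separated, dot decimal, UTF-8, one header row, units
encoded in column names (``current_A`` vs ``current_uA``); a leading
``# nrows=N`` comment guards against silently truncated files.  Reports
and ground-truth sidecars are JSON.  Configuration is YAML or JSON,
validated by pydantic with unknown keys rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError, TraceFormatError
from .synthetic_data import AmpTruth, CellSpec, GridConfig, Kinetics, RedoxSpecies, ScanProgram
from .quantification import SamplePrep
from .traces import AmperogramTrace, InjectionEvent, InjectionSchedule, VoltammogramTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "write_truth_json",
    "RunConfig",
    "load_config",
    "Report",
]

_UNIT_SCALE = {
    "A": 1.0,
    "mA": 1e-3,
    "uA": 1e-6,
    "nA": 1e-9,
    "V": 1.0,
    "mV": 1e-3,
    "s": 1.0,
    "ms": 1e-3,
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
}


def _find_column(df: pd.DataFrame, stem: str) -> tuple[str, float]:
    """Locate ``stem_<unit>`` among the columns and return (name, scale to SI)."""
    for col in df.columns:
        if col == stem or col.startswith(stem + "_"):
            unit = col[len(stem) + 1 :] if col != stem else ""
            if unit == "":
                return col, 1.0
            if unit not in _UNIT_SCALE:
                raise TraceFormatError(f"column {col!r}: unknown unit suffix {unit!r}")
            return col, _UNIT_SCALE[unit]
    raise TraceFormatError(f"missing column {stem}_<unit>; found {list(df.columns)}")


def _read_checked_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"no such file: {path}")
    declared = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "nrows=" in first:
            declared = int(first.split("nrows=")[1].strip())
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if declared is not None and len(df) != declared:
        raise TraceFormatError(
            f"{path}: declares {declared} rows but contains {len(df)} (truncated file?)"
        )
    return df


def read_trace_csv(
    path: str | Path,
    kind: Literal["cv", "amperometry"],
    scan_rate: float | None = None,
    schedule: InjectionSchedule | None = None,
) -> VoltammogramTrace | AmperogramTrace:
    """Read a trace CSV, normalizing units to the internal convention (V, A, s).

    CV files carry ``potential_V`` (or _mV), ``current_A`` (or _uA...) and
    optionally ``cycle``; the scan rate is not part of the file and must
    be supplied.  Amperometry files carry ``time_s`` and a current column.
    """
    df = _read_checked_csv(path)
    if kind == "cv":
        pcol, pscale = _find_column(df, "potential")
        ccol, cscale = _find_column(df, "current")
        if scan_rate is None:
            raise TraceFormatError("scan_rate is required when reading a CV trace")
        cycle = df["cycle"].to_numpy() if "cycle" in df.columns else None
        return VoltammogramTrace(
            potential=df[pcol].to_numpy() * pscale,
            current=df[ccol].to_numpy() * cscale,
            scan_rate=scan_rate,
            cycle=cycle,
            metadata={"source": str(path)},
        )
    if kind == "amperometry":
        tcol, tscale = _find_column(df, "time")
        ccol, cscale = _find_column(df, "current")
        return AmperogramTrace(
            time=df[tcol].to_numpy() * tscale,
            current=df[ccol].to_numpy() * cscale,
            schedule=schedule,
            metadata={"source": str(path)},
        )
    raise TraceFormatError(f"unknown trace kind {kind!r}")


def write_trace_csv(trace: VoltammogramTrace | AmperogramTrace, path: str | Path) -> None:
    """Write a trace in the package CSV dialect with the row-count guard."""
    path = Path(path)
    if isinstance(trace, VoltammogramTrace):
        df = pd.DataFrame(
            {
                "potential_V": trace.potential,
                "current_A": trace.current,
                "cycle": trace.cycle if trace.cycle is not None else 1,
            }
        )
    else:
        df = pd.DataFrame({"time_s": trace.time, "current_A": trace.current})
    with open(path, "w") as fh:
        fh.write(f"# nrows={len(df)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_schedule_csv(path: str | Path) -> InjectionSchedule:
    df = _read_checked_csv(path)
    tcol, tscale = _find_column(df, "time")
    ccol, cscale = _find_column(df, "delta_conc")
    analyte = df["analyte"] if "analyte" in df.columns else ["histamine"] * len(df)
    return InjectionSchedule(
        tuple(
            InjectionEvent(float(t) * tscale, str(a), float(c) * cscale)
            for t, a, c in zip(df[tcol], analyte, df[ccol])
        )
    )


def write_schedule_csv(schedule: InjectionSchedule, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": [e.time for e in schedule.events],
            "analyte": [e.analyte for e in schedule.events],
            "delta_conc_M": [e.delta_conc for e in schedule.events],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# nrows={len(df)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):  # NaN
        return None
    return obj


def write_truth_json(trace: VoltammogramTrace | AmperogramTrace, path: str | Path) -> None:
    """Ground-truth sidecar for a synthetic trace."""
    with open(path, "w") as fh:
        json.dump(_jsonable(dict(trace.metadata)), fh, indent=2)


# --------------------------------------------------------------------------
# configuration


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CellConfig(_Strict):
    n: int = 1
    temperature_K: float = 298.15
    area_cm2: float = 0.12
    e_formal_V: float = 0.0

    def build(self) -> CellSpec:
        return CellSpec(self.n, self.temperature_K, self.area_cm2, self.e_formal_V)


class SpeciesConfig(_Strict):
    d_ox_cm2_s: float = 7.6e-6
    d_red_cm2_s: float = 7.6e-6
    c_bulk_mM: float = 4.0

    def build(self) -> RedoxSpecies:
        # mol/L (mM*1e-3) -> mol/cm^3 (/1000)
        return RedoxSpecies(self.d_ox_cm2_s, self.d_red_cm2_s, self.c_bulk_mM * 1e-6)


class KineticsConfig(_Strict):
    k0_cm_s: float = 3e-3
    alpha: float = 0.5

    def build(self) -> Kinetics:
        return Kinetics(self.k0_cm_s, self.alpha)


class ProgramConfig(_Strict):
    e_start_V: float = -1.0
    e_switch_V: float = 1.0
    scan_rate_mV_s: float = 100.0
    n_cycles: int = 1

    def build(self) -> ScanProgram:
        return ScanProgram(self.e_start_V, self.e_switch_V, self.scan_rate_mV_s * 1e-3, self.n_cycles)


class GridConfigModel(_Strict):
    n_space: int = 150
    n_time: int = 2400
    domain_factor: float = 6.0
    scheme: str = "crank_nicolson"

    def build(self) -> GridConfig:
        return GridConfig(self.n_space, self.n_time, self.domain_factor, self.scheme)


class AmpTruthConfig(_Strict):
    baseline_uA: float = 10.0
    sensitivity_uA_mM: float = 23.3
    tau_s: float = 2.44
    c_sat_mM: float = 1.6
    noise_uA: float = 0.0903
    drift_uA_s: float = 1e-4

    def build(self) -> AmpTruth:
        return AmpTruth(
            baseline_i0=self.baseline_uA * 1e-6,
            sensitivity=self.sensitivity_uA_mM * 1e-6 / 1e-3,
            tau=self.tau_s,
            c_sat=self.c_sat_mM * 1e-3,
            noise_sigma=self.noise_uA * 1e-6,
            drift=self.drift_uA_s * 1e-6,
        )


class PrepConfig(_Strict):
    sample_mass_g: float = 1.0
    diluent_volume_mL: float = 9.0
    injection_volume_uL: float = 5.0
    cell_volume_mL: float = 10.0
    mw_g_mol: float = 111.15
    include_sample_volume: bool = False

    def build(self) -> SamplePrep:
        return SamplePrep(
            self.sample_mass_g,
            self.diluent_volume_mL,
            self.injection_volume_uL,
            self.cell_volume_mL,
            self.mw_g_mol,
            self.include_sample_volume,
        )


class ScheduleConfig(_Strict):
    start_s: float = 120.0
    interval_s: float = 60.0
    n_injections: int = 30
    delta_conc_mM: float = 0.1
    analyte: str = "histamine"

    def build(self) -> InjectionSchedule:
        return InjectionSchedule.uniform(
            self.start_s, self.interval_s, self.n_injections, self.delta_conc_mM * 1e-3, self.analyte
        )


class ThresholdConfig(_Strict):
    linear_range_r2: float = 0.99
    max_rel_deviation: float = 0.05
    blank_window_s: float = 60.0


class SampleRunConfig(_Strict):
    sample_ba_mg_kg: float = 19.24
    peak_decay_tau_s: float = 60.0
    mixing_volume_uL: float = 0.22
    n_injections: int = 3
    interval_s: float = 960.0
    start_s: float = 120.0


class RunConfig(_Strict):
    """Top-level, schema-validated run configuration (unknown keys rejected)."""

    cell: CellConfig = CellConfig()
    species: SpeciesConfig = SpeciesConfig()
    kinetics: KineticsConfig = KineticsConfig()
    program: ProgramConfig = ProgramConfig()
    grid: GridConfigModel = GridConfigModel()
    amp_truth: AmpTruthConfig = AmpTruthConfig()
    prep: PrepConfig = PrepConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    sample_run: SampleRunConfig = SampleRunConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    duration_s: float | None = None
    sample_rate_Hz: float = 10.0
    seed: int = 0
    out_dir: str = "."

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


class CvTraceEntry(_Strict):
    path: str
    scan_rate_mV_s: float


class CvManifest(_Strict):
    """Input manifest for CV analysis: trace files plus cell/species context."""

    cell: CellConfig = CellConfig()
    species: SpeciesConfig = SpeciesConfig()
    alpha: float = 0.5
    branch: str = "anodic"
    traces: list[CvTraceEntry]


def load_manifest(path: str | Path) -> CvManifest:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such manifest: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    try:
        return CvManifest.model_validate(data or {})
    except ValidationError as exc:
        paths = "; ".join(
            "->".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid manifest {path}: {paths}") from exc


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML or JSON config; missing path gives all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    try:
        return RunConfig.model_validate(data or {})
    except ValidationError as exc:
        paths = "; ".join(
            "->".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {paths}") from exc


@dataclass
class Report:
    """Self-describing result envelope: enough metadata to re-run bit-identically."""

    command: str
    config_digest: str
    seed: int
    results: dict[str, Any]
    input_digests: dict[str, str]
    warnings: list[str]
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(_jsonable(asdict(self)), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
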