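"""Time-course containers, CSV/JSON/TSV readers and writers, configuration.

The on-disk time-course format is a plain comma-separated file with a
header row: a mandatory ``time`` column (h), one biomass column named
either ``od600`` or ``biomass`` (the latter in gDW/L), and any number of
metabolite columns in mM. Empty cells are missing values. OD600 is
converted to gDW/L at read time via a strain-specific factor
(0.37 gDW per OD600 unit by default).
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError

__all__ = [
    "TimeCourse",
    "RunConfig",
    "OD_TO_GDW_DEFAULT",
    "read_timecourse",
    "write_timecourse",
    "aggregate_replicates",
    "provenance_record",
]

#: gDW/L per OD600 unit for E. coli under the study conditions.
OD_TO_GDW_DEFAULT = 0.37

_BIOMASS_COLUMNS = {"od600": "od600", "biomass": "gdw_per_l"}


@dataclass
class TimeCourse:
    """Observed (or simulated) batch time course.

    times are strictly increasing hours; biomass carries a unit tag
    (``"od600"`` or ``"gdw_per_l"``); metabolite series are mM. NaN marks a
    missing observation.
    """

    times: np.ndarray
    biomass: np.ndarray
    biomass_unit: str = "gdw_per_l"
    metabolites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise InputError("times must be a non-empty 1-D array")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if self.biomass.shape != self.times.shape:
            raise InputError("biomass length must match times")
        if self.biomass_unit not in ("od600", "gdw_per_l"):
            raise InputError(f"unknown biomass unit {self.biomass_unit!r}")
        for name, series in self.metabolites.items():
            self.metabolites[name] = s = np.asarray(series, dtype=float)
            if s.shape != self.times.shape:
                raise InputError(f"metabolite column {name!r} length must match times")

    @property
    def metabolite_names(self) -> tuple[str, ...]:
        return tuple(self.metabolites)

    def in_gdw(self, factor: float = OD_TO_GDW_DEFAULT) -> "TimeCourse":
        """Return a copy with biomass in gDW/L (no-op if already converted)."""
        if self.biomass_unit == "gdw_per_l":
            return self
        if factor <= 0:
            raise InputError(f"OD-to-gDW factor must be > 0, got {factor}")
        return replace(
            self,
            biomass=self.biomass * factor,
            biomass_unit="gdw_per_l",
            metabolites=dict(self.metabolites),
        )

    def to_frame(self) -> pd.DataFrame:
        biomass_col = "od600" if self.biomass_unit == "od600" else "biomass"
        data = {"time": self.times, biomass_col: self.biomass}
        data.update(self.metabolites)
        return pd.DataFrame(data)


def read_timecourse(path, od_to_gdw: float = OD_TO_GDW_DEFAULT, convert: bool = True) -> TimeCourse:
    """Read a time-course CSV; OD600 biomass is converted to gDW/L.

    Pass ``convert=False`` to keep the biomass in its on-disk unit.
    """
    path = Path(path)
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            header = next(csv.reader(fh), None)
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise InputError(f"{path}: cannot parse CSV: {exc}") from exc

    # pandas silently renames duplicate header fields, so check the raw header
    if header is None:
        raise InputError(f"{path}: empty file")
    if len(set(header)) != len(header):
        raise InputError(f"{path}: duplicate columns in header {header}")
    cols = list(df.columns)
    if "time" not in cols:
        raise InputError(f"{path}: required column 'time' missing (have {cols})")
    biomass_cols = [c for c in cols if c in _BIOMASS_COLUMNS]
    if len(biomass_cols) != 1:
        raise InputError(
            f"{path}: need exactly one biomass column ('od600' or 'biomass'), found {biomass_cols}"
        )
    bcol = biomass_cols[0]

    for col in cols:
        bad = df[col].apply(lambda v: not (pd.isna(v) or isinstance(v, (int, float))))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, data row {row}"
            )
    if df["time"].isna().any():
        raise InputError(f"{path}: missing values in 'time' column")

    tc = TimeCourse(
        times=df["time"].to_numpy(float),
        biomass=df[bcol].to_numpy(float),
        biomass_unit=_BIOMASS_COLUMNS[bcol],
        metabolites={c: df[c].to_numpy(float) for c in cols if c not in ("time", bcol)},
    )
    return tc.in_gdw(od_to_gdw) if convert else tc


def write_timecourse(tc: TimeCourse, path) -> None:
    tc.to_frame().to_csv(path, index=False)


def aggregate_replicates(results: list) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of parameters across replicates.

    Accepts FitResult objects (anything with a ``parameter_series`` method
    returning name -> estimate) or plain mappings. Replicates must share
    the same parameter names. This is the biological-replicate spread, a
    different quantity from the parametric-bootstrap SD of a single fit;
    outputs label it ``sd_across_replicates``.
    """
    if len(results) < 2:
        raise InputError("need >= 2 replicates to aggregate")
    rows = []
    for r in results:
        if hasattr(r, "parameter_series"):
            rows.append(dict(r.parameter_series()))
        elif isinstance(r, dict):
            rows.append(dict(r))
        else:
            raise InputError(f"cannot aggregate object of type {type(r).__name__}")
    keys = list(rows[0])
    for i, row in enumerate(rows[1:], start=2):
        if list(row) != keys:
            raise InputError(
                f"replicate {i} parameters {list(row)} do not match {keys}"
            )
    mat = pd.DataFrame(rows)
    return pd.DataFrame(
        {
            "parameter": keys,
            "mean": mat.mean(axis=0).to_numpy(),
            "sd_across_replicates": mat.std(axis=0, ddof=1).to_numpy(),
            "n": len(rows),
        }
    )


@dataclass
class RunConfig:
    """Run-wide configuration loaded from a YAML key-value file."""

    od_to_gdw: float = OD_TO_GDW_DEFAULT
    carbon_counts: dict[str, int] = field(default_factory=dict)
    degradation_constants: dict[str, float] = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    fba: dict = field(default_factory=dict)
    log_level: str = "INFO"
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.od_to_gdw <= 0:
            raise InputError(f"od_to_gdw must be > 0, got {self.od_to_gdw}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InputError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance_record(config: RunConfig | None, seed: int | None, command: str) -> dict:
    """Machine-readable provenance: version, config hash, seed, command."""
    from . import __version__

    return {
        "package": "dhaflux",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_sha256_16": config.digest() if config is not None else None,
        "timestamp_utc": pd.Timestamp.utcnow().isoformat(),
    }
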