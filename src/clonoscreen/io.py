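"""CSV schemas, unit parsing, run configuration and result writing.

Concentrations are stored internally in molar and accepted either as plain
numbers (``1e-9``) or unit-suffixed strings (``1nM``, ``100 pM``, ``10uM``).
Well tables are long-format CSVs with a fixed header; parsing is strict and
reports every malformed row with its line number. JSON summaries carry the
package version and a hash of the configuration that produced them so runs
are traceable.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "parse_concentration",
    "format_concentration",
    "read_well_table",
    "write_well_table",
    "write_json_result",
    "RunConfig",
]

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6,
               "nm": 1e-9, "pm": 1e-12, "fm": 1e-15}
_CONC_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([a-zA-Zµμ]*)\s*$")

WELL_COLUMNS = ["plate_id", "well", "drug_id", "concentration",
                "radiation_dose", "replicate", "colony_count"]


def parse_concentration(text) -> float:
    """Parse a concentration to molar; accepts '1e-9', '1nM', '100 pM'."""
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return float(text)
    m = _CONC_RE.match(str(text))
    if not m:
        raise ValueError(f"cannot parse concentration {text!r}")
    value, unit = float(m.group(1)), m.group(2).lower()
    if unit == "":
        return value
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown concentration unit {unit!r} in {text!r}")
    return value * _UNIT_SCALE[unit]


def format_concentration(molar: float) -> str:
    """Render a molar concentration in the most natural suffixed unit."""
    if not np.isfinite(molar):
        return ""
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6),
                        ("nM", 1e-9), ("pM", 1e-12)):
        if abs(molar) >= scale:
            return f"{molar / scale:g}{unit}"
    return f"{molar / 1e-12:g}pM"


def read_well_table(path) -> pd.DataFrame:
    """Read a long-format well-count CSV with strict validation.

    Required header: ``plate_id, well, drug_id, concentration,
    radiation_dose, replicate, colony_count``. Empty concentration means a
    control / radiation-only well. All malformed rows are collected and
    reported together with their line numbers.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in WELL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rows, errors = [], []
    for i, rec in raw.iterrows():
        line = i + 2  # 1-based, after header
        try:
            conc = (np.nan if rec["concentration"].strip() == ""
                    else parse_concentration(rec["concentration"]))
            dose = float(rec["radiation_dose"])
            count = int(rec["colony_count"])
            if count < 0:
                raise ValueError("negative colony count")
            rows.append({"plate_id": rec["plate_id"], "well": rec["well"],
                         "drug_id": rec["drug_id"], "concentration": conc,
                         "radiation_dose": dose,
                         "replicate": int(rec["replicate"]),
                         "colony_count": count})
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed rows:\n"
                         + "\n".join(errors))
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


def write_well_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["concentration"] = [
        "" if not np.isfinite(c) else f"{c:.6g}"
        for c in out["concentration"]]
    out.to_csv(path, index=False, columns=WELL_COLUMNS)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_json_result(payload: dict, path, config: dict | None = None) -> None:
    """Write a JSON summary stamped with package version and config hash."""
    from . import __version__
    meta = {"clonoscreen_version": __version__}
    if config is not None:
        meta["config_hash"] = config_hash(config)
    doc = {"meta": meta, **payload}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


_RUN_KEYS = {"assay", "inputs", "out_dir", "seed", "hit_threshold",
             "min_mean", "icx_levels", "ser_level", "params"}


@dataclass
class RunConfig:
    """Validated pipeline run configuration.

    Unknown keys in the source mapping are rejected outright — a misspelled
    threshold silently falling back to a default is worse than an error.
    """

    assay: str
    inputs: dict = field(default_factory=dict)
    out_dir: str = "."
    seed: int = 0
    hit_threshold: float = 1.5
    min_mean: float = 3.0
    icx_levels: tuple[float, ...] = (30.0, 50.0)
    ser_level: float = 0.1
    params: dict = field(default_factory=dict)

    _ASSAYS = ("screen", "cck8", "clonogenic", "flow_apoptosis",
               "flow_cellcycle", "growth", "imaging")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _RUN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "assay" not in data:
            raise ValueError("config missing required key: 'assay'")
        cfg = cls(**data)
        if cfg.assay not in cls._ASSAYS:
            raise ValueError(f"unknown assay {cfg.assay!r}; "
                             f"expected one of {cls._ASSAYS}")
        if not all(0 < x < 100 for x in cfg.icx_levels):
            raise ValueError("icx_levels must lie in (0, 100)")
        if not 0 < cfg.ser_level < 1:
            raise ValueError("ser_level must lie in (0, 1)")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        if "icx_levels" in data:
            data["icx_levels"] = tuple(data["icx_levels"])
        return cls.from_mapping(data)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["icx_levels"] = list(self.icx_levels)
        return d
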