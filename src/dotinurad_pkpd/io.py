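"""Table and configuration I/O.

CSV dialects (decimal-point, blank for missing):

plasma : subject_id, dose_mg, time_h, conc_ng_ml, blq, fed, day
urine  : subject_id, t_start_h, t_end_h, volume_ml, urate_mg_dl,
         creat_mg_dl, drug_ng_ml
sua    : subject_id, time_h, sua_mg_dl, screat_mg_dl

Validation is strict on required columns and per-subject time monotonicity;
unknown columns are preserved with a warning.  Round trips are lossless
(pandas writes shortest-repr floats).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .synthetic import NoiseConfig, PopulationConfig, StudyConfig, StudyDataset

__all__ = [
    "read_plasma",
    "read_urine",
    "read_sua",
    "write_dataset",
    "read_dataset",
    "write_report",
    "load_config",
    "config_hash",
]

PLASMA_COLUMNS = ("subject_id", "dose_mg", "time_h", "conc_ng_ml", "blq",
                  "fed", "day")
URINE_COLUMNS = ("subject_id", "t_start_h", "t_end_h", "volume_ml",
                 "urate_mg_dl", "creat_mg_dl", "drug_ng_ml")
SUA_COLUMNS = ("subject_id", "time_h", "sua_mg_dl", "screat_mg_dl")


def _validate(df: pd.DataFrame, required, name, time_col=None) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{name} table has unknown columns {extra}; preserved",
                      stacklevel=3)
    if time_col is not None:
        bad_rows = []
        for sid, grp in df.groupby("subject_id", sort=False):
            t = grp[time_col].to_numpy()
            bad = grp.index[1:][t[1:] <= t[:-1]]
            bad_rows.extend(bad.tolist())
        if bad_rows:
            raise SchemaError(
                f"{name} table: {time_col} not strictly increasing per "
                f"subject at rows {bad_rows[:10]}"
            )
    return df


def read_plasma(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), PLASMA_COLUMNS, "plasma", "time_h")


def read_urine(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), URINE_COLUMNS, "urine", "t_start_h")


def read_sua(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), SUA_COLUMNS, "sua", "time_h")


def write_dataset(ds: StudyDataset, directory) -> Path:
    """Write a study dataset as plasma/urine/sua/subjects/truth CSVs plus a
    meta.json with design and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds.plasma.to_csv(directory / "plasma.csv", index=False)
    ds.urine.to_csv(directory / "urine.csv", index=False)
    ds.sua.to_csv(directory / "sua.csv", index=False)
    ds.subjects.to_csv(directory / "subjects.csv", index=False)
    ds.truth.to_csv(directory / "truth.csv", index=False)
    (directory / "meta.json").write_text(
        json.dumps({"design": ds.design, "seed": ds.seed}, indent=2)
    )
    return directory


def read_dataset(directory) -> StudyDataset:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    return StudyDataset(
        design=meta["design"],
        seed=meta["seed"],
        plasma=read_plasma(directory / "plasma.csv"),
        urine=read_urine(directory / "urine.csv"),
        sua=read_sua(directory / "sua.csv"),
        subjects=pd.read_csv(directory / "subjects.csv"),
        truth=pd.read_csv(directory / "truth.csv"),
        config=None,
    )


def write_report(report, directory) -> Path:
    """Write a pipeline report: report.json plus the tabular pieces."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=float)
    )
    report.nca_by_dose.to_csv(directory / "nca_by_dose.csv", index=False)
    report.effect_points.to_csv(directory / "effect_points.csv", index=False)
    if report.mad_prediction is not None:
        report.mad_prediction.to_csv(directory / "mad_prediction.csv",
                                     index=False)
    return directory


# ---------------------------------------------------------------------------
# configuration

_REQUIRED_SECTIONS = ("population", "noise", "design", "seed")


def load_config(source) -> tuple[StudyConfig, int]:
    """Build a :class:`StudyConfig` (plus the master seed) from a YAML file
    path or an already-parsed mapping.

    The mapping must contain the sections ``population``, ``noise``,
    ``design`` and the key ``seed``; unknown keys inside a section raise so
    typos do not silently fall back to defaults.
    """
    if not isinstance(source, dict):
        source = yaml.safe_load(Path(source).read_text())
    for section in _REQUIRED_SECTIONS:
        if section not in source:
            raise ConfigError(f"config is missing required section {section!r}")

    def build(cls, mapping, section):
        valid = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(mapping) - valid
        if unknown:
            raise ConfigError(
                f"unknown keys in config section {section!r}: {sorted(unknown)}"
            )
        return cls(**mapping)

    population = build(PopulationConfig, source["population"], "population")
    noise = build(NoiseConfig, source["noise"], "noise")
    design = dict(source["design"])
    valid = {f for f in StudyConfig.__dataclass_fields__} - {"population", "noise"}
    unknown = set(design) - valid
    if unknown:
        raise ConfigError(f"unknown keys in config section 'design': {sorted(unknown)}")
    cfg = StudyConfig(population=population, noise=noise, **design)
    return cfg, int(source["seed"])


def config_hash(*objects) -> str:
    """Stable sha256 over the JSON form of configuration dataclasses."""
    import dataclasses

    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    payload = json.dumps([enc(o) for o in objects], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
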