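"""CSV dialects, configuration and result serialization.

Interchange formats are plain CSV with unit-suffixed column names:

in vitro uptake:  animal, well, nominal_conc_uM, time_min, lysate_pmol,
                  protein_mg, censored
deltaR1 profiles: animal, organ, field_T, arm, t_start_s, t_end_s,
                  deltaR1_per_s

Times are seconds in deltaR1 files (frame timing) and hours inside the
PBPK core; parameters and results travel as JSON, configuration as YAML.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mri import DeltaR1Profile
from .params import (GadoxetateParams, PhysiologyParams, RelaxivityTable)

INVITRO_COLUMNS = ("animal", "well", "nominal_conc_uM", "time_min",
                   "lysate_pmol", "protein_mg", "censored")
DELTAR1_COLUMNS = ("animal", "organ", "field_T", "arm", "t_start_s",
                   "t_end_s", "deltaR1_per_s")


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def read_invitro_csv(path) -> pd.DataFrame:
    """Read and validate an in vitro uptake table."""
    df = pd.read_csv(path)
    _check_columns(df, INVITRO_COLUMNS, path)
    for col in ("nominal_conc_uM", "time_min", "lysate_pmol", "protein_mg"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise SchemaError(
                f"{path}: negative {col} at row {int(bad[0])}")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_invitro_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, list(INVITRO_COLUMNS)].to_csv(path, index=False)


def read_deltaR1_csv(path) -> list[DeltaR1Profile]:
    """Read a deltaR1 table into profiles grouped by
    animal/organ/field/arm; frames are sorted and checked for overlap."""
    df = pd.read_csv(path)
    _check_columns(df, DELTAR1_COLUMNS, path)
    profiles = []
    keys = ["animal", "organ", "field_T", "arm"]
    for (animal, organ, fs, arm), g in df.groupby(keys, sort=True):
        g = g.sort_values("t_start_s")
        profiles.append(DeltaR1Profile(
            animal=str(animal), organ=str(organ), field_strength=float(fs),
            arm=str(arm), t_start=g["t_start_s"].to_numpy(float),
            t_end=g["t_end_s"].to_numpy(float),
            deltaR1=g["deltaR1_per_s"].to_numpy(float)))
    return profiles


def profiles_to_frame(profiles: list[DeltaR1Profile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for a, b, v in zip(p.t_start, p.t_end, p.deltaR1):
            rows.append({"animal": p.animal, "organ": p.organ,
                         "field_T": p.field_strength, "arm": p.arm,
                         "t_start_s": a, "t_end_s": b, "deltaR1_per_s": v})
    return pd.DataFrame(rows, columns=list(DELTAR1_COLUMNS))


def write_deltaR1_csv(profiles: list[DeltaR1Profile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def physiology_from_config(cfg: dict) -> PhysiologyParams:
    return PhysiologyParams(**cfg.get("physiology", {}))


def gadoxetate_from_config(cfg: dict, key: str = "drug") -> GadoxetateParams:
    return GadoxetateParams(**cfg.get(key, {}))


def relaxivity_from_config(cfg: dict) -> RelaxivityTable:
    rel = cfg.get("relaxivity")
    if not rel:
        return RelaxivityTable()
    return RelaxivityTable(
        r1_blood={float(k): float(v) for k, v in rel["r1_blood"].items()},
        r1_hepatocytes={float(k): float(v)
                        for k, v in rel["r1_hepatocytes"].items()})


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, seed: int | None,
                   extra: dict | None = None) -> Path:
    """Record config, config hash, seed and software version so a run can
    be reproduced exactly."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": seed,
                "config_hash": config_hash(cfg), "config": cfg}
    manifest.update(extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=_jsonable))
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))
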