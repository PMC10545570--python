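"""Trial-table CSV dialect and TOML configuration round-tripping.

On disk, CTOAs and RTs are stored in milliseconds (CTOA as an integer,
empty for catch trials); in memory RTs are seconds.  Keeping the file keys
integral avoids float-equality drift when cells are grouped by CTOA.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TRIAL_COLUMNS, DesignConfig, EffectParams, NoiseParams

CSV_COLUMNS = ["participant_id", "block", "trial", "ctoa_ms", "validity",
               "is_catch", "responded", "rt_ms"]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the trial table in the canonical CSV dialect."""
    out = trials.copy()
    out["rt_ms"] = out.pop("rt") * 1000.0
    out["is_catch"] = out["is_catch"].astype(int)
    out["responded"] = out["responded"].astype(int)
    out = out[CSV_COLUMNS]
    out.to_csv(path, index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    """Read the canonical trial CSV; returns RT in seconds."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV is missing columns: {missing}")
    df["ctoa_ms"] = df["ctoa_ms"].astype("Int64")
    df["is_catch"] = df["is_catch"].astype(bool)
    df["responded"] = df["responded"].astype(bool)
    df["rt"] = df.pop("rt_ms").astype(float) / 1000.0
    bad = df["responded"] ^ df["rt"].notna()
    if bad.any():
        raise ValueError("rt must be present iff responded")
    return df[TRIAL_COLUMNS]


def _section(obj) -> dict:
    return dataclasses.asdict(obj)


def load_config(path):
    """Read a TOML config with [design], [effect], [noise] sections.

    Missing sections or keys fall back to the dataclass defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    design = DesignConfig(**raw.get("design", {}))
    effect = EffectParams(**raw.get("effect", {}))
    noise = NoiseParams(**raw.get("noise", {}))
    return design, effect, noise, raw


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if v is None:
        return '""'  # TOML has no null; empty string decodes back to None
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return f'"{v}"'


def dump_config(design: DesignConfig, effect: EffectParams,
                noise: NoiseParams, path, extra: dict | None = None) -> None:
    """Write a config TOML that :func:`load_config` reads back losslessly."""
    lines = []
    for name, obj in (("design", design), ("effect", effect),
                      ("noise", noise)):
        lines.append(f"[{name}]")
        for k, v in _section(obj).items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    for name, sec in (extra or {}).items():
        lines.append(f"[{name}]")
        for k, v in sec.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
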