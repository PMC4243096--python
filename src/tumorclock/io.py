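"""Table readers/writers, config handling and packaged reference tables.

Artifacts are TSV (tab-separated, header row, '.' decimal, no thousands
separators) with provenance — package version, resolved configuration and
seed — embedded as leading ``# key: value`` comment lines, so a written
table can be read back into the identical DataFrame plus its metadata.
Scientific notation is normalized to Python's ``2e-05`` style.
"""

from __future__ import annotations

import importlib.resources
import json
from io import StringIO
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "write_tsv",
    "read_tsv",
    "read_timeline_tsv",
    "write_timeline_tsv",
    "load_config",
    "load_fixture_table",
    "ALLOWED_CONFIG_KEYS",
]


class ConfigError(ValueError):
    pass


ALLOWED_CONFIG_KEYS = {
    "mu0",
    "s",
    "a",
    "b",
    "n_cells",
    "generation_time_days",
    "k_max",
    "method",
    "variant",
    "seed",
    "t_end",
    "n_cells_sim",
    "n_reps",
    "noise_sigma",
    "timeline",
    "patient_id",
    "stage_defs",
    # comparison-clock inputs
    "u",
    "d",
    "n_pop",
    "T",
    "k",
    "F",
    "T_founder",
    "n_target_cells",
    "T_gen",
    "r",
}


def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)  # '2e-05', '0.000843' — round-trips exactly
    return str(v)


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    lines = []
    for key, value in (metadata or {}).items():
        if isinstance(value, (dict, list)):
            value = json.dumps(value, sort_keys=True)
        lines.append(f"# {key}: {value}")
    # repr() round-trips doubles exactly; pandas' default float writer does not
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(repr)
    body = out.to_csv(sep="\t", index=False)
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_tsv(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_tsv`; returns (frame, metadata)."""
    text = Path(path).read_text()
    metadata: dict[str, str] = {}
    data_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ": " in stripped:
                key, value = stripped.split(": ", 1)
                metadata[key] = value
        else:
            data_lines.append(line)
    df = pd.read_csv(
        StringIO("\n".join(data_lines)), sep="\t", float_precision="round_trip"
    )
    for col in df.columns:  # blank string cells are not missing numbers
        if df[col].dtype == object:
            df[col] = df[col].fillna("")
    return df, metadata


TIMELINE_COLUMNS = ("stage", "k", "t_years")


def read_timeline_tsv(path):
    """Parse a (stage, k, t_years) timeline, reporting bad rows by line number."""
    from .inference import PatientTimeline, StageObservation

    path = Path(path)
    rows = []
    header = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in TIMELINE_COLUMNS if c not in header]
            if missing:
                raise ValueError(
                    f"{path}:{lineno}: header missing column(s) {missing}"
                )
            continue
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        rec = dict(zip(header, fields))
        try:
            rows.append(
                StageObservation(rec["stage"], int(rec["k"]), float(rec["t_years"]))
            )
        except (KeyError, ValueError) as err:
            raise ValueError(f"{path}:{lineno}: malformed row ({err})") from err
    if header is None:
        raise ValueError(f"{path}: empty timeline file")
    return PatientTimeline(path.stem, tuple(rows))


def write_timeline_tsv(timeline, path, metadata: dict | None = None) -> None:
    write_tsv(timeline.to_frame(), path, metadata)


def load_config(path) -> dict:
    """Flat key-value config from YAML or JSON; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a flat mapping")
    unknown = sorted(set(cfg) - ALLOWED_CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    # YAML 1.1 leaves unsigned-exponent literals like "1.0e10" as strings
    for key, value in cfg.items():
        if isinstance(value, str):
            try:
                cfg[key] = float(value)
            except ValueError:
                pass
    return cfg


def load_fixture_table(name: str) -> pd.DataFrame:
    """Packaged reference table, e.g. ``load_fixture_table('table1')``."""
    resource = importlib.resources.files("tumorclock") / "fixtures" / f"{name}.tsv"
    with importlib.resources.as_file(resource) as fp:
        df, _ = read_tsv(fp)
    return df
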