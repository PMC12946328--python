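"""Reading, writing and validating trial tables.

The canonical on-disk format is a long CSV with one row per
(trial x member x phase): columns group, condition, list, trial, member,
phase {prior, posterior}, choice {option1, option2}, confidence_pct.  A
schema map renames foreign column layouts (e.g. a deposited dataset) onto
this one at read time.  On ingest, 100% ratings are truncated to 99% and
each (group, condition, list, trial) must carry all six reports (three
members x two phases).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .confidence import OPTIONS, encode_percent
from .decision import MEMBERS

__all__ = ["SchemaError", "TrialValidationError", "RunConfig",
           "read_trials", "long_to_wide", "write_table", "config_hash"]

REQUIRED_COLUMNS = ["group", "condition", "list", "trial", "member",
                    "phase", "choice", "confidence_pct"]
TRIAL_KEY = ["group", "condition", "list", "trial"]


class SchemaError(ValueError):
    """The input file does not map onto the required column schema."""


class TrialValidationError(ValueError):
    """Rows violate the confidence scale or triads are incomplete."""


@dataclass
class RunConfig:
    """Configuration of a pipeline run; recorded in every output."""

    input: str = ""
    output_dir: str = "."
    seed: int = 0
    n_permutations: int = 10000
    n_bootstrap: int = 10000
    excluded_groups: tuple = ()
    schema: dict = field(default_factory=dict)
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def config_hash(config) -> str:
    """Short stable digest of a config mapping (embedded in outputs)."""
    if hasattr(config, "__dataclass_fields__"):
        config = asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_trials(path, schema: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-format trial CSV; returns the wide table.

    ``schema`` maps the file's column names onto the canonical ones, e.g.
    ``{"triad": "group", "noise_level": "condition"}``.  Malformed rows are
    reported with their file line numbers (header = line 1).
    """
    df = pd.read_csv(path, comment="#")
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing} "
                          f"(schema map keys: {sorted(schema or {})})")
    errors = []
    pct = pd.to_numeric(df["confidence_pct"], errors="coerce")
    bad_pct = pct.isna() | (pct < 50) | (pct > 100)
    for idx in df.index[bad_pct]:
        errors.append(f"line {idx + 2}: confidence_pct {df.at[idx, 'confidence_pct']!r} "
                      "outside [50, 100]")
    bad_choice = ~df["choice"].isin(OPTIONS)
    for idx in df.index[bad_choice]:
        errors.append(f"line {idx + 2}: choice {df.at[idx, 'choice']!r} not in {OPTIONS}")
    bad_member = ~df["member"].isin(MEMBERS)
    for idx in df.index[bad_member]:
        errors.append(f"line {idx + 2}: member {df.at[idx, 'member']!r} not in {MEMBERS}")
    bad_phase = ~df["phase"].isin(("prior", "posterior"))
    for idx in df.index[bad_phase]:
        errors.append(f"line {idx + 2}: phase {df.at[idx, 'phase']!r} not prior/posterior")
    if errors:
        head = errors[:20]
        more = f" (+{len(errors) - 20} more)" if len(errors) > 20 else ""
        raise TrialValidationError(f"{path}: {len(errors)} malformed rows:\n  "
                                   + "\n  ".join(head) + more)
    df = df.copy()
    df["confidence_pct"] = pct.where(pct < 100, 99.0)  # truncate on ingest
    return long_to_wide(df)


def long_to_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long report table to one row per trial with signed log-odds.

    Completeness is enforced: every trial needs all three members in both
    phases.  Option 1 is the canonical positive direction.
    """
    df = long_df.copy()
    counts = df.groupby(TRIAL_KEY).size()
    bad = counts[counts != 6]
    if len(bad):
        raise TrialValidationError(
            f"{len(bad)} incomplete trials (need 3 members x 2 phases), e.g. "
            f"{bad.index[0]}: {bad.iloc[0]} rows")
    dup = df.duplicated(subset=TRIAL_KEY + ["member", "phase"])
    if dup.any():
        raise TrialValidationError(f"{int(dup.sum())} duplicate (trial, member, phase) rows")
    df["C"] = encode_percent(df["choice"].to_numpy(), df["confidence_pct"].to_numpy())
    df["col"] = np.where(df["phase"] == "prior", "C_", "Cp_") + df["member"].astype(str)
    extra = [c for c in ("topic", "item_1", "item_2") if c in df.columns]
    wide = df.pivot_table(index=TRIAL_KEY + extra, columns="col", values="C").reset_index()
    wide.columns.name = None
    order = TRIAL_KEY + extra + [f"C_{m}" for m in MEMBERS] + [f"Cp_{m}" for m in MEMBERS]
    return wide[order].sort_values(TRIAL_KEY, kind="stable").reset_index(drop=True)


def write_table(df: pd.DataFrame, path, config: RunConfig | dict | None = None) -> Path:
    """Write a result table as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            seed = config.seed if isinstance(config, RunConfig) else config.get("seed")
            fh.write(f"# triadvote config_hash={config_hash(config)} seed={seed}\n")
        df.to_csv(fh, index=False)
    return path
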