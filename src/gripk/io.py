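"""CSV/JSON readers and writers for the record formats.

All times are hours since admission (floats); CSV dialect is comma-separated,
dot-decimal, UTF-8 with a mandatory header and LF line endings.  Writers are
deterministic: identical input gives byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from gripk.advisor import Advice, KalemicState, TargetRange

MEASUREMENT_COLUMNS = ("patient_id", "time_h", "potassium_mmol_l")
INFUSION_COLUMNS = ("patient_id", "start_h", "end_h", "rate_mmol_h")
HISTORY_COLUMNS = ("start_h", "end_h", "rate_mmol_h")


class ParseError(ValueError):
    """A record file is malformed; the message lists the offending rows."""


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, encoding="utf-8")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, path, columns: Sequence[str],
             nonnegative: Sequence[str] = ()) -> pd.DataFrame:
    """Coerce columns to float, collecting bad rows (1-based data rows)."""
    bad: List[str] = []
    out = df.copy()
    for col in columns:
        values = pd.to_numeric(out[col], errors="coerce")
        for idx in out.index[values.isna()]:
            bad.append(f"row {idx + 2}: non-numeric {col} {out.at[idx, col]!r}")
        out[col] = values
    for col in nonnegative:
        numeric = pd.to_numeric(out[col], errors="coerce")
        for idx in out.index[numeric < 0]:
            bad.append(f"row {idx + 2}: negative {col} ({numeric[idx]})")
    if bad:
        raise ParseError(f"{path}: " + "; ".join(bad))
    return out


def read_measurements(path) -> pd.DataFrame:
    """Read a measurements CSV; rows sorted by (patient_id, time_h)."""
    df = _read_csv(path, MEASUREMENT_COLUMNS)
    df = _numeric(df, path, ["time_h", "potassium_mmol_l"], nonnegative=["time_h"])
    df["patient_id"] = df["patient_id"].astype(str)
    return (df[list(MEASUREMENT_COLUMNS)]
            .sort_values(["patient_id", "time_h"], kind="stable")
            .reset_index(drop=True))


def read_infusions(path) -> pd.DataFrame:
    """Read an infusions CSV; rows sorted by (patient_id, start_h)."""
    df = _read_csv(path, INFUSION_COLUMNS)
    df = _numeric(df, path, ["start_h", "end_h", "rate_mmol_h"],
                  nonnegative=["start_h", "rate_mmol_h"])
    df["patient_id"] = df["patient_id"].astype(str)
    return (df[list(INFUSION_COLUMNS)]
            .sort_values(["patient_id", "start_h"], kind="stable")
            .reset_index(drop=True))


def read_history(path) -> Tuple[Tuple[float, float, float], ...]:
    """Read one patient's infusion history (start_h, end_h, rate_mmol_h)."""
    df = _read_csv(path, HISTORY_COLUMNS)
    df = _numeric(df, path, list(HISTORY_COLUMNS), nonnegative=["start_h", "rate_mmol_h"])
    df = df.sort_values("start_h", kind="stable")
    return tuple((float(r.start_h), float(r.end_h), float(r.rate_mmol_h))
                 for r in df.itertuples())


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic CSV writer (fixed float format, LF endings)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.4f", lineterminator="\n",
              encoding="utf-8")


def advice_to_dict(advice: Advice) -> dict:
    return {
        "rate_mmol_h": advice.rate,
        "next_interval_h": advice.next_interval,
        "state": advice.state.value,
        "alerts": list(advice.alerts),
        "clearance_fraction": advice.clearance_fraction,
        "target_low": advice.target.low,
        "target_high": advice.target.high,
    }


def write_advice(advice: Advice) -> str:
    """Serialize an Advice to JSON with stable key order."""
    return json.dumps(advice_to_dict(advice), indent=2, sort_keys=False)


def advice_from_json(text: str) -> Advice:
    data = json.loads(text)
    return Advice(
        rate=data["rate_mmol_h"],
        next_interval=data["next_interval_h"],
        state=KalemicState(data["state"]),
        alerts=tuple(data["alerts"]),
        clearance_fraction=data["clearance_fraction"],
        target=TargetRange(data["target_low"], data["target_high"]),
    )


def render_label(advice: Advice) -> str:
    """Human-readable pump label: rate, next measurement, alerts."""
    lines = [
        "GRIP-K POTASSIUM ADVICE",
        f"pump rate:        {advice.rate:.1f} mmol/h ({advice.rate:.1f} mL/h of 1 mmol/mL KCl)",
        f"next measurement: in {advice.next_interval:.0f} h",
        f"state:            {advice.state.value}",
        f"target range:     {advice.target.low:.1f}-{advice.target.high:.1f} mmol/L",
    ]
    for alert in advice.alerts:
        lines.append(f"!! {alert.replace('_', ' ').upper()} - NOTIFY PHYSICIAN !!")
    return "\n".join(lines)


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a simulation run."""

    tool_version: str
    config: dict
    seed: int
    file_checksums: Dict[str, str]
    created: Optional[str] = None  # ISO timestamp; omitted for byte-stable output

    def to_json(self) -> str:
        data = {"tool_version": self.tool_version, "config": self.config,
                "seed": self.seed, "file_checksums": self.file_checksums}
        if self.created is not None:
            data["created"] = self.created
        return json.dumps(data, indent=2, sort_keys=True)


def sha256_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(manifest.to_json() + "\n", encoding="utf-8")
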