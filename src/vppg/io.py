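"""File formats: trace CSV + JSON sidecar, cohort manifest, YAML config.

All files are plain text: traces as UTF-8 CSV (columns time_s, ppg_au,
post_maneuver_flag, "." decimal), per-trace metadata as a JSON sidecar with
the same basename, cohorts as a directory of traces plus a manifest CSV
(one row per limb) whose leading ``#`` comment lines carry provenance
(tool version, seed, config hash).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ManeuverProtocol, VppgTrace

__all__ = [
    "write_trace",
    "read_trace",
    "Manifest",
    "read_manifest",
    "write_manifest",
    "write_cohort",
    "ManifestError",
]

MANIFEST_COLUMNS = ["trace_path", "patient_id", "side", "us_positive"]
_SIDES = {"left", "right"}
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class ManifestError(ValueError):
    """Raised for malformed manifests; message names the offending lines."""


def write_trace(trace: VppgTrace, path, meta: dict | None = None) -> Path:
    """Write a trace CSV and its JSON metadata sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "ppg_au": trace.samples,
            "post_maneuver_flag": trace.post_maneuver.astype(int),
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "patient_id": trace.patient_id,
        "side": trace.side,
        "protocol": trace.protocol.to_dict(),
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_trace(path) -> tuple[VppgTrace, dict]:
    """Read a trace CSV and its sidecar; returns (trace, sidecar metadata)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "ppg_au"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    meta = json.loads(path.with_suffix(".json").read_text())
    protocol = ManeuverProtocol.from_dict(meta["protocol"])
    trace = VppgTrace(
        patient_id=str(meta["patient_id"]),
        side=meta["side"],
        protocol=protocol,
        samples=df["ppg_au"].to_numpy(),
    )
    return trace, meta


@dataclass
class Manifest:
    """Cohort index: one row per limb, plus a provenance block."""

    rows: pd.DataFrame
    provenance: dict

    def __len__(self) -> int:
        return len(self.rows)


def _validate_manifest_rows(df: pd.DataFrame, line_offset: int = 2) -> None:
    """line_offset maps dataframe index to file line number (header + 1-based)."""
    problems = []
    for idx, row in df.iterrows():
        line = idx + line_offset
        if str(row["side"]) not in _SIDES:
            problems.append(f"line {line}: unknown side {row['side']!r}")
    dup = df.duplicated(subset=["patient_id", "side"], keep=False)
    if dup.any():
        lines = [str(i + line_offset) for i in df.index[dup]]
        problems.append(
            "duplicate (patient_id, side) on lines " + ", ".join(lines)
        )
    if problems:
        raise ManifestError("; ".join(problems))


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ManifestError(f"cannot parse us_positive value {x!r}")


def read_manifest(path) -> Manifest:
    path = Path(path)
    provenance: dict = {}
    n_comments = 0
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if not raw.startswith("#"):
                break
            n_comments += 1
            body = raw.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                provenance[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing columns {sorted(missing)}")
    df = df[MANIFEST_COLUMNS].copy()
    # file line = comment lines + header + 1-based data row
    _validate_manifest_rows(df, line_offset=n_comments + 2)
    df["us_positive"] = df["us_positive"].map(_parse_bool)
    return Manifest(rows=df.reset_index(drop=True), provenance=provenance)


def write_manifest(manifest: Manifest, path) -> Path:
    path = Path(path)
    _validate_manifest_rows(manifest.rows.reset_index(drop=True))
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(manifest.provenance):
            fh.write(f"# {key}: {manifest.provenance[key]}\n")
        out = manifest.rows[MANIFEST_COLUMNS].copy()
        out["us_positive"] = out["us_positive"].map(lambda b: str(bool(b)).lower())
        out.to_csv(fh, index=False, lineterminator="\n")
    return path


def write_cohort(cohort, out_dir, provenance: dict | None = None) -> Path:
    """Write every (trace, us_positive) pair and a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trace, positive in cohort:
        name = f"{trace.patient_id}_{trace.side}.csv"
        write_trace(trace, out_dir / name, meta={"us_positive": bool(positive)})
        rows.append(
            {
                "trace_path": name,
                "patient_id": trace.patient_id,
                "side": trace.side,
                "us_positive": bool(positive),
            }
        )
    manifest = Manifest(rows=pd.DataFrame(rows), provenance=provenance or {})
    return write_manifest(manifest, out_dir / "manifest.csv")
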