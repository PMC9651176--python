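"""Extraction of the quantitative emptying statistic %PPGmax from a trace.

The Pra phase reveals any venous volume not emptied during abduction, so the
maximal PPG over the whole Ca-Pra maneuver (PPGmax) can be read as 100%
forearm emptying even though the raw signal is semi-quantitative.  The value
at the end of the Ca phase (End-Ca-PPG), normalized to PPGmax, gives the
percentage of emptying achieved during abduction:

    %PPGmax = 100 · End-Ca-PPG / PPGmax

%PPGmax is at most 100 (End-Ca lies inside the max window) and can be
negative — even below −100 — when persistent arterial inflow with arrested
outflow swells the forearm beyond its resting volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import VppgTrace

__all__ = [
    "LimbFeatures",
    "zero_baseline",
    "extract_features",
    "batch_features",
    "features_from_cohort",
    "END_CA_WINDOW_S",
]

logger = logging.getLogger(__name__)

#: width of the window (s) whose median defines the end-of-Ca value; a short
#: median is used rather than the single 4 Hz sample for noise robustness
END_CA_WINDOW_S = 1.0


@dataclass(frozen=True)
class LimbFeatures:
    """PPGmax, End-Ca-PPG and %PPGmax for one limb; AU and percent."""

    ppg_max: float
    end_ca_ppg: float
    pct_ppgmax: float
    valid: bool = True
    reason: str = ""


def zero_baseline(trace: VppgTrace) -> VppgTrace:
    """Shift the trace so the resting-baseline window has mean exactly 0."""
    rest = trace.rest_mask()
    if not rest.any():
        raise ValueError("trace has no samples in the rest window")
    shift = float(trace.samples[rest].mean())
    return VppgTrace(
        patient_id=trace.patient_id,
        side=trace.side,
        protocol=trace.protocol,
        samples=trace.samples - shift,
    )


def extract_features(
    trace: VppgTrace, end_ca_window_s: float = END_CA_WINDOW_S
) -> LimbFeatures:
    """Compute PPGmax, End-Ca-PPG and %PPGmax from a zero-baselined trace.

    PPGmax is the maximum over the maneuver window [rest_end, pra_end]
    (rest and arm-lowering samples excluded, the latter because lowering is
    not standardized).  End-Ca-PPG is the median of the last
    ``end_ca_window_s`` seconds of the Ca phase.  When PPGmax ≤ 0 the limb
    never showed detectable emptying and %PPGmax is undefined: the features
    are flagged invalid rather than dividing by a non-positive maximum.
    """
    p = trace.protocol
    t = trace.times
    if t[-1] < p.ca_end:
        raise ValueError("trace ends before the Ca window")
    maneuver = (t >= p.rest_duration) & (t <= p.pra_end)
    end_ca = (t > p.ca_end - end_ca_window_s) & (t <= p.ca_end)
    if not end_ca.any():
        raise ValueError("no samples in the end-of-Ca window")
    ppg_max = float(trace.samples[maneuver].max())
    end_ca_ppg = float(np.median(trace.samples[end_ca]))
    if ppg_max <= 0:
        return LimbFeatures(
            ppg_max=ppg_max,
            end_ca_ppg=end_ca_ppg,
            pct_ppgmax=float("nan"),
            valid=False,
            reason="no detectable emptying (PPGmax <= 0)",
        )
    return LimbFeatures(
        ppg_max=ppg_max,
        end_ca_ppg=end_ca_ppg,
        pct_ppgmax=100.0 * end_ca_ppg / ppg_max,
    )


def batch_features(
    manifest: pd.DataFrame,
    base_dir=None,
) -> tuple[pd.DataFrame, list[str]]:
    """Extract features for every limb in a manifest.

    ``manifest`` needs columns trace_path, patient_id, side, us_positive.
    Returns (table, errors): one row per readable limb with columns
    patient_id, side, ppg_max, end_ca_ppg, pct_ppgmax, valid, reason,
    us_positive, and a list of row-level error messages (unreadable files do
    not abort the run).
    """
    from .io import read_trace  # local import to avoid a cycle

    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    rows = []
    errors: list[str] = []
    for _, rec in manifest.iterrows():
        path = rec["trace_path"]
        if base_dir is not None:
            from pathlib import Path

            path = Path(base_dir) / path
        try:
            trace, meta = read_trace(path)
        except (OSError, ValueError) as exc:
            msg = f"{rec['patient_id']}/{rec['side']}: cannot read {path}: {exc}"
            errors.append(msg)
            logger.warning(msg)
            continue
        feats = extract_features(zero_baseline(trace))
        rows.append(
            {
                "patient_id": rec["patient_id"],
                "side": rec["side"],
                "ppg_max": feats.ppg_max,
                "end_ca_ppg": feats.end_ca_ppg,
                "pct_ppgmax": feats.pct_ppgmax,
                "valid": feats.valid,
                "reason": feats.reason,
                "us_positive": bool(rec["us_positive"]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "side",
            "ppg_max",
            "end_ca_ppg",
            "pct_ppgmax",
            "valid",
            "reason",
            "us_positive",
        ],
    )
    n_invalid = int((~table["valid"]).sum()) if len(table) else 0
    logger.info(
        "batch_features: %d limbs, %d invalid, %d read errors",
        len(table),
        n_invalid,
        len(errors),
    )
    return table, errors


def features_from_cohort(cohort) -> pd.DataFrame:
    """Feature table straight from in-memory (trace, us_positive) pairs."""
    rows = []
    for trace, positive in cohort:
        feats = extract_features(zero_baseline(trace))
        rows.append(
            {
                "patient_id": trace.patient_id,
                "side": trace.side,
                "ppg_max": feats.ppg_max,
                "end_ca_ppg": feats.end_ca_ppg,
                "pct_ppgmax": feats.pct_ppgmax,
                "valid": feats.valid,
                "reason": feats.reason,
                "us_positive": bool(positive),
            }
        )
    return pd.DataFrame(rows)
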