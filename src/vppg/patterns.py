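"""Rule-based classification of Ca-Pra traces into qualitative response patterns.

Six morphologies are seen clinically:

* complete emptying — the normal response; the signal plateaus during Ca and
  the Pra phase adds nothing;
* incomplete emptying — a rise during Pra reveals venous volume not emptied
  during abduction (outflow impairment);
* refill after initial emptying — outflow arrested while arterial inflow
  persists: an early emptying peak, then the forearm swells (the signal can
  go below zero), then a steep Pra rise;
* venodilation filling — emptying completes in Ca, but the signal declines
  during Pra (post-ischemic venodilation after inflow impairment);
* slowed-but-complete outflow — emptying reaches its maximum only at the
  very end of Ca.

All decision thresholds are relative to PPGmax, so classification is
invariant to the per-limb probe gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import LimbFeatures
from .simulate import VppgTrace

__all__ = ["PatternRules", "PatternLabel", "classify_pattern", "PATTERN_NAMES"]

PATTERN_NAMES = (
    "complete_emptying",
    "incomplete_emptying",
    "refill_incomplete",
    "venodilation_filling",
    "slowed_outflow_complete",
    "invalid",
)


@dataclass(frozen=True)
class PatternRules:
    """Classifier thresholds, as fractions of PPGmax (plus one time limit).

    delta_rise: minimum Pra rise (fraction of PPGmax) to call emptying
        incomplete; the default 0.13 makes the rule cohere with an 87%
        emptying criterion (100 − 87 = 13 points of PPGmax).
    delta_fall: minimum Pra decline to call venodilation filling.
    t_slow: seconds after abduction onset by which a complete emptier must
        have reached 90% of its End-Ca value, else outflow is called slowed.
    """

    delta_rise: float = 0.13
    delta_fall: float = 0.10
    t_slow: float = 20.0


@dataclass(frozen=True)
class PatternLabel:
    label: str
    evidence: dict

    def __post_init__(self) -> None:
        if self.label not in PATTERN_NAMES:
            raise ValueError(f"unknown pattern label {self.label!r}")


def classify_pattern(
    trace: VppgTrace,
    features: LimbFeatures,
    rules: PatternRules | None = None,
) -> PatternLabel:
    """Assign one of the qualitative response patterns to a trace.

    Decision sequence: (1) a Pra rise beyond delta_rise·PPGmax means
    incomplete emptying, subtyped as refill when an early Ca peak exceeds
    the End-Ca value by the same margin; (2) otherwise a Pra decline beyond
    delta_fall·PPGmax means venodilation filling; (3) otherwise emptying was
    complete.  A complete (or venodilation-masked complete) emptier that
    took longer than t_slow to reach 90% of its End-Ca value is re-labelled
    slowed-but-complete.  Incomplete evidence takes precedence over
    venodilation when both rules fire, since the degree of emptying is the
    primary clinical question.
    """
    rules = rules or PatternRules()
    if not features.valid:
        return PatternLabel("invalid", {"reason": features.reason})

    p = trace.protocol
    t = trace.times
    s = trace.samples
    ca = (t >= p.rest_duration) & (t <= p.ca_end)
    pra = (t > p.ca_end) & (t <= p.pra_end)
    end_pra = (t > p.pra_end - 1.0) & (t <= p.pra_end)

    ppg_max = features.ppg_max
    end_ca = features.end_ca_ppg
    pra_peak = float(s[pra].max())
    pra_rise = pra_peak - end_ca
    pra_decline = pra_peak - float(np.median(s[end_pra]))
    ca_peak = float(s[ca].max())

    # time from abduction onset to first crossing of 90% of the End-Ca value
    if end_ca > 0:
        crossed = np.flatnonzero(ca & (s >= 0.9 * end_ca))
        t90 = float(t[crossed[0]] - p.rest_duration) if crossed.size else float("inf")
    else:
        t90 = float("nan")

    evidence = {
        "pra_rise": pra_rise,
        "ca_peak_excess": ca_peak - end_ca,
        "pra_decline": pra_decline,
        "time_to_90pct_s": t90,
    }

    if pra_rise > rules.delta_rise * ppg_max:
        if ca_peak > end_ca + rules.delta_rise * ppg_max:
            return PatternLabel("refill_incomplete", evidence)
        return PatternLabel("incomplete_emptying", evidence)
    if pra_decline > rules.delta_fall * ppg_max:
        label = "venodilation_filling"
    else:
        label = "complete_emptying"
    if np.isfinite(t90) and t90 > rules.t_slow:
        return PatternLabel("slowed_outflow_complete", evidence)
    return PatternLabel(label, evidence)
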