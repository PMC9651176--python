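"""End-to-end orchestration: simulate (optional) → features → classify → ROC → metrics.

The pipeline is driven by a plain dict (usually loaded from YAML) naming
either a simulation spec (``cohort``) or an existing ``manifest``.  Its
report is a single JSON-serializable dict — cohort counts, the %PPGmax
distribution summary, the AUC block, the closest-to-corner cutoff, the
confusion metrics at that cutoff and at the configured reference cutoff,
and pattern frequencies — plus a Markdown rendering.  Every report embeds
tool version, master seed and a config hash, and a fixed seed reproduces
the JSON bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import round_half_up, table_at_cutoff
from .features import batch_features, extract_features, features_from_cohort, zero_baseline
from .io import read_manifest, write_cohort
from .patterns import PatternRules, classify_pattern
from .roc import auc_with_se, closest_corner_cutoff, empirical_roc
from .simulate import (
    CohortSpec,
    ManeuverProtocol,
    SeveritySampler,
    default_negative_sampler,
    default_positive_sampler,
    simulate_cohort,
)

__all__ = ["run_pipeline", "default_config", "config_hash", "cohort_spec_from_config"]

logger = logging.getLogger(__name__)


def default_config(seed: int = 0) -> dict:
    """Study-scale default: simulate the 424-patient cohort, reference cutoff 87."""
    return {
        "seed": seed,
        "cohort": {
            "n_patients": 424,
            "right_only": 41,
            "left_only": 44,
            "bilateral": 61,
            "none": 278,
        },
        "reference_cutoff": 87.0,
    }


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def cohort_spec_from_config(config: dict) -> CohortSpec:
    c = dict(config.get("cohort", {}))
    spec_kwargs = {
        k: c[k]
        for k in ("n_patients", "right_only", "left_only", "bilateral", "none")
        if k in c
    }
    if "sampler_pos" in c:
        spec_kwargs["sampler_pos"] = SeveritySampler.from_dict(c["sampler_pos"])
    if "sampler_neg" in c:
        spec_kwargs["sampler_neg"] = SeveritySampler.from_dict(c["sampler_neg"])
    if "protocol" in c:
        spec_kwargs["protocol"] = ManeuverProtocol.from_dict(c["protocol"])
    return CohortSpec(seed=int(config.get("seed", 0)), **spec_kwargs)


def _classify_cohort(cohort, rules: PatternRules) -> pd.Series:
    labels = []
    for trace, _ in cohort:
        z = zero_baseline(trace)
        labels.append(classify_pattern(z, extract_features(z), rules).label)
    return pd.Series(labels, name="pattern")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full analysis described by ``config``; return the report.

    ``config`` must contain either ``cohort`` (simulation spec; see
    :func:`default_config`) or ``manifest`` (path to an existing cohort).
    When ``out_dir`` is given, report.json and report.md are written there
    (plus the simulated cohort itself when ``config['write_traces']`` is
    true).
    """
    seed = int(config.get("seed", 0))
    reference_cutoff = float(config.get("reference_cutoff", 87.0))
    rules = PatternRules(**config.get("pattern_rules", {}))
    report: dict = {
        "provenance": {
            "tool": "vppg",
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(config),
        }
    }

    if "manifest" in config:
        manifest = read_manifest(config["manifest"])
        base = Path(config["manifest"]).parent
        table, errors = batch_features(manifest.rows, base_dir=base)
        report["read_errors"] = errors
        patterns = None
    elif "cohort" in config:
        spec = cohort_spec_from_config(config)
        cohort = simulate_cohort(spec)
        table = features_from_cohort(cohort)
        patterns = _classify_cohort(cohort, rules)
        if out_dir is not None and config.get("write_traces", False):
            write_cohort(
                cohort,
                Path(out_dir) / "traces",
                provenance=dict(report["provenance"], tool_version=__version__),
            )
    else:
        raise ValueError("config must name either 'cohort' or 'manifest'")

    valid = table[table["valid"]]
    pct = valid["pct_ppgmax"].to_numpy()
    labels = valid["us_positive"].to_numpy(dtype=bool)
    report["cohort"] = {
        "n_limbs": int(len(table)),
        "n_valid": int(len(valid)),
        "n_invalid": int(len(table) - len(valid)),
        "n_positive_limbs": int(labels.sum()),
        "n_negative_limbs": int(len(valid) - labels.sum()),
    }
    if len(valid):
        q25, q50, q75 = np.percentile(pct, [25, 50, 75])
        report["pct_ppgmax"] = {
            "median": round_half_up(float(q50), 1),
            "q25": round_half_up(float(q25), 1),
            "q75": round_half_up(float(q75), 1),
            "min": round_half_up(float(pct.min()), 1),
            "max": round_half_up(float(pct.max()), 1),
        }
    if patterns is not None:
        freq = patterns.value_counts().sort_index()
        report["pattern_frequencies"] = {k: int(v) for k, v in freq.items()}

    if labels.all() or not labels.any():
        report["roc"] = {"skipped": "single-class cohort; ROC is undefined"}
        logger.warning("ROC stage skipped: only one ultrasound class present")
    else:
        auc = auc_with_se(pct, labels)
        points = empirical_roc(pct, labels)
        best = closest_corner_cutoff(points)
        report["roc"] = {
            "auc": round(auc.auc, 4),
            "se": round(auc.se, 4),
            "z": round(auc.z, 3),
            "p": float(f"{auc.p:.3e}"),
            "n_pos": auc.n_pos,
            "n_neg": auc.n_neg,
        }
        report["optimal_cutoff"] = {
            "cutoff_pct_ppgmax": round(best.cutoff, 2),
            "sensitivity": round(best.sensitivity, 4),
            "specificity": round(best.specificity, 4),
            "distance": round(best.distance, 4),
        }
        report["metrics_at_optimal"] = table_at_cutoff(
            pct, labels, best.cutoff
        ).metrics_pct()
        report["metrics_at_reference"] = {
            "cutoff": reference_cutoff,
            **table_at_cutoff(pct, labels, reference_cutoff).metrics_pct(),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
        (out_dir / "report.md").write_text(_render_markdown(report))
        table.to_csv(out_dir / "features.csv", index=False)
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# VPPG Ca-Pra analysis report", ""]
    prov = report["provenance"]
    lines.append(
        f"tool {prov['tool']} {prov['version']} · seed {prov['seed']} · "
        f"config {prov['config_hash']}"
    )
    lines.append("")
    for section in (
        "cohort",
        "pct_ppgmax",
        "pattern_frequencies",
        "roc",
        "optimal_cutoff",
        "metrics_at_optimal",
        "metrics_at_reference",
    ):
        if section not in report:
            continue
        lines.append(f"## {section}")
        lines.append("")
        block = report[section]
        for key in block:
            lines.append(f"- {key}: {block[key]}")
        lines.append("")
    return "\n".join(lines)
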