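"""Compartment-model simulator: morphology, invariants, cohort structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vppg import (
    CohortSpec,
    ManeuverProtocol,
    SimParams,
    extract_features,
    preset_pattern,
    simulate_cohort,
    simulate_trace,
    zero_baseline,
)


def reference_euler(params: SimParams, protocol: ManeuverProtocol) -> np.ndarray:
    """Independent re-derivation of the difference equations, plain Python.

    Deliberately written from the model statement rather than the package
    internals, so a transcription error in either shows up as a mismatch.
    """
    dt = 1.0 / protocol.sample_rate
    t = [i * dt for i in range(protocol.n_samples)]
    v = [params.v_full]
    for i in range(1, len(t)):
        ti, vi = t[i - 1], v[-1]
        if ti < protocol.rest_duration:
            dv = 0.0
        elif ti < protocol.ca_end:
            ramp = 1.0
            if params.block_onset_s > 0:
                ramp = min(1.0, (ti - protocol.rest_duration) / params.block_onset_s)
            dv = params.inflow_q * (1 - params.inflow_block) - params.outflow_rate * (
                1 - params.outflow_block * ramp
            ) * (vi - params.v_empty)
        elif ti < protocol.pra_end:
            dtp = ti - protocol.ca_end
            q = params.inflow_q * (
                1
                + params.surge_gain
                * params.inflow_block
                * math.exp(-dtp / params.surge_tau)
            )
            ve = params.v_empty * (
                1
                + params.venodilation
                * params.inflow_block
                * (1 - math.exp(-dtp / params.dilation_tau))
            )
            dv = q - params.outflow_rate * (vi - ve)
        else:
            dv = (params.v_full - vi) / params.lowering_tau
        v.append(vi + dt * dv)
    ppg = params.gain * (params.v_full - np.array(v))
    rest = np.array(t) < protocol.rest_duration
    return ppg - ppg[rest].mean()


@pytest.mark.parametrize("name", list("ABCDEF"))
def test_noise_free_trace_matches_reference_integration(name, protocol):
    params = preset_pattern(name)
    got = simulate_trace(params, protocol).samples
    expected = reference_euler(params, protocol)
    np.testing.assert_allclose(got, expected, rtol=0, atol=1e-12)


def test_patent_limb_empties_fully_and_pra_adds_nothing(protocol):
    """With no outflow block the Ca phase empties the forearm completely."""
    trace = simulate_trace(SimParams(outflow_block=0.0), protocol)
    feats = extract_features(trace)
    assert feats.pct_ppgmax == pytest.approx(100.0, abs=0.1)
    t = trace.times
    ca = (t >= protocol.rest_duration) & (t <= protocol.ca_end)
    maneuver = (t >= protocol.rest_duration) & (t <= protocol.pra_end)
    assert trace.samples[ca].max() == pytest.approx(
        trace.samples[maneuver].max(), abs=0.01
    )


def test_total_block_with_persistent_inflow_goes_negative(protocol):
    """Arrested outflow + patent artery: the forearm swells past resting volume."""
    trace = simulate_trace(SimParams(outflow_block=1.0), protocol)
    feats = extract_features(trace)
    assert feats.end_ca_ppg < 0
    # steep emptying once the compression is released
    t = trace.times
    pra = (t > protocol.ca_end) & (t <= protocol.pra_end)
    assert trace.samples[pra].max() > 0.8 * feats.ppg_max


def test_ischemic_limb_rises_then_declines_in_pra(protocol):
    """Total block of both flows: flat Ca, Pra rise, then venodilation filling."""
    trace = simulate_trace(
        SimParams(outflow_block=1.0, inflow_block=1.0, venodilation=2.0), protocol
    )
    t = trace.times
    s = trace.samples
    ca = (t >= protocol.rest_duration) & (t <= protocol.ca_end)
    assert np.abs(s[ca]).max() < 0.05 * s.max()  # flat near zero during Ca
    pra_idx = np.flatnonzero((t > protocol.ca_end) & (t <= protocol.pra_end))
    peak = s[pra_idx].argmax()
    assert 0 < peak < len(pra_idx) - 1  # interior Pra maximum
    assert s[pra_idx[-1]] < s[pra_idx[peak]] - 1e-3  # late decline


@pytest.mark.parametrize("c_pair", [(0.0, 0.3), (0.3, 0.6), (0.6, 0.9), (0.9, 1.0)])
def test_pct_ppgmax_non_increasing_in_outflow_block(c_pair, protocol):
    lo, hi = c_pair
    f_lo = extract_features(simulate_trace(SimParams(outflow_block=lo), protocol))
    f_hi = extract_features(simulate_trace(SimParams(outflow_block=hi), protocol))
    assert f_hi.pct_ppgmax <= f_lo.pct_ppgmax + 1e-9


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    c=st.floats(0, 1),
    a=st.floats(0, 1),
    d=st.floats(0, 3),
    seed=st.integers(0, 2**31 - 1),
)
def test_trace_is_finite_with_zeroed_baseline(c, a, d, seed):
    trace = simulate_trace(
        SimParams(
            outflow_block=c, inflow_block=a, venodilation=d, noise_sd=0.2, seed=seed
        )
    )
    assert np.all(np.isfinite(trace.samples))
    assert abs(trace.samples[trace.rest_mask()].mean()) < 1e-9


def test_same_seed_reproduces_trace_bit_identically():
    p = SimParams(outflow_block=0.5, noise_sd=0.3, seed=99)
    a = simulate_trace(p).samples
    b = simulate_trace(p).samples
    assert np.array_equal(a, b)


@pytest.mark.parametrize(
    "bad",
    [
        dict(outflow_block=1.5),
        dict(inflow_block=-0.1),
        dict(outflow_rate=float("nan")),
        dict(inflow_q=float("inf")),
        dict(v_full=0.5, v_empty=1.0),
    ],
)
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        SimParams(**bad)


def test_invalid_protocol_rejected():
    with pytest.raises(ValueError):
        ManeuverProtocol(sample_rate=0)
    with pytest.raises(ValueError):
        ManeuverProtocol(ca_end=50, pra_end=45)


def test_unknown_preset_rejected():
    with pytest.raises(KeyError):
        preset_pattern("G")


class TestCohort:
    def test_study_scale_marginals_are_exact(self):
        spec = CohortSpec(seed=3)
        cohort = simulate_cohort(spec)
        assert len(cohort) == 848
        right_pos = sum(1 for tr, p in cohort if p and tr.side == "right")
        left_pos = sum(1 for tr, p in cohort if p and tr.side == "left")
        assert right_pos == 102
        assert left_pos == 105
        assert right_pos + left_pos == 207

    def test_small_cohort_marginals(self, small_cohort_spec):
        cohort = simulate_cohort(small_cohort_spec)
        assert len(cohort) == 40
        assert sum(p for tr, p in cohort if tr.side == "right") == 3 + 5
        assert sum(p for tr, p in cohort if tr.side == "left") == 4 + 5

    def test_all_negative_cohort(self):
        spec = CohortSpec(
            n_patients=5, right_only=0, left_only=0, bilateral=0, none=5, seed=0
        )
        assert sum(p for _, p in simulate_cohort(spec)) == 0

    def test_counts_must_sum_to_n_patients(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=10, right_only=1, left_only=1, bilateral=1, none=1)

    def test_same_seed_reproduces_cohort(self, small_cohort_spec):
        a = simulate_cohort(small_cohort_spec)
        b = simulate_cohort(small_cohort_spec)
        assert all(
            np.array_equal(ta.samples, tb.samples) and pa == pb
            for (ta, pa), (tb, pb) in zip(a, b)
        )

    def test_different_seeds_differ(self, small_cohort_spec):
        from dataclasses import replace

        a = simulate_cohort(small_cohort_spec)
        b = simulate_cohort(replace(small_cohort_spec, seed=12))
        assert not np.array_equal(a[0][0].samples, b[0][0].samples)
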