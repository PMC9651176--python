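"""Forward simulation of forearm venous volume during the Ca-Pra maneuver.

The Candlestick-Prayer ("Ca-Pra") maneuver is a positional provocation test
for venous thoracic outlet syndrome: 90° arm abduction (candlestick, "Ca")
may compress the subclavian vein; bringing the elbows forward at the same
elevation (prayer, "Pra") opens the costo-clavicular angle and releases the
compression while keeping the hydrostatic drive for emptying.  A low-pass
photo-plethysmography (VPPG) probe on the forearm tracks the slow venous
volume component in arbitrary units (AU): increases from the resting zero
denote forearm emptying, decreases denote filling.

The model here is a single venous compartment with first-order emptying,
whose outflow conductance and arterial inflow are switched by arm position:

rest (arms down)        V = V_full                       (complete filling)
Ca   (abduction)        dV/dt = q·(1−a) − k0·(1−c)·(V − V_empty)
Pra  (elbows forward)   dV/dt = q_h(t) − k0·(V − V_e(t))
after pra_end           V relaxes back to V_full         (arm lowering)

with c ∈ [0,1] the fractional outflow block during Ca, a ∈ [0,1] the
fractional arterial inflow block during Ca, and, during Pra,

    q_h(t) = q·(1 + surge_gain·a·exp(−Δt/surge_tau))        (reactive
             hyperaemic inflow surge after inflow impairment)
    V_e(t) = V_empty·(1 + d·a·(1 − exp(−Δt/dilation_tau)))  (post-ischemic
             venodilation raising the relaxed venous volume)

The PPG readout is G·(V_full − V) plus Gaussian sensor noise, re-zeroed to
the mean of the resting baseline window — exactly how the recording device
defines its zero-volume reference.  Integration is explicit Euler on the
sample grid (0.25 s at 4 Hz), stable for k0 ≤ 2 s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ManeuverProtocol",
    "SimParams",
    "VppgTrace",
    "SeveritySampler",
    "CohortSpec",
    "simulate_trace",
    "preset_pattern",
    "PRESET_LABELS",
    "simulate_cohort",
    "default_positive_sampler",
    "default_negative_sampler",
    "default_cohort_spec",
]


@dataclass(frozen=True)
class ManeuverProtocol:
    """Timing of the recording: rest baseline, Ca phase, Pra phase, total.

    Defaults follow the routine clinical protocol: 2 s resting baseline
    (zero-volume reference), candlestick held until second 30, prayer until
    second 45, device stops at 60 s, sampling at 4 Hz.
    """

    rest_duration: float = 2.0
    ca_end: float = 30.0
    pra_end: float = 45.0
    total_duration: float = 60.0
    sample_rate: float = 4.0

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(x)
            for x in (
                self.rest_duration,
                self.ca_end,
                self.pra_end,
                self.total_duration,
                self.sample_rate,
            )
        ):
            raise ValueError("protocol timings must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not (0 < self.rest_duration < self.ca_end < self.pra_end <= self.total_duration):
            raise ValueError(
                "require 0 < rest_duration < ca_end < pra_end <= total_duration, got "
                f"{self.rest_duration}, {self.ca_end}, {self.pra_end}, {self.total_duration}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sample_rate))

    def times(self) -> np.ndarray:
        """Sample times in seconds, t_i = i / sample_rate."""
        return np.arange(self.n_samples) / self.sample_rate

    def to_dict(self) -> dict:
        return {
            "rest_duration": self.rest_duration,
            "ca_end": self.ca_end,
            "pra_end": self.pra_end,
            "total_duration": self.total_duration,
            "sample_rate": self.sample_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ManeuverProtocol":
        return cls(**d)


@dataclass(frozen=True)
class SimParams:
    """Per-limb hemodynamic parameters of the compartment model.

    outflow_block c: fractional reduction of venous outflow conductance in Ca.
    inflow_block a: fractional reduction of arterial inflow in Ca.
    venodilation d: magnitude of the post-ischemic rise of the relaxed venous
        volume during Pra; only active when a > 0 (it is a consequence of
        inflow impairment).
    outflow_rate k0: emptying rate constant (s⁻¹) with patent outflow.
    inflow_q: resting arterial inflow (volume-units/s).
    gain: AU per volume-unit; the per-limb "semi-quantitative" probe gain.
    noise_sd: sensor noise, AU.
    block_onset_s: seconds over which the outflow block ramps in after
        abduction starts (the costo-clavicular angle closes as the arm
        reaches position); 0 means instantaneous.
    """

    outflow_block: float = 0.0
    inflow_block: float = 0.0
    venodilation: float = 0.0
    outflow_rate: float = 0.3
    inflow_q: float = 0.06
    gain: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    block_onset_s: float = 0.0
    surge_gain: float = 3.0
    surge_tau: float = 4.0
    dilation_tau: float = 6.0
    v_empty: float = 1.0
    v_full: float = 10.0
    lowering_tau: float = 2.0

    def __post_init__(self) -> None:
        numeric = {
            "outflow_block": self.outflow_block,
            "inflow_block": self.inflow_block,
            "venodilation": self.venodilation,
            "outflow_rate": self.outflow_rate,
            "inflow_q": self.inflow_q,
            "gain": self.gain,
            "noise_sd": self.noise_sd,
            "block_onset_s": self.block_onset_s,
            "surge_gain": self.surge_gain,
            "surge_tau": self.surge_tau,
            "dilation_tau": self.dilation_tau,
            "v_empty": self.v_empty,
            "v_full": self.v_full,
            "lowering_tau": self.lowering_tau,
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        for name in ("outflow_block", "inflow_block"):
            if numeric[name] > 1:
                raise ValueError(f"{name} must lie in [0, 1], got {numeric[name]!r}")
        if self.v_full <= self.v_empty:
            raise ValueError("v_full must exceed v_empty")

    def to_dict(self) -> dict:
        return {
            "outflow_block": self.outflow_block,
            "inflow_block": self.inflow_block,
            "venodilation": self.venodilation,
            "outflow_rate": self.outflow_rate,
            "inflow_q": self.inflow_q,
            "gain": self.gain,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "block_onset_s": self.block_onset_s,
            "surge_gain": self.surge_gain,
            "surge_tau": self.surge_tau,
            "dilation_tau": self.dilation_tau,
            "v_empty": self.v_empty,
            "v_full": self.v_full,
            "lowering_tau": self.lowering_tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class VppgTrace:
    """One limb's VPPG recording on the protocol's time grid.

    ``samples`` are in AU, zeroed to the resting baseline.  Samples after
    ``protocol.pra_end`` are still present (arm lowering) but flagged
    ``post_maneuver`` and must be excluded from feature extraction.
    """

    patient_id: str
    side: str
    protocol: ManeuverProtocol
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.samples.shape != (self.protocol.n_samples,):
            raise ValueError(
                f"expected {self.protocol.n_samples} samples, got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.protocol.times()

    @property
    def post_maneuver(self) -> np.ndarray:
        """Boolean mask of arm-lowering samples (t > pra_end), discarded downstream."""
        return self.times > self.protocol.pra_end

    def rest_mask(self) -> np.ndarray:
        return self.times < self.protocol.rest_duration


def _integrate_volume(params: SimParams, protocol: ManeuverProtocol) -> np.ndarray:
    """Explicit Euler integration of the compartment volume on the sample grid."""
    t = protocol.times()
    dt = 1.0 / protocol.sample_rate
    n = protocol.n_samples
    v = np.empty(n)
    v[0] = params.v_full
    c, a, d = params.outflow_block, params.inflow_block, params.venodilation
    k0, q = params.outflow_rate, params.inflow_q
    for i in range(1, n):
        ti = t[i - 1]
        vi = v[i - 1]
        if ti < protocol.rest_duration:
            dv = 0.0  # arms down, compartment full
        elif ti < protocol.ca_end:
            if params.block_onset_s > 0:
                ramp = min(1.0, (ti - protocol.rest_duration) / params.block_onset_s)
            else:
                ramp = 1.0
            c_eff = c * ramp
            dv = q * (1.0 - a) - k0 * (1.0 - c_eff) * (vi - params.v_empty)
        elif ti < protocol.pra_end:
            dtp = ti - protocol.ca_end
            q_h = q * (1.0 + params.surge_gain * a * math.exp(-dtp / params.surge_tau))
            v_e = params.v_empty * (
                1.0 + d * a * (1.0 - math.exp(-dtp / params.dilation_tau))
            )
            dv = q_h - k0 * (vi - v_e)
        else:
            dv = (params.v_full - vi) / params.lowering_tau  # arm lowering refill
        v[i] = vi + dt * dv
    return v


def simulate_trace(
    params: SimParams,
    protocol: ManeuverProtocol | None = None,
    patient_id: str = "sim",
    side: str = "right",
) -> VppgTrace:
    """Simulate one limb's VPPG trace for the Ca-Pra maneuver.

    The PPG readout is ``gain * (v_full − V(t))`` plus Gaussian noise, then
    shifted so the resting-baseline window has mean exactly zero (the
    device's zero-volume convention).  Deterministic for a given
    ``params.seed``.
    """
    protocol = protocol or ManeuverProtocol()
    volume = _integrate_volume(params, protocol)
    ppg = params.gain * (params.v_full - volume)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        ppg = ppg + rng.normal(0.0, params.noise_sd, size=ppg.shape)
    rest = protocol.times() < protocol.rest_duration
    ppg = ppg - ppg[rest].mean()
    return VppgTrace(patient_id=patient_id, side=side, protocol=protocol, samples=ppg)


# Parameter sets reproducing the six qualitative response morphologies seen
# clinically (noise-free).  A/B: normal — fast complete emptying, flat Pra.
# C: incomplete emptying (partial outflow block).  D: refill — near-total
# outflow block with persistent inflow; brief early emptying while the block
# engages, then forearm swelling beyond resting volume (negative PPG).
# E: severely slowed outflow that still completes by the end of Ca, with
# inflow impairment causing post-ischemic filling during Pra.  F: normal
# outflow but inflow impairment in Ca, hence venodilation filling in Pra.
_PRESETS: dict[str, SimParams] = {
    "A": SimParams(outflow_block=0.0, outflow_rate=0.35),
    "B": SimParams(outflow_block=0.3, outflow_rate=0.5, gain=0.7),
    "C": SimParams(outflow_block=0.88, outflow_rate=0.3),
    "D": SimParams(
        outflow_block=1.0,
        outflow_rate=0.8,
        inflow_q=0.4,
        block_onset_s=3.0,
    ),
    "E": SimParams(
        outflow_block=0.78,
        inflow_block=0.95,
        venodilation=1.5,
        outflow_rate=0.3,
    ),
    "F": SimParams(
        outflow_block=0.0,
        inflow_block=0.85,
        venodilation=2.0,
        outflow_rate=0.4,
    ),
}

#: the pattern label each preset is designed to elicit from the classifier
PRESET_LABELS: dict[str, str] = {
    "A": "complete_emptying",
    "B": "complete_emptying",
    "C": "incomplete_emptying",
    "D": "refill_incomplete",
    "E": "slowed_outflow_complete",
    "F": "venodilation_filling",
}


def preset_pattern(name: str) -> SimParams:
    """Return the documented parameter set for response morphology A..F."""
    try:
        return _PRESETS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose one of {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SeveritySampler:
    """Distribution over per-limb SimParams for one ultrasound class.

    Limbs are a mixture of a *patent* phenotype (little or no hemodynamic
    effect of arm position: outflow block c uniform on [0, c_patent_max],
    emptying essentially complete) and, with probability ``p_impaired``, an
    *impaired* phenotype.  Impaired limbs are themselves a mixture: with
    weight ``w_moderate`` a moderate block c = c_mod_lo + (c_mod_hi −
    c_mod_lo)·Beta(mod_a, mod_b) (partial emptying), otherwise a severe
    block c ~ U(c_sev_lo, 1) whose arterial inflow is boosted by a
    log-normal factor — the refill morphology, which can push the signal
    below zero.  ``p_inflow`` limbs additionally carry an arterial inflow
    block a ~ U(a_low, a_high) with venodilation d ~ U(d_low, d_high) (the
    Pra-filling morphologies).  Rates and the probe gain get log-normal
    per-limb jitter (the "semi-quantitative" amplitude spread), and the
    block engages over a uniform onset ramp as the arm reaches position.
    """

    p_impaired: float
    w_moderate: float
    mod_a: float
    mod_b: float
    c_mod_lo: float = 0.68
    c_mod_hi: float = 0.92
    c_sev_lo: float = 0.90
    sev_q_boost_mu: float = 1.1
    sev_q_boost_sigma: float = 0.6
    c_patent_max: float = 0.5
    p_inflow: float = 0.08
    a_low: float = 0.4
    a_high: float = 1.0
    d_low: float = 0.5
    d_high: float = 2.0
    q_median: float = 0.06
    q_sigma: float = 0.25
    k0_median: float = 0.3
    k0_sigma: float = 0.10
    gain_median: float = 1.0
    gain_sigma: float = 0.8
    onset_low: float = 1.0
    onset_high: float = 4.0
    noise_sd: float = 0.12

    def phenotype_quota(self, n: int) -> list[str]:
        """Deterministic phenotype composition for n limbs of this class.

        Cohort generation assigns phenotypes by exact quota (largest-count
        rounding) rather than per-limb coin flips, so the class composition
        — the condition the samplers are calibrated to — holds at any
        cohort size instead of only in expectation.
        """
        n_impaired = round(self.p_impaired * n)
        n_moderate = round(self.w_moderate * n_impaired)
        n_severe = n_impaired - n_moderate
        return (
            ["patent"] * (n - n_impaired)
            + ["moderate"] * n_moderate
            + ["severe"] * n_severe
        )

    def draw_phenotype(self, rng: np.random.Generator, phenotype: str) -> SimParams:
        """Draw SimParams for a limb of a given phenotype."""
        q_boost = 1.0
        a = d = 0.0
        if phenotype == "moderate":
            c = self.c_mod_lo + (self.c_mod_hi - self.c_mod_lo) * float(
                rng.beta(self.mod_a, self.mod_b)
            )
        elif phenotype == "severe":
            c = float(rng.uniform(self.c_sev_lo, 1.0))
            q_boost = float(
                rng.lognormal(self.sev_q_boost_mu, self.sev_q_boost_sigma)
            )
        elif phenotype == "patent":
            c = float(rng.uniform(0.0, self.c_patent_max))
        else:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        if rng.random() < self.p_inflow:
            # arterial inflow impairment (with consequent venodilation);
            # on a patent limb this is the pure Pra-filling morphology
            a = float(rng.uniform(self.a_low, self.a_high))
            d = float(rng.uniform(self.d_low, self.d_high))
        return SimParams(
            outflow_block=c,
            inflow_block=a,
            venodilation=d,
            outflow_rate=float(self.k0_median * rng.lognormal(0.0, self.k0_sigma)),
            inflow_q=float(
                self.q_median * q_boost * rng.lognormal(0.0, self.q_sigma)
            ),
            gain=float(self.gain_median * rng.lognormal(0.0, self.gain_sigma)),
            noise_sd=self.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            block_onset_s=float(rng.uniform(self.onset_low, self.onset_high)),
        )

    def draw(self, rng: np.random.Generator) -> SimParams:
        """Draw SimParams with the phenotype itself sampled (standalone use)."""
        if rng.random() < self.p_impaired:
            phenotype = "moderate" if rng.random() < self.w_moderate else "severe"
        else:
            phenotype = "patent"
        return self.draw_phenotype(rng, phenotype)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "SeveritySampler":
        return cls(**d)


def default_positive_sampler() -> SeveritySampler:
    """Severity distribution for limbs with positional compression on ultrasound."""
    return SeveritySampler(
        p_impaired=0.68,
        w_moderate=0.50,
        mod_a=1.0,
        mod_b=2.2,
        c_mod_lo=0.70,
        c_mod_hi=0.92,
        c_patent_max=0.45,
        p_inflow=0.12,
    )


def default_negative_sampler() -> SeveritySampler:
    """Severity distribution for ultrasound-negative limbs.

    Deliberately overlaps the positive sampler heavily: in this referral
    population venous outflow impairment is frequent even without a
    visualized compression (and conversely collaterals can normalize outflow
    despite compression), which is why the test's discrimination is modest.
    """
    return SeveritySampler(
        p_impaired=0.49,
        w_moderate=0.86,
        mod_a=1.0,
        mod_b=1.2,
        c_mod_lo=0.78,
        c_mod_hi=0.94,
        c_patent_max=0.68,
        p_inflow=0.04,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure: patient count, per-side compression counts, samplers.

    ``side_status_counts`` gives the number of patients with right-only,
    left-only, bilateral, and no ultrasound-confirmed compression; they must
    sum to ``n_patients``.  Every patient contributes both limbs.
    """

    n_patients: int = 424
    right_only: int = 41
    left_only: int = 44
    bilateral: int = 61
    none: int = 278
    sampler_pos: SeveritySampler = field(default_factory=default_positive_sampler)
    sampler_neg: SeveritySampler = field(default_factory=default_negative_sampler)
    seed: int = 0
    protocol: ManeuverProtocol = field(default_factory=ManeuverProtocol)

    def __post_init__(self) -> None:
        counts = (self.right_only, self.left_only, self.bilateral, self.none)
        if any(k < 0 for k in counts) or self.n_patients < 0:
            raise ValueError("counts must be non-negative")
        if sum(counts) != self.n_patients:
            raise ValueError(
                f"side-status counts {counts} sum to {sum(counts)}, "
                f"not n_patients={self.n_patients}"
            )

    @property
    def n_limbs(self) -> int:
        return 2 * self.n_patients

    @property
    def n_right_positive(self) -> int:
        return self.right_only + self.bilateral

    @property
    def n_left_positive(self) -> int:
        return self.left_only + self.bilateral

    @property
    def n_positive_limbs(self) -> int:
        return self.n_right_positive + self.n_left_positive


def simulate_cohort(spec: CohortSpec) -> list[tuple[VppgTrace, bool]]:
    """Generate both limbs of every patient with ultrasound labels.

    Returns a list of (trace, us_positive) pairs of length 2·n_patients,
    ordered right then left within patient.  Positive limbs draw SimParams
    from ``sampler_pos``, negative limbs from ``sampler_neg``; phenotypes
    within each ultrasound class are allocated by exact quota (see
    :meth:`SeveritySampler.phenotype_quota`) and shuffled.  Per-limb RNG
    substreams are spawned from the spec seed, so the whole cohort is
    bit-reproducible.
    """
    statuses = (
        ["right_only"] * spec.right_only
        + ["left_only"] * spec.left_only
        + ["bilateral"] * spec.bilateral
        + ["none"] * spec.none
    )
    master = np.random.SeedSequence(spec.seed)
    order_rng = np.random.default_rng(master.spawn(1)[0])
    order_rng.shuffle(statuses)
    limb_positive = [
        status == "bilateral" or status == f"{side}_only"
        for status in statuses
        for side in ("right", "left")
    ]
    n_pos = sum(limb_positive)
    quota_pos = spec.sampler_pos.phenotype_quota(n_pos)
    quota_neg = spec.sampler_neg.phenotype_quota(len(limb_positive) - n_pos)
    order_rng.shuffle(quota_pos)
    order_rng.shuffle(quota_neg)
    limb_seeds = master.spawn(2 * spec.n_patients)

    out: list[tuple[VppgTrace, bool]] = []
    k = 0
    for i, status in enumerate(statuses):
        pid = f"P{i + 1:04d}"
        for side in ("right", "left"):
            positive = limb_positive[k]
            sampler = spec.sampler_pos if positive else spec.sampler_neg
            phenotype = (quota_pos if positive else quota_neg).pop()
            rng = np.random.default_rng(limb_seeds[k])
            k += 1
            params = sampler.draw_phenotype(rng, phenotype)
            trace = simulate_trace(params, spec.protocol, patient_id=pid, side=side)
            out.append((trace, positive))
    return out


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The study-scale cohort: 424 patients, compression counts 41/44/61/278."""
    return CohortSpec(seed=seed)
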