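"""Synthetic longitudinal MS cohorts with known ground truth.

The generator runs the damage ODE forward under archetype-specific
parameters and stochastic attack trains, reads out EDSS and brain volume
through per-patient calibrations, and degrades the result the way clinical
data are degraded: irregular visit schedules, half-point EDSS quantization,
observation noise, and missing visits.  Every patient's generating
archetype, parameters, attack train and calibration are returned alongside
the cohort so that each pipeline stage can be checked against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import PatientCalibration, derive_scaling, initial_myelination
from .core_model import (
    DAYS_PER_MONTH,
    EDSS_MAX,
    ModelParams,
    quantize_edss,
    simulate_batch,
)
from .inflammatory import IntervalDistribution, PulseTrain, build_lambda, sample_pulse_train
from .io_cohort import Cohort, PatientRecord, Visit

__all__ = [
    "Archetype",
    "SynthConfig",
    "GroundTruth",
    "generate_cohort",
    "archetype_presets",
]


@dataclass(frozen=True)
class Archetype:
    """One disease-course archetype: ODE parameters plus attack statistics."""

    name: str
    params: ModelParams
    gev_shape: float
    gev_loc: float  # months between attacks, location
    gev_scale: float  # months, scale
    amp_scale: float = 0.1  # peak lam per unit of (dEDSS / EDSS_MAX), 1/day
    amp_exp_scale: float = 0.5  # dEDSS = 1 + Exp(amp_exp_scale), clipped at 3
    subtype: str = "unknown"

    def interval_distribution(self) -> IntervalDistribution:
        return IntervalDistribution(
            family="GEV",
            params={"shape": self.gev_shape, "loc": self.gev_loc, "scale": self.gev_scale},
            criterion_value=0.0,
        )

    def amplitude_sampler(self):
        hi = 3.0

        def sample(n: int, rng: np.random.Generator) -> np.ndarray:
            return np.clip(1.0 + rng.exponential(self.amp_exp_scale, size=n), 1.0, hi)

        return sample

    def deterministic_train(self, horizon_days: float) -> PulseTrain:
        """The archetype's noise-free attack schedule: events at the median
        inter-attack interval with the mean attack size (used to realize the
        archetype's characteristic curve without renewal-process spread)."""
        gap = self.interval_distribution()._frozen().median() * DAYS_PER_MONTH
        times = np.arange(gap, horizon_days, gap)
        amp = self.amp_scale * (1.0 + self.amp_exp_scale) / EDSS_MAX
        return PulseTrain(event_times=times, amplitudes=np.full(times.size, amp))


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 66
    archetypes: list[Archetype] = field(default_factory=lambda: archetype_presets()["four_cluster"])
    mixture_weights: list[float] | None = None  # default: uniform
    visit_spacing_months: float = 6.0
    visit_jitter_months: float = 1.5
    follow_up_months: float = 240.0
    edss_noise_sd: float = 0.25
    with_bv: bool = False
    bi_mean: float = -0.05
    bi_sd: float = 0.01
    ci_mean: float = 1.2
    ci_sd: float = 0.03
    bv_noise_sd: float = 0.01
    missing_rate: float = 0.1
    age_onset_mean: float = 30.0
    age_onset_sd: float = 8.0
    seed: int = 0
    step_days: float = 1.0
    out_spacing_days: float = 10.0
    #: replace each patient's stochastic attack train by the archetype's
    #: deterministic schedule, so within-archetype spread is observational only
    deterministic_trains: bool = False

    def __post_init__(self) -> None:
        if self.mixture_weights is not None:
            w = np.asarray(self.mixture_weights, dtype=float)
            if len(w) != len(self.archetypes):
                raise ValueError("one mixture weight per archetype required")
            if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("mixture weights must sum to 1")
        for sd in (self.edss_noise_sd, self.bv_noise_sd, self.visit_jitter_months):
            if sd < 0:
                raise ValueError("noise magnitudes must be non-negative")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


@dataclass
class GroundTruth:
    patient_id: str
    archetype: str
    archetype_index: int
    params: ModelParams
    train: PulseTrain
    calib: PatientCalibration
    age_onset: float


def archetype_presets() -> dict:
    """Named archetypes for the three clinical subtypes and a four-cluster
    severity scenario.

    The presets encode the qualitative subtype ordering the model implies:
    remyelination rate and capacity growth fall from RRMS to SPMS to PPMS
    (km and delta decreasing) while both axon-loss rates rise (kd and kmd
    increasing), with transection of intact axons always far rarer than
    degeneration of demyelinated ones (kmd << kd).  The PPMS preset is
    degeneration-dominated (D > Ad throughout); the RRMS preset is
    relapse-dominated (intervals with Ad > D).
    """
    rrms = Archetype(
        name="RRMS",
        params=ModelParams(km=0.05, kmd=1e-5, kd=0.01, q=0.5, delta=0.1),
        gev_shape=0.25,
        gev_loc=14.0,
        gev_scale=6.0,
        amp_scale=0.04,
        subtype="RRMS",
    )
    spms = Archetype(
        name="SPMS",
        params=ModelParams(km=0.015, kmd=8e-5, kd=0.04, q=0.5, delta=0.02),
        gev_shape=0.25,
        gev_loc=20.0,
        gev_scale=8.0,
        amp_scale=0.035,
        subtype="SPMS",
    )
    ppms = Archetype(
        name="PPMS",
        params=ModelParams(km=0.004, kmd=1.5e-4, kd=0.1, q=0.5, delta=0.005),
        gev_shape=0.25,
        gev_loc=30.0,
        gev_scale=10.0,
        amp_scale=0.015,
        subtype="PPMS",
    )
    # four severity clusters, separated in time-to-milestone profile:
    # mild relapsing, slow progression, fast progression, severe early progression
    four = [
        replace(rrms, name="cluster_mild"),
        Archetype(
            name="cluster_slow",
            params=ModelParams(km=0.015, kmd=4e-5, kd=0.035, q=0.5, delta=0.02),
            gev_shape=0.25,
            gev_loc=13.0,
            gev_scale=5.0,
            amp_scale=0.035,
            amp_exp_scale=0.25,
            subtype="SPMS",
        ),
        Archetype(
            name="cluster_fast",
            params=ModelParams(km=0.008, kmd=2.2e-4, kd=0.09, q=0.5, delta=0.008),
            gev_shape=0.25,
            gev_loc=18.0,
            gev_scale=7.0,
            amp_scale=0.035,
            amp_exp_scale=0.25,
            subtype="SPMS",
        ),
        Archetype(
            name="cluster_severe",
            params=ModelParams(km=0.002, kmd=7e-4, kd=0.2, q=0.5, delta=0.003),
            gev_shape=0.25,
            gev_loc=30.0,
            gev_scale=9.0,
            amp_scale=0.015,
            amp_exp_scale=0.25,
            subtype="PPMS",
        ),
    ]
    return {"RRMS": rrms, "SPMS": spms, "PPMS": ppms, "four_cluster": four}


def _simulate_patient(
    arche: Archetype,
    ami0: float,
    horizon_days: float,
    rng: np.random.Generator,
    step: float,
    out_spacing: float,
    deterministic: bool = False,
):
    if deterministic:
        train = arche.deterministic_train(horizon_days)
    else:
        train = sample_pulse_train(
            arche.interval_distribution(),
            arche.amplitude_sampler(),
            horizon=horizon_days,
            rng=rng,
            amp_scale=arche.amp_scale,
        )
    lam = build_lambda(train)
    t_out = np.arange(0.0, horizon_days + out_spacing, out_spacing)
    states = simulate_batch(
        arche.params.as_array()[None, :],
        lam,
        np.array([ami0, 0.0, 1.0, 0.0]),
        t_out,
        step=step,
    )[0]
    return train, t_out, states


def archetype_reference_curves(
    archetypes: list[Archetype],
    grid_months: np.ndarray,
    ami0: float = 0.9,
    step_days: float = 1.0,
) -> np.ndarray:
    """Each archetype's characteristic normalized EDSS curve on a month grid
    (deterministic attack schedule, EDSS scale divided by the maximal score)."""
    grid_months = np.asarray(grid_months, dtype=float)
    horizon = float(grid_months.max()) * DAYS_PER_MONTH
    kei = EDSS_MAX / ami0
    curves = []
    for a in archetypes:
        lam = build_lambda(a.deterministic_train(horizon))
        t_out = np.arange(0.0, horizon + 10.0, 10.0)
        st = simulate_batch(
            a.params.as_array()[None, :],
            lam,
            np.array([ami0, 0.0, 1.0, 0.0]),
            t_out,
            step=step_days,
        )[0]
        e = kei * np.maximum(st[:, 1], st[:, 3])
        curves.append(np.interp(grid_months * DAYS_PER_MONTH, t_out, e) / EDSS_MAX)
    return np.array(curves)


def generate_cohort(config: SynthConfig) -> tuple[Cohort, list[GroundTruth]]:
    """Generate one cohort and its per-patient ground truth, reproducibly
    from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_arch = len(config.archetypes)
    weights = (
        np.asarray(config.mixture_weights, dtype=float)
        if config.mixture_weights is not None
        else np.full(n_arch, 1.0 / n_arch)
    )
    horizon_days = config.follow_up_months * DAYS_PER_MONTH
    patients: list[PatientRecord] = []
    truths: list[GroundTruth] = []
    for i in range(config.n_patients):
        child = np.random.default_rng(rng.integers(2**31 - 1))
        ai = int(child.choice(n_arch, p=weights))
        arche = config.archetypes[ai]
        age = float(
            np.clip(
                child.normal(config.age_onset_mean, config.age_onset_sd), 10.0, 55.0
            )
        )
        ami0 = initial_myelination(age)
        bi = min(child.normal(config.bi_mean, config.bi_sd), -1e-4)
        ci = child.normal(config.ci_mean, config.ci_sd)
        calib = derive_scaling(bi, ci, ami0)
        train, t_out, states = _simulate_patient(
            arche,
            ami0,
            horizon_days,
            child,
            config.step_days,
            config.out_spacing_days,
            deterministic=config.deterministic_trains,
        )
        edss_s = np.maximum(states[:, 1], states[:, 3])
        vs = states[:, 0] + states[:, 1]

        # irregular visit schedule
        t_visits = [0.0]
        while True:
            gap = max(
                0.5,
                child.normal(config.visit_spacing_months, config.visit_jitter_months),
            )
            nxt = t_visits[-1] + gap
            if nxt > config.follow_up_months:
                break
            t_visits.append(nxt)
        keep = [0] + [
            j
            for j in range(1, len(t_visits))
            if child.random() >= config.missing_rate
        ]
        if len(keep) < 2 and len(t_visits) > 1:
            keep = [0, len(t_visits) - 1]
        visits = []
        for j in keep:
            tm = t_visits[j]
            td = tm * DAYS_PER_MONTH
            e_raw = calib.kei * np.interp(td, t_out, edss_s)
            e = quantize_edss(
                float(np.clip(e_raw + child.normal(0.0, config.edss_noise_sd), 0, 10))
            )
            bv_val = None
            if config.with_bv:
                bv_val = float(
                    calib.kbi * np.interp(td, t_out, vs)
                    + calib.vdi
                    + child.normal(0.0, config.bv_noise_sd)
                )
            visits.append(Visit(time=tm, edss=float(e), bv=bv_val))
        pid = f"synth-{i:04d}"
        patients.append(
            PatientRecord(
                patient_id=pid, visits=visits, subtype=arche.subtype, age_onset=age
            )
        )
        truths.append(
            GroundTruth(
                patient_id=pid,
                archetype=arche.name,
                archetype_index=ai,
                params=arche.params,
                train=train,
                calib=calib,
                age_onset=age,
            )
        )
    return Cohort(patients=patients, label=f"synthetic-seed{config.seed}"), truths
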