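"""Stochastic inflammatory forcing derived from EDSS time series.

Confirmed disability-progression events (an EDSS increase of at least one
point sustained at a visit three or more months later) are extracted from
clinical series; the intervals between consecutive events are fitted with
candidate heavy-tailed distributions (the generalized extreme value family is
the reference model for these rare-event intervals); and new attack trains
are sampled from the fitted interval and amplitude distributions to drive the
ODE forcing ``lam(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import interpolate, stats

from .core_model import DAYS_PER_MONTH, EDSS_MAX
from .io_cohort import PatientRecord

__all__ = [
    "DeltaEvent",
    "IntervalSample",
    "IntervalDistribution",
    "PulseTrain",
    "FAMILIES",
    "extract_confirmed_events",
    "interevent_intervals",
    "fit_interval_distribution",
    "sample_pulse_train",
    "build_lambda",
]


@dataclass(frozen=True)
class DeltaEvent:
    """One confirmed ΔEDSS progression event."""

    onset_time: float  # months from onset
    delta_edss: float  # score increase, >= 1
    confirmed_at: float  # months; confirmed_at - onset_time >= 3

    def __post_init__(self) -> None:
        if self.delta_edss < 1:
            raise ValueError("delta_edss must be >= 1")
        if self.confirmed_at - self.onset_time < 3 - 1e-9:
            raise ValueError("confirmation must be >= 3 months after onset")


@dataclass
class IntervalSample:
    """Inter-event intervals ΔT (months) from one patient or a pooled cluster."""

    dt_values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.dt_values = np.asarray(self.dt_values, dtype=float)
        if self.dt_values.size and np.min(self.dt_values) <= 0:
            raise ValueError("intervals must be positive")


@dataclass
class IntervalDistribution:
    """A fitted candidate distribution for ΔT, ranked by information criterion.

    For the GEV family ``params`` holds (shape, loc, scale) in the standard
    extreme-value convention (shape xi > 0 = heavy Frechet tail); scipy's
    ``genextreme`` uses c = -xi internally.
    """

    family: str
    params: dict
    criterion_value: float
    log_likelihood: float = math.nan

    def __post_init__(self) -> None:
        scale = self.params.get("scale")
        if scale is not None and scale <= 0:
            raise ValueError("scale parameter must be positive")

    def _frozen(self):
        p = self.params
        if self.family == "GEV":
            return stats.genextreme(-p["shape"], loc=p["loc"], scale=p["scale"])
        if self.family == "inverse-Gaussian":
            return stats.invgauss(p["mu"], loc=p["loc"], scale=p["scale"])
        if self.family == "logistic":
            return stats.logistic(loc=p["loc"], scale=p["scale"])
        if self.family == "exponential":
            return stats.expon(loc=p["loc"], scale=p["scale"])
        if self.family == "t-location-scale":
            return stats.t(p["df"], loc=p["loc"], scale=p["scale"])
        raise ValueError(f"unknown family {self.family!r}")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=size, random_state=rng)

    def mean(self) -> float:
        return float(self._frozen().mean())


FAMILIES = ("GEV", "inverse-Gaussian", "logistic", "exponential", "t-location-scale")

_SCIPY_DISTS = {
    "GEV": stats.genextreme,
    "inverse-Gaussian": stats.invgauss,
    "logistic": stats.logistic,
    "exponential": stats.expon,
    "t-location-scale": stats.t,
}

_N_PARAMS = {
    "GEV": 3,
    "inverse-Gaussian": 3,
    "logistic": 2,
    "exponential": 2,
    "t-location-scale": 3,
}


@dataclass
class PulseTrain:
    """Rectangular attack pulses: lam jumps to ``amplitude`` for ``width`` days
    after each event time; overlapping pulses add."""

    event_times: np.ndarray  # days, increasing
    amplitudes: np.ndarray  # peak lam values, 1/day, >= 0
    width: float = 30.0  # days
    baseline_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.event_times.size != self.amplitudes.size:
            raise ValueError("event_times and amplitudes must align")
        if self.event_times.size and np.any(np.diff(self.event_times) < 0):
            raise ValueError("event times must be increasing")
        if self.amplitudes.size and np.min(self.amplitudes) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.width <= 0:
            raise ValueError("pulse width must be positive")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


def extract_confirmed_events(patient: PatientRecord) -> list[DeltaEvent]:
    """Scan a patient's visits for confirmed ΔEDSS progression events.

    A rolling confirmed baseline starts at the first visit's EDSS.  An event
    fires at visit j when ``edss_j - baseline >= 1`` and some later visit k
    with ``t_k - t_j >= 3`` months still shows ``edss_k - baseline >= 1``;
    the baseline then resets to ``edss_j``.
    """
    visits = patient.visits
    if len(visits) < 2:
        return []
    times = np.array([v.time for v in visits])
    edss = np.array([v.edss for v in visits])
    events: list[DeltaEvent] = []
    baseline = edss[0]
    j = 1
    while j < len(visits):
        if edss[j] - baseline >= 1:
            later = np.where(
                (times - times[j] >= 3 - 1e-9) & (edss - baseline >= 1)
            )[0]
            later = later[later > j]
            if later.size:
                events.append(
                    DeltaEvent(
                        onset_time=float(times[j]),
                        delta_edss=float(edss[j] - baseline),
                        confirmed_at=float(times[later[0]]),
                    )
                )
                baseline = edss[j]
        j += 1
    return events


def interevent_intervals(
    events: Sequence[DeltaEvent], source: str = ""
) -> IntervalSample:
    """ΔT between consecutive event onsets; empty when fewer than 2 events."""
    if len(events) < 2:
        return IntervalSample(np.empty(0), source)
    onsets = np.array([e.onset_time for e in events])
    return IntervalSample(np.diff(onsets), source)


def fit_interval_distribution(
    sample: IntervalSample,
    families: Iterable[str] = FAMILIES,
    criterion: str = "bic",
    min_size: int = 8,
) -> list[IntervalDistribution]:
    """Maximum-likelihood fit of each candidate family, ranked best-first.

    Ranking uses BIC by default (``criterion="aic"`` for AIC).  Raises on
    samples smaller than ``min_size`` or with no spread.
    """
    x = sample.dt_values
    n = x.size
    if n < min_size:
        raise ValueError(f"sample too small: {n} < {min_size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all intervals identical")
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")

    results: list[IntervalDistribution] = []
    for fam in families:
        if fam not in _SCIPY_DISTS:
            raise ValueError(f"unknown family {fam!r}")
        dist = _SCIPY_DISTS[fam]
        try:
            if fam in ("inverse-Gaussian", "exponential"):
                # supported on [loc, inf); anchor loc below the sample minimum
                fitted = dist.fit(x, floc=0.0) if x.min() > 0 else dist.fit(x)
            else:
                fitted = dist.fit(x)
            ll = float(np.sum(dist.logpdf(x, *fitted)))
        except Exception:
            continue
        if not np.isfinite(ll):
            continue
        k = _N_PARAMS[fam]
        crit = k * math.log(n) - 2 * ll if criterion == "bic" else 2 * k - 2 * ll
        if fam == "GEV":
            c, loc, scale = fitted
            params = {"shape": -c, "loc": loc, "scale": scale}
        elif fam == "inverse-Gaussian":
            mu, loc, scale = fitted
            params = {"mu": mu, "loc": loc, "scale": scale}
        elif fam == "t-location-scale":
            df, loc, scale = fitted
            params = {"df": df, "loc": loc, "scale": scale}
        else:
            loc, scale = fitted
            params = {"loc": loc, "scale": scale}
        results.append(
            IntervalDistribution(
                family=fam, params=params, criterion_value=crit, log_likelihood=ll
            )
        )
    if not results:
        raise RuntimeError("no candidate family could be fitted")
    results.sort(key=lambda r: r.criterion_value)
    return results


def sample_pulse_train(
    dist_dt: IntervalDistribution,
    dist_amp,
    horizon: float,
    rng: np.random.Generator,
    n_events_cap: int = 1000,
    amp_scale: float = 0.05,
    width: float = 30.0,
) -> PulseTrain:
    """Draw one attack train over ``horizon`` days.

    Renewal process: i.i.d. ΔT draws (months, negative draws rejected and
    resampled) are cumulated into event times; each event's peak intensity is
    ``amp_scale * dEDSS / EDSS_MAX`` with the ΔEDSS magnitude drawn from
    ``dist_amp`` (anything with an ``rvs``-style ``sample(size, rng)`` or a
    callable returning draws).
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    times: list[float] = []
    t = 0.0
    while len(times) < n_events_cap:
        dt = math.nan
        for _ in range(1000):
            dt = float(dist_dt.sample(1, rng)[0])
            if dt > 0:
                break
        if not dt > 0:
            raise RuntimeError("interval distribution yields no positive draws")
        t += dt * DAYS_PER_MONTH
        if t > horizon:
            break
        times.append(t)
    times_arr = np.array(times)
    if hasattr(dist_amp, "sample"):
        amps_edss = np.asarray(dist_amp.sample(len(times), rng), dtype=float)
    else:
        amps_edss = np.asarray(dist_amp(len(times), rng), dtype=float)
    amps = amp_scale * np.clip(amps_edss, 0.0, None) / EDSS_MAX
    return PulseTrain(event_times=times_arr, amplitudes=amps, width=width)


def build_lambda(
    train: PulseTrain,
    rng: np.random.Generator | None = None,
    smooth: bool = False,
    horizon: float | None = None,
    jitter_rel_sd: float = 0.1,
    inv_chi2_df: float = 3.0,
    knot_spacing: float = 5.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Turn a pulse train into a callable forcing ``lam(t) >= 0``.

    With ``smooth`` off the pulses are evaluated piecewise-constantly.  With
    ``smooth`` on, the pulse profile is sampled on a knot grid, zero-mean
    normal jitter is added (one variance per train, drawn as
    ``(jitter_rel_sd * peak)^2 * df / chi2(df)`` — an inverse-chi-squared
    spread emulating between-train baseline diversity), a smoothing spline is
    fitted through the jittered points, and the result is clipped at zero.
    """
    events = train.event_times
    amps = train.amplitudes
    width = train.width
    baseline = train.baseline_fn

    def piecewise(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        for e, a in zip(events, amps):
            out += np.where((t >= e) & (t < e + width), a, 0.0)
        if baseline is not None:
            out = out + np.clip(baseline(t), 0.0, None)
        return out

    if not smooth:
        return piecewise

    if rng is None:
        raise ValueError("smooth mode requires a seeded rng")
    if horizon is None:
        horizon = float(events[-1] + 2 * width) if events.size else 10 * width
    knots = np.arange(0.0, horizon + knot_spacing, knot_spacing)
    base = piecewise(knots)
    peak = float(amps.max()) if amps.size else 1e-3
    sigma2 = (jitter_rel_sd * peak) ** 2 * inv_chi2_df / float(
        stats.chi2.rvs(inv_chi2_df, random_state=rng)
    )
    jittered = base + rng.normal(0.0, math.sqrt(sigma2), size=knots.shape)
    spline = interpolate.make_smoothing_spline(knots, jittered)

    def smooth_fn(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.clip(spline(np.clip(t, knots[0], knots[-1])), 0.0, None)

    return smooth_fn
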