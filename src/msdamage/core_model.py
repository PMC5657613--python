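"""Four-compartment ODE of CNS damage in multiple sclerosis.

The model tracks the volume fraction of the normalized healthy brain occupied
by myelinated axons (``Am``) and demyelinated axons (``Ad``), the myelination
capacity of the oligodendrocyte system (``M``, in healthy-adult-brain units)
and the cumulative fraction of irreversibly degenerated axons (``D``).
Autoimmune attack enters as a non-negative time-dependent forcing ``lam(t)``
(1/day) that strips myelin from intact axons:

    dAm/dt = km*Ad*M - lam(t)*Am - kmd*Am
    dAd/dt = -km*Ad*M + lam(t)*Am - kd*Ad
    dM/dt  = -km*Ad*M + delta*Ad*M**q
    dD/dt  = kd*Ad + kmd*Am

``Am + Ad + D`` is conserved exactly (damage moves axons between the three
pools; ``M`` is a resource, not part of the conserved volume).  Clinical
readouts are derived from a trajectory: the structural volume ``Vs = Am + Ad``
maps linearly to normalized brain volume, and disability is read out as
``max(Ad, D)`` scaled to the EDSS.

Rates are per day; clinical series are in months (1 month = 30.4375 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DAYS_PER_MONTH",
    "EDSS_MAX",
    "PARAM_BOUNDS",
    "PARAM_NAMES",
    "ModelParams",
    "ModelState",
    "Trajectory",
    "derivatives",
    "simulate",
    "simulate_batch",
    "edss_readout",
    "bv_readout",
    "quantize_edss",
]

#: Days per month used to convert clinical (month) time to model (day) time.
DAYS_PER_MONTH = 30.4375

#: Maximal EDSS score (death due to MS).
EDSS_MAX = 10.0

PARAM_NAMES = ("km", "kmd", "kd", "q", "delta")

#: Biologically plausible ranges for the five rate/shape constants.
PARAM_BOUNDS = {
    "km": (0.0, 100.0),
    "kmd": (0.0, 0.01),
    "kd": (0.0, 1.0),
    "q": (0.0, 1.0),
    "delta": (0.0, 1.0),
}


@dataclass(frozen=True)
class ModelParams:
    """The five biological constants of the damage model.

    Parameters
    ----------
    km : float
        Remyelination rate (myelin sheets produced per day), 1/day.
    kmd : float
        Acute loss rate of myelinated axons (transection in acute plaques), 1/day.
    kd : float
        Delayed loss rate of demyelinated axons (chronic plaques), 1/day.
    q : float
        Cooperativity of myelin-sheet production; sub-linear growth of the
        myelination capacity requires ``q < 1``.
    delta : float
        Growth rate of the myelination capacity, 1/day.
    """

    km: float
    kmd: float
    kd: float
    q: float
    delta: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")

    def validate_ranges(self) -> None:
        """Raise if any parameter lies outside its biological range."""
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside biological range [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.km, self.kmd, self.kd, self.q, self.delta])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ModelParams":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state (Am, Ad, M, D); all components non-negative."""

    am: float
    ad: float
    m: float
    d: float

    def __post_init__(self) -> None:
        if min(self.am, self.ad, self.m, self.d) < 0:
            raise ValueError("state components must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.am, self.ad, self.m, self.d])

    @classmethod
    def healthy(cls, am0: float = 1.0) -> "ModelState":
        """All axons myelinated, capacity at the healthy baseline."""
        return cls(am=am0, ad=0.0, m=1.0, d=0.0)


@dataclass
class Trajectory:
    """Simulated time course on a day grid, with derived readout series."""

    t: np.ndarray  # days, strictly increasing
    am: np.ndarray
    ad: np.ndarray
    m: np.ndarray
    d: np.ndarray

    @property
    def vs(self) -> np.ndarray:
        """Structural volume fraction Vs = Am + Ad."""
        return self.am + self.ad

    @property
    def edss_s(self) -> np.ndarray:
        """Unscaled simulated disability max(Ad, D), in [0, Am0+Ad0+D0]."""
        return np.maximum(self.ad, self.d)

    @property
    def conserved(self) -> np.ndarray:
        return self.am + self.ad + self.d

    def conservation_drift(self) -> float:
        c = self.conserved
        return float(np.max(np.abs(c - c[0])))


def derivatives(state: ModelState, params: ModelParams, lam: float) -> ModelState:
    """Right-hand side of the model at one state and attack intensity.

    Returns the per-field rates (1/day) packed in a :class:`ModelState`-shaped
    record (rates may be negative; no positivity check is applied to them).
    ``dAm + dAd + dD = 0`` holds exactly by construction.
    """
    if lam < 0:
        raise ValueError("attack intensity lam must be non-negative")
    if min(state.am, state.ad, state.m, state.d) < 0:
        raise ValueError("state components must be non-negative")
    remyel = params.km * state.ad * state.m
    dam = remyel - lam * state.am - params.kmd * state.am
    dad = -remyel + lam * state.am - params.kd * state.ad
    dm = -remyel + params.delta * state.ad * state.m**params.q
    dd = params.kd * state.ad + params.kmd * state.am
    out = ModelState.__new__(ModelState)
    object.__setattr__(out, "am", dam)
    object.__setattr__(out, "ad", dad)
    object.__setattr__(out, "m", dm)
    object.__setattr__(out, "d", dd)
    return out


def _rhs_batch(y: np.ndarray, p: np.ndarray, lam: np.ndarray | float) -> np.ndarray:
    """Vectorized RHS.  y: (n, 4) states; p: (n, 5) params; lam scalar or (n,)."""
    am, ad, m = y[:, 0], y[:, 1], y[:, 2]
    km, kmd, kd, q, delta = p[:, 0], p[:, 1], p[:, 2], p[:, 3], p[:, 4]
    remyel = km * ad * m
    attack = lam * am
    dy = np.empty_like(y)
    dy[:, 0] = remyel - attack - kmd * am
    dy[:, 1] = -remyel + attack - kd * ad
    # m**q on the clipped capacity (intermediate RK4 stages may dip below 0);
    # numpy gives 0**0 = 1, the correct q -> 0 limit
    dy[:, 2] = -remyel + delta * ad * np.maximum(m, 0.0) ** q
    dy[:, 3] = kd * ad + kmd * am
    return dy


def _step_all_numpy(
    params: np.ndarray,
    y: np.ndarray,
    h_all: np.ndarray,
    nsubs: np.ndarray,
    lam0: np.ndarray,
    lamh: np.ndarray,
    lam1: np.ndarray,
    m_cap: float,
    out: np.ndarray,
    max_refine: int = 1,  # stiffness refinement lives in the JIT kernel
) -> None:
    i = 0
    for j in range(1, out.shape[1]):
        for _ in range(nsubs[j - 1]):
            h = h_all[i]
            k1 = _rhs_batch(y, params, lam0[:, i])
            k2 = _rhs_batch(y + 0.5 * h * k1, params, lamh[:, i])
            k3 = _rhs_batch(y + 0.5 * h * k2, params, lamh[:, i])
            k4 = _rhs_batch(y + h * k3, params, lam1[:, i])
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            neg_am = np.minimum(y[:, 0], 0.0)
            neg_ad = np.minimum(y[:, 1], 0.0)
            y[:, 0] -= neg_am
            y[:, 1] -= neg_ad
            y[:, 3] += neg_am + neg_ad
            np.clip(y[:, 2], 0.0, m_cap, out=y[:, 2])
            np.maximum(y[:, 3], 0.0, out=y[:, 3])
            i += 1
        out[:, j] = y


try:  # JIT-compiled stepping kernel; numpy fallback keeps results identical
    import numba as _numba

    @_numba.njit(cache=False, inline="always")
    def _rk4_one(am, ad, m, d, km, kmd, kd, q, delta, l0, lh, l1, h):  # pragma: no cover
        rem = km * ad * m
        mp = m if m > 0.0 else 0.0
        a1 = rem - l0 * am - kmd * am
        b1 = -rem + l0 * am - kd * ad
        c1 = -rem + delta * ad * mp**q
        d1 = kd * ad + kmd * am

        ua = am + 0.5 * h * a1
        ub = ad + 0.5 * h * b1
        um = m + 0.5 * h * c1
        rem = km * ub * um
        mp = um if um > 0.0 else 0.0
        a2 = rem - lh * ua - kmd * ua
        b2 = -rem + lh * ua - kd * ub
        c2 = -rem + delta * ub * mp**q
        d2 = kd * ub + kmd * ua

        ua = am + 0.5 * h * a2
        ub = ad + 0.5 * h * b2
        um = m + 0.5 * h * c2
        rem = km * ub * um
        mp = um if um > 0.0 else 0.0
        a3 = rem - lh * ua - kmd * ua
        b3 = -rem + lh * ua - kd * ub
        c3 = -rem + delta * ub * mp**q
        d3 = kd * ub + kmd * ua

        ua = am + h * a3
        ub = ad + h * b3
        um = m + h * c3
        rem = km * ub * um
        mp = um if um > 0.0 else 0.0
        a4 = rem - l1 * ua - kmd * ua
        b4 = -rem + l1 * ua - kd * ub
        c4 = -rem + delta * ub * mp**q
        d4 = kd * ub + kmd * ua

        h6 = h / 6.0
        am += h6 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        ad += h6 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        m += h6 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
        d += h6 * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        return am, ad, m, d

    @_numba.njit(cache=False, fastmath=False)
    def _step_all_jit(params, y, h_all, nsubs, lam0, lamh, lam1, m_cap, out, max_refine):  # pragma: no cover - exercised via simulate_batch
        n = y.shape[0]
        alive = np.ones(n, dtype=np.bool_)
        i = 0
        for j in range(1, out.shape[1]):
            for _ in range(nsubs[j - 1]):
                h = h_all[i]
                for r in range(n):
                    if not alive[r]:
                        continue
                    km = params[r, 0]
                    kmd = params[r, 1]
                    kd = params[r, 2]
                    q = params[r, 3]
                    delta = params[r, 4]
                    l0 = lam0[r, i]
                    lh = lamh[r, i]
                    l1 = lam1[r, i]
                    am = y[r, 0]
                    ad = y[r, 1]
                    m = y[r, 2]
                    d = y[r, 3]
                    # stiffness-driven local refinement: the fastest local
                    # timescale is the demyelinated-pool turnover km*M + kd
                    lmax = l0 if l0 > lh else lh
                    if l1 > lmax:
                        lmax = l1
                    rate = km * (m if m > 0.0 else 0.0) + kd + kmd + lmax
                    nloc = int(0.5 * h * rate) + 1
                    if nloc > max_refine:
                        nloc = max_refine
                    gross = False
                    if nloc == 1:
                        am, ad, m, d = _rk4_one(
                            am, ad, m, d, km, kmd, kd, q, delta, l0, lh, l1, h
                        )
                        if am < 0.0:
                            if am < -0.25:
                                gross = True
                            d += am
                            am = 0.0
                        if ad < 0.0:
                            if ad < -0.25:
                                gross = True
                            d += ad
                            ad = 0.0
                        if m < 0.0:
                            m = 0.0
                        elif m > m_cap:
                            m = m_cap
                        if d < 0.0:
                            d = 0.0
                    else:
                        hl = h / nloc
                        for sub in range(nloc):
                            f = (sub + 0.5) / nloc
                            ll = l0 if f < 0.25 else (lh if f < 0.75 else l1)
                            am, ad, m, d = _rk4_one(
                                am, ad, m, d, km, kmd, kd, q, delta, ll, ll, ll, hl
                            )
                            if am < 0.0:
                                if am < -0.25:
                                    gross = True
                                d += am
                                am = 0.0
                            if ad < 0.0:
                                if ad < -0.25:
                                    gross = True
                                d += ad
                                ad = 0.0
                            if m < 0.0:
                                m = 0.0
                            elif m > m_cap:
                                m = m_cap
                            if d < 0.0:
                                d = 0.0
                    finite = (
                        np.isfinite(am)
                        and np.isfinite(ad)
                        and np.isfinite(m)
                        and np.isfinite(d)
                    )
                    if not finite or gross or am > 1e6 or ad > 1e6 or m > 1e9:
                        alive[r] = False
                        am = np.nan
                        ad = np.nan
                        m = np.nan
                        d = np.nan
                    y[r, 0] = am
                    y[r, 1] = ad
                    y[r, 2] = m
                    y[r, 3] = d
                i += 1
            for r in range(n):
                out[r, j, 0] = y[r, 0]
                out[r, j, 1] = y[r, 1]
                out[r, j, 2] = y[r, 2]
                out[r, j, 3] = y[r, 3]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def simulate_batch(
    params: np.ndarray,
    lam_fn: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    t_grid: np.ndarray,
    step: float = 0.25,
    m_cap: float | None = None,
    nan_policy: str = "raise",
    max_refine: int = 16,
) -> np.ndarray:
    """Integrate the model for many parameter sets under one shared forcing.

    Fixed-step classical RK4.  Between consecutive output times the step is
    shrunk to divide the interval exactly.  After every step, negative ``Am``
    or ``Ad`` is clipped to zero and the clipped mass is routed to ``D`` so the
    conservation law survives aggressive steps; negative ``M`` is clipped.

    Parameters
    ----------
    params : (n, 5) array
        One row per parameter set, ordered (km, kmd, kd, q, delta).
    lam_fn : callable
        Vectorized map from times (days) to attack intensities (>= 0).
    init : (4,) or (n, 4) array
        Initial state(s) (Am, Ad, M, D).
    t_grid : (T,) array
        Strictly increasing output times in days.
    step : float
        Nominal RK4 step in days; must not exceed the minimal grid spacing.

    ``nan_policy="raise"`` aborts on a non-finite state (divergence) with the
    diagnostic time; ``"propagate"`` marks diverged rows NaN and lets them
    flow through so a caller exploring unstable parameter regions can
    penalize them.  When a row's fastest local timescale (demyelinated-pool
    turnover ``km*M + kd`` plus the forcing) is too fast for ``step``, the
    step is refined locally for that row, up to ``max_refine``-fold; rows
    stiffer than that diverge and are treated per ``nan_policy``.

    Returns
    -------
    (n, T, 4) array of states at the output times.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a 1-D array with at least one time")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    spacings = np.diff(t_grid)
    if spacings.size and step > np.min(spacings) + 1e-12:
        raise ValueError("step must not exceed the minimal grid spacing")
    n = params.shape[0]
    y = np.array(np.broadcast_to(np.asarray(init, dtype=float), (n, 4)))
    if np.min(y) < 0:
        raise ValueError("initial state must be non-negative")

    # substep plan: step counts and sizes per output interval, then one
    # vectorized evaluation of the forcing at every RK4 stage time
    nsubs = np.maximum(1, np.ceil(spacings / step - 1e-9).astype(int))
    hs = spacings / nsubs
    t_starts: list[np.ndarray] = []
    for j, (t0, nsub, h) in enumerate(zip(t_grid[:-1], nsubs, hs)):
        t_starts.append(t0 + h * np.arange(nsub))
    starts = np.concatenate(t_starts) if t_starts else np.empty(0)
    h_all = np.repeat(hs, nsubs)

    def _lam_at(t: np.ndarray) -> np.ndarray:
        v = np.asarray(lam_fn(t), dtype=float)
        if v.ndim == 1:  # shared forcing
            v = np.broadcast_to(v, (n, v.size))
        return np.ascontiguousarray(v)

    lam0 = _lam_at(starts)
    lamh = _lam_at(starts + 0.5 * h_all)
    lam1 = _lam_at(starts + h_all)
    if lam0.size and min(lam0.min(), lamh.min(), lam1.min()) < 0:
        raise ValueError("attack intensity lam must be non-negative")

    out = np.empty((n, len(t_grid), 4))
    out[:, 0] = y
    cap = np.inf if m_cap is None else float(m_cap)
    stepper = _step_all_jit if _HAVE_NUMBA else _step_all_numpy
    stepper(
        np.ascontiguousarray(params),
        np.ascontiguousarray(y),
        h_all,
        nsubs,
        lam0,
        lamh,
        lam1,
        cap,
        out,
        max_refine,
    )
    if nan_policy == "raise" and not np.all(np.isfinite(out)):
        bad_t = t_grid[np.where(~np.isfinite(out).all(axis=(0, 2)))[0][0]]
        raise FloatingPointError(f"simulation diverged near t={bad_t:.2f} days")
    return out


def simulate(
    params: ModelParams,
    lam_fn: Callable[[np.ndarray], np.ndarray] | None,
    init: ModelState,
    t_grid: np.ndarray,
    step: float = 0.25,
    m_cap: float | None = None,
    max_refine: int = 16,
) -> Trajectory:
    """Integrate one parameter set; see :func:`simulate_batch` for semantics.

    ``lam_fn=None`` means no inflammatory forcing (lam identically zero).
    """
    if lam_fn is None:
        lam_fn = lambda t: np.zeros_like(np.asarray(t, dtype=float))
    states = simulate_batch(
        params.as_array()[None, :], lam_fn, init.as_array(), t_grid, step, m_cap,
        max_refine=max_refine,
    )[0]
    return Trajectory(
        t=np.asarray(t_grid, dtype=float),
        am=states[:, 0],
        ad=states[:, 1],
        m=states[:, 2],
        d=states[:, 3],
    )


def quantize_edss(edss: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest 0.5 EDSS step, ties toward higher disability,
    capped at :data:`EDSS_MAX`."""
    q = np.floor(np.asarray(edss, dtype=float) * 2.0 + 0.5) / 2.0
    q = np.clip(q, 0.0, EDSS_MAX)
    return float(q) if np.isscalar(edss) else q


def edss_readout(traj: Trajectory, calib, quantize: bool = False) -> np.ndarray:
    """Clinical EDSS series ``kei * max(Ad, D)``; optionally quantized to the
    half-point clinical scale."""
    if calib.kei <= 0:
        raise ValueError("calibration kei must be positive")
    edss = calib.kei * traj.edss_s
    if quantize:
        edss = quantize_edss(edss)
    return edss


def bv_readout(traj: Trajectory, calib) -> np.ndarray:
    """Normalized brain-volume series ``kbi * Vs + Vdi``."""
    for v in (calib.kbi, calib.vdi):
        if not np.isfinite(v):
            raise ValueError("calibration fields must be finite")
    return calib.kbi * traj.vs + calib.vdi
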