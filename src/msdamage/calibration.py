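"""Linking the damage model to clinical readouts and fitting its parameters.

Per-patient calibration constants tie the simulated volume fractions to the
observed EDSS and normalized brain volume:

    kei = EDSS_max / Am(0)          (EDSS per unit damaged fraction)
    kbi = -kei * Bi                 (volume per unit structural fraction)
    Vdi = Ci + EDSS_max * Bi        (residual volume at maximal disability)

where Bi (slope, expected negative) and Ci (intercept) come from the ordinary
least-squares line of BV on EDSS at out-of-relapse visits, and the initial
myelinated fraction Am(0) declines ~1% per year of onset age above 20.

Cluster-level parameters of the ODE are estimated with a real-coded genetic
algorithm (tournament selection, blend crossover, adaptive Gaussian mutation,
elitism) minimizing the squared EDSS error on a random half of the data
points, simulation averaged over several stochastic attack trains; the 10
best parameter sets form the retained ensemble.  Subtype-specific ensembles
are the cluster-count-weighted linear combinations of the cluster ensembles,
compared with pairwise rank-sum tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core_model import (
    DAYS_PER_MONTH,
    EDSS_MAX,
    PARAM_BOUNDS,
    PARAM_NAMES,
    ModelParams,
    simulate_batch,
)
from .inflammatory import PulseTrain, build_lambda
from .io_cohort import PatientRecord

__all__ = [
    "PatientCalibration",
    "FitEnsemble",
    "GAConfig",
    "ClusterSeries",
    "initial_myelination",
    "fit_bv_edss_line",
    "derive_scaling",
    "objective_sse",
    "fit_parameters_ga",
    "subtype_parameters",
    "compare_subtype_params",
]


@dataclass(frozen=True)
class PatientCalibration:
    """Scaling constants linking simulation to a patient's clinical readouts."""

    bi: float  # slope of BV on EDSS (expected < 0)
    ci: float  # intercept (normalized volume)
    kei: float  # EDSS per damaged volume fraction
    kbi: float  # volume per structural volume fraction
    vdi: float  # residual minimal volume
    ami0: float  # initial myelinated fraction, <= 1
    edss_max: float = EDSS_MAX

    def edss_from_sim(self, edss_s: np.ndarray) -> np.ndarray:
        """Forward map: simulated damage fraction -> clinical EDSS."""
        return self.edss_max * np.asarray(edss_s) / self.ami0

    def bv_from_sim(self, vs: np.ndarray) -> np.ndarray:
        """Forward map: simulated structural fraction -> normalized BV."""
        return -self.kei * self.bi * np.asarray(vs) + self.vdi

    def sim_from_bv(self, bv: np.ndarray) -> np.ndarray:
        """Inverse map: normalized BV -> simulated structural fraction."""
        return (
            self.ami0
            / (self.edss_max * self.bi)
            * (self.ci + self.edss_max * self.bi - np.asarray(bv))
        )

    def sim_from_edss(self, edss: np.ndarray) -> np.ndarray:
        """Inverse map: clinical EDSS -> simulated damage fraction."""
        return np.asarray(edss) * self.ami0 / self.edss_max


@dataclass
class GAConfig:
    population: int = 100
    generations: int = 500
    crossover_rate: float = 0.8
    tournament: int = 3
    elite: int = 2
    mutation_prob: float = 0.25
    mutation_sd0: float = 0.25  # initial per-gene sd on the unit cube
    mutation_sd_final: float = 0.02  # adaptive shrink target
    top_n: int = 10
    n_trains: int = 5
    log_scale: bool = True  # search rate constants on a log axis (q stays linear)
    patience: int | None = 30  # stop early after this many stale generations
    max_points: int = 120
    step_days: float = 1.0
    out_spacing_days: float = 10.0


@dataclass
class FitEnsemble:
    cluster_id: int
    param_sets: list[tuple[ModelParams, float]]  # ranked by train objective
    test_objectives: list[float]
    ga_config: GAConfig
    split_seed: int
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        objs = [o for _, o in self.param_sets]
        if any(b < a - 1e-12 for a, b in zip(objs, objs[1:])):
            raise ValueError("objective values must be non-decreasing in rank")
        for p, _ in self.param_sets:
            p.validate_ranges()

    @property
    def best(self) -> ModelParams:
        return self.param_sets[0][0]

    def params_matrix(self) -> np.ndarray:
        return np.vstack([p.as_array() for p, _ in self.param_sets])


@dataclass
class ClusterSeries:
    """Observed EDSS data points of one cluster: flattened (time, score) pairs."""

    times_months: np.ndarray
    edss: np.ndarray
    cluster_id: int = 0

    def __post_init__(self) -> None:
        self.times_months = np.asarray(self.times_months, dtype=float)
        self.edss = np.asarray(self.edss, dtype=float)
        if self.times_months.size != self.edss.size:
            raise ValueError("times and scores must align")
        if self.times_months.size == 0:
            raise ValueError("empty cluster data")


def initial_myelination(age_onset: float, floor: float = 0.5) -> float:
    """Initial myelinated fraction: 1 below onset age 20, then declining by
    1% per year of age, floored."""
    if age_onset < 0:
        raise ValueError("age at onset must be non-negative")
    if age_onset < 20:
        return 1.0
    return max(1.0 - (age_onset - 20.0) * 0.01, floor)


def fit_bv_edss_line(
    patient: PatientRecord, exclude_months: Sequence[float] = (), window: float = 3.0
) -> tuple[float, float, float]:
    """OLS of BV on EDSS over out-of-relapse paired visits -> (Bi, Ci, r).

    ``exclude_months`` lists relapse onset months; visits within ``window``
    months after an onset are dropped as in-relapse measurements.
    """
    ts, xs, ys = [], [], []
    for v in patient.visits:
        if v.bv is None:
            continue
        if any(0 <= v.time - m < window for m in exclude_months):
            continue
        ts.append(v.time)
        xs.append(v.edss)
        ys.append(v.bv)
    if len(xs) < 3:
        raise ValueError(
            f"patient {patient.patient_id}: need >= 3 paired out-of-relapse "
            f"visits, got {len(xs)}"
        )
    if np.ptp(xs) == 0:
        raise ValueError("zero EDSS variance; BV-EDSS line undefined")
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def derive_scaling(
    bi: float, ci: float, ami0: float, edss_max: float = EDSS_MAX
) -> PatientCalibration:
    """Derive (kei, kbi, Vdi) from the BV-EDSS line and the initial state."""
    if ami0 <= 0:
        raise ValueError("Ami0 must be positive")
    if bi == 0:
        warnings.warn("flat BV-EDSS line: kbi = 0, BV carries no damage signal")
    kei = edss_max / ami0
    kbi = -kei * bi
    vdi = ci + edss_max * bi
    return PatientCalibration(
        bi=bi, ci=ci, kei=kei, kbi=kbi, vdi=vdi, ami0=ami0, edss_max=edss_max
    )


def _sim_edss_at(
    params: np.ndarray,
    trains: Sequence[PulseTrain],
    calib: PatientCalibration,
    times_months: np.ndarray,
    cfg: GAConfig,
) -> np.ndarray:
    """Mean simulated EDSS for each parameter row at the observation months,
    averaged over the attack trains.  params: (n, 5) -> (n, T)."""
    t_obs = np.asarray(times_months, dtype=float) * DAYS_PER_MONTH
    horizon = float(t_obs.max()) + 1.0
    t_out = np.arange(0.0, horizon + cfg.out_spacing_days, cfg.out_spacing_days)
    init = np.array([calib.ami0, 0.0, 1.0, 0.0])
    acc = np.zeros((params.shape[0], t_obs.size))
    for train in trains:
        lam = build_lambda(train)
        with np.errstate(all="ignore"):
            states = simulate_batch(
                params, lam, init, t_out, step=cfg.step_days, nan_policy="propagate"
            )
        edss_s = np.maximum(states[:, :, 1], states[:, :, 3])
        edss = calib.kei * edss_s
        for i in range(edss.shape[0]):
            acc[i] += np.interp(t_obs, t_out, edss[i])
    return acc / len(trains)


def objective_sse(
    params: ModelParams | np.ndarray,
    cluster_data: ClusterSeries,
    trains: Sequence[PulseTrain],
    calib: PatientCalibration,
    cfg: GAConfig | None = None,
) -> float | np.ndarray:
    """Sum of squared EDSS errors between observations and the train-averaged
    simulation.  Accepts one ModelParams (returns a scalar) or an (n, 5)
    matrix (returns a vector)."""
    cfg = cfg or GAConfig()
    single = isinstance(params, ModelParams)
    mat = params.as_array()[None, :] if single else np.atleast_2d(params)
    sim = _sim_edss_at(mat, trains, calib, cluster_data.times_months, cfg)
    with np.errstate(invalid="ignore"):
        sse = ((sim - cluster_data.edss[None, :]) ** 2).sum(axis=1)
    # numerically diverged candidates (stiff corners of the search box) are
    # infeasible rather than fatal
    sse = np.where(np.isfinite(sse), sse, 1e12)
    return float(sse[0]) if single else sse


_LB = np.array([PARAM_BOUNDS[n][0] for n in PARAM_NAMES])
_UB = np.array([PARAM_BOUNDS[n][1] for n in PARAM_NAMES])


def fit_parameters_ga(
    cluster_data: ClusterSeries,
    trains: Sequence[PulseTrain],
    calib: PatientCalibration,
    cfg: GAConfig | None = None,
    rng: np.random.Generator | int | None = 0,
) -> FitEnsemble:
    """Genetic-algorithm parameter estimation for one cluster.

    The data points are split at random into equal train/test halves; the GA
    minimizes the train-half squared error; the ranked top-N sets are
    returned with their test-half objectives.  Genes live on the unit cube
    scaled to the biological bounds; mutation sd shrinks linearly over the
    generations (adaptive mutation).
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(rng)
    split_seed = int(rng.integers(2**31 - 1))
    n_pts = cluster_data.times_months.size
    if n_pts == 0:
        raise ValueError("empty cluster data")
    idx = np.arange(n_pts)
    if n_pts > cfg.max_points:
        idx = np.sort(
            np.random.default_rng(split_seed).choice(
                n_pts, cfg.max_points, replace=False
            )
        )
    perm = np.random.default_rng(split_seed).permutation(idx)
    half = max(1, len(perm) // 2)
    tr_idx, te_idx = np.sort(perm[:half]), np.sort(perm[half:])
    train_data = ClusterSeries(
        cluster_data.times_months[tr_idx],
        cluster_data.edss[tr_idx],
        cluster_data.cluster_id,
    )
    test_data = (
        ClusterSeries(
            cluster_data.times_months[te_idx],
            cluster_data.edss[te_idx],
            cluster_data.cluster_id,
        )
        if te_idx.size
        else train_data
    )

    span = _UB - _LB
    # log-axis floors for the zero-bounded rate constants; q (index 3) linear
    log_lo = _UB * 1e-6
    log_idx = np.array([0, 1, 2, 4])

    def decode(genes: np.ndarray) -> np.ndarray:
        g = np.clip(genes, 0.0, 1.0)
        vals = _LB + g * span
        if cfg.log_scale:
            vals = vals.copy()
            vals[:, log_idx] = log_lo[log_idx] * (
                _UB[log_idx] / log_lo[log_idx]
            ) ** g[:, log_idx]
        return vals

    pop = rng.random((cfg.population, 5))
    fitness = objective_sse(decode(pop), train_data, trains, calib, cfg)
    archive: dict[tuple, float] = {}

    def record(genes: np.ndarray, fits: np.ndarray) -> None:
        for g, f in zip(decode(genes), fits):
            archive[tuple(np.round(g, 12))] = float(f)

    record(pop, fitness)
    best_so_far = float(fitness.min())
    stale = 0
    for gen in range(cfg.generations):
        frac = gen / max(1, cfg.generations - 1)
        sd = cfg.mutation_sd0 + (cfg.mutation_sd_final - cfg.mutation_sd0) * frac
        order = np.argsort(fitness)
        elite = pop[order[: cfg.elite]]
        children = []
        while len(children) < cfg.population - cfg.elite:
            cand = rng.integers(0, cfg.population, size=(2, cfg.tournament))
            pa = pop[cand[0][np.argmin(fitness[cand[0]])]]
            pb = pop[cand[1][np.argmin(fitness[cand[1]])]]
            if rng.random() < cfg.crossover_rate:
                w = rng.random(5)
                child = w * pa + (1 - w) * pb
            else:
                child = pa.copy()
            mut = rng.random(5) < cfg.mutation_prob
            child = np.where(mut, child + rng.normal(0.0, sd, 5), child)
            children.append(np.clip(child, 0.0, 1.0))
        pop = np.vstack([elite, np.array(children)])
        fitness = objective_sse(decode(pop), train_data, trains, calib, cfg)
        record(pop, fitness)
        if cfg.patience is not None:
            fmin = float(fitness.min())
            if fmin < best_so_far - 1e-9:
                best_so_far = fmin
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break

    ranked = sorted(archive.items(), key=lambda kv: kv[1])[: cfg.top_n]
    top_params = [ModelParams.from_array(np.array(g)) for g, _ in ranked]
    top_mat = np.vstack([p.as_array() for p in top_params])
    test_obj = objective_sse(top_mat, test_data, trains, calib, cfg)
    return FitEnsemble(
        cluster_id=cluster_data.cluster_id,
        param_sets=[(p, o) for p, (_, o) in zip(top_params, ranked)],
        test_objectives=[float(o) for o in test_obj],
        ga_config=cfg,
        split_seed=split_seed,
        train_indices=tr_idx,
        test_indices=te_idx,
    )


def subtype_parameters(
    ensembles: dict[int, FitEnsemble], counts: dict[str, dict[int, int]]
) -> dict[str, list[ModelParams]]:
    """Subtype-specific parameter ensembles as count-weighted combinations.

    ``counts[subtype][cluster]`` is the number of that subtype's patients in
    the cluster.  For each rank r, the subtype's r-th parameter set is the
    weighted mean of the clusters' r-th sets, weights proportional to the
    subtype's cluster occupancy.
    """
    out: dict[str, list[ModelParams]] = {}
    for subtype, per_cluster in counts.items():
        total = sum(per_cluster.values())
        if total <= 0:
            raise ValueError(f"subtype {subtype!r} absent from all clusters")
        weights = {c: n / total for c, n in per_cluster.items() if n > 0}
        n_ranks = min(len(ensembles[c].param_sets) for c in weights)
        sets = []
        for r in range(n_ranks):
            combo = np.zeros(5)
            for c, w in weights.items():
                combo += w * ensembles[c].param_sets[r][0].as_array()
            sets.append(ModelParams.from_array(combo))
        out[subtype] = sets
    return out


def compare_subtype_params(
    samples: dict[str, list[ModelParams]], exact_max_n: int = 25
) -> dict[str, dict[tuple[str, str], float]]:
    """Pairwise two-sided rank-sum (Wilcoxon/Mann-Whitney) p-values per
    parameter; exact null for groups of <= ``exact_max_n``, normal
    approximation otherwise; raw p-values (no multiplicity correction)."""
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 subtypes")
    for s, sets in samples.items():
        if len(sets) < 2:
            raise ValueError(f"subtype {s!r} needs at least 2 parameter sets")
    out: dict[str, dict[tuple[str, str], float]] = {p: {} for p in PARAM_NAMES}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa = np.vstack([p.as_array() for p in samples[a]])
            xb = np.vstack([p.as_array() for p in samples[b]])
            for j, pname in enumerate(PARAM_NAMES):
                va, vb = xa[:, j], xb[:, j]
                if np.ptp(np.concatenate([va, vb])) == 0:
                    out[pname][(a, b)] = float("nan")  # degenerate, all tied
                    continue
                method = (
                    "exact"
                    if max(len(va), len(vb)) <= exact_max_n
                    and not _has_ties(va, vb)
                    else "asymptotic"
                )
                res = stats.mannwhitneyu(
                    va, vb, alternative="two-sided", method=method
                )
                out[pname][(a, b)] = float(res.pvalue)
    return out


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    allv = np.concatenate([a, b])
    return np.unique(allv).size < allv.size
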