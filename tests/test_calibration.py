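"""Clinical calibration algebra, GA fitting, subtype parameter statistics."""

import math

import numpy as np
import pytest

from msdamage import (
    Archetype,
    ClusterSeries,
    GAConfig,
    ModelParams,
    SynthConfig,
    compare_subtype_params,
    derive_scaling,
    fit_bv_edss_line,
    fit_parameters_ga,
    generate_cohort,
    initial_myelination,
    objective_sse,
    subtype_parameters,
)
from msdamage.calibration import FitEnsemble
from msdamage.core_model import DAYS_PER_MONTH
from tests.conftest import make_patient


class TestInitialMyelination:
    @pytest.mark.parametrize(
        "age,expected", [(15.0, 1.0), (20.0, 1.0), (40.0, 0.8), (70.0, 0.5)]
    )
    def test_age_rule(self, age, expected):
        assert initial_myelination(age) == pytest.approx(expected)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            initial_myelination(-1.0)


class TestBvEdssLine:
    def test_noiseless_line_recovered_exactly(self):
        edss = [1.0, 2.0, 3.0, 4.0]
        bv = [1.2 - 0.05 * e for e in edss]
        p = make_patient("p", [0, 6, 12, 18], edss, bv=bv)
        bi, ci, r = fit_bv_edss_line(p)
        assert bi == pytest.approx(-0.05, abs=1e-12)
        assert ci == pytest.approx(1.2, abs=1e-12)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_two_points_rejected(self):
        p = make_patient("p", [0, 6], [1.0, 2.0], bv=[1.15, 1.1])
        with pytest.raises(ValueError, match=">= 3"):
            fit_bv_edss_line(p)

    def test_in_relapse_visits_excluded(self):
        edss = [1.0, 5.0, 2.0, 3.0, 4.0]
        bv = [1.2 - 0.05 * e for e in [1.0, 1.0, 2.0, 3.0, 4.0]]  # relapse outlier
        p = make_patient("p", [0, 7, 12, 18, 24], edss, bv=bv)
        bi, ci, r = fit_bv_edss_line(p, exclude_months=[6.0])
        assert bi == pytest.approx(-0.05, abs=1e-12)

    def test_estimator_unbiased_on_noisy_cohort(self, rng):
        biases = []
        for _ in range(40):
            bi_true = rng.normal(-0.05, 0.01)
            edss = rng.choice(np.arange(0, 8.5, 0.5), size=20)
            bv = 1.2 + bi_true * edss + rng.normal(0, 0.005, 20)
            p = make_patient("p", np.arange(20) * 3.0, edss, bv=bv)
            bi, *_ = fit_bv_edss_line(p)
            biases.append(bi - bi_true)
        assert abs(np.mean(biases)) < 0.05 * 0.05


class TestDeriveScaling:
    def test_reference_values(self):
        c = derive_scaling(bi=-0.05, ci=1.2, ami0=0.9)
        assert c.kei == pytest.approx(10 / 0.9, rel=1e-12)  # 11.111...
        assert c.kbi == pytest.approx(10 / 0.9 * 0.05, rel=1e-12)  # 0.5555...
        assert c.vdi == pytest.approx(0.7, rel=1e-12)

    def test_nonpositive_ami0_rejected(self):
        with pytest.raises(ValueError):
            derive_scaling(-0.05, 1.2, 0.0)

    def test_forward_inverse_round_trip(self):
        c = derive_scaling(bi=-0.05, ci=1.2, ami0=0.9)
        vs = np.linspace(0.1, 0.9, 33)
        assert np.max(np.abs(c.sim_from_bv(c.bv_from_sim(vs)) - vs)) < 1e-12
        es = np.linspace(0.0, 0.9, 33)
        assert np.max(np.abs(c.sim_from_edss(c.edss_from_sim(es)) - es)) < 1e-12

    def test_bv_line_reproduced_on_noiseless_data(self):
        # scaling algebra closes: BV(EDSS) recovers the generating line
        c = derive_scaling(bi=-0.05, ci=1.2, ami0=0.9)
        edss_s = np.linspace(0.0, 0.9, 10)  # simulated damage fraction
        vs = 0.9 - edss_s  # degeneration-only limit: Vs = Ami0 - D
        edss = c.edss_from_sim(edss_s)
        bv = c.bv_from_sim(vs)
        assert np.allclose(bv, -0.05 * edss + 1.2, atol=1e-12)


class TestObjective:
    CAL = derive_scaling(-0.05, 1.2, 0.9)

    def test_perfect_match_is_zero(self):
        from msdamage import build_lambda, PulseTrain

        train = PulseTrain(np.array([100.0]), np.array([0.005]))
        truth = ModelParams(0.02, 1e-4, 0.05, 0.5, 0.02)
        tm = np.arange(0, 120.0, 6.0)
        cfg = GAConfig()
        from msdamage.calibration import _sim_edss_at

        sim = _sim_edss_at(truth.as_array()[None, :], [train], self.CAL, tm, cfg)[0]
        data = ClusterSeries(tm, sim)
        assert objective_sse(truth, data, [train], self.CAL, cfg) == pytest.approx(0.0, abs=1e-18)

    def test_hand_arithmetic(self):
        # observations (2,3,4) against a flat simulation at 2 -> 0+1+4
        data = ClusterSeries(np.array([0.0, 6.0, 12.0]), np.array([2.0, 3.0, 4.0]))
        cfg = GAConfig()

        def fake_sim(params, trains, calib, times, c):
            return np.full((params.shape[0], times.size), 2.0)

        import msdamage.calibration as cal

        orig = cal._sim_edss_at
        cal._sim_edss_at = fake_sim
        try:
            val = objective_sse(ModelParams(1, 0, 0, 0.5, 0), data, [], self.CAL, cfg)
        finally:
            cal._sim_edss_at = orig
        assert val == pytest.approx(5.0)

    def test_invariant_to_point_order(self):
        from msdamage import build_lambda, PulseTrain

        train = PulseTrain(np.array([100.0]), np.array([0.005]))
        tm = np.arange(0, 120.0, 6.0)
        obs = np.linspace(0, 5, tm.size)
        perm = np.random.default_rng(0).permutation(tm.size)
        p = ModelParams(0.02, 1e-4, 0.05, 0.5, 0.02)
        cfg = GAConfig()
        v1 = objective_sse(p, ClusterSeries(tm, obs), [train], self.CAL, cfg)
        v2 = objective_sse(p, ClusterSeries(tm[perm], obs[perm]), [train], self.CAL, cfg)
        assert v1 == pytest.approx(v2, rel=1e-12)


def _oracle_setup(seed, generations=40, population=30):
    truth = ModelParams(km=0.005, kmd=2e-4, kd=0.01, q=0.5, delta=0.005)
    arche = Archetype(
        name="oracle", params=truth, gev_shape=0.25, gev_loc=14.0, gev_scale=6.0,
        amp_scale=0.08,
    )
    cfg = SynthConfig(
        n_patients=8, archetypes=[arche], follow_up_months=180.0, seed=seed,
        deterministic_trains=True, age_onset_sd=0.0, visit_spacing_months=1.0,
        visit_jitter_months=0.3, edss_noise_sd=0.1,
    )
    cohort, _ = generate_cohort(cfg)
    data = ClusterSeries(
        np.concatenate([p.times for p in cohort]),
        np.concatenate([p.edss for p in cohort]),
    )
    train = arche.deterministic_train(cfg.follow_up_months * DAYS_PER_MONTH)
    calib = derive_scaling(-0.05, 1.2, 0.9)
    gacfg = GAConfig(population=population, generations=generations, max_points=10000)
    return truth, data, train, calib, gacfg


class TestGeneticAlgorithm:
    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ClusterSeries(np.empty(0), np.empty(0))

    def test_fit_respects_bounds_and_is_reproducible(self):
        truth, data, train, calib, gacfg = _oracle_setup(0, generations=15, population=20)
        e1 = fit_parameters_ga(data, [train], calib, gacfg, rng=3)
        e2 = fit_parameters_ga(data, [train], calib, gacfg, rng=3)
        for (p1, o1), (p2, o2) in zip(e1.param_sets, e2.param_sets):
            assert p1 == p2 and o1 == o2
        for p, _ in e1.param_sets:
            p.validate_ranges()  # raises if outside biological ranges
        objs = [o for _, o in e1.param_sets]
        assert objs == sorted(objs)

    def test_best_beats_generating_parameters_on_training_half(self):
        truth, data, train, calib, gacfg = _oracle_setup(1, generations=100, population=50)
        ens = fit_parameters_ga(data, [train], calib, gacfg, rng=1)
        tr = ens.train_indices
        train_data = ClusterSeries(data.times_months[tr], data.edss[tr])
        truth_obj = objective_sse(truth, train_data, [train], calib, gacfg)
        assert ens.param_sets[0][1] <= truth_obj + 1e-6


class TestSubtypeParameters:
    COUNTS = {  # cluster occupancy per subtype (discovery-style table)
        "RRMS": {0: 1, 1: 1, 2: 6, 3: 6},
        "SPMS": {0: 7, 1: 16, 2: 8, 3: 9},
        "PPMS": {0: 3, 1: 8, 2: 0, 3: 0},
    }

    @staticmethod
    def _ensembles(shift=0.0):
        out = {}
        for c in range(4):
            sets = [
                (ModelParams(0.01 * (c + 1), 1e-4, 0.01 + 0.01 * c + shift, 0.5, 0.01), float(r))
                for r in range(10)
            ]
            out[c] = FitEnsemble(
                cluster_id=c, param_sets=sets, test_objectives=[0.0] * 10,
                ga_config=GAConfig(), split_seed=0,
            )
        return out

    def test_rrms_weights_from_occupancy_table(self):
        total = sum(self.COUNTS["RRMS"].values())
        w = [n / total for n in self.COUNTS["RRMS"].values()]
        assert w == pytest.approx([1 / 14, 1 / 14, 6 / 14, 6 / 14])
        # weighted combination: kd = sum_c w_c * kd_c
        samples = subtype_parameters(self._ensembles(), self.COUNTS)
        kd = samples["RRMS"][0].kd
        expected = sum(wi * (0.01 + 0.01 * c) for c, wi in enumerate(w))
        assert kd == pytest.approx(expected, rel=1e-12)

    def test_subtype_in_single_cluster_copies_its_sets(self):
        ens = self._ensembles()
        samples = subtype_parameters(ens, {"X": {2: 5}})
        for rank, p in enumerate(samples["X"]):
            assert p == ens[2].param_sets[rank][0]

    def test_absent_subtype_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            subtype_parameters(self._ensembles(), {"X": {0: 0, 1: 0}})


class TestSubtypeComparison:
    @staticmethod
    def _sample(kd_values):
        return [ModelParams(0.01, 1e-4, kd, 0.5, 0.01) for kd in kd_values]

    def test_identical_samples_not_significant(self):
        vals = np.linspace(0.01, 0.1, 10)
        res = compare_subtype_params(
            {"A": self._sample(vals), "B": self._sample(vals)}
        )
        assert res["kd"][("A", "B")] > 0.05

    def test_disjoint_samples_reach_exact_enumeration_minimum(self):
        a = self._sample(np.linspace(0.01, 0.05, 10))
        b = self._sample(np.linspace(0.2, 0.4, 10))
        res = compare_subtype_params({"A": a, "B": b})
        # two-sided exact rank-sum minimum for n=m=10
        assert res["kd"][("A", "B")] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_monotone_kd_ordering_detected(self, rng):
        samples = {
            "RRMS": self._sample(rng.normal(0.01, 0.001, 10).clip(1e-4)),
            "SPMS": self._sample(rng.normal(0.04, 0.004, 10).clip(1e-4)),
            "PPMS": self._sample(rng.normal(0.10, 0.01, 10).clip(1e-4)),
        }
        medians = [np.median([p.kd for p in samples[s]]) for s in ("RRMS", "SPMS", "PPMS")]
        assert medians[0] < medians[1] < medians[2]
        res = compare_subtype_params(samples)
        assert res["kd"][("RRMS", "PPMS")] < 0.05
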