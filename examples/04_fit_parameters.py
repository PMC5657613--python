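"""Genetic-algorithm parameter estimation on a known-truth cluster.

Generates a 15-patient cluster from one parameter set with a shared attack
schedule, then fits the five rate constants by GA (tournament selection,
blend crossover, adaptive mutation, log-scaled rate genes) minimizing the
squared EDSS error on a random half of the data points.  Printed: the
median of the 10 best parameter sets against the generating truth.
"""

import numpy as np

from msdamage import (
    Archetype,
    ClusterSeries,
    GAConfig,
    ModelParams,
    SynthConfig,
    derive_scaling,
    fit_parameters_ga,
    generate_cohort,
)
from msdamage.core_model import DAYS_PER_MONTH, PARAM_NAMES

truth = ModelParams(km=0.005, kmd=2e-4, kd=0.01, q=0.5, delta=0.005)
arche = Archetype(
    name="oracle", params=truth, gev_shape=0.25, gev_loc=14.0, gev_scale=6.0,
    amp_scale=0.08,
)
cfg = SynthConfig(
    n_patients=15, archetypes=[arche], follow_up_months=240.0, seed=0,
    deterministic_trains=True, age_onset_sd=0.0,
    visit_spacing_months=1.0, visit_jitter_months=0.3, edss_noise_sd=0.1,
)
cohort, _ = generate_cohort(cfg)
data = ClusterSeries(
    np.concatenate([p.times for p in cohort]),
    np.concatenate([p.edss for p in cohort]),
)
train = arche.deterministic_train(cfg.follow_up_months * DAYS_PER_MONTH)
calib = derive_scaling(bi=-0.05, ci=1.2, ami0=0.9)

ens = fit_parameters_ga(
    data, [train], calib,
    GAConfig(population=50, generations=100, max_points=10000), rng=1,
)
median = np.median(ens.params_matrix(), axis=0)

print(f"best train objective: {ens.param_sets[0][1]:.1f} "
      f"(test: {ens.test_objectives[0]:.1f})")
print(f"{'param':6} {'truth':>10} {'top-10 median':>14} {'rel. error':>11}")
for i, name in enumerate(PARAM_NAMES):
    t = truth.as_array()[i]
    rel = abs(median[i] - t) / t
    print(f"{name:6} {t:10.5f} {median[i]:14.5f} {rel:10.1%}")
print("\nThe degeneration rate kd is the clinically decisive constant; its")
print("top-10 median should land within ~25% of the generating value.")
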