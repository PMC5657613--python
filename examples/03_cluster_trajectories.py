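"""Cluster disability trajectories and check archetype recovery.

Generates a four-archetype cohort (mild relapsing to severe early
progression), snaps the EDSS series to an annual grid, normalizes and
KNN-imputes, then selects the cluster count by average silhouette and
reports how well the recovered groups match the generating archetypes.
"""

import numpy as np

from msdamage import SynthConfig, fit_clusters, generate_cohort, preprocess_matrix
from msdamage.clustering import clustering_error_rate, match_labels

# archetype-curve conditions: shared attack schedules and a common onset age,
# so within-group spread is observational (noise + quantization + scheduling)
cohort, truth = generate_cohort(
    SynthConfig(n_patients=60, seed=3, deterministic_trains=True, age_onset_sd=0.0)
)
grid = np.arange(0.0, 241.0, 12.0)  # annual grid over 20 years

matrix = preprocess_matrix(cohort, grid, knn_k=3)
model = fit_clusters(matrix, k_range=(3, 8), n_starts=5, rng=0)

print("average silhouette per candidate k:")
for k, s in sorted(model.silhouette.items()):
    marker = "  <- selected" if k == model.k else ""
    print(f"  k={k}: {s:.3f}{marker}")

true_labels = np.array([t.archetype_index for t in truth])
perm = match_labels(true_labels, model.hard_labels, model.k) if model.k == 4 else None
if perm is not None:
    agree = float(np.mean(perm[model.hard_labels] == true_labels))
    print(f"\nlabel agreement with generating archetypes: {agree:.0%}")

err = clustering_error_rate(model, cohort, horizon=24.0)
print(f"short-follow-up (24 mo) misassignment: "
      f"{err['mean_percent']:.1f}% +/- {err['sd_percent']:.1f} across clusters")
print("Patients can thus be assigned to long-term phenotype groups from a")
print("couple of years of EDSS observations, at the printed error rate.")
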