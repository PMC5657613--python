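# msdamage

Dynamic modelling of central-nervous-system damage in multiple sclerosis
(MS), for quantitative neurologists and disease modellers who want to go
from longitudinal disability scores (EDSS) and MRI brain volumes to
mechanistic rate constants of demyelination, remyelination and axon loss.

## The model

The normalized brain is split into myelinated axons *A<sub>m</sub>*,
demyelinated axons *A<sub>d</sub>* and cumulatively degenerated axons *D*,
with *M* the remyelination capacity of the oligodendrocyte system
(healthy-adult-brain units).  Autoimmune attack enters as a non-negative
forcing λ(t) (1/day):

    dAm/dt =  km·Ad·M − λ(t)·Am − kmd·Am
    dAd/dt = −km·Ad·M + λ(t)·Am − kd·Ad
    dM/dt  = −km·Ad·M + δ·Ad·M^q        (q < 1: sub-linear capacity growth)
    dD/dt  =  kd·Ad + kmd·Am

so that *A<sub>m</sub> + A<sub>d</sub> + D* is exactly conserved.  Clinical
readouts are EDSS(t) = k<sub>e</sub>·max(A<sub>d</sub>, D) and normalized
brain volume BV(t) = k<sub>b</sub>·(A<sub>m</sub>+A<sub>d</sub>) + V<sub>d</sub>,
with the per-patient scalings derived from the linear BV–EDSS relation and
an age-adjusted initial myelinated fraction.

λ(t) is a stochastic train of rectangular attack pulses whose inter-event
times follow a generalized extreme value (GEV) distribution fitted to
confirmed disability-progression events (an EDSS increase ≥ 1 point
sustained ≥ 3 months later).

Around the core sit the analysis stages of a complete study pipeline:
trajectory clustering (k-means + fuzzy c-means, silhouette-selected k),
genetic-algorithm parameter estimation per cluster, subtype-specific
parameter ensembles with rank-sum comparisons, eFAST global sensitivity
analysis with a dummy-parameter significance floor, milestone-probability
curves with Hill characterization, and a synthetic-cohort generator with
known ground truth that makes every stage testable offline.

## A worked example

```python
import numpy as np
from msdamage import (SynthConfig, generate_cohort, preprocess_matrix,
                      fit_clusters)

cohort, truth = generate_cohort(
    SynthConfig(n_patients=60, seed=3, deterministic_trains=True,
                age_onset_sd=0.0))
grid = np.arange(0.0, 241.0, 12.0)          # annual grid over 20 years
model = fit_clusters(preprocess_matrix(cohort, grid), k_range=(3, 8), rng=0)
print(model.k, {k: round(s, 3) for k, s in model.silhouette.items()})
```

prints

```
4 {3: 0.658, 4: 0.684, 5: 0.676, 6: 0.632, 7: 0.391, 8: 0.364}
```

— the silhouette criterion selects four phenotype clusters, and (see
`examples/03_cluster_trajectories.py`) the recovered labels agree 100% with
the generating archetypes; truncating every series to 24 months misassigns
5.0% ± 6.3 of patients, i.e. long-term phenotype group membership is already
visible in short follow-up.

The `examples/` directory holds one short script per capability — ODE
disease courses, confirmed-event extraction and GEV interval fitting,
clustering, GA fitting, eFAST, and brain-volume validation — each printing
the numbers it computes and a line on what they mean.  A thin CLI
(`msdamage synth|events|cluster|fit|sensitivity|validate|report`) chains the
same stages on files.

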