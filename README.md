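# defaunation

Quantifying faunal loss from camera-trap surveys: weighted defaunation
indices, hierarchical Bayesian community occupancy models with imperfect
detection, and Monte-Carlo propagation of occupancy posteriors into an
occupancy-based defaunation index.

The package is aimed at ecologists comparing mammal and ground-bird
communities across disturbed tropical forest landscapes — for example a
moderately logged but unhunted region against a structurally intact but
heavily snared one — using systematic camera-trap data (stations on a
~2.5 km grid, two cameras per station, deployments of at least 60 days
pooled into 10-day occasions).

## The methods

**Defaunation index.** For a focal assemblage *f* and reference
assemblage *r* over units *k* with importance weights ω<sub>k</sub>:

    D(r, f) = Σ_k ω_k (N_k,r − N_k,f) / Σ_k ω_k (N_k,r + N_k,f)

with N ∈ {0, 1} for presence/absence, D ∈ [−1, 1]; positive values mean
the focal assemblage is more defaunated. Weights are equal (1),
conservation status (IUCN LC=1 … CR=5, DD=2.5), body mass to the 3/4
power, or body-mass rank. A unit recorded at fewer than 2.5% of a site's
stations is *functionally extinct* (scored 0).

**Community occupancy model.** For unit *i*, station *j*, occasion *k*:

    z_ij ~ Bernoulli(ψ_ij),   logit(ψ_ij) = α_{i,site[j]} + β1_i·canopy_j + β2_i·village_j
    y_ijk ~ Bernoulli(z_ij · p_ijk),   logit(p_ijk) = α.p_i + β.e_i·effort_jk

Species-level parameters are draws from community normal distributions
(e.g. β1<sub>i</sub> ~ N(μ<sub>β1</sub>, σ<sub>β1</sub>)), sharing strength across rare and common
species. Fitting is by Metropolis-within-Gibbs MCMC with exact latent-state
updates; convergence is checked with the Gelman-Rubin statistic and
summaries are posterior means, sds, and 75%/95% percentile credible
intervals.

**Occupancy-based defaunation.** Presence/absence entries are replaced by
posterior occupancy probabilities; 30,000 Monte-Carlo repetitions each
resample one posterior ψ per (unit, site) and evaluate D against a
reference site, giving a distribution of D with percentile confidence
limits.

A synthetic-data generator (`defaunation.simulate`) reproduces the survey
design — jittered 2.5 km station grids, staggered ≥60-day deployments,
canopy from a smooth spatial field, villages and their quartic-kernel
density, and detections from the exact occupancy process above — so every
stage is testable end to end without field data.

## Worked example

```python
import numpy as np, pandas as pd
from defaunation import defaunation_index, functional_extinction, species_weights

traits = pd.DataFrame({
    "unit_id": ["muntjac", "pangolin", "civet", "porcupine", "pheasant", "macaque"],
    "iucn":    ["DD", "CR", "LC", "LC", "NT", "VU"],
    "body_mass_g": [15_000, 5_000, 3_500, 4_000, 1_200, 8_000]})

presence = pd.DataFrame(0, index=traits["unit_id"],
                        columns=[f"st{j}" for j in range(80)])
for unit, n in [("muntjac", 30), ("civet", 55), ("porcupine", 12),
                ("pheasant", 1), ("macaque", 6)]:
    presence.loc[unit, presence.columns[:n]] = 1

focal = functional_extinction(presence, reference_units=traits["unit_id"])
reference = pd.Series(1, index=pd.Index(traits["unit_id"]))
for scheme in ("equal", "conservation", "size"):
    print(scheme, round(defaunation_index(reference, focal,
                                          species_weights(traits, scheme)), 3))
```

prints

```
equal 0.2
conservation 0.318
size 0.112
```

The pangolin (never recorded) and the pheasant (1 of 80 stations, below
the 2.5% cutoff) are functionally extinct. Under equal weights the site
has lost 2 of its 6 expected units, D = 2/10 = 0.20; conservation
weighting raises D to 0.32 because the lost pangolin is Critically
Endangered, while size weighting lowers it to 0.11 because the heaviest
units survive.

The `examples/` directory has one short script per capability:
covariates (canopy closure, village kernel density), simulating and
fitting the community occupancy model, Monte-Carlo occupancy-based
defaunation, and the full pipeline (also available as the `defaunation`
command-line tool; see `defaunation --help`).

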