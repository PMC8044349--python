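# strucnet

White-matter structural connectome analysis in Python: streamline-count
network construction, small-world graph metrics with random-network
normalization, the network-based statistic (NBS), and covariate-adjusted
group comparison with FDR correction and ROC/AUC nodal discrimination.

## Who it is for and what it does

Studies that differentiate dementia subtypes (e.g. Alzheimer's disease vs
subcortical ischemic vascular dementia) from diffusion MRI typically follow
one pipeline: deterministic (FACT) tractography thresholded at FA 0.2 and a
45-degree turning angle; a 90-region parcellation whose region pairs become
network edges when connected by **more than 3** streamlines; the binary
small-world battery

- characteristic path length `Lp`, global efficiency `E_g`, local
  efficiency `E_loc`, clustering `C_p`,
- `γ = C_p / ⟨C_p^null⟩`, `λ = L_p / ⟨L_p^null⟩`, `σ = γ/λ` against 100
  degree-preserving random networks (σ > 1 = small-world organization),
- unnormalized nodal betweenness `BC(v) = Σ_{s≠t≠v} σ_st(v)/σ_st`;

group inference on edges via the NBS (edgewise GLM with age/sex/education
covariates, primary t threshold, max-connected-component permutation test
with Freedman–Lane residual shuffling); and per-metric group tests with
Benjamini–Hochberg FDR plus ROC/AUC for nodal discrimination.

`strucnet` implements that chain as a library with a seeded synthetic-cohort
generator (modular negative-binomial count connectomes, demographic-moment
covariates, planted and recoverable group effects), so every stage runs and
is validated without any imaging data. See `docs/methods.md` for the model,
parameter defaults, and what the generator does and does not emulate.

## Worked example

```python
import numpy as np
from strucnet import CohortSpec, generate_cohort, small_world

subjects, truth = generate_cohort(CohortSpec(n_per_group={"NC": 2}, seed=42))
adjacency = (subjects[0].counts > 3).astype(np.int8)   # the >3-fiber rule
gm = small_world(adjacency, n_null=100, rng=np.random.default_rng(0))
print(gm.lp, gm.eg, gm.sigma)
```

prints (see `examples/03_small_world_metrics.py` for the annotated version)

```
subject NC_01: connected=True
  Lp    = 3.132   (characteristic path length, hops)
  Eg    = 0.376   (global efficiency)
  Eloc  = 0.353   (local efficiency)
  Cp    = 0.250   (clustering coefficient)
  gamma = 4.149, lambda = 1.187, sigma = 3.495
```

i.e. the synthetic control connectome is ~4x more clustered than its
degree-matched random networks at nearly random path length — σ well above
1, the small-world signature. Planted effects are recovered by the NBS
(`examples/04_nbs_group_difference.py`):

```
planted component: 12 edges, attenuation factor 0.3
component 0: size=11 edges, p_FWER=0.0010, 11/12 planted edges recovered
```

The `examples/` directory has one short script per capability: cohort
simulation, toy FACT tractography, metrics, NBS, nodal ROC, and the full
pipeline. A thin CLI wraps the pipeline (`strucnet run --seed 42 --out
out/`, stages also available individually); outputs are byte-identical under
identical config + seed.

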