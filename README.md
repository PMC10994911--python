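# suscnet

Individual brain **susceptibility networks** from quantitative
susceptibility mapping (QSM), for researchers studying how regional brain
iron relates to cognition.

QSM gives every voxel a magnetic susceptibility value (an iron proxy).
For a single subject, `suscnet` treats each atlas region's in-mask voxel
values as a sample from a regional susceptibility distribution, estimates
each region's PDF by kernel density estimation, and connects two regions
by the similarity of their distributions:

```
D_KL(I, J) = ∫ [ I(x) log(I(x)/J(x)) + J(x) log(J(x)/I(x)) ] dx
KLSE(I, J) = exp(−D_KL(I, J)) ∈ (0, 1]
```

The resulting N×N weighted matrix (one per subject — no cross-subject
covariance needed) is thresholded into binary networks over sparsities
0.05–0.40 (step 0.01) and analyzed with the standard connectome toolkit:

* small-world metrics (Cp, Lp, γ, λ, σ = γ/λ), global/local efficiency,
  nodal centralities, and AUCs across sparsities;
* rich-club organization (φ(k), weighted φʷ(k), normalization against
  1000 degree-preserving rewirings, top-12% hubs, rich-club / feeder /
  local connection classes);
* covariate-adjusted group statistics (age, gender, education),
  Freedman–Lane permutation tests on edges, functional-network labelling
  of significant edges, and mediation with BC bootstrap CIs;
* test–retest reliability (spatial correlation of mean matrices;
  per-connection consistency ICC);
* sparse (ℓ1) logistic regression on edge features with leave-one-out
  cross-validation (λ = 0.01), selected-feature reporting.

A synthetic-cohort generator (`suscnet.synth`) reproduces the statistical
structure the method consumes — community-structured region
distributions, planted group effects, covariates, paired retest
sessions — so the entire pipeline runs and is tested without any MRI
data.

## Worked example

```python
import numpy as np
import suscnet as sn

# one synthetic subject: 90 regions in 8 communities
spec = sn.SyntheticCohortSpec(seed=42, n_regions=90, groups={"HC": 1},
                              voxels_per_region=(100, 300))
samples, cohort, _ = sn.generate_cohort(spec)

mat = sn.build_susceptibility_matrix(samples[0])   # 90x90 KLSE matrix
adj = sn.threshold_by_sparsity(mat, 0.20)          # 801 strongest edges
gm = sn.global_metrics(adj)
sw = sn.normalize_small_world(adj, n_rand=100, seed=0)
print(f"Cp={gm.cp:.3f} Lp={gm.lp:.3f} Eglob={gm.eglob:.3f}")
print(f"gamma={sw.gamma:.2f} lambda={sw.lam:.2f} sigma={sw.sigma:.2f}")
```

```
Cp=0.755 Lp=3.670 Eglob=0.430
gamma=3.37 lambda=1.99 sigma=1.69
```

Clustering is 3.4× that of degree-matched random networks while path
length is only 2× longer, so σ = γ/λ = 1.69 > 1: the community
structure of the regional susceptibility distributions produces a
small-world network, as expected for a brain-like similarity graph.

A command-line interface mirrors the library
(`suscnet simulate | build-network | metrics | richclub | compare |
classify | trt | mediate`), each subcommand writing TSV/JSON outputs
plus a provenance file with its config and seeds.

## Documentation

`docs/methods.md` describes the model, every numerical convention
(bandwidth rule, grids, floors, tie-breaking, permutation scheme), what
the synthetic cohorts do and do not emulate, and known limitations.
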