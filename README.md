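# fedgh — federated gradient harmonization for keypoint regression

`fedgh` is a simulation framework for studying **server-side aggregation
under non-IID clients** in heatmap-based human keypoint regression, built
for rehabilitation-monitoring scenarios where a single instrumented arm
(shoulder, elbow, wrist) is observed by several fixed cameras and the
images cannot be pooled centrally.

When client datasets differ in viewpoint, illumination and pose
distribution, locally computed updates can point in opposing directions:
a pair of client gradients with negative inner product partially cancels
under plain averaging, slowing or reversing the global update.  The
package implements **gradient harmonization (FedGH)**, which

1. converts each client's post-training parameters into a gradient
   g_k = (w_k − w_t)/η,
2. corrects conflicts pairwise: whenever ⟨g_k, g_j⟩ < 0 against a
   randomly drawn partner, g_k is projected onto the orthogonal
   complement of g_j (g_k′ = g_k − (⟨g_k,g_j⟩/‖g_j‖²)·g_j), at most once
   per gradient,
3. scores each corrected gradient against the consensus ("ideal")
   direction d = (1/K)Σ g_k′ via β_k = max(0, ⟨g_k′, d⟩)·n_k, normalises
   to simplex weights α_k (equal weights when all scores vanish), and
4. updates the global model w_{t+1} = w_t + η·Σ α_k g_k′.

The residual disagreement of a round is measured by the conflict
objective Σ_{i<j} 1[⟨g_i,g_j⟩ < 0]·|⟨g_i,g_j⟩|.

Around this core the package provides:

- a **quantity-skewed partitioner** (preset client weights, a minimum
  per-client count, exact total conservation, seeded shuffling),
- five **baseline strategies** under one plug-in contract: FedAvg,
  FedProx, FedBN, FedDyn, FedAW,
- a compact **heatmap keypoint regressor** (strided conv backbone,
  deconvolution head, Gaussian targets, argmax decoding) in pure numpy,
- a **procedural scene generator** for single-arm poses with exact
  keypoint labels, four mirrored/sheared viewpoints, occlusion and
  illumination bias, and a scalar divergence dial from IID to strongly
  opposed client profiles,
- **PCK evaluation** with adaptive per-joint normalization (image
  diagonal / upper arm / forearm at thresholds 0.3 / 0.4 / 0.5) and
  paired t-tests between per-round metric series.

## Worked example

```python
import numpy as np
from fedgh import (FederationConfig, run_training,
                   conflict_profiles, make_federated_dataset)

profiles = conflict_profiles(10)                    # opposed viewpoints
ds = make_federated_dataset(500, profiles, seed=1234)
cfg = FederationConfig(rounds=30, n_samples=500, seed=0,
                       aggregator="fedgh", eval_every=30)
res = run_training(cfg, dataset=ds)
last = res.frame.iloc[-1]
print(f"round {int(last['round'])+1}: mean PCK {last['mean_pck']:.4f}, "
      f"detection accuracy {last['detection_accuracy']:.4f}, "
      f"projections this round {int(last['n_projections'])}")
```

Output:

```
round 30: mean PCK 0.8200, detection accuracy 0.8333, projections this round 3
```

Mean PCK is the unweighted average over the three joints of the fraction
of test predictions whose normalized distance to ground truth falls
within the per-joint threshold; detection accuracy pools all visible
joints at the 0.5 multiplier; `n_projections` counts how many client
gradients the server corrected in that round.  Under the same conditions
plain averaging (`aggregator="fedavg"`) reaches a median mean PCK of
0.8267 over seeds 0–2 versus 0.8333 for gradient harmonization.

The same experiment is available from a shell:

```sh
fedgh train --seed 0 --rounds 30 --aggregator fedgh --out runs/fedgh
fedgh compare --seeds 0,1,2 --rounds 30 --out runs/comparison
```

`compare` writes a per-strategy summary (max/final mean PCK), per-round
CSVs and a paired t-test table of the harmonizing strategy against each
baseline.

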