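# emotrain

Directional emotion entrainment analysis for online communities.

When people interact, their emotions tend to synchronize ("entrain"). On
social platforms this shows up as one user's stream of emotion states —
coded negative / neutral / positive as −1 / 0 / +1, one state per day-bin —
becoming predictable from a peer's history. `emotrain` is a library (plus a
thin CLI) for researchers in computational social science and affective
dynamics who want to quantify that process on time-stamped event streams:

* **Entrainment strength** between users is measured with transfer entropy:
  `Etr(i → j) = TE(j → i) = H(x_{t+1} | x_t^m) − H(x_{t+1} | x_t^m, y_t^n)`,
  the reduction in uncertainty about adopter *i*'s next state once source
  *j*'s recent history is known, beyond *i*'s own history (orders default
  to m = n = 3; entropies in bits). The measure is asymmetric, so the
  *direction* of influence is identified.
* **Dyad patterns**: at each timestamp, every pair is classified against the
  community-mean threshold θ_t as **Dual** (both directions ≥ θ_t),
  **Single** (exactly one), or **None**, and the disparity
  `EnDis = |Etr_ij − Etr_ji| / max(Etr_ij, Etr_ji)` summarizes how one-sided
  a relationship is.
* **Community convergence** is tracked by the mean pairwise cross-entropy
  `⟨CE⟩_t = (1/N²) Σ_{i≠j} CE(p_i^t, p_j^t)` between users' emotion-state
  distributions.
* **Prediction**: a log-linear factor graph over all users' next emotion
  states combines per-user modality features (emotion and activity n-grams)
  with pairwise entrainment factors, trained by regularized maximum
  likelihood with exact or loopy sum-product inference; flat-classifier
  baselines with chain-cluster and neighbor-distribution encodings provide
  the comparison tiers.
* **Synthetic communities** with planted, tunable directional coupling
  (follower copies source's previous state with probability κ) supply
  ground truth for every stage.

## Worked example

Plant a one-directional coupling (user 1 copies user 0 with probability
0.8) and recover its direction:

```python
import numpy as np
from emotrain import (SyntheticConfig, generate_community, TEConfig,
                      etr, en_dis, classify_dyad)

cfg = SyntheticConfig(n_users=2, n_steps=5000,
                      coupling_edges=[(0, 1, 0.8)], seed=7)
community = generate_community(cfg)
source, follower = community.series[0], community.series[1]

te_cfg = TEConfig()  # m = n = 3, plug-in counts, bits
toward_source = etr(follower, source, te_cfg)
toward_follower = etr(source, follower, te_cfg)
theta = np.mean([toward_source, toward_follower])

print(f"Etr(follower -> source) = {toward_source:.3f} bits")
print(f"Etr(source -> follower) = {toward_follower:.3f} bits")
print(f"EnDis = {en_dis(toward_source, toward_follower):.3f}")
print(f"pattern: {classify_dyad(toward_source, toward_follower, theta)}")
```

prints

```
Etr(follower -> source) = 0.927 bits
Etr(source -> follower) = 0.133 bits
EnDis = 0.856
pattern: Single
```

The follower-to-source strength (0.927 bits) dwarfs the reverse direction
(0.133 bits, which is finite-sample bias: the source never looks at the
follower), `EnDis = 0.856` flags the dyad as strongly one-sided, and the
threshold classification calls it Single — exactly the planted structure.

The same pipeline runs from the shell:

```
emotrain simulate --n-users 4 --n-steps 400 --edges 0:1:0.9 --seed 3 --out events.jsonl
emotrain entrain --events events.jsonl --order 1 --min-samples 10 --out edges.tsv
emotrain peers --edges edges.tsv
```

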