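# Methods

## The measurement model

Each user contributes a time-binned sequence of ternary emotion states
(negative / neutral / positive, coded −1 / 0 / +1; one bin per day by
default, configurable to weeks). Emotion dynamics are treated as a
finite-order Markov process, which licenses estimating next-state
uncertainty from history n-grams.

**Entrainment strength.** The strength with which adopter *i* moves toward
source *j* is the transfer entropy read in the adopter direction,

    Etr(i → j) = TE(j → i) = H(x_{t+1} | x_t^m) − H(x_{t+1} | x_t^m, y_t^n),

with `x` the adopter's series, `y` the source's, and history orders
m = n = 3 by default. All entropies are in bits (the base is a convention;
log base 2 is fixed package-wide). Transfer entropy is asymmetric, so
reciprocal strengths identify the direction of influence without a model
of the interaction itself.

**Estimators.** The default estimator is the plug-in: conditional entropies
from the joint frequencies of the observed (m+1)- and (m+n+1)-grams over
all fully observed windows. It is non-negative by construction. A second
estimator smooths the sorted per-gram contributions into a profile on
[0, 1] and integrates it with composite Simpson quadrature
(`simpson_estimate`, the textbook (h/3)[f₀ + 4Σf_odd + 2Σf_even + f_n]
rule, exact for cubics). The binding between the quadrature and the
discrete gram statistics admits more than one reading; the smoothing
estimator is provided behind `TEConfig(estimator="simpson")`, its
quadrature operator is tested against closed forms and scipy, and every
validation study binds to the plug-in path. Negative values (possible only
under smoothing) clamp to zero.

**Missing data** (bins with no observation) are excluded from the count
tables, never imputed: a window enters the counts only when the target's
m+1 consecutive states and the source's n aligned states are all observed.
Below `min_samples` aligned windows (default 30) the pair raises an
insufficient-data error and network construction lists it as excluded
rather than dropping it silently.

**Dyad patterns.** At timestamp *t* the community threshold θ_t is the mean
of all finite directed strengths (ordered pairs; averaging over ordered
versus unordered pairs is a convention — ordered is used). Each dyad is
then Dual (both directions ≥ θ_t), Single (exactly one ≥), or None, with
the boundary inclusive. The disparity EnDis = |Etr_ij − Etr_ji| /
max(Etr_ij, Etr_ji) is undefined (NaN) when both strengths are zero; such
dyads are excluded from averages.

**Emotional distance.** Per-user state distributions are relative
frequencies over the window ending at *t* (cumulative by default, or a
fixed width), with add-ε smoothing (ε = 1e-6, renormalized) so
cross-entropies stay finite. The community distance
⟨CE⟩_t = (1/N²) Σ_{i≠j} CE(p_i, p_j) keeps the 1/N² normalizer as defined,
so its value for a perfectly homogeneous community is H(p)(N²−N)/N², not
H(p).

**Estimation window.** Whether strengths at time *t* should use cumulative
history or a sliding window is genuinely open; the default is cumulative
(all history up to *t*), with a fixed-width window available everywhere a
window argument exists.

## The synthetic generator

Every user evolves as a first-order Markov chain on the ternary alphabet;
the default base transition is mildly sticky (stay probability 0.5, the
neutral state the main conduit between the poles), reflecting day-scale
mood inertia. A coupling edge (source, follower, κ) makes the follower
copy the source's previous state with probability κ, otherwise drawing
from the base chain; updates are synchronous from t−1 states only, so
mutual (Dual) coupling is well-defined and order-free. When several edges
target one follower, each fires independently and the last firing edge in
list order wins. Missingness is independent Bernoulli per (user, bin) on
the observation layer; posting counts are Poisson. Planted patterns (Dual
iff both directions coupled, Single iff one, plus sampled uncoupled None
controls) give every estimator a ground truth. Identical config and seed
reproduce the community bit-exactly.

What the generator does *not* emulate: real corpora have heterogeneous
per-user dynamics, bursty (non-Poisson) activity, informative missingness,
and couplings that are neither lag-1 nor constant in time. Passing the
validation studies therefore shows the estimators recover planted
structure of the stated kind at the stated sizes — not that any particular
platform behaves like the generator.

### Finite-sample bias and the choice of order

The order-3 plug-in estimate counts 3⁷ = 2187 joint cells; at a few
thousand samples its bias is of order df / (2N ln 2) ≈ 0.5 bits, which is
the same magnitude as a strong coupling signal, and the bias differs
across dyads whose dynamics differ. Studies run at 5000 bins where only a
*within-dyad directional comparison* is needed (directionality recovery,
null calibration, coupling monotonicity) keep the default order 3: the
bias largely cancels between the two directions of one dyad. Studies that
compare strengths *across* dyads against a common threshold — pattern
recovery at 2000 bins, the strength-versus-distance regression, and the
prediction-task entrainment network on cohorts with a few hundred bins —
use order m = n = 1 (27 cells, bias ~0.005–0.03 bits), which exposes the
planted structure the order-3 tables drown. This is the usual order /
sample-size trade-off of plug-in information estimates, stated here as the
package's default analysis choice at these problem sizes.

## Peer- and community-level analyses

Reciprocal correlation is the Pearson correlation between the two
directional strengths across dyads (pooled or at one timestamp). Group
distances compare mean pairwise cross-entropy across pattern groups with
independent two-tailed t-tests. R_t = #Dual_t / #Single_t is undefined
(missing, not infinite) when no Single dyads exist at *t*; its first-peak
bin separates the relationship "develop" and "maintain" stages. Lead times
are (first Dual bin − first Single bin) per dyad, onset meaning the first
bin with that classification (no persistence requirement — onset is
otherwise undefined); dyads never reaching both patterns are censored and
counted separately. The distance regression is OLS of a dyad's mean
cross-entropy distance on the *minor* of its two reciprocal strengths.

Community lifecycle follows the six-month rule: a user joins at their
first post and is abandoned when their last post lies ≥ 182 day-bins
(configurable) before the corpus end; users posting within the final six
months are never called abandoned. Growth curves are fitted log-linearly
(least squares on log counts), with trailing periods excludable for series
whose growth stalls near the end of observation.

## The polarity stage

Mood labels map to states through a user-supplied two-column lexicon;
unknown labels are excluded from emotion series but retained for activity
accounting. Raw text (pre-tokenized; tokenization is an injected
dependency) goes through multinomial naive Bayes over unigrams and
adjacent bigrams with Laplace smoothing (α = 1). Negation is handled by
prefixing `neg-` to the k = 2 tokens following a negation indicator, not
crossing punctuation — a bounded forward scope, the standard reading of
prefix-based negation marking. Posterior ties break toward neutral.
Self-training repeatedly moves unlabeled documents whose max posterior
meets the confidence threshold (default 0.9; the threshold is genuinely a
free parameter) into the training set with their predicted labels —
permanently, matching the augmentation semantics — and refits until
nothing qualifies or `max_rounds` is hit.

## The factor-graph predictor

The joint distribution over all users' states is log-linear with three
factor families: per-user modality indicators g(y_i, m_ij) with weights
α (one weight per feature *and* state, so a single-node model reduces
exactly to multinomial logistic regression); a pairwise association factor
counting the dyad directions whose strength reaches En₀; and a pairwise
pattern factor scoring Dual/Single/None as 2/1/0.

Two design points deserve emphasis:

* **Label coupling.** As written, the pairwise factors score the *graph*
  (they do not mention y_i, y_j) and therefore cancel in inference. The
  default `variant="coupled"` applies their score only when y_i = y_j,
  which is the reading under which entrainment can inform prediction —
  entrained dyads are pulled toward matching states. The literal reading
  remains available (`variant="literal"`) and is tested to be
  label-independent.
* **Weight tying.** β and γ are single scalars shared across edges:
  per-edge weights are unidentifiable when each dyad contributes one
  prediction instance.

Modality features are emotion-state and activity-level unigrams/bigrams
over a short history window, each tagged with its relative temporal index;
activity discretizes against the community mean posts per bin (low < 1×,
medium in [1×, 2×), high ≥ 2×). A constant bias feature makes the empty
history fall back to the learned class prior. En₀ is the mean strength
over the preceding seven day-bins where estimable; on short synthetic
timelines where a 7-bin window cannot support TE estimation it defaults to
the network threshold θ_t.

Inference is exact enumeration up to 12 variable nodes and loopy
sum-product beyond (damping 0.5, max 200 sweeps, message tolerance 1e-6;
non-convergence is reported with the residual and the beliefs still
returned). Learning maximizes the L2-penalized log-likelihood (λ = 0.1
default) with analytic gradients — observed minus expected sufficient
statistics, the expectations from enumeration or from node/pairwise
beliefs. On enumerable graphs the optimizer is L-BFGS on the exact
objective; on larger graphs it is plain gradient ascent on the
belief-propagation gradient (no exact objective exists there), with a
divergence guard that aborts after ten consecutive gradient-norm
increases.

**Final-bin prediction task.** Training instances are the full community
assignments at every earlier bin (features from the preceding
`history_len` bins; a `train_window` caps how many bins enter learning on
long timelines); the final bin never enters features, factors, or the
entrainment network. Users split into four folds; per fold the train-fold
users are clamped to their observed final states and the held-out users'
marginals are inferred jointly — transductive node classification, so
entrainment edges can carry a clamped neighbor's label to a test user.
Accuracies average over folds, and the modality-only ablation reuses the
identical folds for a paired comparison.

**Baselines.** Flat classifiers (multinomial naive Bayes, multinomial
logistic regression as the maximum-entropy model) consume tiered feature
sets: modality alone, plus the chain-cluster group id (users linked when
both reciprocal strengths reach En₀; groups are connected components,
i.e. the transitive closure), plus the discretized strength-weighted
emotion distribution of the top-K (default 5) solely entrained neighbors
(codes 1 / 2 / 3 for [0, ¼), [¼, ½) — closed on the left — and the rest;
a user with no qualifying neighbor gets the documented missing code 0).
All tiers share the fold partition with the factor-graph model.

## Validation studies and their sizes

The studies in `emotrain.experiments` (run by `tests/test_acceptance.py`
and `scripts/acceptance.py`) use these problem sizes, chosen as the
smallest at which each effect is stable:

* estimator-versus-reference agreement: 200 random pairs of length ≤ 50,
  orders 1–3, tolerance 1e-12 against an independent dict-counting
  implementation;
* lag-1 copy closed form: 50 000 bins, orders 1/1, expected log₂3 bits;
* directionality recovery and null calibration: 100 replicate dyads at
  5000 bins, κ = 0.8; the null is 200 circular shifts of the source;
* coupling monotonicity: κ ∈ {0, 0.25, 0.5, 0.75, 1}, 100 replicates each;
* pattern recovery: 200 disjoint dyads (70 Dual / 70 Single / 60 None) at
  2000 bins, order-1 strengths, threshold θ = mean of all computed
  strengths;
* convergence trend: a 10-user hub community, coupling switched on at
  mid-run, windowed distributions (100 bins);
* inference agreement: 50 random models of 4–8 nodes with weights in the
  small-coupling regime (α ~ N(0, 0.3), edge weights ~ N(0, 0.1)), loopy
  beliefs within 1e-3 total variation of enumeration and exact on chains;
* learning diagnostics: finite-difference gradient check at 1e-5; a
  6-node model sampled exactly (2000 draws) whose generating parameters
  dominate ±0.5 coordinate perturbations in held-out likelihood;
* prediction ablation: six replicate 8-user cohorts whose followers copy
  their source within the same bin (copy probability 0.9, sources sticky
  at stay 0.8 — the inertia is what makes a contemporaneous copy visible
  to transfer entropy), 1000 bins for the network, last 40 bins for
  learning;
* self-training safety: 60 labeled / 200 unlabeled / 300 held-out
  documents from known class-conditional token distributions.

## Known limitations

* The plug-in estimator is biased upward at small samples; no bias
  correction (Panzeri–Treves, bootstrap) is implemented beyond the
  order-choice guidance above. The circular-shift null is the recommended
  significance reference.
* Loopy belief propagation degrades with edge-weight magnitude; the 1e-3
  agreement band holds in the small-weight regime, not universally.
* The factor-graph learner assumes fully observed training assignments;
  bins with any missing label are skipped rather than marginalized.
* The generator's copy dynamics are lag-1 and time-homogeneous; Dual
  coupling at high κ produces state-swapping trajectories whose transfer
  entropy is lower than the Single case at equal κ (the adopter's own
  lag-2 history already explains the copy), which is a property of the
  dynamics, not an estimator defect.
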