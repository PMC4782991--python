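"""Entrainment-augmented factor-graph (EnFG) emotion prediction.

A log-linear model over the joint emotion states y_i in {NEG, NEU, POS} of a
community of users,

    log p(y) = sum_i sum_j alpha_j g(y_i, m_ij)
             + sum_e beta  g_etr(e) + sum_e gamma g_pat(e)  -  log Z,

with three factor families: modality factors tying a user's label to binary
features of their own history (emotion-state and activity-level n-grams,
each tagged with its relative temporal index); an entrainment association
factor g_etr(e) in {0, 1, 2} counting the directions of dyad e whose strength
reaches the community threshold En0; and an entrainment pattern factor
g_pat(e) in {0, 1, 2} scoring Dual / Single / None dyads.

Read literally, the two pairwise factors do not reference the labels and so
cancel in inference; the default "coupled" variant therefore applies their
score only when y_i = y_j, which is what lets entrainment inform prediction
(emotionally entrained dyads pull toward matching states). The literal
reading stays available via ``variant="literal"``.

Edge weights beta and gamma are tied across edges: per-edge weights are
unlearnable when each dyad contributes a single prediction instance.

Inference is exact enumeration up to ``enum_threshold`` variable nodes and
loopy sum-product message passing beyond; learning is L2-regularized
maximum likelihood with analytic gradients (observed minus expected
sufficient statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .series import NEG, NEU, POS
from .entrainment import DUAL, SINGLE, EntrainmentNetwork

_CLASSES = np.array([NEG, NEU, POS])
_STATE_NAME = {NEG: "NEG", NEU: "NEU", POS: "POS"}


# ---------------------------------------------------------------------------
# modality features


def activity_level(n_posts: float, mean_posts: float) -> str:
    """Discretize a posting count against the community mean.

    low below 1x the mean, medium in [1x, 2x), high at or above 2x.
    """
    if mean_posts <= 0:
        raise ValueError("mean_posts must be positive")
    if n_posts < mean_posts:
        return "low"
    if n_posts < 2 * mean_posts:
        return "medium"
    return "high"


def build_modality_features(series, history_bins, mean_posts: float) -> set:
    """Feature set of one user over an ordered window of history bins.

    Emits emotion-state unigrams per observed bin and bigrams per adjacent
    observed pair, plus the same n-grams over the discretized activity level;
    every feature carries its relative temporal index (0 for the most recent
    history bin, -1 for the one before, ...). A constant ``("bias",)``
    feature is always present so an empty history falls back to the learned
    class prior.
    """
    history_bins = list(history_bins)
    feats = {("bias",)}
    if not history_bins:
        return feats
    last = history_bins[-1]
    prev_state = prev_level = prev_rel = None
    for b in history_bins:
        rel = b - last
        state = series.states[b]
        level = activity_level(series.n_posts[b], mean_posts)
        feats.add(("act", rel, level))
        if prev_rel is not None and rel - prev_rel == 1:
            feats.add(("act2", rel, (prev_level, level)))
        if not np.isnan(state):
            feats.add(("emo", rel, _STATE_NAME[int(state)]))
            if prev_state is not None and rel - prev_rel == 1:
                feats.add(("emo2", rel, (prev_state, _STATE_NAME[int(state)])))
            prev_state = _STATE_NAME[int(state)]
        else:
            prev_state = None
        prev_level, prev_rel = level, rel
    return feats


class FeatureVocabulary:
    """Stable feature -> column index mapping shared across instances."""

    def __init__(self):
        self.index = {}

    def encode(self, feature_sets, grow: bool = True) -> np.ndarray:
        """Binary matrix (n_users, n_features) for a list of feature sets."""
        if grow:
            for fs in feature_sets:
                for f in sorted(fs, key=repr):
                    if f not in self.index:
                        self.index[f] = len(self.index)
        x = np.zeros((len(feature_sets), len(self.index)))
        for r, fs in enumerate(feature_sets):
            for f in fs:
                k = self.index.get(f)
                if k is not None:
                    x[r, k] = 1.0
        return x

    def __len__(self):
        return len(self.index)


# ---------------------------------------------------------------------------
# the estimator


def _as_codes(y) -> np.ndarray:
    y = np.asarray(y)
    codes = np.searchsorted(_CLASSES, y)
    if (codes > 2).any() or (_CLASSES[np.clip(codes, 0, 2)] != y).any():
        raise ValueError("labels must be in {-1, 0, +1}")
    return codes


class EnFGClassifier(BaseEstimator, ClassifierMixin):
    """Log-linear factor graph over users' ternary emotion states.

    Parameters
    ----------
    variant : {"coupled", "literal"}
        "coupled" applies each pairwise factor's score when the two labels
        agree (default); "literal" applies it unconditionally, in which case
        the pairwise factors cancel in inference.
    lam : float
        L2 regularization weight on all parameters.
    enum_threshold : int
        Exact enumeration is used up to this many variable nodes, loopy
        sum-product beyond.
    damping, bp_max_iter, bp_tol :
        Loopy message-passing controls.
    max_iter, gtol :
        Optimizer budget and gradient-norm convergence for learning.

    Attributes
    ----------
    alpha_ : ndarray (n_features, 3)
        Modality weights per (feature, state).
    beta_ : float
        Tied entrainment-association weight.
    gamma_ : float
        Tied entrainment-pattern weight.
    classes_ : ndarray
        ``[-1, 0, 1]``.
    converged_ : bool
    """

    def __init__(self, variant: str = "coupled", lam: float = 0.1,
                 enum_threshold: int = 12, damping: float = 0.5,
                 bp_max_iter: int = 200, bp_tol: float = 1e-6,
                 max_iter: int = 500, gtol: float = 1e-4):
        self.variant = variant
        self.lam = lam
        self.enum_threshold = enum_threshold
        self.damping = damping
        self.bp_max_iter = bp_max_iter
        self.bp_tol = bp_tol
        self.max_iter = max_iter
        self.gtol = gtol

    # -- scoring -----------------------------------------------------------

    @staticmethod
    def _edge_arrays(edges, n_nodes):
        if edges is None or len(edges) == 0:
            return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                    np.zeros(0), np.zeros(0))
        e = np.asarray(edges, dtype=float)
        i, j = e[:, 0].astype(np.int64), e[:, 1].astype(np.int64)
        if (i == j).any():
            raise ValueError("self-edges are not allowed")
        if i.min() < 0 or max(i.max(), j.max()) >= n_nodes:
            raise ValueError("edge endpoint outside the node range")
        return i, j, e[:, 2], e[:, 3]

    def eval_score(self, x, y, edges=None) -> float:
        """Unnormalized log-score of a full assignment (Eq.-style sum)."""
        check_is_fitted(self, "alpha_")
        codes = _as_codes(y)
        s = self._node_scores(x)
        total = float(s[np.arange(len(codes)), codes].sum())
        ei, ej, g_etr, g_pat = self._edge_arrays(edges, len(codes))
        w = self.beta_ * g_etr + self.gamma_ * g_pat
        if self.variant == "coupled":
            total += float((w * (codes[ei] == codes[ej])).sum())
        else:
            total += float(w.sum())
        return total

    def _node_scores(self, x) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.alpha_

    # -- inference ---------------------------------------------------------

    @staticmethod
    def _assignments(n: int) -> np.ndarray:
        idx = np.arange(3**n)
        return (idx[:, None] // 3 ** np.arange(n - 1, -1, -1)[None, :]) % 3

    def _enumerate(self, node_scores, ei, ej, w, clamped=None):
        n = node_scores.shape[0]
        a = self._assignments(n)
        scores = node_scores[np.arange(n)[None, :], a].sum(axis=1)
        if self.variant == "coupled" and ei.size:
            agree = a[:, ei] == a[:, ej]
            scores = scores + agree @ w
        if clamped:
            keep = np.ones(a.shape[0], dtype=bool)
            for node, code in clamped.items():
                keep &= a[:, node] == code
            a, scores = a[keep], scores[keep]
        log_z = logsumexp(scores)
        p = np.exp(scores - log_z)
        marginals = np.zeros((n, 3))
        for c in range(3):
            marginals[:, c] = p @ (a == c)
        p_agree = p @ (a[:, ei] == a[:, ej]) if ei.size else np.zeros(0)
        return marginals, p_agree, float(log_z)

    def _loopy_bp(self, node_scores, ei, ej, w, clamped=None):
        n = node_scores.shape[0]
        phi = node_scores.copy()
        if clamped:
            for node, code in clamped.items():
                phi[node] = -50.0
                phi[node, code] = 0.0
        if self.variant != "coupled" or ei.size == 0:
            b = phi - logsumexp(phi, axis=1, keepdims=True)
            return np.exp(b), np.full(ei.size, 1.0 / 3.0), None
        n_e = ei.size
        # directed messages: 2 per edge, log-space, rows [e fwd i->j; e bwd j->i]
        msg = np.zeros((2 * n_e, 3))
        src = np.concatenate([ei, ej])
        dst = np.concatenate([ej, ei])
        w2 = np.concatenate([w, w])
        # log edge potential applied to a message: logsumexp over sender state
        converged = False
        for _ in range(self.bp_max_iter):
            # belief at each node from node potential + incoming messages
            incoming = np.zeros((n, 3))
            np.add.at(incoming, dst, msg)
            new = np.empty_like(msg)
            for d in range(2 * n_e):
                rev = (d + n_e) % (2 * n_e)
                h = phi[src[d]] + incoming[src[d]] - msg[rev]
                # psi(s, s') = exp(w * [s == s']); message is logsumexp over
                # the sender state s (rows)
                stack = np.broadcast_to(h[:, None], (3, 3)).copy()
                stack[np.arange(3), np.arange(3)] += w2[d]
                m = logsumexp(stack, axis=0)
                new[d] = m - logsumexp(m)
            delta = np.abs(new - msg).max()
            msg = self.damping * msg + (1.0 - self.damping) * new
            if delta < self.bp_tol:
                converged = True
                break
        incoming = np.zeros((n, 3))
        np.add.at(incoming, dst, msg)
        b = phi + incoming
        b = np.exp(b - logsumexp(b, axis=1, keepdims=True))
        # pairwise beliefs for the agreement expectation
        p_agree = np.empty(n_e)
        for e in range(n_e):
            hi = phi[ei[e]] + incoming[ei[e]] - msg[e + n_e]
            hj = phi[ej[e]] + incoming[ej[e]] - msg[e]
            pair = hi[:, None] + hj[None, :]
            pair[np.arange(3), np.arange(3)] += w[e]
            pair = np.exp(pair - logsumexp(pair))
            p_agree[e] = np.trace(pair)
        residual = None if converged else float(delta)
        return b, p_agree, residual

    def infer_marginals(self, x, edges=None, clamped: dict | None = None):
        """Per-node distributions over (NEG, NEU, POS), columns in class order.

        ``clamped`` maps node index -> observed label in {-1, 0, +1}; clamped
        nodes are fixed and propagate through the pairwise factors. Exact by
        enumeration on small graphs, loopy sum-product otherwise (a
        non-convergence residual is recorded on ``bp_residual_`` and the
        result still returned).
        """
        check_is_fitted(self, "alpha_")
        x = np.asarray(x, dtype=float)
        ei, ej, g_etr, g_pat = self._edge_arrays(edges, x.shape[0])
        w = self.beta_ * g_etr + self.gamma_ * g_pat
        clamp_codes = None
        if clamped:
            clamp_codes = {int(k): int(_as_codes([v])[0]) for k, v in clamped.items()}
        s = self._node_scores(x)
        if x.shape[0] <= self.enum_threshold:
            marginals, _, _ = self._enumerate(s, ei, ej, w, clamp_codes)
            self.bp_residual_ = None
        else:
            marginals, _, residual = self._loopy_bp(s, ei, ej, w, clamp_codes)
            self.bp_residual_ = residual
        return marginals

    def log_partition(self, x, edges=None) -> float:
        """log Z of the fitted model on a given graph (enumeration only)."""
        check_is_fitted(self, "alpha_")
        x = np.asarray(x, dtype=float)
        if x.shape[0] > self.enum_threshold:
            raise ValueError("log_partition requires an enumerable graph")
        ei, ej, g_etr, g_pat = self._edge_arrays(edges, x.shape[0])
        w = self.beta_ * g_etr + self.gamma_ * g_pat
        _, _, log_z = self._enumerate(self._node_scores(x), ei, ej, w)
        if self.variant == "literal":
            log_z += float(w.sum())  # constant pairwise factors shift every score
        return log_z

    def predict(self, x, edges=None, clamped: dict | None = None):
        """Argmax-marginal state per node; ties break toward NEU."""
        m = self.infer_marginals(x, edges, clamped)
        best = m.max(axis=1)
        out = np.empty(m.shape[0], dtype=np.int64)
        for r in range(m.shape[0]):
            # candidate order NEU, NEG, POS so NEU wins exact ties
            for c in (1, 0, 2):
                if m[r, c] >= best[r] - 1e-12:
                    out[r] = _CLASSES[c]
                    break
        return out

    # -- learning ----------------------------------------------------------

    def _pack(self, alpha, beta, gamma):
        return np.concatenate([alpha.ravel(), [beta, gamma]])

    def _unpack(self, theta, n_feat):
        return theta[: 3 * n_feat].reshape(n_feat, 3), theta[-2], theta[-1]

    def fit(self, X, Y, edges=None):
        """Fit by L2-regularized maximum likelihood on full assignments.

        Parameters
        ----------
        X : (n_nodes, n_features) binary matrix
            Modality features per user (shared across samples).
        Y : (n_samples, n_nodes) or (n_nodes,)
            Observed joint label assignments.
        edges : sequence of (i, j, g_etr, g_pat), optional
            Pairwise factor values per dyad.
        """
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y))
        if Y.shape[1] != X.shape[0]:
            raise ValueError("each sample must assign every node")
        instances = [(X, y) for y in Y]
        return self.fit_instances(instances, edges)

    def fit_instances(self, instances, edges=None):
        """Fit from per-sample (X, y) pairs sharing one edge set and weights.

        Each instance supplies its own feature matrix (features may differ
        over time) and a full label assignment; all instances share the tied
        parameters (alpha, beta, gamma).
        """
        if not instances:
            raise ValueError("no training instances")
        checked = [(np.asarray(x, dtype=float), _as_codes(y)) for x, y in instances]
        n_feat = checked[0][0].shape[1]
        n_nodes = checked[0][0].shape[0]
        for x, y in checked:
            if x.shape != (n_nodes, n_feat) or y.size != n_nodes:
                raise ValueError("instances must share node and feature counts")
        ll_and_grad = self.objective(instances, edges)
        n_s = len(checked)
        use_enum = n_nodes <= self.enum_threshold

        theta0 = np.zeros(3 * n_feat + 2)
        if use_enum:

            def objective(theta):
                value, grad = ll_and_grad(theta)
                if not np.isfinite(value):
                    raise FloatingPointError("EnFG learning diverged (non-finite objective)")
                return -value, -grad

            res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                           options={"maxiter": self.max_iter, "gtol": self.gtol,
                                    "ftol": 1e-12})
            theta = res.x
            self.converged_ = bool(res.success) or float(np.abs(res.jac).max()) < self.gtol
            self.n_iter_ = int(res.nit)
            self.opt_result_ = res
        else:
            # plain gradient ascent on the BP-approximated likelihood; the
            # gradient is observed minus expected counts under the beliefs
            theta = theta0
            step = 0.5 / max(n_s, 1)
            prev_norm, growth_streak = np.inf, 0
            self.converged_ = False
            for it in range(self.max_iter):
                _, grad = ll_and_grad(theta)
                gnorm = float(np.abs(grad).max())
                if not np.isfinite(gnorm):
                    raise FloatingPointError("EnFG learning diverged (non-finite gradient)")
                if gnorm < self.gtol:
                    self.converged_ = True
                    break
                growth_streak = growth_streak + 1 if gnorm > prev_norm else 0
                if growth_streak >= 10:
                    raise FloatingPointError(
                        f"EnFG learning diverged: gradient norm grew for 10 "
                        f"consecutive steps (last {gnorm:.3g})"
                    )
                prev_norm = gnorm
                theta = theta + step * grad
            self.n_iter_ = it + 1
            self.opt_result_ = None
        self.alpha_, self.beta_, self.gamma_ = self._unpack(theta, n_feat)
        self.beta_, self.gamma_ = float(self.beta_), float(self.gamma_)
        self.classes_ = _CLASSES.copy()
        return self

    def objective(self, instances, edges=None):
        """Penalized log-likelihood objective for diagnostics and learning.

        Returns a callable mapping a flat parameter vector (alpha raveled,
        then beta, gamma) to ``(value, ascent_gradient)``; the value is the
        exact penalized log-likelihood on enumerable graphs and None under
        loopy message passing (where only the gradient is available).
        Labels are states in {-1, 0, +1}.
        """
        instances = [(np.asarray(x, dtype=float), _as_codes(y)) for x, y in instances]
        n_feat = instances[0][0].shape[1]
        n_nodes = instances[0][0].shape[0]
        ei, ej, g_etr, g_pat = self._edge_arrays(edges, n_nodes)

        # observed sufficient statistics
        obs_alpha = np.zeros((n_feat, 3))
        obs_beta = obs_gamma = 0.0
        for x, y in instances:
            for c in range(3):
                obs_alpha[:, c] += x[y == c].sum(axis=0)
            if self.variant == "coupled" and ei.size:
                agree = (y[ei] == y[ej]).astype(float)
                obs_beta += float(g_etr @ agree)
                obs_gamma += float(g_pat @ agree)

        use_enum = n_nodes <= self.enum_threshold
        coupled = self.variant == "coupled" and ei.size > 0

        def ll_and_grad(theta):
            """Penalized log-likelihood (None under BP) and its ascent gradient."""
            alpha, beta, gamma = self._unpack(theta, n_feat)
            w = beta * g_etr + gamma * g_pat
            ll = 0.0
            exp_alpha = np.zeros((n_feat, 3))
            exp_beta = exp_gamma = 0.0
            for x, y in instances:
                s = x @ alpha
                if use_enum:
                    marg, p_agree, log_z = self._enum_theta(s, ei, ej, w)
                    score = float(s[np.arange(n_nodes), y].sum())
                    if coupled:
                        score += float(w @ (y[ei] == y[ej]).astype(float))
                    ll += score - log_z
                else:
                    marg, p_agree, _ = self._bp_theta(s, ei, ej, w)
                exp_alpha += x.T @ marg
                if coupled:
                    exp_beta += float(g_etr @ p_agree)
                    exp_gamma += float(g_pat @ p_agree)
            g_alpha = obs_alpha - exp_alpha - 2.0 * self.lam * alpha
            if coupled:
                g_beta = obs_beta - exp_beta - 2.0 * self.lam * beta
                g_gamma = obs_gamma - exp_gamma - 2.0 * self.lam * gamma
            else:
                g_beta = -2.0 * self.lam * beta
                g_gamma = -2.0 * self.lam * gamma
            penalty = self.lam * (np.sum(alpha**2) + beta**2 + gamma**2)
            value = (ll - penalty) if use_enum else None
            return value, self._pack(g_alpha, g_beta, g_gamma)

        return ll_and_grad

    # theta-parameterized inference used inside the objective (pre-fit)
    def _enum_theta(self, node_scores, ei, ej, w):
        return self._enumerate(node_scores, ei, ej, w)

    def _bp_theta(self, node_scores, ei, ej, w):
        return self._loopy_bp(node_scores, ei, ej, w)

    def log_likelihood(self, instances, edges=None) -> float:
        """Mean per-sample log-likelihood of full assignments (enumeration)."""
        check_is_fitted(self, "alpha_")
        total = 0.0
        instances = [(np.asarray(x, dtype=float), _as_codes(y)) for x, y in instances]
        for x, y in instances:
            n = x.shape[0]
            ei, ej, g_etr, g_pat = self._edge_arrays(edges, n)
            w = self.beta_ * g_etr + self.gamma_ * g_pat
            s = x @ self.alpha_
            _, _, log_z = self._enumerate(s, ei, ej, w)
            score = float(s[np.arange(n), y].sum())
            if self.variant == "coupled" and ei.size:
                score += float(w @ (y[ei] == y[ej]).astype(float))
            total += score - log_z
        return total / len(instances)


# ---------------------------------------------------------------------------
# the end-to-end prediction task


@dataclass
class PredictionResult:
    """Final-timestamp prediction outcome."""

    accuracy: float
    fold_accuracies: list
    predictions: dict
    gold: dict
    model: EnFGClassifier
    fold_assignments: dict = field(default_factory=dict)


def factor_edges_from_network(network: EntrainmentNetwork, en0: float | None = None,
                              users=None) -> list:
    """Pairwise factor values (i, j, g_etr, g_pat) from an entrainment network.

    ``g_etr`` counts the dyad's directions whose strength reaches En0 (the
    two directed association factors of one dyad, summed under weight tying);
    ``g_pat`` scores the pattern 2/1/0 for Dual/Single/None. ``en0`` defaults
    to the network's theta_t. ``users`` fixes the node index order (defaults
    to sorted node ids).
    """
    if en0 is None:
        en0 = network.theta_t
    if users is None:
        users = sorted({u for pair in network.strengths for u in pair})
    pos = {u: k for k, u in enumerate(users)}
    edges = []
    for key, d in network.dyads.items():
        i, j = d.dyad
        if i not in pos or j not in pos:
            continue
        g_etr = int(d.etr_ij >= en0) + int(d.etr_ji >= en0)
        g_pat = {DUAL: 2, SINGLE: 1}.get(d.pattern, 0)
        if g_etr or g_pat:
            edges.append((pos[i], pos[j], float(g_etr), float(g_pat)))
    return edges


def predict_final(series_map, *, network: EntrainmentNetwork | None = None,
                  en0: float | None = None, folds: int = 4, history_len: int = 3,
                  variant: str = "coupled", use_entrainment: bool = True,
                  lam: float = 0.1, te_cfg=None, seed: int = 0,
                  enum_threshold: int = 12,
                  train_window: int | None = None) -> PredictionResult:
    """Predict every user's emotion state at the final time bin.

    Training instances are the full community assignments at every earlier
    bin with complete observations, each paired with modality features built
    from the ``history_len`` bins preceding it; the final bin never enters
    features, factors, or the entrainment network. Users are split into
    ``folds`` folds: per fold, the model clamps the train-fold users to their
    observed final states and infers marginals for the held-out users;
    accuracies are averaged over folds.

    ``use_entrainment=False`` drops the pairwise factors (modality-only
    ablation) while keeping the identical folds, so comparisons are paired.
    ``train_window`` restricts the training instances to the last so many
    bins before the target (the entrainment network still sees the full
    history), keeping learning cost flat on long timelines.
    """
    if hasattr(series_map, "series"):
        series_map = series_map.series
    users = sorted(series_map)
    n_steps = len(series_map[users[0]])
    final = n_steps - 1
    if final < history_len + 1:
        raise ValueError("timeline too short for the requested history length")

    edges = []
    if use_entrainment:
        if network is None:
            from .entrainment import build_network

            trimmed = {u: series_map[u].slice(0, final) for u in users}
            network = build_network(trimmed, cfg=te_cfg)
        edges = factor_edges_from_network(network, en0=en0, users=users)

    mean_posts = float(np.mean([s.n_posts[:final].mean() for s in series_map.values()]))
    vocab = FeatureVocabulary()

    def instance_features(t):
        window = range(t - history_len, t)
        return [build_modality_features(series_map[u], window, mean_posts) for u in users]

    first_train = history_len
    if train_window is not None:
        first_train = max(history_len, final - train_window)
    train_instances = []
    for t in range(first_train, final):
        labels = np.array([series_map[u].states[t] for u in users])
        if np.isnan(labels).any():
            continue
        train_instances.append((vocab.encode(instance_features(t)), labels))
    if not train_instances:
        raise ValueError("no complete training bins")
    x_final = vocab.encode(instance_features(final), grow=False)
    # earlier instances were encoded before the vocabulary finished growing;
    # pad their matrices to the final width (absent features are zeros)
    train_instances = [
        (np.pad(x, ((0, 0), (0, len(vocab) - x.shape[1]))), y) for x, y in train_instances
    ]

    model = EnFGClassifier(variant=variant, lam=lam, enum_threshold=enum_threshold)
    model.fit_instances(train_instances, edges)

    gold = {u: series_map[u].states[final] for u in users}
    known = [k for k, u in enumerate(users) if not np.isnan(gold[users[k]])]
    if len(known) < folds:
        raise ValueError("fewer labeled users than folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc, predictions, fold_of = [], {}, {}
    for f, (train_idx, test_idx) in enumerate(kf.split(known)):
        clamp = {known[k]: int(gold[users[known[k]]]) for k in train_idx}
        pred = model.predict(x_final, edges, clamped=clamp)
        hits = []
        for k in test_idx:
            node = known[k]
            u = users[node]
            predictions[u] = int(pred[node])
            fold_of[u] = f
            hits.append(predictions[u] == int(gold[u]))
        fold_acc.append(float(np.mean(hits)))
    return PredictionResult(
        accuracy=float(np.mean(fold_acc)),
        fold_accuracies=fold_acc,
        predictions=predictions,
        gold={u: (None if np.isnan(v) else int(v)) for u, v in gold.items()},
        model=model,
        fold_assignments=fold_of,
    )
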