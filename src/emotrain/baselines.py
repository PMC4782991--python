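"""Baseline feature encodings for conventional per-user classifiers.

Conventional classifiers cannot consume relational factors directly, so the
entrainment structure is flattened into per-user features added in tiers,
mirroring the sequential-addition ablation design:

* ``modality``   — the flattened modality n-gram vector alone;
* ``+dual``      — plus the user's chain-cluster group id (users linked when
  both directed strengths reach En0; groups are the connected components of
  the linked graph, i.e. the transitive closure of the chain);
* ``+single``    — plus the discretized emotion distribution of the user's
  top-K most solely entrained neighbors, strength-weighted.

Tier accuracies are averaged over a shared fold partition so comparisons
against the factor-graph model are paired.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.model_selection import KFold

from .entrainment import SINGLE, EntrainmentNetwork

MISSING_CODE = 0  # per-dimension code when a user has no qualifying neighbor


def chain_cluster(network: EntrainmentNetwork, en0: float | None = None,
                  users=None) -> dict:
    """Group users by chain clustering over reciprocal super-threshold links.

    Users i and j are linked when both Etr(i -> j) >= En0 and
    Etr(j -> i) >= En0; groups are the connected components of the linked
    graph, so chains a-b, b-c place a and c in one group even without a
    direct link. Returns a mapping user -> group id; singletons get their
    own group.
    """
    if en0 is None:
        en0 = network.theta_t
    if users is None:
        users = sorted({u for pair in network.strengths for u in pair})
    g = nx.Graph()
    g.add_nodes_from(users)
    for (i, j), w in network.strengths.items():
        if w >= en0 and network.strengths.get((j, i), -np.inf) >= en0:
            g.add_edge(i, j)
    labels = {}
    for gid, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        for u in comp:
            labels[u] = gid
    return labels


def discretize_distribution(d: np.ndarray) -> np.ndarray:
    """Per-dimension code of a probability vector: 1 if < 1/4, 2 if in
    [1/4, 1/2) (closed on the left), 3 otherwise."""
    d = np.asarray(d, dtype=float)
    codes = np.where(d < 0.25, 1, np.where(d < 0.5, 2, 3))
    return codes.astype(np.int64)


def single_neighbor_distribution(user, network: EntrainmentNetwork,
                                 distributions: dict, k: int = 5):
    """Strength-weighted emotion distribution of solely entrained neighbors.

    Neighbors j qualify when the (user, j) dyad is Single with the user as
    the over-threshold adopter: Etr(user -> j) >= theta_t and
    Etr(j -> user) < theta_t. The top ``k`` by Etr(user -> j) are averaged,

        D_i = sum_j Etr(i -> j) d_j / sum_j Etr(i -> j),

    then discretized per :func:`discretize_distribution`.

    Returns ``(D_i, codes)`` or ``(None, codes_of_zeros)`` when no neighbor
    qualifies (the documented missing-value code).
    """
    theta = network.theta_t
    candidates = []
    for key, d in network.dyads.items():
        if user not in key or d.pattern != SINGLE:
            continue
        i, j = d.dyad
        other, fwd, bwd = (j, d.etr_ij, d.etr_ji) if i == user else (i, d.etr_ji, d.etr_ij)
        if fwd >= theta and bwd < theta:
            candidates.append((fwd, other))
    if not candidates:
        return None, np.full(3, MISSING_CODE, dtype=np.int64)
    candidates.sort(key=lambda c: (-c[0], repr(c[1])))
    top = candidates[:k]
    weights = np.array([w for w, _ in top])
    mat = np.stack([np.asarray(distributions[u], dtype=float) for _, u in top])
    d_i = weights @ mat / weights.sum()
    return d_i, discretize_distribution(d_i)


def _one_hot(values, n=None):
    values = np.asarray(values, dtype=np.int64)
    n = int(values.max()) + 1 if n is None else n
    out = np.zeros((values.size, n))
    out[np.arange(values.size), values] = 1.0
    return out


def build_feature_tiers(x_modality: np.ndarray, group_ids=None, single_codes=None) -> dict:
    """Stack the tiered design matrices from the component encodings."""
    tiers = {"modality": x_modality}
    x = x_modality
    if group_ids is not None:
        x = np.hstack([x, _one_hot(group_ids)])
        tiers["+dual"] = x
    if single_codes is not None:
        codes = np.asarray(single_codes, dtype=np.int64)
        # one-hot each of the three dimensions over codes {0..3}
        blocks = [_one_hot(codes[:, d], 4) for d in range(codes.shape[1])]
        tiers["+single"] = np.hstack([x] + blocks)
    return tiers


def run_baseline(tiers: dict, labels, classifier: str = "maximum-entropy",
                 folds: int = 4, seed: int = 0, fold_indices=None) -> pd.DataFrame:
    """Cross-validated accuracy per feature tier for a flat classifier.

    Parameters
    ----------
    tiers : dict name -> (n_users, n_features) matrix
        Typically from :func:`build_feature_tiers`.
    labels : array-like in {-1, 0, +1}
        Final-timestamp emotion state per user.
    classifier : {"naive-bayes", "maximum-entropy"}
        Multinomial naive Bayes or multinomial logistic regression.
    fold_indices : list of (train, test) index arrays, optional
        Shared fold partition (to pair with the factor-graph evaluation);
        defaults to a seeded KFold.

    Returns
    -------
    DataFrame with columns (tier, fold, accuracy).
    """
    y = np.asarray(labels)
    n = y.size
    if fold_indices is None:
        if n < folds:
            raise ValueError(f"cannot build {folds} folds from {n} users")
        fold_indices = list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(np.arange(n)))
    rows = []
    for tier, x in tiers.items():
        for f, (train, test) in enumerate(fold_indices):
            if classifier == "naive-bayes":
                clf = MultinomialNB(alpha=1.0)
            elif classifier == "maximum-entropy":
                clf = LogisticRegression(max_iter=2000)
            else:
                raise ValueError(f"unknown classifier {classifier!r}")
            clf.fit(x[train], y[train])
            acc = float((clf.predict(x[test]) == y[test]).mean())
            rows.append({"tier": tier, "fold": f, "accuracy": acc})
    return pd.DataFrame(rows)
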