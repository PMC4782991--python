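"""Mood-label and text polarity: mapping posts to the ternary emotion states.

Two routes produce the -1/0/+1 emotion coding. Platforms with explicit mood
labels use a lexicon lookup (:func:`map_labels`); unlabeled text goes through
a multinomial naive Bayes classifier over unigram/bigram features with a
``neg-`` prefix applied to tokens in the scope of a negation indicator, plus
an optional self-training loop that augments the training set with its own
high-confidence predictions.

Tokenization is an injected dependency: documents arrive pre-tokenized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.naive_bayes import MultinomialNB
from sklearn.utils.validation import check_is_fitted

from .series import NEG, NEU, POS

UNKNOWN = "UNKNOWN"

_STATE_NAMES = {"POS": POS, "NEU": NEU, "NEG": NEG}

DEFAULT_NEGATORS = frozenset({"not", "no", "never", "n't", "cannot", "without"})

_PUNCTUATION = frozenset(".,;:!?()[]{}\"'")


@dataclass
class PolarityLexicon:
    """Mapping from mood-label strings to emotion states.

    Labels absent from the mapping resolve to :data:`UNKNOWN` and are
    excluded from emotion series (but kept for activity accounting).
    """

    mapping: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for label, state in self.mapping.items():
            if isinstance(state, str):
                state = _STATE_NAMES[state.upper()]
            if state not in (NEG, NEU, POS):
                raise ValueError(f"label {label!r} maps to invalid state {state!r}")
            clean[label] = state
        self.mapping = clean

    def __getitem__(self, label):
        return self.mapping.get(label, UNKNOWN)

    def __len__(self):
        return len(self.mapping)

    @classmethod
    def from_tsv(cls, path) -> "PolarityLexicon":
        """Load a two-column TSV of (label, state) rows; state in POS/NEU/NEG."""
        df = pd.read_csv(path, sep="\t", header=None, names=["label", "state"],
                         dtype=str, comment="#")
        return cls({r.label: r.state for r in df.itertuples()})


def map_labels(events: pd.DataFrame, lexicon: PolarityLexicon) -> pd.DataFrame:
    """Attach emotion states to a labeled event stream.

    Adds a ``state`` column (-1/0/+1, or NaN for unknown or untagged labels)
    to a copy of ``events``; rows with NaN state are excluded from
    entrainment computation downstream but retained here so posting activity
    stays complete (the POS/NEU/NEG/UNKNOWN/NOTAG accounting).
    """
    out = events.copy()

    def _lookup(label):
        if label is None or (isinstance(label, float) and np.isnan(label)):
            return np.nan
        state = lexicon[label]
        return np.nan if state == UNKNOWN else float(state)

    out["state"] = out["label"].map(_lookup) if "label" in out else np.nan
    return out


def featurize(tokens, negators=DEFAULT_NEGATORS, scope: int = 2) -> list:
    """Unigram + adjacent-bigram features with negation prefixing.

    Any token within ``scope`` tokens after a negation indicator receives the
    prefix ``neg-``; the scope does not cross punctuation. Bigrams join the
    (possibly prefixed) unigram stream with ``_``. Returns a feature list
    (multiset semantics: repeats are kept).
    """
    marked = []
    remaining = 0
    for tok in tokens:
        if tok in _PUNCTUATION:
            remaining = 0
            marked.append(tok)
            continue
        if tok in negators:
            marked.append(tok)
            remaining = scope
            continue
        if remaining > 0:
            marked.append("neg-" + tok)
            remaining -= 1
        else:
            marked.append(tok)
    feats = list(marked)
    feats.extend(f"{a}_{b}" for a, b in zip(marked, marked[1:]))
    return feats


class PolarityNB(BaseEstimator, ClassifierMixin):
    """Multinomial naive Bayes polarity classifier over n-gram features.

    Documents are token lists; features are the unigrams and bigrams of
    :func:`featurize` with the ``neg-`` negation rule. Additive (Laplace)
    smoothing with ``alpha=1``; posterior ties break toward the neutral
    class. ``self_train`` runs the semi-supervised loop that permanently
    adds high-confidence pseudo-labeled documents and refits.

    Parameters
    ----------
    alpha : float
        Additive smoothing for the per-class feature distributions.
    negators : frozenset of str
        Negation indicators triggering the ``neg-`` prefix.
    scope : int
        Number of tokens a negator's scope extends over (punctuation-bounded).
    self_train_confidence : float in (0.5, 1]
        Minimum max-posterior for a pseudo-label to enter the training set.
    max_rounds : int
        Upper bound on self-training iterations.
    """

    def __init__(self, alpha: float = 1.0, negators=DEFAULT_NEGATORS, scope: int = 2,
                 self_train_confidence: float = 0.9, max_rounds: int = 10):
        self.alpha = alpha
        self.negators = negators
        self.scope = scope
        self.self_train_confidence = self_train_confidence
        self.max_rounds = max_rounds

    # -- vectorization -----------------------------------------------------

    def _count_matrix(self, docs, vocab, grow: bool):
        rows, cols, vals = [], [], []
        for r, doc in enumerate(docs):
            counts = Counter(featurize(doc, self.negators, self.scope))
            for feat, c in counts.items():
                if feat not in vocab:
                    if not grow:
                        continue
                    vocab[feat] = len(vocab)
                rows.append(r)
                cols.append(vocab[feat])
                vals.append(c)
        from scipy.sparse import csr_matrix

        return csr_matrix(
            (vals, (rows, cols)), shape=(len(docs), max(len(vocab), 1)), dtype=np.float64
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        """Fit on a labeled corpus: X a sequence of token lists, y in {-1,0,+1}."""
        docs = list(X)
        y = np.asarray(list(y))
        if len(docs) == 0:
            raise ValueError("empty training corpus")
        if len(docs) != y.size:
            raise ValueError("X and y length mismatch")
        self.vocabulary_ = {}
        mat = self._count_matrix(docs, self.vocabulary_, grow=True)
        self._nb = MultinomialNB(alpha=self.alpha)
        self._nb.fit(mat, y)
        self.classes_ = self._nb.classes_
        self.train_docs_ = docs
        self.train_labels_ = y
        self.train_size_history_ = [len(docs)]
        return self

    def predict_log_proba(self, X):
        check_is_fitted(self, "vocabulary_")
        mat = self._count_matrix(list(X), self.vocabulary_, grow=False)
        return self._nb.predict_log_proba(mat)

    def predict_proba(self, X):
        return np.exp(self.predict_log_proba(X))

    def predict(self, X):
        """Argmax-posterior state per document; ties break toward NEU."""
        proba = self.predict_proba(X)
        best = proba.max(axis=1)
        out = np.empty(proba.shape[0], dtype=self.classes_.dtype)
        # candidate order puts NEU first so it wins exact ties
        order = np.argsort([0 if c == NEU else 1 for c in self.classes_], kind="stable")
        for r in range(proba.shape[0]):
            for k in order:
                if proba[r, k] >= best[r] - 1e-12:
                    out[r] = self.classes_[k]
                    break
        return out

    def self_train(self, X_unlabeled, confidence: float | None = None,
                   max_rounds: int | None = None) -> "PolarityNB":
        """Semi-supervised augmentation with high-confidence predictions.

        Repeatedly classifies the unlabeled pool, permanently moves every
        document whose max posterior meets the confidence threshold into the
        training set with its predicted label, and refits; stops when a round
        adds nothing or after ``max_rounds``. Deterministic given input
        order. Returns self (refitted in place).
        """
        check_is_fitted(self, "vocabulary_")
        confidence = self.self_train_confidence if confidence is None else confidence
        max_rounds = self.max_rounds if max_rounds is None else max_rounds
        pool = list(X_unlabeled)
        for _ in range(max_rounds):
            if not pool:
                break
            proba = self.predict_proba(pool)
            conf = proba.max(axis=1)
            take = conf >= confidence
            if not take.any():
                break
            labels = self.predict([pool[i] for i in np.nonzero(take)[0]])
            self.train_docs_ = self.train_docs_ + [pool[i] for i in np.nonzero(take)[0]]
            self.train_labels_ = np.concatenate([self.train_labels_, labels])
            pool = [d for d, t in zip(pool, take) if not t]
            history = self.train_size_history_ + [len(self.train_docs_)]
            self.fit(self.train_docs_, self.train_labels_)
            self.train_size_history_ = history
        return self
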