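"""Per-user emotion trajectories.

A user's stream of posts is binned (one bin per day by default); each bin
carries at most one emotion state from the ternary alphabet {-1, 0, +1}
(negative, neutral, positive) plus a posting count. Bins without an observed
state are missing (NaN) and are excluded from entrainment estimation rather
than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG, NEU, POS = -1, 0, 1
STATES = (NEG, NEU, POS)

#: order of the dimensions in every emotion-state probability vector
DIST_STATES = (POS, NEU, NEG)


@dataclass
class EmotionSeries:
    """One user's time-binned ternary emotion trajectory.

    Parameters
    ----------
    user_id : hashable
        User identifier.
    states : array-like of float
        Emotion state per bin, values in {-1, 0, +1}; NaN marks a bin with no
        observation.
    n_posts : array-like of int, optional
        Posts per bin; defaults to one post per observed bin.
    """

    user_id: object
    states: np.ndarray
    n_posts: np.ndarray = field(default=None)

    def __post_init__(self):
        states = np.asarray(self.states, dtype=float)
        observed = ~np.isnan(states)
        bad = observed & ~np.isin(states, STATES)
        if bad.any():
            raise ValueError(
                f"states outside the ternary alphabet {STATES} at bins "
                f"{np.nonzero(bad)[0][:5].tolist()}"
            )
        self.states = states
        if self.n_posts is None:
            self.n_posts = observed.astype(np.int64)
        else:
            n_posts = np.asarray(self.n_posts, dtype=np.int64)
            if n_posts.shape != states.shape:
                raise ValueError("states and n_posts must share an index range")
            if (n_posts < 0).any():
                raise ValueError("n_posts must be non-negative")
            self.n_posts = n_posts

    def __len__(self) -> int:
        return self.states.size

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of bins with an observed state."""
        return ~np.isnan(self.states)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def slice(self, start: int, stop: int) -> "EmotionSeries":
        return EmotionSeries(self.user_id, self.states[start:stop], self.n_posts[start:stop])


def as_states(series) -> np.ndarray:
    """Coerce an :class:`EmotionSeries` or array-like to a float state array."""
    if isinstance(series, EmotionSeries):
        return series.states
    return EmotionSeries("_", np.asarray(series, dtype=float)).states
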