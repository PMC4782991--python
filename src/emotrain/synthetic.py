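"""Synthetic communities of coupled ternary emotion chains.

Every user's emotion state evolves as a first-order Markov chain on
{-1, 0, +1}; a directed coupling edge (source, follower, kappa) makes the
follower copy the source's previous state with probability kappa and
otherwise draw from the base chain conditioned on its own previous state.
Updates are synchronous from t-1 states only, so bidirectional (Dual)
coupling is well-defined and order-free. Planted dyad patterns provide
ground truth for the entrainment estimators: Dual iff both directions are
coupled, Single iff exactly one, None for sampled uncoupled control pairs.

The generator emulates the structure of emotion-tagged social-media streams
(long timelines, users joining and abandoning, per-bin posting counts,
missing observations) without claiming to match any real corpus's dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import EmotionSeries, STATES
from .entrainment import DUAL, SINGLE, NONE

#: day-granularity mood persistence: users tend to stay in their current
#: state, with the neutral state acting as the main conduit between poles
DEFAULT_TRANSITION = np.array(
    [
        [0.50, 0.30, 0.20],  # from NEG
        [0.25, 0.50, 0.25],  # from NEU
        [0.20, 0.30, 0.50],  # from POS
    ]
)


@dataclass
class SyntheticConfig:
    """Parameters of a planted-coupling community simulation.

    Parameters
    ----------
    n_users : int
        Community size.
    n_steps : int
        Number of time bins.
    base_transition : (3, 3) array
        Row-stochastic transition matrix over states (-1, 0, +1).
    coupling_edges : list of (source, follower, kappa)
        Directed coupling: the follower copies the source's previous state
        with probability ``kappa`` in [0, 1].
    activity_rate : float
        Mean posts per user per bin (Poisson).
    missing_rate : float
        Probability a user has no observation in a bin (independent
        Bernoulli per user and bin).
    n_control_dyads : int
        Uncoupled pairs sampled as planted None dyads, so pattern-recovery
        accuracy has a denominator.
    seed : int
        Seed for all randomness; identical config + seed is bit-exact.
    """

    n_users: int
    n_steps: int
    base_transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    coupling_edges: list = field(default_factory=list)
    activity_rate: float = 1.0
    missing_rate: float = 0.0
    n_control_dyads: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_users < 1 or self.n_steps < 1:
            raise ValueError("n_users and n_steps must be positive")
        p = np.asarray(self.base_transition, dtype=float)
        if p.shape != (3, 3) or (p < 0).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("base_transition must be a 3x3 row-stochastic matrix")
        self.base_transition = p
        for src, fol, kappa in self.coupling_edges:
            if src == fol:
                raise ValueError(f"self-edge on user {src}")
            if not 0.0 <= kappa <= 1.0:
                raise ValueError(f"kappa={kappa} outside [0, 1] on edge ({src}, {fol})")
            if not (0 <= src < self.n_users and 0 <= fol < self.n_users):
                raise ValueError(f"edge ({src}, {fol}) references unknown users")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.activity_rate <= 0:
            raise ValueError("activity_rate must be positive")

    def planted_pattern(self, i, j) -> str:
        """Dual/Single/None pattern implied by the coupling edges for (i, j)."""
        fwd = any(s == i and f == j for s, f, k in self.coupling_edges if k > 0)
        bwd = any(s == j and f == i for s, f, k in self.coupling_edges if k > 0)
        return (NONE, SINGLE, DUAL)[fwd + bwd]


@dataclass
class SyntheticCommunity:
    """A generated community: series per user plus planted dyad patterns."""

    series: dict
    planted_patterns: dict
    config: SyntheticConfig

    def too_short_users(self, order_m: int = 3) -> set:
        """Users whose observed span is too short for order-m TE estimation.

        A span shorter than ``order_m + 2`` bins cannot form a single aligned
        (m+1)-gram window.
        """
        out = set()
        for uid, s in self.series.items():
            idx = np.nonzero(s.observed)[0]
            span = 0 if idx.size == 0 else int(idx[-1] - idx[0] + 1)
            if span < order_m + 2:
                out.add(uid)
        return out

    def to_events(self) -> pd.DataFrame:
        """Flatten to the event-stream format (user, bin, state, n_posts)."""
        rows = []
        for uid, s in self.series.items():
            for b in range(len(s)):
                state = s.states[b]
                if np.isnan(state) and s.n_posts[b] == 0:
                    continue
                rows.append(
                    {
                        "user": uid,
                        "bin": b,
                        "state": None if np.isnan(state) else int(state),
                        "n_posts": int(s.n_posts[b]),
                    }
                )
        return pd.DataFrame(rows, columns=["user", "bin", "state", "n_posts"])


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(transition.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _draw_states(rng, prev_codes: np.ndarray, cum_p: np.ndarray) -> np.ndarray:
    u = rng.random(prev_codes.size)
    return (u[:, None] > cum_p[prev_codes]).sum(axis=1)


def generate_community(config: SyntheticConfig) -> SyntheticCommunity:
    """Simulate a community of coupled emotion chains.

    All users draw their initial state from the base chain's stationary
    distribution. At each subsequent bin every user first draws from
    ``base_transition`` conditioned on its own t-1 state; then each coupling
    edge fires independently with probability kappa and overwrites the
    follower's draw with the source's t-1 state (when several edges target
    the same follower, the last edge in list order that fires wins). Missing
    observations and posting counts are laid on top of the latent states.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n_u, n_t = config.n_users, config.n_steps
    cum_p = np.cumsum(config.base_transition, axis=1)
    pi = stationary_distribution(config.base_transition)

    codes = np.empty((n_u, n_t), dtype=np.int64)  # 0,1,2 <-> -1,0,+1
    codes[:, 0] = rng.choice(3, size=n_u, p=pi)
    edges = config.coupling_edges
    if edges:
        e_src = np.array([e[0] for e in edges], dtype=np.int64)
        e_fol = np.array([e[1] for e in edges], dtype=np.int64)
        e_kap = np.array([e[2] for e in edges], dtype=float)
        # one coin per (edge, bin), drawn up front so the inner loop stays
        # vectorized; edge order is preserved (fancy assignment keeps the
        # last firing edge for a shared follower)
        coins = rng.random((len(edges), n_t)) < e_kap[:, None]
    for t in range(1, n_t):
        nxt = _draw_states(rng, codes[:, t - 1], cum_p)
        if edges:
            fired = np.nonzero(coins[:, t])[0]
            if fired.size:
                nxt[e_fol[fired]] = codes[e_src[fired], t - 1]
        codes[:, t] = nxt

    n_posts = rng.poisson(config.activity_rate, size=(n_u, n_t))
    missing = (
        rng.random((n_u, n_t)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((n_u, n_t), dtype=bool)
    )

    states = codes.astype(float) - 1.0
    states[missing] = np.nan
    series = {
        u: EmotionSeries(u, states[u], n_posts[u]) for u in range(n_u)
    }

    patterns = {}
    coupled_pairs = set()
    for src, fol, kappa in config.coupling_edges:
        if kappa > 0:
            key = frozenset((src, fol))
            coupled_pairs.add(key)
            patterns[key] = config.planted_pattern(src, fol)
    if config.n_control_dyads > 0:
        candidates = [
            frozenset((i, j))
            for i in range(n_u)
            for j in range(i + 1, n_u)
            if frozenset((i, j)) not in coupled_pairs
        ]
        if config.n_control_dyads > len(candidates):
            raise ValueError("not enough uncoupled pairs for n_control_dyads")
        picks = rng.choice(len(candidates), size=config.n_control_dyads, replace=False)
        for k in picks:
            patterns[candidates[int(k)]] = NONE

    return SyntheticCommunity(series=series, planted_patterns=patterns, config=config)


def generate_community_timeline(
    config: SyntheticConfig, join_times, abandon_times
) -> SyntheticCommunity:
    """Community with per-user active intervals [join, abandon).

    Observations exist only within each user's active interval; outside it
    the series is missing and posting counts are zero. Join/abandon times are
    validated per user (join < abandon, both within [0, n_steps]).
    """
    join = np.asarray(join_times, dtype=np.int64)
    abandon = np.asarray(abandon_times, dtype=np.int64)
    if join.shape != (config.n_users,) or abandon.shape != (config.n_users,):
        raise ValueError("join/abandon times must give one entry per user")
    if (join < 0).any() or (abandon > config.n_steps).any():
        raise ValueError("join/abandon times outside [0, n_steps]")
    if (join >= abandon).any():
        bad = int(np.nonzero(join >= abandon)[0][0])
        raise ValueError(f"user {bad}: join must precede abandon")

    com = generate_community(config)
    for u, s in com.series.items():
        mask = np.ones(config.n_steps, dtype=bool)
        mask[join[u] : abandon[u]] = False
        s.states[mask] = np.nan
        s.n_posts[mask] = 0
    return com


def sample_join_times(n_users: int, n_steps: int, rate: float, seed: int = 0) -> np.ndarray:
    """Join times whose cumulative count grows like exp(rate * t).

    Draws arrival times with density proportional to ``exp(rate * t)`` on
    [0, n_steps), so a log-linear fit of the cumulative user count recovers
    ``rate``. Used to emulate exponential community growth.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n_users)
    if abs(rate) < 1e-12:
        t = u * n_steps
    else:
        # inverse CDF of density ~ exp(rate * t) on [0, T]
        t = np.log1p(u * np.expm1(rate * n_steps)) / rate
    return np.minimum(t.astype(np.int64), n_steps - 1)
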