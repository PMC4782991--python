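"""Peer-level entrainment analyses over dyad trajectories.

Works on sequences of per-timestamp :class:`~emotrain.entrainment.DyadEntrainment`
records (one trajectory per user pair): reciprocity of directional strengths,
emotional distance by pattern group, the Dual/Single count ratio R_t whose
rise-then-fall separates the relationship 'develop' and 'maintain' stages,
lead-time distributions between first Dual and first Single onset, and the
strength-versus-distance regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
import statsmodels.api as sm

from .entrainment import DUAL, SINGLE, NONE


@dataclass
class DyadTrajectory:
    """Per-bin entrainment records and pairwise CE distance for one dyad."""

    dyad: tuple
    bins: np.ndarray
    etr_ij: np.ndarray
    etr_ji: np.ndarray
    patterns: list
    ce: np.ndarray = None

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=np.int64)
        if (np.diff(self.bins) <= 0).any():
            raise ValueError("bins must be strictly increasing")
        self.etr_ij = np.asarray(self.etr_ij, dtype=float)
        self.etr_ji = np.asarray(self.etr_ji, dtype=float)
        bad = set(self.patterns) - {DUAL, SINGLE, NONE}
        if bad:
            raise ValueError(f"unknown patterns {bad}")
        if self.ce is not None:
            self.ce = np.asarray(self.ce, dtype=float)

    def first_onset(self, pattern: str):
        """First bin where the dyad is classified as ``pattern``, or None."""
        for b, p in zip(self.bins, self.patterns):
            if p == pattern:
                return int(b)
        return None


@dataclass
class StageSummary:
    """R_t series and stage segmentation of a set of dyad trajectories.

    ``r_t[t]`` is #Dual_t / #Single_t (NaN when no Single dyads exist at t,
    recorded as missing rather than infinity); the peak (first argmax) marks
    the boundary between the relationship 'develop' and 'maintain' stages.
    """

    bins: np.ndarray
    r_t: np.ndarray
    n_dual: np.ndarray
    n_single: np.ndarray
    peak_bin: int
    boundary: int
    lead_times: np.ndarray = field(default=None)


def reciprocal_correlation(trajectories, t: int | None = None):
    """Pearson correlation between the two directional strengths across dyads.

    ``t=None`` pools every (dyad, bin) record; otherwise only records at bin
    ``t`` enter. Returns ``(r, p_value)`` from a two-sided test. A positive r
    is the signature of reciprocal entrainment: users who entrain strongly
    toward a partner tend to be entrained back with similar strength.
    """
    a, b = [], []
    for tr in trajectories:
        sel = slice(None) if t is None else (tr.bins == t)
        a.extend(np.atleast_1d(tr.etr_ij[sel]))
        b.extend(np.atleast_1d(tr.etr_ji[sel]))
    a, b = np.asarray(a), np.asarray(b)
    if a.size < 10:
        raise ValueError("need >= 10 dyad records with defined strengths")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant strengths")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def groupwise_distance(trajectories, t: int):
    """Mean pairwise CE per pattern group at bin ``t``, with two-sample tests.

    Returns ``(means, tests)``: ``means`` maps each non-empty pattern group
    to its mean CE distance, ``tests`` maps unordered group pairs to the
    (t statistic, p value) of an independent two-tailed t-test.
    """
    groups = {}
    for tr in trajectories:
        if tr.ce is None:
            continue
        idx = np.nonzero(tr.bins == t)[0]
        for k in idx:
            groups.setdefault(tr.patterns[k], []).append(tr.ce[k])
    if not groups:
        raise ValueError(f"no classified dyads at bin {t}")
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    tests = {}
    names = sorted(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ga, gb = names[i], names[j]
            if len(groups[ga]) > 1 and len(groups[gb]) > 1:
                tstat, p = stats.ttest_ind(groups[ga], groups[gb])
                tests[(ga, gb)] = (float(tstat), float(p))
    return means, tests


def dual_single_ratio(trajectories) -> StageSummary:
    """R_t = #Dual_t / #Single_t per bin, with peak-based stage segmentation.

    The peak (first occurrence on ties, NaN bins ignored) separates the
    'develop' stage (rising mutual entrainment) from the 'maintain' stage.
    Raises if no bin ever has a Single dyad.
    """
    all_bins = sorted({int(b) for tr in trajectories for b in tr.bins})
    if not all_bins:
        raise ValueError("no classified bins")
    n_dual = np.zeros(len(all_bins))
    n_single = np.zeros(len(all_bins))
    pos = {b: k for k, b in enumerate(all_bins)}
    for tr in trajectories:
        for b, p in zip(tr.bins, tr.patterns):
            if p == DUAL:
                n_dual[pos[int(b)]] += 1
            elif p == SINGLE:
                n_single[pos[int(b)]] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r_t = np.where(n_single > 0, n_dual / np.maximum(n_single, 1), np.nan)
    if np.isnan(r_t).all():
        raise ValueError("R_t undefined at every bin (no Single dyads)")
    peak_idx = int(np.nanargmax(r_t))
    lead, _, _ = lead_time_distribution(trajectories)
    return StageSummary(
        bins=np.asarray(all_bins),
        r_t=r_t,
        n_dual=n_dual,
        n_single=n_single,
        peak_bin=all_bins[peak_idx],
        boundary=all_bins[peak_idx],
        lead_times=lead,
    )


def lead_time_distribution(trajectories):
    """Signed lead time (first Dual bin - first Single bin) per dyad.

    Positive values mean Single came first. Dyads that never reach both
    patterns are excluded from the signed histogram and counted separately.

    Returns
    -------
    lead_times : ndarray
        One signed value per dyad reaching both patterns.
    n_excluded : int
        Dyads never classified as both Dual and Single.
    p_single_first : float
        Fraction of signed lead times that are positive (Single-first),
        among nonzero lead times; NaN if none.
    """
    leads, excluded = [], 0
    for tr in trajectories:
        fd, fs = tr.first_onset(DUAL), tr.first_onset(SINGLE)
        if fd is None or fs is None:
            excluded += 1
            continue
        leads.append(fd - fs)
    leads = np.asarray(leads, dtype=float)
    nz = leads[leads != 0]
    p_single_first = float((nz > 0).mean()) if nz.size else float("nan")
    return leads, excluded, p_single_first


def strength_vs_distance_regression(min_strengths, ce_distances):
    """OLS of emotional distance on the minor reciprocal entrainment strength.

    One point per dyad: x = min(Etr_ij, Etr_ji) (the weaker of the two
    directions), y = the dyad's mean CE distance. A negative slope reproduces
    the convergence-under-entrainment effect: more strongly (reciprocally)
    entrained dyads sit emotionally closer.

    Returns a dict with slope, intercept, their standard errors, the slope's
    two-sided p-value, and r_squared.
    """
    x = np.asarray(min_strengths, dtype=float)
    y = np.asarray(ce_distances, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 dyads for a regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all strengths equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "slope_se": float(model.bse[1]),
        "slope_pvalue": float(model.pvalues[1]),
        "r_squared": float(model.rsquared),
    }
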