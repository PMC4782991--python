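"""Community lifecycle statistics: join/abandon accounting and growth fits.

A user joins the community at their first post and abandons it after their
last post if that post lies at least six months (182 day-bins by default)
before the end of the observation window; users posting within the final six
months are never called abandoned. User-base and post-volume growth curves
are fitted with the exponential law y = a * exp(b * (t - t0)) via least
squares on the log-transformed counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

SIX_MONTHS_BINS = 182  # at one-day bins


@dataclass
class LifecycleRecord:
    """First/last posting bin of one user plus the abandonment call."""

    user: object
    first_post: int
    last_post: int
    abandoned: bool


@dataclass
class GrowthFit:
    """Fitted exponential growth y = a * exp(b * (t - t0))."""

    a: float
    b: float
    t0: float
    window: tuple
    b_se: float
    residual_std: float

    def predict(self, t):
        return self.a * np.exp(self.b * (np.asarray(t, dtype=float) - self.t0))


def lifecycle_records(events: pd.DataFrame, corpus_end: int | None = None,
                      abandon_gap: int = SIX_MONTHS_BINS) -> list:
    """Per-user first/last post bins and abandonment flags.

    ``events`` needs columns ``user`` and ``bin``. A user is abandoned when
    their last post is at least ``abandon_gap`` bins before ``corpus_end``
    (default: the last bin observed in the stream).
    """
    if corpus_end is None:
        corpus_end = int(events["bin"].max())
    grouped = events.groupby("user")["bin"].agg(["min", "max"])
    return [
        LifecycleRecord(
            user=u,
            first_post=int(row["min"]),
            last_post=int(row["max"]),
            abandoned=bool(corpus_end - row["max"] >= abandon_gap),
        )
        for u, row in grouped.iterrows()
    ]


def lifecycle_breakdown(events: pd.DataFrame, period_bins: int,
                        corpus_end: int | None = None,
                        abandon_gap: int = SIX_MONTHS_BINS) -> pd.DataFrame:
    """Per-period four-way breakdown of active users.

    For each period (of ``period_bins`` bins) the active users split into:
    ``joined`` (first post this period, not abandoned the same period),
    ``joined_abandoned`` (first and last qualifying post this period),
    ``abandoned`` (last qualifying post this period, joined earlier), and
    ``other_active``. The four categories partition the users active in the
    period. Abandonment follows the six-month gap rule; a user's abandon
    period is the period of their last post.
    """
    if period_bins < 1:
        raise ValueError("period_bins must be positive")
    records = lifecycle_records(events, corpus_end=corpus_end, abandon_gap=abandon_gap)
    if corpus_end is None:
        corpus_end = int(events["bin"].max())
    n_periods = corpus_end // period_bins + 1
    rows = []
    for p in range(n_periods):
        lo, hi = p * period_bins, (p + 1) * period_bins
        joined = joined_abandoned = abandoned = other = 0
        for r in records:
            active = r.first_post < hi and (not r.abandoned or r.last_post >= lo)
            if not active:
                continue
            joins_now = lo <= r.first_post < hi
            abandons_now = r.abandoned and lo <= r.last_post < hi
            if joins_now and abandons_now:
                joined_abandoned += 1
            elif joins_now:
                joined += 1
            elif abandons_now:
                abandoned += 1
            else:
                other += 1
        rows.append(
            {
                "period": p,
                "joined": joined,
                "joined_abandoned": joined_abandoned,
                "abandoned": abandoned,
                "other_active": other,
                "total_active": joined + joined_abandoned + abandoned + other,
            }
        )
    return pd.DataFrame(rows)


def fit_exponential_growth(counts, t=None, exclude_last: int = 0) -> GrowthFit:
    """Least-squares fit of y = a * exp(b * (t - t0)) on log-transformed counts.

    Linear in t after the log transform; ``exclude_last`` drops trailing
    periods from the fit window (for series whose growth stalls near the end
    of observation). Counts must be strictly positive within the window.
    """
    y = np.asarray(counts, dtype=float)
    t = np.arange(y.size, dtype=float) if t is None else np.asarray(t, dtype=float)
    if exclude_last > 0:
        y, t = y[:-exclude_last], t[:-exclude_last]
    if y.size < 3:
        raise ValueError("need >= 3 points to fit exponential growth")
    if (y <= 0).any():
        raise ValueError("counts must be positive for the log transform")
    t0 = float(t[0])
    model = sm.OLS(np.log(y), sm.add_constant(t - t0)).fit()
    resid = model.resid
    return GrowthFit(
        a=float(np.exp(model.params[0])),
        b=float(model.params[1]),
        t0=t0,
        window=(float(t[0]), float(t[-1])),
        b_se=float(model.bse[1]),
        residual_std=float(resid.std(ddof=2)) if resid.size > 2 else 0.0,
    )
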