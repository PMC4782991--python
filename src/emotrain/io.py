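"""Event-stream readers/writers, cohort sampling, and run provenance.

The canonical on-disk format is JSON-lines with one event per line:
``{"user": ..., "bin": int, "state": -1|0|1|null, "n_posts": int}``; a TSV
with the same columns is accepted interchangeably. Timestamped inputs use
half-open day bins in UTC. Planted dyad patterns travel in a sidecar JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .series import EmotionSeries
from .entrainment import TEConfig

DAY = "day"
WEEK = "week"
_BIN_DAYS = {DAY: 1, WEEK: 7}


@dataclass
class RunConfig:
    """Pipeline-wide settings recorded into every output's provenance."""

    bin_width: str = DAY
    te: TEConfig = field(default_factory=TEConfig)
    sample_n_users: int = 20000
    min_tags: int = 3
    cohort_top_n: int = 10000
    seed: int = 0
    out_dir: str = "out"

    def __post_init__(self):
        if self.bin_width not in _BIN_DAYS:
            raise ValueError(f"bin_width must be one of {sorted(_BIN_DAYS)}")
        if self.min_tags < 1:
            raise ValueError("min_tags must be >= 1")


@dataclass
class EventStream:
    """Validated, binned events plus rejected-line diagnostics."""

    events: pd.DataFrame
    rejects: list = field(default_factory=list)

    def __len__(self):
        return len(self.events)


_COLUMNS = ("user", "bin", "state", "n_posts")


def _validate_row(rec, lineno):
    if "user" not in rec:
        return None, (lineno, "missing user")
    if "bin" in rec and rec["bin"] is not None:
        try:
            b = int(rec["bin"])
        except (TypeError, ValueError):
            return None, (lineno, f"bad bin {rec['bin']!r}")
        if b < 0:
            return None, (lineno, f"negative bin {b}")
    elif "timestamp" in rec:
        try:
            ts = pd.Timestamp(rec["timestamp"])
        except (TypeError, ValueError):
            return None, (lineno, f"bad timestamp {rec['timestamp']!r}")
        b = int((ts.tz_localize("UTC") if ts.tz is None else ts).value // 86_400_000_000_000)
    else:
        return None, (lineno, "missing bin/timestamp")
    state = rec.get("state")
    if state is not None and not (isinstance(state, float) and np.isnan(state)):
        try:
            state = int(state)
        except (TypeError, ValueError):
            return None, (lineno, f"bad state {state!r}")
        if state not in (-1, 0, 1):
            return None, (lineno, f"state {state} outside ternary alphabet")
    else:
        state = None
    n_posts = rec.get("n_posts", 1)
    try:
        n_posts = int(n_posts)
    except (TypeError, ValueError):
        return None, (lineno, f"bad n_posts {n_posts!r}")
    row = {"user": rec["user"], "bin": b, "state": state, "n_posts": n_posts,
           "label": rec.get("label")}
    return row, None


def read_events(path) -> EventStream:
    """Read a JSON-lines or TSV event stream, reporting malformed lines.

    The format is chosen by extension (``.tsv``/``.tab`` vs JSON-lines
    default). Malformed lines are collected as (line number, reason) pairs
    in ``rejects`` rather than aborting the read; an empty file yields an
    empty stream.
    """
    path = Path(path)
    rows, rejects = [], []
    if path.suffix in (".tsv", ".tab"):
        df = pd.read_csv(path, sep="\t")
        for k, rec in enumerate(df.to_dict("records")):
            row, err = _validate_row(rec, k + 2)  # header is line 1
            (rows.append(row) if err is None else rejects.append(err))
    else:
        with open(path) as fh:
            for k, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as e:
                    rejects.append((k, f"invalid JSON: {e.msg}"))
                    continue
                row, err = _validate_row(rec, k)
                (rows.append(row) if err is None else rejects.append(err))
    events = pd.DataFrame(rows, columns=list(_COLUMNS) + ["label"])
    return EventStream(events=events, rejects=rejects)


def write_events(events: pd.DataFrame, path) -> None:
    """Write events as JSON-lines (the format :func:`read_events` accepts)."""
    with open(path, "w") as fh:
        for rec in events.to_dict("records"):
            out = {
                "user": rec["user"],
                "bin": int(rec["bin"]),
                "state": None if rec.get("state") is None or
                (isinstance(rec.get("state"), float) and np.isnan(rec["state"]))
                else int(rec["state"]),
                "n_posts": int(rec.get("n_posts", 1)),
            }
            fh.write(json.dumps(out) + "\n")


def events_to_series(events: pd.DataFrame, n_bins: int | None = None) -> dict:
    """Pivot an event stream into per-user :class:`EmotionSeries`."""
    if n_bins is None:
        n_bins = int(events["bin"].max()) + 1
    out = {}
    for user, grp in events.groupby("user"):
        states = np.full(n_bins, np.nan)
        posts = np.zeros(n_bins, dtype=np.int64)
        for rec in grp.itertuples():
            if rec.state is not None and not (isinstance(rec.state, float) and np.isnan(rec.state)):
                states[rec.bin] = rec.state
            posts[rec.bin] += rec.n_posts
        out[user] = EmotionSeries(user, states, posts)
    return out


def sample_cohort(events: pd.DataFrame, rule: str, n: int, min_tags: int = 3,
                  seed: int = 0) -> list:
    """Deterministic user sampling with an eligibility filter.

    ``rule="random-with-min-tags"`` samples ``n`` users uniformly among those
    with at least ``min_tags`` emotion-tagged events; ``rule="top-by-tags"``
    takes the ``n`` users with the most tagged events. When fewer users are
    eligible than requested, all of them are returned (with a warning).
    """
    tagged = events[events["state"].notna()] if "state" in events else events
    counts = tagged.groupby("user").size().sort_index()
    if rule == "random-with-min-tags":
        eligible = counts[counts >= min_tags].index.to_numpy()
        if eligible.size <= n:
            if eligible.size < n:
                import warnings

                warnings.warn(f"only {eligible.size} eligible users for a request of {n}")
            return sorted(eligible.tolist())
        rng = np.random.default_rng(seed)
        return sorted(rng.choice(eligible, size=n, replace=False).tolist())
    if rule == "top-by-tags":
        ranked = counts.sort_values(ascending=False, kind="stable")
        return ranked.index[:n].tolist()
    raise ValueError(f"unknown sampling rule {rule!r}")


def provenance(config, seed: int) -> dict:
    """(config hash, seed, package version) stamped into pipeline artifacts."""
    from . import __version__

    if hasattr(config, "__dataclass_fields__"):
        payload = asdict(config)
    else:
        payload = dict(config)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {"config_hash": digest, "seed": int(seed), "version": __version__}
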