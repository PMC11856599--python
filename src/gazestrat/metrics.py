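"""Per-trial gaze features and per-item standardization.

Seven features summarise each participant x item trial of a matrix-reasoning
test recorded with an eye tracker:

- ``ra``  : response accuracy (0/1)
- ``rt``  : response time in seconds (total time on the item, ``T_item``)
- ``ptm`` : proportional time on matrix, ``T_matrix / T_item``
- ``lft`` : latency to first toggle — time until gaze first enters the
  response-options area (``rt`` if it never does)
- ``rlt`` : rate of latency to first toggle, ``lft / rt``
- ``not`` : number of toggles — gaze shifts between the matrix area and the
  options area, counted in both directions with off-AOI dwells skipped
- ``rot`` : rate of toggling, ``not / rt``

High PTM / RLT / LFT and few toggles are the signature of constructive
matching (mentally building the answer from the matrix); low values with many
toggles indicate response elimination (ruling out options by repeated
matrix-options comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AOI_MATRIX",
    "AOI_OPTIONS",
    "AOI_OTHER",
    "FEATURE_ORDER",
    "EYE_METRICS",
    "FixationEvent",
    "FeatureRow",
    "compute_trial_features",
    "compute_features_table",
    "standardize_per_item",
]

AOI_MATRIX = "matrix"
AOI_OPTIONS = "options"
AOI_OTHER = "other"
_VALID_AOIS = frozenset({AOI_MATRIX, AOI_OPTIONS, AOI_OTHER})

#: canonical feature order used throughout the pipeline
FEATURE_ORDER = ("ra", "rt", "ptm", "lft", "rlt", "not", "rot")
#: the five eye-tracking metrics (excludes the behavioural ra / rt)
EYE_METRICS = ("ptm", "lft", "rlt", "not", "rot")


@dataclass(frozen=True)
class FixationEvent:
    """One AOI dwell within a trial. Times are seconds, onset 0-based."""

    participant_id: str
    item_id: str
    aoi: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.aoi not in _VALID_AOIS:
            raise ValueError(f"unknown AOI label {self.aoi!r}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class FeatureRow:
    """The seven per-trial features; the currency of the whole analysis."""

    participant_id: str
    item_id: str
    ra: int
    rt: float
    ptm: float
    lft: float
    rlt: float
    not_: int
    rot: float

    def as_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "item_id": self.item_id,
            "ra": self.ra,
            "rt": self.rt,
            "ptm": self.ptm,
            "lft": self.lft,
            "rlt": self.rlt,
            "not": self.not_,
            "rot": self.rot,
        }
        return d


def compute_trial_features(
    events: Sequence[FixationEvent] | Iterable[FixationEvent],
    ra: int,
    rt: float,
) -> FeatureRow:
    """Compute the seven features for a single trial.

    Parameters
    ----------
    events
        AOI-tagged dwells of one participant on one item, ordered by onset.
    ra
        Response accuracy for the trial (0 or 1).
    rt
        Total response time in seconds (``T_item``), taken from the trial log;
        off-AOI and blink time therefore stays in the denominator. Fixations
        overrunning ``rt`` are truncated at ``rt`` with a warning.
    """
    events = list(events)
    if not events:
        raise ValueError("empty event list")
    if rt <= 0:
        raise ValueError("rt must be > 0")
    if ra not in (0, 1):
        raise ValueError("ra must be 0 or 1")
    onsets = [ev.onset for ev in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("events must be ordered by onset")

    t_matrix = 0.0
    lft = None
    toggle_seq = []  # AOI sequence restricted to {matrix, options}
    truncated = False
    for ev in events:
        end = ev.onset + ev.duration
        dur = ev.duration
        if end > rt + 1e-9:
            truncated = True
            dur = max(rt - ev.onset, 0.0)
        if dur <= 0:
            continue
        if ev.aoi == AOI_MATRIX:
            t_matrix += dur
            toggle_seq.append(AOI_MATRIX)
        elif ev.aoi == AOI_OPTIONS:
            if lft is None:
                lft = ev.onset
            toggle_seq.append(AOI_OPTIONS)
    if truncated:
        warnings.warn("fixation(s) overrunning rt truncated at rt", stacklevel=2)
    if lft is None:
        # participant never looked at the options: limiting constructive-
        # matching case -> LFT = RT, RLT = 1, NOT = 0
        lft = rt
    n_toggles = sum(1 for a, b in zip(toggle_seq, toggle_seq[1:]) if a != b)
    pid, iid = events[0].participant_id, events[0].item_id
    return FeatureRow(
        participant_id=pid,
        item_id=iid,
        ra=int(ra),
        rt=float(rt),
        ptm=t_matrix / rt,
        lft=float(lft),
        rlt=lft / rt,
        not_=int(n_toggles),
        rot=n_toggles / rt,
    )


def compute_features_table(
    fixations: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Compute the feature table from fixation and trial logs.

    ``fixations`` columns: participant_id, item_id, aoi, onset_s, duration_s.
    ``trials`` columns: participant_id, item_id, ra, rt_s.
    Returns one row per trial with the seven features.
    """
    required_f = {"participant_id", "item_id", "aoi", "onset_s", "duration_s"}
    required_t = {"participant_id", "item_id", "ra", "rt_s"}
    if not required_f.issubset(fixations.columns):
        raise ValueError(f"fixations table needs columns {sorted(required_f)}")
    if not required_t.issubset(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(required_t)}")

    grouped = fixations.groupby(["participant_id", "item_id"], sort=False)
    rows = []
    for trial in trials.itertuples(index=False):
        key = (trial.participant_id, trial.item_id)
        try:
            g = grouped.get_group(key)
        except KeyError:
            raise ValueError(f"no fixations for trial {key}") from None
        g = g.sort_values("onset_s", kind="mergesort")
        events = [
            FixationEvent(
                participant_id=str(trial.participant_id),
                item_id=str(trial.item_id),
                aoi=str(r.aoi),
                onset=float(r.onset_s),
                duration=float(r.duration_s),
            )
            for r in g.itertuples(index=False)
        ]
        row = compute_trial_features(events, int(trial.ra), float(trial.rt_s))
        rows.append(row.as_dict())
    return pd.DataFrame(rows)


def standardize_per_item(
    rows: pd.DataFrame, metrics: Sequence[str]
) -> pd.DataFrame:
    """Z-score the chosen metrics within each item (mean 0, sd 1, ddof=1).

    The mixture model weighs metrics on a common scale, so every metric is
    standardized across participants separately for each item. A zero-variance
    metric on an item yields all zeros with a warning; an item seen by fewer
    than two participants is an error.
    """
    missing = [m for m in metrics if m not in rows.columns]
    if missing:
        raise ValueError(f"metrics not in table: {missing}")
    out = rows.copy()
    for item, g in rows.groupby("item_id", sort=False):
        if len(g) < 2:
            raise ValueError(
                f"item {item!r} has fewer than 2 participants; cannot standardize"
            )
        for m in metrics:
            vals = g[m].to_numpy(dtype=float)
            sd = vals.std(ddof=1)
            if sd == 0:
                warnings.warn(
                    f"metric {m!r} has zero variance on item {item!r}; "
                    "standardized values set to 0",
                    stacklevel=2,
                )
                out.loc[g.index, m] = 0.0
            else:
                out.loc[g.index, m] = (vals - vals.mean()) / sd
    return out
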