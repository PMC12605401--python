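"""Interaction times and recognition-memory indices.

Implements the discrimination index DI = (novel - familiar) / total with
an exploration-only denominator (total = novel + familiar), the
cumulative DI (running mean of per-trial DIs), the per-minute running DI
over cumulative exploration, early/late trial-block averages, and the
early-window (minutes 1-2) DI with the saturation (+1 / -1) exclusion
rule.

Minute bins are half-open [60*(m-1), 60*m) in retained-frame time: the
i-th retained frame of a session sits at time i/fps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior_classifier import Bout

__all__ = [
    "InteractionSummary",
    "DIRecord",
    "interaction_times",
    "discrimination_index",
    "di_record",
    "cumulative_di",
    "running_di_per_minute",
    "block_average_di",
    "early_window_di",
    "score_exploration_table",
]

_CLASSES = ("sniff", "rear", "other")


@dataclass
class InteractionSummary:
    """Seconds of sniff / rear / other / total per cage, with per-minute
    and cumulative per-minute variants (minutes 1-based)."""

    totals: pd.DataFrame            # index cage, columns sniff/rear/other/total
    per_minute: pd.DataFrame        # index (minute, cage), same columns
    cumulative: pd.DataFrame        # index (minute, cage), same columns
    fps: float
    n_minutes: int

    def seconds(self, cage: str, measure: str = "total") -> float:
        if cage in self.totals.index:
            return float(self.totals.loc[cage, measure])
        return 0.0

    def cumulative_seconds(self, cage: str, minute: int,
                           measure: str = "total") -> float:
        try:
            return float(self.cumulative.loc[(minute, cage), measure])
        except KeyError:
            return 0.0


@dataclass(frozen=True)
class DIRecord:
    subject_id: str
    trial_or_phase: str
    measure: str
    di: float  # NaN when undefined (zero_total)
    excluded: bool
    exclusion_reason: str  # none | saturated_plus1 | saturated_minus1 | zero_total


def interaction_times(series: pd.DataFrame, fps: float,
                      bouts: Sequence[Bout] | None = None) -> InteractionSummary:
    """Per-cage, per-class interaction seconds plus per-minute bins.

    ``series`` is the (smoothed) per-frame label table; minute binning
    needs frame resolution, so the label series rather than the bout
    table is the primary input (``bouts`` is accepted for API symmetry
    and cross-checked when given).
    """
    cages = ["A", "B"]
    cols = list(_CLASSES) + ["total"]
    n = len(series)
    n_minutes = max(1, int(np.ceil(n / (60.0 * fps)))) if n else 1

    minutes = np.arange(n) // int(round(60 * fps)) + 1 if n else np.array([], dtype=int)
    idx = pd.MultiIndex.from_product([range(1, n_minutes + 1), cages],
                                     names=["minute", "cage"])
    per_minute = pd.DataFrame(0.0, index=idx, columns=cols)

    if n:
        df = pd.DataFrame({
            "minute": minutes,
            "cage": series["cage_context"].to_numpy(),
            "label": series["label"].to_numpy(),
        })
        counts = (df[df["cage"] != "none"]
                  .groupby(["minute", "cage", "label"]).size())
        for (minute, cage, label), cnt in counts.items():
            if label in _CLASSES:
                per_minute.loc[(minute, cage), label] = cnt / fps
    per_minute["total"] = per_minute[list(_CLASSES)].sum(axis=1)

    cumulative = per_minute.groupby(level="cage", sort=False).cumsum()
    totals = per_minute.groupby(level="cage", sort=False).sum().reindex(cages).fillna(0.0)

    if bouts is not None:
        check = {(c, k): 0.0 for c in cages for k in _CLASSES}
        for b in bouts:
            check[(b.cage_context, b.label)] += b.duration_s
        for (c, k), v in check.items():
            if abs(v - totals.loc[c, k]) > 1.5 / fps:
                raise ValueError("bout table inconsistent with label series")

    return InteractionSummary(totals=totals, per_minute=per_minute,
                              cumulative=cumulative, fps=fps, n_minutes=n_minutes)


def discrimination_index(time_novel: float, time_familiar: float) -> float:
    """(novel - familiar) / (novel + familiar); NaN when both are zero."""
    if time_novel < 0 or time_familiar < 0:
        raise ValueError("exploration times must be non-negative")
    total = time_novel + time_familiar
    if total == 0:
        return float("nan")
    return (time_novel - time_familiar) / total


def di_record(subject_id: str, trial_or_phase: str, measure: str,
              time_novel: float, time_familiar: float) -> DIRecord:
    """DI with the saturation exclusion flags: a DI of exactly +1 or -1
    (only one side explored) is excluded; zero exploration is flagged
    undefined rather than imputed."""
    di = discrimination_index(time_novel, time_familiar)
    if np.isnan(di):
        return DIRecord(subject_id, trial_or_phase, measure, di, True, "zero_total")
    if di == 1.0:
        return DIRecord(subject_id, trial_or_phase, measure, di, True, "saturated_plus1")
    if di == -1.0:
        return DIRecord(subject_id, trial_or_phase, measure, di, True, "saturated_minus1")
    return DIRecord(subject_id, trial_or_phase, measure, di, False, "none")


def cumulative_di(dis: Sequence[float]) -> np.ndarray:
    """cDI_k = mean(DI_1..DI_k)."""
    arr = np.asarray(dis, dtype=float)
    if arr.size == 0:
        raise ValueError("cumulative DI of an empty sequence")
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("DI values must lie in [-1, 1]")
    return np.cumsum(arr) / np.arange(1, arr.size + 1)


def running_di_per_minute(summary: InteractionSummary, measure: str = "total",
                          novel_cage: str = "A",
                          familiar_cage: str = "B") -> pd.DataFrame:
    """Running DI per minute from cumulative exploration of each cage
    through that minute; minutes with zero cumulative total are NaN and
    flagged."""
    rows = []
    for m in range(1, summary.n_minutes + 1):
        nov = summary.cumulative_seconds(novel_cage, m, measure)
        fam = summary.cumulative_seconds(familiar_cage, m, measure)
        di = discrimination_index(nov, fam)
        rows.append({"minute": m, "di": di, "undefined": bool(np.isnan(di))})
    return pd.DataFrame(rows)


def block_average_di(dis: Mapping[int, float] | Sequence[float],
                     early: tuple[int, int] = (1, 4),
                     late: tuple[int, int] = (8, 11)) -> tuple[float, float]:
    """Arithmetic mean DI over the early and late trial blocks
    (1-based, inclusive).  Requires every trial of both blocks."""
    if isinstance(dis, Mapping):
        series = pd.Series(dict(dis), dtype=float)
    else:
        series = pd.Series(np.asarray(dis, dtype=float),
                           index=range(1, len(dis) + 1))
    needed = max(early[1], late[1])
    if len(series) == 0 or int(series.index.max()) < needed:
        raise ValueError(f"need at least {needed} trials, got {len(series)}")

    def block_mean(lo: int, hi: int) -> float:
        trials = range(lo, hi + 1)
        vals = series.reindex(trials)
        if vals.isna().any():
            missing = [t for t in trials if pd.isna(series.get(t))]
            raise ValueError(f"missing trial(s) {missing} in block {lo}-{hi}")
        return float(vals.mean())

    return block_mean(*early), block_mean(*late)


def early_window_di(summary: InteractionSummary, measure: str = "total",
                    novel_cage: str = "A", familiar_cage: str = "B",
                    window_minutes: int = 2,
                    subject_id: str = "") -> DIRecord:
    """DI over cumulative exploration in the first ``window_minutes``
    minutes, with saturation exclusion."""
    if summary.n_minutes < window_minutes:
        raise ValueError(
            f"need >= {window_minutes} minutes of data, have {summary.n_minutes}")
    nov = summary.cumulative_seconds(novel_cage, window_minutes, measure)
    fam = summary.cumulative_seconds(familiar_cage, window_minutes, measure)
    return di_record(subject_id, f"minutes_1-{window_minutes}", measure, nov, fam)


def score_exploration_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a trial-exploration table (columns subject_id, group, trial,
    time_novel_s, time_familiar_s) into per-trial DI and cDI records."""
    out = []
    for (subject, group), sub in table.groupby(["subject_id", "group"], sort=False):
        sub = sub.sort_values("trial")
        recs = [
            di_record(str(subject), f"trial_{int(r.trial)}", "total",
                      float(r.time_novel_s), float(r.time_familiar_s))
            for r in sub.itertuples()
        ]
        dis = np.array([r.di for r in recs], dtype=float)
        with np.errstate(invalid="ignore"):
            cdis = (np.nancumsum(dis) /
                    np.cumsum(~np.isnan(dis))) if len(dis) else np.array([])
        for rec, trial, cdi in zip(recs, sub["trial"], cdis):
            out.append({
                "subject_id": rec.subject_id,
                "group": group,
                "trial": int(trial),
                "measure": rec.measure,
                "di": rec.di,
                "cdi": float(cdi),
                "excluded": rec.excluded,
                "reason": rec.exclusion_reason,
            })
    return pd.DataFrame(out)
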