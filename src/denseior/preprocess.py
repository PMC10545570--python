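"""From trial-level RTs to normalized condition time courses.

Pipeline order: screen participants on catch-trial false alarms, filter
trials, z-scale RTs within participant (over all retained trials,
regardless of CTOA and validity), compute cell means per participant x
CTOA x validity, then the grand-average time courses and the
invalid-minus-valid difference course that the model fits and spectral
tests consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterRules",
    "ParticipantSummary",
    "TimeCourse",
    "DifferenceTimeCourse",
    "CellMeans",
    "screen_participants",
    "apply_screening",
    "filter_trials",
    "zscore_rts",
    "cell_means",
    "condition_timecourses",
    "difference_course",
    "preprocess",
]

FA_THRESHOLD = 0.20  # exclude if false-alarm rate strictly exceeds this


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    n_catch: int
    n_false_alarms: int
    false_alarm_rate: float  # NaN when no catch trials
    excluded: bool
    reason: str = ""


@dataclass(frozen=True)
class FilterRules:
    """Trial-retention rules. Defaults: completed non-catch trials with
    RT in [0.15 s, deadline]; the anticipation cutoff is a package default,
    configurable because exclusion conventions vary between labs."""
    drop_catch: bool = True
    drop_misses: bool = True
    min_rt: float = 0.15  # seconds; None disables
    max_rt: float = 2.0   # seconds; None disables


@dataclass
class TimeCourse:
    """Grand-average normalized RT per CTOA for one validity condition."""
    ctoa: np.ndarray          # seconds, length 25
    mean_z_rt: np.ndarray     # z-units
    within_subject_se: np.ndarray  # Cousineau-Morey corrected, z-units
    condition: str
    n_participants: int


@dataclass
class DifferenceTimeCourse:
    """Invalid - valid normalized RT difference per CTOA."""
    ctoa: np.ndarray               # seconds
    diff: np.ndarray               # grand average, z-units
    se: np.ndarray                 # between-participant SE of the difference
    per_participant_diff: np.ndarray  # participants x CTOAs
    participants: list


@dataclass
class CellMeans:
    """Per-participant mean z-RT in every CTOA x validity cell."""
    ctoa: np.ndarray      # seconds, length C
    participants: list    # length P
    valid: np.ndarray     # P x C
    invalid: np.ndarray   # P x C


def screen_participants(trials: pd.DataFrame,
                        threshold: float = FA_THRESHOLD) -> list[ParticipantSummary]:
    """Flag participants whose catch-trial false-alarm rate exceeds the
    threshold (strictly greater; a rate of exactly 20% is retained)."""
    if not trials["responded"].isin([True, False]).all():
        raise ValueError("responded must be boolean")
    out = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        catch = grp[grp["is_catch"]]
        n_catch = len(catch)
        n_fa = int(catch["responded"].sum())
        if n_catch == 0:
            out.append(ParticipantSummary(pid, 0, 0, float("nan"), True,
                                          "no catch trials: rate undefined"))
            continue
        rate = n_fa / n_catch
        excluded = rate > threshold
        reason = (f"false-alarm rate {rate:.3f} > {threshold}" if excluded
                  else "")
        out.append(ParticipantSummary(pid, n_catch, n_fa, rate, excluded,
                                      reason))
    return out


def apply_screening(trials: pd.DataFrame,
                    summaries: list[ParticipantSummary]) -> pd.DataFrame:
    keep = {s.participant_id for s in summaries if not s.excluded}
    return trials[trials["participant_id"].isin(keep)].reset_index(drop=True)


def filter_trials(trials: pd.DataFrame,
                  rules: FilterRules = FilterRules()) -> tuple[pd.DataFrame, dict]:
    """Apply retention rules; returns (retained trials, counts per rule)."""
    df = trials
    log: dict[str, int] = {"input": len(df)}
    if rules.drop_catch:
        n = int(df["is_catch"].sum())
        df = df[~df["is_catch"]]
        log["dropped_catch"] = n
    if rules.drop_misses:
        n = int((~df["responded"]).sum())
        df = df[df["responded"]]
        log["dropped_misses"] = n
    if rules.min_rt is not None:
        mask = df["rt"].notna() & (df["rt"] < rules.min_rt)
        log["dropped_below_min_rt"] = int(mask.sum())
        df = df[~mask]
    if rules.max_rt is not None:
        mask = df["rt"].notna() & (df["rt"] > rules.max_rt)
        log["dropped_above_max_rt"] = int(mask.sum())
        df = df[~mask]
    log["retained"] = len(df)
    return df.reset_index(drop=True), log


def zscore_rts(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ``z_rt``: per participant, (rt - mean) / sample SD over all
    retained trials, pooling CTOAs and validity conditions."""
    out = trials.reset_index(drop=True).copy()
    grouped = out.groupby("participant_id")["rt"]
    for pid, rt in grouped:
        if rt.count() < 2:
            raise ValueError(f"participant {pid}: fewer than 2 retained "
                             f"trials; cannot z-scale")
        if rt.std(ddof=1) == 0:
            raise ValueError(f"participant {pid}: zero RT variance; "
                             f"cannot z-scale")
    out["z_rt"] = (out["rt"] - grouped.transform("mean")) \
        / grouped.transform(lambda x: x.std(ddof=1))
    return out


def cell_means(trials: pd.DataFrame, value: str = "z_rt") -> CellMeans:
    """Mean of ``value`` per participant x CTOA x validity.

    Aborts if any cell is empty: the downstream analyses assume a complete
    participants x CTOAs x 2 grid.
    """
    ctoas_ms = np.sort(trials["ctoa_ms"].dropna().unique().astype(int))
    participants = sorted(trials["participant_id"].unique())
    table = trials.pivot_table(index="participant_id",
                               columns=["validity", "ctoa_ms"],
                               values=value, aggfunc="mean", observed=True)
    mats = {}
    for cond in ("valid", "invalid"):
        cols = [(cond, ms) for ms in ctoas_ms]
        missing = [c for c in cols if c not in table.columns]
        if missing or table.loc[participants, cols].isna().any().any():
            empty = missing + [
                (c[0], c[1]) for c in cols if c in table.columns
                and table.loc[participants, c].isna().any()]
            raise ValueError(
                f"empty design cells (validity, ctoa_ms): {empty[:5]}"
                f"{'...' if len(empty) > 5 else ''}; the analyses require a "
                f"complete grid")
        mats[cond] = table.loc[participants, cols].to_numpy(dtype=float)
    return CellMeans(ctoa=ctoas_ms / 1000.0, participants=list(participants),
                     valid=mats["valid"], invalid=mats["invalid"])


def _morey_se(cells: np.ndarray) -> np.ndarray:
    """Cousineau-Morey within-subject SE per cell.

    ``cells`` is participants x M (here M = 2 conditions x C CTOAs):
    subtract each participant's mean over all M cells, add back the grand
    mean, take SD/sqrt(n) per cell and inflate by sqrt(M/(M-1)).
    """
    n, m = cells.shape
    if n < 2:
        return np.zeros(m)
    adj = cells - cells.mean(axis=1, keepdims=True) + cells.mean()
    se = adj.std(axis=0, ddof=1) / math.sqrt(n)
    return se * math.sqrt(m / (m - 1))


def condition_timecourses(cm: CellMeans) -> dict[str, TimeCourse]:
    """Grand-average time courses with Morey-corrected within-subject SEs
    (normalization spans all 2 x C cells jointly)."""
    c = len(cm.ctoa)
    stacked = np.hstack([cm.valid, cm.invalid])  # P x 2C
    se = _morey_se(stacked)
    out = {}
    for i, cond in enumerate(("valid", "invalid")):
        cells = stacked[:, i * c:(i + 1) * c]
        out[cond] = TimeCourse(ctoa=cm.ctoa, mean_z_rt=cells.mean(axis=0),
                               within_subject_se=se[i * c:(i + 1) * c],
                               condition=cond,
                               n_participants=len(cm.participants))
    return out


def difference_course(cm: CellMeans) -> DifferenceTimeCourse:
    """Invalid - valid per participant and grand average.  Positive values
    at short CTOAs reflect facilitation of the cued location; negative
    values at long CTOAs reflect inhibition of return."""
    per = cm.invalid - cm.valid
    n = per.shape[0]
    se = per.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(per.shape[1])
    return DifferenceTimeCourse(ctoa=cm.ctoa, diff=per.mean(axis=0), se=se,
                                per_participant_diff=per,
                                participants=list(cm.participants))


def preprocess(trials: pd.DataFrame, rules: FilterRules = FilterRules(),
               fa_threshold: float = FA_THRESHOLD):
    """Full pipeline: screen -> filter -> z-scale -> cell means -> courses.

    Returns (summaries, filter_log, cell_means, timecourses, diff_course).
    """
    summaries = screen_participants(trials, threshold=fa_threshold)
    retained = apply_screening(trials, summaries)
    if retained.empty:
        raise ValueError("all participants excluded during screening")
    filtered, log = filter_trials(retained, rules)
    z = zscore_rts(filtered)
    cm = cell_means(z)
    tcs = condition_timecourses(cm)
    diff = difference_course(cm)
    return summaries, log, cm, tcs, diff
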