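"""Classic inhibition-of-return replication check.

A 2 (validity) x 5 (CTOA) repeated-measures ANOVA on normalized cell-mean
RTs over the five grid CTOAs closest to the classic 50/100/200/300/500 ms
probes, with Greenhouse-Geisser sphericity correction and generalized
eta squared, followed by Bonferroni-corrected paired t tests per CTOA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .preprocess import CellMeans

__all__ = [
    "REPLICATION_TARGETS_MS",
    "AnovaResult",
    "PosthocResult",
    "select_replication_ctoas",
    "subset_cell_means",
    "rm_anova_validity_by_ctoa",
    "posthoc_bonferroni",
]

REPLICATION_TARGETS_MS = (50, 100, 200, 300, 500)


@dataclass(frozen=True)
class AnovaResult:
    effect: str          # validity, ctoa, validity*ctoa
    F: float
    df1: float
    df2: float
    eps: float           # Greenhouse-Geisser epsilon (1 for 1-df effects)
    df1_gg: float
    df2_gg: float
    p_gg: float
    eta_g_squared: float


@dataclass(frozen=True)
class PosthocResult:
    ctoa: float          # seconds
    t: float             # paired t on invalid - valid
    df: int
    p_raw: float
    p_bonferroni: float
    significant: bool


def select_replication_ctoas(grid, targets_ms=REPLICATION_TARGETS_MS) -> np.ndarray:
    """Grid CTOAs (seconds) nearest to the classic probe delays.

    Ties are broken toward the shorter CTOA.  Targets outside the grid's
    range are rejected.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    out = []
    for ms in targets_ms:
        target = ms / 1000.0
        if target < grid[0] - 1e-12 or target > grid[-1] + 1e-12:
            raise ValueError(f"target CTOA {ms} ms lies outside the grid "
                             f"[{grid[0] * 1000:.0f}, {grid[-1] * 1000:.0f}] ms")
        d = np.abs(grid - target)
        # pick the first (shorter) CTOA among near-ties; the 1 ns slack
        # absorbs float representation error in the grid arithmetic
        out.append(grid[int(np.flatnonzero(d <= d.min() + 1e-9)[0])])
    return np.array(out)


def subset_cell_means(cm: CellMeans, ctoas) -> CellMeans:
    """Restrict a cell-mean grid to the given CTOAs (seconds)."""
    idx = []
    for c in np.asarray(ctoas, dtype=float):
        j = np.flatnonzero(np.isclose(cm.ctoa, c))
        if len(j) != 1:
            raise ValueError(f"CTOA {c} s not on the cell-mean grid")
        idx.append(int(j[0]))
    return CellMeans(ctoa=cm.ctoa[idx], participants=list(cm.participants),
                     valid=cm.valid[:, idx], invalid=cm.invalid[:, idx])


def _long_frame(cm: CellMeans) -> pd.DataFrame:
    P, C = cm.valid.shape
    rows = []
    for s, pid in enumerate(cm.participants):
        for cond, mat in (("valid", cm.valid), ("invalid", cm.invalid)):
            for j in range(C):
                rows.append({"participant": pid, "validity": cond,
                             "ctoa": round(cm.ctoa[j] * 1000),
                             "z_rt": mat[s, j]})
    return pd.DataFrame(rows)


def rm_anova_validity_by_ctoa(cm: CellMeans) -> list[AnovaResult]:
    """Two-way fully within-subject ANOVA (validity x CTOA).

    Greenhouse-Geisser correction is applied to every effect with more
    than one numerator df; effect sizes are generalized eta squared.
    Requires a complete participants x 2 x C grid.
    """
    if np.isnan(cm.valid).any() or np.isnan(cm.invalid).any():
        raise ValueError("cell-mean grid contains missing cells")
    if len(cm.participants) < 2:
        raise ValueError("need at least 2 participants")
    df = _long_frame(cm)
    table = pg.rm_anova(data=df, dv="z_rt", within=["validity", "ctoa"],
                        subject="participant", correction=True,
                        effsize="ng2")
    name_map = {"validity": "validity", "ctoa": "ctoa",
                "validity * ctoa": "validity*ctoa"}
    out = []
    for _, row in table.iterrows():
        effect = name_map[row["Source"]]
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        eps = float(row["eps"]) if df1 > 1 else 1.0
        p_gg = float(row["p_GG_corr"]) if df1 > 1 else float(row["p_unc"])
        out.append(AnovaResult(
            effect=effect, F=float(row["F"]), df1=df1, df2=df2, eps=eps,
            df1_gg=df1 * eps, df2_gg=df2 * eps, p_gg=p_gg,
            eta_g_squared=float(row["ng2"])))
    return out


def posthoc_bonferroni(cm: CellMeans) -> list[PosthocResult]:
    """Two-sided paired t test (invalid - valid) at each CTOA, Bonferroni
    corrected by the number of CTOAs tested.

    Positive t means slower invalid responses (facilitation of the cued
    location); negative t means inhibition of return.
    """
    n_tests = len(cm.ctoa)
    n = len(cm.participants)
    out = []
    for j, c in enumerate(cm.ctoa):
        d = cm.invalid[:, j] - cm.valid[:, j]
        if np.allclose(d, 0):
            tval, p_raw = 0.0, 1.0  # no difference anywhere: t degenerates
        else:
            res = stats.ttest_rel(cm.invalid[:, j], cm.valid[:, j])
            tval, p_raw = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, p_raw * n_tests)
        out.append(PosthocResult(ctoa=float(c), t=tval,
                                 df=n - 1, p_raw=p_raw,
                                 p_bonferroni=p_adj,
                                 significant=p_adj < 0.05))
    return out
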