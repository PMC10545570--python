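"""Information-criterion model comparison.

Criteria use the Gaussian maximum-likelihood form based on the residual
sum of squares, with the additive constant n*ln(2*pi) + n omitted from
AICc and BIC alike: differences, Akaike weights and Bayes factors are
unaffected.  The effective parameter count k includes the residual
variance (k = free model parameters + 1).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FitResult

__all__ = [
    "aicc",
    "bic",
    "akaike_weights",
    "bic_bayes_factor",
    "compare",
    "per_participant_winners",
    "MODEL_CLASS",
]

# model classes used for participant-level winner tallies: the linear and
# exponential forms are both expressions of non-rhythmic inhibitory tagging
MODEL_CLASS = {
    "intercept": "intercept",
    "linear": "ior",
    "exponential": "ior",
    "rhythmic": "rhythmic",
    "hybrid": "hybrid",
}

TIE_TOL = 1e-9


def _check(rss: float, n: int, k: int) -> None:
    if rss <= 0:
        raise ValueError("rss must be > 0 (a perfect fit has no defined "
                         "Gaussian criterion)")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC: n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1)."""
    _check(rss, n, k)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def bic(rss: float, n: int, k: int) -> float:
    """Bayesian information criterion: n*ln(rss/n) + k*ln(n)."""
    _check(rss, n, k)
    return n * math.log(rss / n) + k * math.log(n)


def akaike_weights(values) -> np.ndarray:
    """Akaike weights over a model set: w_i = exp(-d_i/2)/sum_j exp(-d_j/2)
    with d_i the criterion difference to the set's minimum."""
    v = np.asarray(values, dtype=float)
    d = v - v.min()
    w = np.exp(-d / 2)
    return w / w.sum()


def bic_bayes_factor(bic_a: float, bic_b: float) -> float:
    """BIC-approximate Bayes factor in favor of model a: exp((bic_b-bic_a)/2)."""
    return math.exp((bic_b - bic_a) / 2)


@dataclass
class ComparisonRow:
    model: str
    k: int
    rss: float
    aicc: float
    bic: float
    delta_aicc: float
    akaike_weight: float
    bf_best_vs_model: float  # BIC-approximate evidence of the best model over this one


def compare(fits) -> pd.DataFrame:
    """Rank a set of fitted models.

    Accepts a mapping or sequence of :class:`FitResult`; returns a frame
    with AICc, BIC, delta-AICc versus the best model, Akaike weights, and
    the BIC-approximate Bayes factor of the best model over each model.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    rows = []
    for fr in fits:
        rows.append({"model": fr.model, "k": fr.k, "rss": fr.rss,
                     "n": fr.n, "aicc": aicc(fr.rss, fr.n, fr.k),
                     "bic": bic(fr.rss, fr.n, fr.k),
                     **{p: fr.params.get(p, np.nan)
                        for p in ("b0", "b1", "N0", "tau", "a", "f", "phi")}})
    df = pd.DataFrame(rows)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    df["akaike_weight"] = akaike_weights(df["aicc"].to_numpy())
    best_bic = df["bic"].min()
    df["bf_best_vs_model"] = [bic_bayes_factor(best_bic, b)
                              for b in df["bic"]]
    return df.sort_values("aicc").reset_index(drop=True)


def _winners(values: dict[str, float], tol: float = TIE_TOL) -> list[str]:
    best = min(values.values())
    return [m for m, v in values.items() if v - best < tol]


def per_participant_winners(fits_by_participant, criteria=("aicc", "bic"),
                            tol: float = TIE_TOL) -> dict:
    """Tally, per criterion, how many participants each model class wins.

    ``fits_by_participant`` maps participant id to a dict/sequence of
    :class:`FitResult`.  Ties within ``tol`` are credited to every tied
    model's class, so with cross-class ties a participant can appear in
    more than one class.
    """
    fns = {"aicc": aicc, "bic": bic}
    tallies = {c: Counter({cls: 0 for cls in set(MODEL_CLASS.values())})
               for c in criteria}
    for pid, fits in fits_by_participant.items():
        if isinstance(fits, dict):
            fits = list(fits.values())
        for c in criteria:
            vals = {fr.model: fns[c](fr.rss, fr.n, fr.k) for fr in fits}
            classes = {MODEL_CLASS[m] for m in _winners(vals, tol)}
            for cls in classes:
                tallies[c][cls] += 1
    return {c: dict(t) for c, t in tallies.items()}
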