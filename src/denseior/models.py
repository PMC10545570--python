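"""Candidate models of the invalid-valid RT difference time course.

Five nested models are fitted to the 25-point difference course by
ordinary least squares:

    intercept    rt(t) = b0
    linear       rt(t) = b0 + b1*t
    exponential  rt(t) = b0 + N0*exp(-t/tau)
    rhythmic     rt(t) = b0 + a*sin(2*pi*f*t + phi)
    hybrid       rt(t) = b0 + N0*exp(-t/tau) + a*sin(2*pi*f*t + phi)

The linear and exponential forms express inhibitory tagging (a transient
facilitation decaying into sustained inhibition); the rhythmic form a
periodically reorienting attentional spotlight; the hybrid their sum.

Fitting uses variable projection: conditional on the nonlinear parameters
(tau and/or f) the remaining parameters enter linearly, so a deterministic
grid over (f, tau) with an exact linear solve at each node locates the
basin, and bounded Levenberg/TRF polish from the best nodes refines it.
Amplitude is constrained a >= 0 with phase reported in [0, 2*pi) to remove
the sign/phase aliasing degeneracy.  t is in seconds, f in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MODEL_NAMES",
    "MODEL_PARAMS",
    "FrequencyBounds",
    "FitResult",
    "predict",
    "fit",
    "fit_all",
]

MODEL_NAMES = ("intercept", "linear", "exponential", "rhythmic", "hybrid")

MODEL_PARAMS = {
    "intercept": ("b0",),
    "linear": ("b0", "b1"),
    "exponential": ("b0", "N0", "tau"),
    "rhythmic": ("b0", "a", "f", "phi"),
    "hybrid": ("b0", "N0", "tau", "a", "f", "phi"),
}

# effective parameter count for information criteria: free model
# parameters + 1 for the residual variance of the Gaussian likelihood
MODEL_K = {name: len(p) + 1 for name, p in MODEL_PARAMS.items()}

_LIN_BOUND = 10.0   # |b0|, |b1|, |N0| upper bound (z-units; data are O(1))
_TAU_BOUNDS = (1e-3, 10.0)  # seconds
_A_MAX = 10.0


@dataclass(frozen=True)
class FrequencyBounds:
    """Allowed sinusoid frequency range in Hz."""
    f_min: float = 1.0
    f_max: float = 11.0

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")

    @classmethod
    def full(cls) -> "FrequencyBounds":
        """Technically plausible range on the default grid, 1-11 Hz
        (excludes the 11.9 Hz Nyquist limit of the 42 ms spacing)."""
        return cls(1.0, 11.0)

    @classmethod
    def theta(cls) -> "FrequencyBounds":
        """Theta band, 3-8 Hz: the range the rhythmic-sampling account
        specifically predicts."""
        return cls(3.0, 8.0)

    def validate_against_grid(self, t: np.ndarray) -> None:
        dt = np.diff(np.sort(t))
        nyquist = 1.0 / (2.0 * dt.min())
        if self.f_max >= nyquist:
            raise ValueError(f"f_max={self.f_max} is not below the Nyquist "
                             f"frequency {nyquist:.3f} Hz of the grid")


@dataclass
class FitResult:
    model: str
    params: dict
    rss: float
    n: int
    k: int
    converged: bool
    n_starts: int
    f_at_lower_bound: bool = False

    @property
    def param_vector(self) -> np.ndarray:
        return np.array([self.params[p] for p in MODEL_PARAMS[self.model]])


def predict(model: str, params, t) -> np.ndarray:
    """Evaluate a model at times ``t`` (seconds).

    ``params`` maps parameter names to values (extraneous keys ignored).
    """
    t = np.asarray(t, dtype=float)
    if model not in MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    p = {k: float(params[k]) for k in MODEL_PARAMS[model]}
    out = np.full_like(t, p["b0"])
    if model == "linear":
        out = out + p["b1"] * t
    if model in ("exponential", "hybrid"):
        if p["tau"] <= 0:
            raise ValueError("tau must be > 0")
        out = out + p["N0"] * np.exp(-t / p["tau"])
    if model in ("rhythmic", "hybrid"):
        if p["f"] < 0:
            raise ValueError("f must be >= 0")
        out = out + p["a"] * np.sin(2 * np.pi * p["f"] * t + p["phi"])
    return out


def _lstsq_rss(X: np.ndarray, y: np.ndarray):
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _wrap_phase(phi: float) -> float:
    phi = float(phi) % (2 * math.pi)
    return 0.0 if phi >= 2 * math.pi else phi


def _sincos_to_amp_phase(A: float, B: float):
    """a*sin(x+phi) = A*sin(x) + B*cos(x) -> (a, phi) with a >= 0."""
    a = math.hypot(A, B)
    phi = _wrap_phase(math.atan2(B, A))
    return a, phi


def _polish(model: str, t, y, x0, lower, upper):
    def resid(x):
        p = dict(zip(MODEL_PARAMS[model], x))
        return predict(model, p, t) - y

    x0 = np.clip(x0, lower, upper)
    try:
        sol = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        return sol.x, float(sol.fun @ sol.fun), bool(sol.success)
    except Exception:
        r = resid(x0)
        return x0, float(r @ r), False


def _tau_grid(extra: float | None = None) -> np.ndarray:
    grid = np.geomspace(0.02, 2.0, 25)
    if extra is not None:
        grid = np.append(grid, extra)
    return grid


def _f_grid(fb: FrequencyBounds, step: float, extra: float | None = None):
    n = max(2, int(round((fb.f_max - fb.f_min) / step)) + 1)
    grid = np.linspace(fb.f_min, fb.f_max, n)
    if extra is not None and fb.f_min <= extra <= fb.f_max:
        grid = np.append(grid, extra)
    return grid


def _hybrid_grid_candidates(t, y, taus, fs):
    """Exact linear solve of (b0, N0, a*cos, a*sin) at every (tau, f) node
    via batched normal equations; returns candidate parameter vectors
    sorted by grid RSS."""
    ones = np.ones_like(t)
    E = np.exp(-t[None, :] / taus[:, None])            # T x n
    W = 2 * np.pi * fs[:, None] * t[None, :]
    S, C = np.sin(W), np.cos(W)                        # F x n
    T, F, n = len(taus), len(fs), len(t)
    # design column stack per node: [1, e, s, c]
    cols = np.empty((T, F, 4, n))
    cols[:, :, 0] = ones
    cols[:, :, 1] = E[:, None, :]
    cols[:, :, 2] = S[None, :, :]
    cols[:, :, 3] = C[None, :, :]
    G = np.einsum("tfin,tfjn->tfij", cols, cols)
    b = np.einsum("tfin,n->tfi", cols, y)
    coef = np.einsum("tfij,tfj->tfi", np.linalg.pinv(G), b)
    pred = np.einsum("tfi,tfin->tfn", coef, cols)
    rss = ((y[None, None, :] - pred) ** 2).sum(axis=-1)
    out = []
    for ti, fi in zip(*np.unravel_index(np.argsort(rss, axis=None), rss.shape)):
        c = coef[ti, fi]
        a, phi = _sincos_to_amp_phase(c[2], c[3])
        out.append((float(rss[ti, fi]),
                    np.array([c[0], c[1], taus[ti], a, fs[fi], phi])))
    return out


def fit(model: str, t, y, fbounds: FrequencyBounds | None = None,
        f_grid_step: float = 0.25, n_polish: int = 3,
        hints: dict | None = None) -> FitResult:
    """Fit one model to a series by bounded least squares.

    ``t`` in seconds, ``y`` in z-units.  Sinusoid-bearing models require
    ``fbounds``; the frequency estimate is flagged when it sits on the
    lower bound (within 1e-6 Hz), the signature of a sinusoid absorbing a
    slow trend rather than a genuine rhythm.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D and equal length")
    if len(t) < MODEL_K[model]:
        raise ValueError(f"{model}: need at least {MODEL_K[model]} points")
    needs_f = model in ("rhythmic", "hybrid")
    if needs_f:
        if fbounds is None:
            fbounds = FrequencyBounds.full()
        fbounds.validate_against_grid(t)

    ones = np.ones_like(t)

    if model == "intercept":
        b0 = float(y.mean())
        rss = float(((y - b0) ** 2).sum())
        return FitResult(model, {"b0": b0}, rss, len(t), MODEL_K[model],
                         True, 1)

    if model == "linear":
        coef, rss = _lstsq_rss(np.column_stack([ones, t]), y)
        return FitResult(model, {"b0": float(coef[0]), "b1": float(coef[1])},
                         rss, len(t), MODEL_K[model], True, 1)

    candidates = []  # (rss_grid, x0)
    if model == "exponential":
        for tau in _tau_grid():
            X = np.column_stack([ones, np.exp(-t / tau)])
            coef, rss = _lstsq_rss(X, y)
            candidates.append((rss, np.array([coef[0], coef[1], tau])))
        lower = np.array([-_LIN_BOUND, -_LIN_BOUND, _TAU_BOUNDS[0]])
        upper = np.array([_LIN_BOUND, _LIN_BOUND, _TAU_BOUNDS[1]])

    elif model == "rhythmic":
        for f in _f_grid(fbounds, f_grid_step):
            w = 2 * np.pi * f * t
            X = np.column_stack([ones, np.sin(w), np.cos(w)])
            coef, rss = _lstsq_rss(X, y)
            a, phi = _sincos_to_amp_phase(coef[1], coef[2])
            candidates.append((rss, np.array([coef[0], a, f, phi])))
        lower = np.array([-_LIN_BOUND, 0.0, fbounds.f_min, -2 * np.pi])
        upper = np.array([_LIN_BOUND, _A_MAX, fbounds.f_max, 4 * np.pi])

    elif model == "hybrid":
        # seed the grids with the best tau/f from the nested fits so the
        # hybrid can never do worse than either component model
        hints = hints or {}
        tau_hint = hints.get("tau")
        if tau_hint is None:
            tau_hint = fit("exponential", t, y).params["tau"]
        f_hint = hints.get("f")
        if f_hint is None:
            f_hint = fit("rhythmic", t, y, fbounds, f_grid_step).params["f"]
        candidates = _hybrid_grid_candidates(
            t, y, _tau_grid(extra=tau_hint),
            _f_grid(fbounds, f_grid_step, extra=f_hint))
        lower = np.array([-_LIN_BOUND, -_LIN_BOUND, _TAU_BOUNDS[0], 0.0,
                          fbounds.f_min, -2 * np.pi])
        upper = np.array([_LIN_BOUND, _LIN_BOUND, _TAU_BOUNDS[1], _A_MAX,
                          fbounds.f_max, 4 * np.pi])
    else:
        raise ValueError(f"unknown model {model!r}")

    candidates.sort(key=lambda c: c[0])
    best_x, best_rss, best_ok = None, math.inf, False
    for rss0, x0 in candidates[:n_polish]:
        x, rss, ok = _polish(model, t, y, x0, lower, upper)
        if rss < best_rss:
            best_x, best_rss, best_ok = x, rss, ok
    # keep the raw grid solution if polish somehow regressed (grid RSS
    # recomputed exactly: batched normal equations can lose precision)
    x0 = np.clip(candidates[0][1], lower, upper)
    r0 = predict(model, dict(zip(MODEL_PARAMS[model], x0)), t) - y
    rss0 = float(r0 @ r0)
    if rss0 < best_rss:
        best_x, best_rss, best_ok = x0, rss0, True

    params = dict(zip(MODEL_PARAMS[model], (float(v) for v in best_x)))
    if "phi" in params:
        params["phi"] = _wrap_phase(params["phi"])
    f_low = needs_f and abs(params.get("f", np.inf) - fbounds.f_min) < 1e-6
    return FitResult(model, params, best_rss, len(t), MODEL_K[model],
                     best_ok, len(candidates), f_at_lower_bound=f_low)


def fit_all(t, y, fbounds: FrequencyBounds | None = None,
            f_grid_step: float = 0.25, n_polish: int = 3) -> dict[str, FitResult]:
    """Fit all five candidate models to one series.

    The exponential and rhythmic solutions seed the hybrid's grid, so the
    nesting inequality rss(hybrid) <= min(rss(exponential), rss(rhythmic))
    holds by construction.
    """
    out: dict[str, FitResult] = {}
    for m in ("intercept", "linear", "exponential", "rhythmic"):
        out[m] = fit(m, t, y, fbounds=fbounds, f_grid_step=f_grid_step,
                     n_polish=n_polish)
    out["hybrid"] = fit("hybrid", t, y, fbounds=fbounds,
                        f_grid_step=f_grid_step, n_polish=n_polish,
                        hints={"tau": out["exponential"].params["tau"],
                               "f": out["rhythmic"].params["f"]})
    return out
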