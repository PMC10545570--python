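"""Spectral test for rhythmicity in behavioral time courses.

The grand-average time course (25 CTOAs) is detrended by removing its
least-squares quadratic in time, Fourier transformed, and each non-DC
amplitude is compared against a max-statistic permutation null: on each
permutation the CTOA labels are shuffled independently within every
participant (destroying temporal structure while preserving each
participant's value distribution), the permuted grand average is
re-detrended and re-transformed, and the maximum amplitude across bins is
recorded.  Comparing every bin to the distribution of the maximum controls
the familywise error rate across frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "detrend2",
    "quadratic_residual_matrix",
    "amplitude_spectrum",
    "permutation_test",
    "run_spectral_battery",
    "SpectrumTestResult",
]

MIN_RECOMMENDED_PERMS = 999


@dataclass
class SpectrumTestResult:
    condition: str
    ctoa: np.ndarray            # seconds
    detrended: np.ndarray       # grand-average series after detrending
    freqs: np.ndarray           # Hz, non-DC bins up to Nyquist
    amplitude: np.ndarray       # 2|X_k|/N per bin
    max_distribution: np.ndarray
    threshold_95: float
    p: np.ndarray               # per-bin, max-corrected
    n_permutations: int
    seed: object

    @property
    def significant(self) -> np.ndarray:
        return self.p < 0.05


def quadratic_residual_matrix(t: np.ndarray) -> np.ndarray:
    """Projection onto the orthogonal complement of span{1, t, t^2}."""
    t = np.asarray(t, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 points for quadratic detrending")
    ts = (t - t.mean()) / t.std()  # standardized for conditioning
    T = np.column_stack([np.ones_like(ts), ts, ts ** 2])
    Q, _ = np.linalg.qr(T)
    return np.eye(len(t)) - Q @ Q.T


def detrend2(series, t) -> np.ndarray:
    """Remove the least-squares second-order polynomial trend in ``t``.

    The residual is orthogonal to {1, t, t^2}; any purely quadratic input
    maps to (numerically) zero.
    """
    y = np.asarray(series, dtype=float)
    R = quadratic_residual_matrix(np.asarray(t, dtype=float))
    if y.shape[-1] != R.shape[0]:
        raise ValueError("series and t must have equal length")
    return y @ R.T


def amplitude_spectrum(series, dt: float):
    """One-sided amplitude spectrum of an N-point series.

    Returns (freqs, amps) for bins k = 1..floor(N/2) at k/(N*dt) Hz with
    amplitude 2|X_k|/N, i.e. a unit sinusoid exactly on a bin has
    amplitude 1.
    """
    y = np.asarray(series, dtype=float)
    n = y.shape[-1]
    kmax = n // 2
    coefs = np.fft.rfft(y, axis=-1)[..., 1:kmax + 1]
    freqs = np.arange(1, kmax + 1) / (n * dt)
    return freqs, 2.0 * np.abs(coefs) / n


def _check_uniform_grid(t: np.ndarray) -> float:
    d = np.diff(t)
    if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
        raise ValueError("CTOA grid must be uniformly spaced for the FFT")
    return float(d[0])


def permutation_test(cells: np.ndarray, t: np.ndarray, n_perm: int = 10000,
                     seed=0, condition: str = "",
                     batch: int = 500) -> SpectrumTestResult:
    """Max-amplitude permutation test on a participants x CTOAs matrix.

    p(bin) = (1 + #{permutation max >= observed amplitude}) / (n_perm + 1):
    the observed data count as one member of their own null ordering, so
    p can never be exactly 0.
    """
    X = np.asarray(cells, dtype=float)
    t = np.asarray(t, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(t):
        raise ValueError("cells must be participants x len(t)")
    if not np.isfinite(X).all():
        raise ValueError("cells matrix must be complete (no NaNs)")
    if n_perm < MIN_RECOMMENDED_PERMS:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution for "
                      f"a familywise alpha of .05; use >= 999", stacklevel=2)
    dt = _check_uniform_grid(t)
    P, C = X.shape
    R = quadratic_residual_matrix(t)

    grand = X.mean(axis=0)
    detr = grand @ R.T
    freqs, amp = amplitude_spectrum(detr, dt)

    rng = np.random.default_rng(seed)
    rows = np.arange(P)[:, None]
    max_amps = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # independent CTOA-label shuffle within each participant
        idx = np.argsort(rng.random((b, P, C)), axis=-1)
        perm_avg = X[rows, idx].mean(axis=1)          # b x C
        _, amps = amplitude_spectrum(perm_avg @ R.T, dt)
        max_amps[done:done + b] = amps.max(axis=-1)
        done += b

    # the 1e-12 slack keeps float noise from breaking exact ties (e.g. a
    # constant dataset, where every amplitude is analytically zero)
    p = (1 + (max_amps[None, :] >= amp[:, None] - 1e-12).sum(axis=1)) \
        / (n_perm + 1)
    return SpectrumTestResult(
        condition=condition, ctoa=t, detrended=detr, freqs=freqs,
        amplitude=amp, max_distribution=max_amps,
        threshold_95=float(np.quantile(max_amps, 0.95)), p=p,
        n_permutations=n_perm, seed=seed)


def run_spectral_battery(valid: np.ndarray, invalid: np.ndarray,
                         difference: np.ndarray, t: np.ndarray,
                         n_perm: int = 10000, seed: int = 0) -> dict:
    """Run the permutation test for the valid, invalid, and difference
    (invalid - valid) time courses with a shared permutation budget and
    per-condition seeds derived from one master seed."""
    out = {}
    for j, (name, mat) in enumerate((("valid", valid), ("invalid", invalid),
                                     ("difference", difference))):
        ss = np.random.SeedSequence((int(seed), j))
        out[name] = permutation_test(mat, t, n_perm=n_perm, seed=ss,
                                     condition=name)
    return out
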