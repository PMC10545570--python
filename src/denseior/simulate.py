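"""Synthetic trial-level data for a densely sampled exogenous cueing task.

Emulates a Posner-style detection experiment in which a non-informative
peripheral cue precedes the target by one of 25 cue--target onset
asynchronies (CTOAs, 42--1050 ms in 42 ms steps), with valid and invalid
trials plus target-absent catch trials.  The generative signal is the
invalid-minus-valid reaction-time difference curve d(t) expressed in
z-units; every participant's RTs are drawn around a personal baseline
with condition offsets of +-d(t)/2 so that the expected cell-mean
difference equals d(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "EffectParams",
    "NoiseParams",
    "build_schedule",
    "difference_curve",
    "simulate_participant",
    "simulate_cohort",
]

TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "ctoa_ms",
    "validity",
    "is_catch",
    "responded",
    "rt",
]

VALIDITIES = ("valid", "invalid")


@dataclass(frozen=True)
class DesignConfig:
    """Experimental design: CTOA grid, cell sizes, catch trials, blocks."""

    ctoa_min: float = 0.042  # seconds
    ctoa_step: float = 0.042  # seconds
    n_ctoas: int = 25
    trials_per_cell: int = 12
    n_catch: int = 60
    n_blocks: int = 6
    n_participants: int = 39
    response_deadline: float = 2.0  # seconds

    def __post_init__(self) -> None:
        if self.ctoa_min <= 0 or self.ctoa_step <= 0:
            raise ValueError("CTOA grid must be strictly positive")
        if min(self.n_ctoas, self.trials_per_cell, self.n_blocks,
               self.n_participants) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_catch < 0:
            raise ValueError("n_catch must be >= 0")
        if self.response_deadline <= 0:
            raise ValueError("response_deadline must be positive")

    @property
    def ctoa_grid(self) -> np.ndarray:
        """CTOA values in seconds: ctoa_min + i*ctoa_step, i = 0..n_ctoas-1."""
        return self.ctoa_min + self.ctoa_step * np.arange(self.n_ctoas)

    @property
    def ctoa_grid_ms(self) -> np.ndarray:
        """CTOA grid as integer milliseconds (the on-disk representation)."""
        return np.rint(self.ctoa_grid * 1000).astype(int)

    @property
    def n_trials(self) -> int:
        return self.n_ctoas * len(VALIDITIES) * self.trials_per_cell + self.n_catch


@dataclass(frozen=True)
class EffectParams:
    """Parameters of the generative invalid-valid difference curve (z-units).

    d(t) = b0 + N0*exp(-t/tau) + a*sin(2*pi*f*t + phi): an exponentially
    decaying inhibitory-tagging component riding on a constant offset, plus
    an optional sinusoidal (rhythmic-sampling) component.  Defaults are the
    hybrid-curve estimates from the original 39-participant experiment.
    """

    b0: float = -0.48
    N0: float = 0.82
    tau: float = 0.18  # seconds
    a: float = 0.14
    f: float = 1.05  # Hz
    phi: float = 0.72  # radians

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.a < 0:
            raise ValueError("amplitude a must be >= 0")
        if self.f < 0:
            raise ValueError("frequency f must be >= 0")
        phi = float(self.phi) % (2 * math.pi)
        if phi >= 2 * math.pi:  # modulo of a tiny negative can round up
            phi = 0.0
        object.__setattr__(self, "phi", phi)


@dataclass(frozen=True)
class NoiseParams:
    """Stochastic structure of simulated RTs.

    A participant's non-catch RT is

        rt = base_rt_mean + intercept_p + scale_p * (offset * effect_scale + eps)

    where offset = +-d(ctoa)/2 in z-units (valid gets -d/2, invalid +d/2),
    eps is zero-mean trial noise with SD ``trial_sd`` seconds,
    intercept_p ~ N(0, participant_intercept_sd) and
    scale_p = exp(N(0, participant_scale_sd)) model between-participant
    variation in baseline speed and overall RT variability.
    ``effect_scale`` converts the z-unit effect into seconds; within-
    participant z-scaling later divides it back out, so its default is tied
    to ``trial_sd`` to keep the normalized difference curve close to d(t).
    """

    base_rt_mean: float = 0.35  # seconds
    participant_intercept_sd: float = 0.04  # seconds
    participant_scale_sd: float = 0.10  # unitless (lognormal sigma)
    trial_sd: float = 0.08  # seconds
    effect_scale: float = 0.08  # seconds per z-unit
    rt_distribution: str = "normal"  # or "shifted-lognormal"
    false_alarm_rate: float = 0.05
    miss_rate: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("participant_intercept_sd", "participant_scale_sd",
                     "trial_sd", "effect_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("false_alarm_rate", "miss_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rt_distribution not in ("normal", "shifted-lognormal"):
            raise ValueError("rt_distribution must be 'normal' or "
                             "'shifted-lognormal'")


def difference_curve(t, p: EffectParams) -> np.ndarray:
    """Evaluate d(t) = b0 + N0*exp(-t/tau) + a*sin(2*pi*f*t + phi).

    ``t`` is in seconds (scalar or array); the result is in z-units.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return (p.b0 + p.N0 * np.exp(-t / p.tau)
            + p.a * np.sin(2 * np.pi * p.f * t + p.phi))


def build_schedule(cfg: DesignConfig, seed: int) -> pd.DataFrame:
    """Build one participant's counterbalanced, shuffled trial schedule.

    Every block receives an equal share of each CTOA x validity cell and of
    the catch trials; order within a block is a seeded random permutation.
    Returns a frame with columns block, trial, ctoa_ms, validity, is_catch.
    """
    if cfg.trials_per_cell % cfg.n_blocks:
        raise ValueError(
            f"trials_per_cell={cfg.trials_per_cell} is not divisible by "
            f"n_blocks={cfg.n_blocks}; cells cannot be counterbalanced "
            f"at block level")
    if cfg.n_catch % cfg.n_blocks:
        raise ValueError(
            f"n_catch={cfg.n_catch} is not divisible by "
            f"n_blocks={cfg.n_blocks}")

    per_block = cfg.trials_per_cell // cfg.n_blocks
    catch_per_block = cfg.n_catch // cfg.n_blocks
    grid_ms = cfg.ctoa_grid_ms

    rng = np.random.default_rng(seed)
    blocks = []
    for b in range(cfg.n_blocks):
        ctoas, vals, catch = [], [], []
        for ms in grid_ms:
            for v in VALIDITIES:
                ctoas += [ms] * per_block
                vals += [v] * per_block
                catch += [False] * per_block
        ctoas += [-1] * catch_per_block
        vals += [""] * catch_per_block
        catch += [True] * catch_per_block
        order = rng.permutation(len(ctoas))
        blk = pd.DataFrame({
            "block": b + 1,
            "ctoa_ms": np.asarray(ctoas)[order],
            "validity": np.asarray(vals, dtype=object)[order],
            "is_catch": np.asarray(catch)[order],
        })
        blocks.append(blk)
    out = pd.concat(blocks, ignore_index=True)
    out.insert(1, "trial", np.arange(1, len(out) + 1))
    out["ctoa_ms"] = out["ctoa_ms"].where(~out["is_catch"], other=pd.NA)
    out["ctoa_ms"] = out["ctoa_ms"].astype("Int64")
    out["validity"] = out["validity"].where(~out["is_catch"], other=pd.NA)
    return out


def _trial_noise(rng: np.random.Generator, n: int, sd: float,
                 distribution: str) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    if distribution == "normal":
        return rng.normal(0.0, sd, n)
    # shifted lognormal with fixed shape, rescaled to zero mean / sd
    sigma = 0.5
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    mu = math.exp(sigma ** 2 / 2)
    s = math.sqrt((math.exp(sigma ** 2) - 1) * math.exp(sigma ** 2))
    return (raw - mu) / s * sd


def simulate_participant(schedule: pd.DataFrame, effect: EffectParams,
                         noise: NoiseParams, seed,
                         participant_id: str = "P01",
                         deadline: float = 2.0) -> pd.DataFrame:
    """Simulate one participant's responses on a schedule.

    Valid trials get a -d(t)/2 offset, invalid trials +d(t)/2, so the
    expected invalid-valid cell-mean difference is d(t)*effect_scale.
    Catch trials are responded to with probability ``false_alarm_rate``;
    non-catch trials are missed with probability ``miss_rate``.  RTs are
    clipped to (0, deadline].
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)

    intercept = rng.normal(0.0, noise.participant_intercept_sd)
    scale = math.exp(rng.normal(0.0, noise.participant_scale_sd)) \
        if noise.participant_scale_sd > 0 else 1.0

    is_catch = schedule["is_catch"].to_numpy(dtype=bool)
    ctoa_s = np.where(is_catch, 0.0,
                      schedule["ctoa_ms"].fillna(0).to_numpy(dtype=float) / 1000.0)
    d = difference_curve(ctoa_s, effect)
    sign = np.where(schedule["validity"].fillna("").to_numpy() == "invalid",
                    0.5, -0.5)
    offset = np.where(is_catch, 0.0, sign * d)

    eps = _trial_noise(rng, n, noise.trial_sd, noise.rt_distribution)
    rt = (noise.base_rt_mean + intercept
          + scale * (offset * noise.effect_scale + eps))
    rt = np.clip(rt, 1e-3, deadline)

    u = rng.uniform(size=n)
    responded = np.where(is_catch, u < noise.false_alarm_rate,
                         u >= noise.miss_rate)
    rt = np.where(responded, rt, np.nan)

    out = schedule.copy()
    out.insert(0, "participant_id", participant_id)
    out["responded"] = responded
    out["rt"] = rt
    return out[TRIAL_COLUMNS]


def participant_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-participant stream: SeedSequence((master, index))."""
    return np.random.SeedSequence((int(master_seed), int(index)))


def simulate_cohort(cfg: DesignConfig, effect: EffectParams,
                    noise: NoiseParams, master_seed: int) -> pd.DataFrame:
    """Simulate all participants; one schedule and RT stream per participant.

    Participant i's schedule and responses are both driven by the seed
    sequence (master_seed, i), so any sub-cohort is reproducible piecewise.
    """
    width = max(2, len(str(cfg.n_participants)))
    frames = []
    ids = set()
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:0{width}d}"
        if pid in ids:
            raise ValueError(f"duplicate participant id {pid}")
        ids.add(pid)
        ss = participant_seed(master_seed, i)
        sched_seed, sim_seed = ss.spawn(2)
        schedule = build_schedule(cfg, sched_seed)
        frames.append(simulate_participant(
            schedule, effect, noise, sim_seed, participant_id=pid,
            deadline=cfg.response_deadline))
    return pd.concat(frames, ignore_index=True)
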