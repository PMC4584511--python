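"""Synthetic task generators and noisy observers.

Two psychophysical tasks probe hazard-adaptive evidence accumulation:

* **triangles** — one sample per trial.  A hidden source (one of two
  Gaussians separated by d = 1 in internal units, each with standard
  deviation ``sigma = sigma_over_d``) emits a "star" position ``x`` each
  trial; the source switches between trials as a Bernoulli process with
  the block's hazard ``H``.  The log-likelihood ratio of a star is exactly
  ``x * d / sigma**2``.

* **dots-reversal** — one choice per trial about the final direction of a
  random-dot motion stream whose direction flips as a Poisson process at
  ``lam`` (0.1 or 2 Hz).  Frames arrive at 60 Hz; per-frame signed
  coherence is realized as a binomial fraction of coherently displaced
  dots around the trial's nominal level (high on 25% of trials, low on
  75%).  Trial durations follow min(10, 5 + tau) seconds with tau
  exponential.

:func:`observe` turns trial tables into choices from a parameterized
observer (normative / leaky / bounded / block-independent) with its own
subjective hazard, gain, and decision noise — the synthetic stand-in for
human choice data used throughout the fitting and analysis suites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import belief

__all__ = [
    "TrianglesConfig",
    "DotsConfig",
    "DotsData",
    "ObserverParams",
    "gen_triangles",
    "gen_dots",
    "observe",
    "observe_triangles",
    "observe_dots",
]

#: hazard set used in the triangles experiment
TRIANGLES_HAZARDS = (0.05, 0.1, 0.3, 0.5, 0.7, 0.9, 0.95)
#: ratio of generative std to triangle separation, one of three session values
TRIANGLES_SIGMA_RATIOS = (0.24, 0.33, 0.41)
FRAME_RATE = 60.0

TRIANGLES_COLUMNS = ["block", "trial", "H_true", "source", "x", "llr", "feedback"]
DOTS_TRIAL_COLUMNS = [
    "trial",
    "lam",
    "coh_level",
    "expected_abs_coherence",
    "duration_s",
    "n_switches",
    "t_since_last_switch",
    "t_penultimate",
    "final_dir",
]
DOTS_FRAME_COLUMNS = ["trial", "frame", "signed_coherence"]


@dataclass(frozen=True)
class TrianglesConfig:
    """Block structure of the triangles task.

    ``feedback_layout`` = (leading feedback, middle no-feedback, trailing
    feedback) trial counts; the default (400, 400, 200) reproduces the
    1000-trial feedback sessions.
    """

    hazard_set: Sequence[float] = (0.1, 0.3, 0.7)
    n_trials_per_block: int = 1000
    sigma_over_d: float = 0.33
    feedback_layout: tuple[int, int, int] = (400, 400, 200)
    seed: int | None = None

    def __post_init__(self):
        if not all(0.0 < h < 1.0 for h in self.hazard_set):
            raise ValueError("hazard values must lie in (0, 1)")
        if self.sigma_over_d <= 0:
            raise ValueError("sigma_over_d must be > 0")


@dataclass(frozen=True)
class DotsConfig:
    """Session structure of the dots-reversal task."""

    lam: float = 0.1
    n_trials: int = 200
    frame_rate: float = FRAME_RATE
    tau_mean: float = 2.5
    coherence_high: float = 0.8
    coherence_low: float = 0.15
    p_high: float = 0.25
    n_dots: int = 100
    fixed_coherence: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (0 < self.coherence_low <= 1 and 0 < self.coherence_high <= 1):
            raise ValueError("coherences must lie in (0, 1]")


@dataclass(frozen=True)
class ObserverParams:
    """Synthetic decision-maker.

    model : 'normative' | 'leaky' | 'bounded' | 'block_independent'
    subjective_hazard : H per block (triangles, mapping block id -> H or a
        single value) or the subjective switch rate lam in Hz (dots)
    gain : evidence gain — beta on star position (triangles) or k on signed
        coherence (dots)
    noise : choice noise upsilon in log-odds units (triangles); dots frame
        noise is signal-dependent, sqrt(2 k <|C|>) per frame
    leak / bound : K (leaky) or theta (bounded), per block or scalar
    """

    model: str = "normative"
    subjective_hazard: float | Mapping = 0.3
    gain: float = 1.0
    noise: float = 1.0
    leak: float | Mapping | None = None
    bound: float | Mapping | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.model not in {"normative", "leaky", "bounded", "block_independent"}:
            raise ValueError(f"unknown observer model {self.model!r}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _per_block(value, block):
    if isinstance(value, Mapping):
        return float(value[block])
    return float(value)


def gen_triangles(config: TrianglesConfig) -> pd.DataFrame:
    """Generate a triangles-task trial table (one row per trial).

    Sources sit at +/- 1/2 (separation d = 1); the star position is the
    source plus Gaussian noise of std ``sigma_over_d``; ``llr`` is the
    analytic log-likelihood ratio ``x / sigma**2``.
    """
    rng = np.random.default_rng(config.seed)
    sigma = config.sigma_over_d
    n = config.n_trials_per_block
    lead, mid, trail = config.feedback_layout
    rows = []
    for b, H in enumerate(config.hazard_set):
        switches = rng.random(n) < H
        switches[0] = False
        source = np.where(np.cumsum(switches) % 2 == 0, 1, -1)
        source = source * (1 if rng.random() < 0.5 else -1)
        x = source * 0.5 + rng.normal(0.0, sigma, size=n)
        llr = x / sigma**2
        idx = np.arange(n)
        feedback = (idx < lead) | (idx >= lead + mid)
        if lead + mid + trail > n:
            feedback = np.ones(n, dtype=bool)
        rows.append(
            pd.DataFrame(
                {
                    "block": b,
                    "trial": idx,
                    "H_true": H,
                    "source": source,
                    "x": x,
                    "llr": llr,
                    "feedback": feedback,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class DotsData:
    """Trial-level table plus the per-frame long-format coherence table."""

    trials: pd.DataFrame
    frames: pd.DataFrame
    frame_rate: float = FRAME_RATE


def gen_dots(config: DotsConfig) -> DotsData:
    """Generate a dots-reversal session.

    Direction switch times form a Poisson process at ``lam`` within each
    trial; per-frame signed coherence is Binomial(n_dots, level)/n_dots
    with the sign of the current direction (or exactly the nominal level
    when ``fixed_coherence``).  Durations are min(10, 5 + tau) seconds.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.frame_rate
    trial_rows = []
    frame_trial = []
    frame_idx = []
    frame_coh = []
    for t in range(config.n_trials):
        tau = rng.exponential(config.tau_mean)
        duration = min(10.0, 5.0 + tau)
        n_frames = int(round(duration * config.frame_rate))
        # the stimulus lasts a whole number of frames; store that duration so
        # switch times never exceed it
        duration = n_frames * dt
        high = rng.random() < config.p_high
        level = config.coherence_high if high else config.coherence_low
        d0 = 1 if rng.random() < 0.5 else -1
        flips = rng.random(n_frames) < -math.expm1(-config.lam * dt)
        flips[0] = False
        direction = np.where(np.cumsum(flips) % 2 == 0, d0, -d0)
        switch_frames = np.flatnonzero(flips)
        switch_times = (switch_frames + 1) * dt
        n_switches = switch_frames.size
        if n_switches == 0:
            t_since = duration
            t_pen = np.nan
        else:
            t_since = duration - switch_times[-1]
            t_pen = switch_times[-1] - (switch_times[-2] if n_switches > 1 else 0.0)
        if config.fixed_coherence:
            mag = np.full(n_frames, level)
        else:
            mag = rng.binomial(config.n_dots, level, size=n_frames) / config.n_dots
        signed = direction * mag
        trial_rows.append(
            (
                t,
                config.lam,
                "high" if high else "low",
                level,
                duration,
                n_switches,
                t_since,
                t_pen,
                int(direction[-1]),
            )
        )
        frame_trial.append(np.full(n_frames, t))
        frame_idx.append(np.arange(n_frames))
        frame_coh.append(signed)
    trials = pd.DataFrame(trial_rows, columns=DOTS_TRIAL_COLUMNS)
    frames = pd.DataFrame(
        {
            "trial": np.concatenate(frame_trial),
            "frame": np.concatenate(frame_idx),
            "signed_coherence": np.concatenate(frame_coh),
        }
    )
    return DotsData(trials=trials, frames=frames, frame_rate=config.frame_rate)


def _prior_fn(obs: ObserverParams, block, H_subj):
    """Return a scalar prior map L_prev -> psi for the given block."""
    model = obs.model
    if model in ("normative", "block_independent"):
        r = belief._log_prior_ratio(H_subj) if 0.0 < H_subj < 1.0 else None
        if H_subj == 0.0:
            return lambda L: L
        if H_subj == 1.0:
            return lambda L: -L
        return lambda L: L + np.logaddexp(r, -L) - np.logaddexp(r, L)
    if model == "leaky":
        K = _per_block(obs.leak, block)
        return lambda L: (1.0 - K) * L
    if model == "bounded":
        theta = _per_block(obs.bound, block)
        return lambda L: min(max(L, -theta), theta)
    raise ValueError(model)


def observe_triangles(trials: pd.DataFrame, obs: ObserverParams) -> pd.DataFrame:
    """Simulate per-trial choices on the triangles task.

    The observer runs its belief model within each block (belief reset to 0
    at block starts) on evidence ``gain * x`` with its subjective hazard,
    then chooses ``sign(L + zeta)`` with ``zeta ~ N(0, noise)``.  Exact
    zeros are broken by a fair coin.  Adds columns ``L`` and ``choice``
    (+/-1).
    """
    required = {"block", "x"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table missing columns {sorted(required - set(trials.columns))}")
    rng = np.random.default_rng(obs.seed)
    out = trials.copy()
    L_all = np.empty(len(out))
    choice_all = np.empty(len(out), dtype=int)
    pos = 0
    for b, grp in out.groupby("block", sort=True):
        H_subj = _per_block(obs.subjective_hazard, b)
        if obs.model == "block_independent":
            # hazard labels shuffled across the whole session, trial by trial
            hs = list(obs.subjective_hazard.values()) if isinstance(obs.subjective_hazard, Mapping) else [H_subj]
            H_seq = rng.choice(hs, size=len(grp))
        else:
            H_seq = None
        x = grp["x"].to_numpy()
        n = len(x)
        L = 0.0
        Ls = np.empty(n)
        prior = _prior_fn(obs, b, H_subj)
        for i in range(n):
            if H_seq is not None:
                prior = _prior_fn(obs, b, float(H_seq[i]))
            L = float(prior(L)) + obs.gain * x[i]
            Ls[i] = L
        zeta = rng.normal(0.0, obs.noise, size=n) if obs.noise > 0 else np.zeros(n)
        noisy = Ls + zeta
        ch = np.sign(noisy)
        ties = ch == 0
        if ties.any():
            ch[ties] = rng.choice([-1.0, 1.0], size=int(ties.sum()))
        L_all[pos : pos + n] = Ls
        choice_all[pos : pos + n] = ch.astype(int)
        pos += n
    out["L"] = L_all
    out["choice"] = choice_all
    return out


def observe_dots(data: DotsData, obs: ObserverParams) -> pd.DataFrame:
    """Simulate final-direction choices on the dots-reversal task.

    The observer's per-frame evidence is ``k*C + sqrt(2 k <|C|>) eta`` with
    standard-normal ``eta``; beliefs run through the observer's prior map
    with subjective per-frame hazard ``lam_subj / frame_rate``; the choice
    is the sign of the final belief (fair coin at exactly 0).  Returns the
    trial table with ``L_final`` and ``choice`` columns added.
    """
    rng = np.random.default_rng(obs.seed)
    k = obs.gain
    H_subj = _per_block(obs.subjective_hazard, 0) / data.frame_rate
    trials = data.trials.copy()
    frames_by_trial = {t: g["signed_coherence"].to_numpy() for t, g in data.frames.groupby("trial")}
    L_final = np.empty(len(trials))
    choice = np.empty(len(trials), dtype=int)
    for i, row in enumerate(trials.itertuples(index=False)):
        C = frames_by_trial[row.trial]
        s = math.sqrt(2.0 * k * row.expected_abs_coherence)
        prior = _prior_fn(obs, 0, H_subj)
        eta = rng.standard_normal(C.size)
        L = 0.0
        for m in range(C.size):
            L = float(prior(L)) + k * C[m] + s * eta[m]
        L_final[i] = L
        if L == 0.0:
            choice[i] = rng.choice([-1, 1])
        else:
            choice[i] = 1 if L > 0 else -1
    trials["L_final"] = L_final
    trials["choice"] = choice
    return trials


def observe(data, obs: ObserverParams):
    """Dispatch on task container: DataFrame -> triangles, DotsData -> dots."""
    if isinstance(data, DotsData):
        return observe_dots(data, obs)
    if isinstance(data, pd.DataFrame):
        return observe_triangles(data, obs)
    raise TypeError(f"unsupported trial container {type(data)!r}")
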