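"""Model-free behavioral analyses of choice data.

* two-parameter logistic psychometric fits of switch probability against
  the evidence for a change,
* non-parametric estimation of the prior mapping ``psi`` from choices,
  with a Tikhonov smoothness penalty on adjacent node differences,
* change-point vs non-change-point accuracy trade-off tables,
* bootstrap accuracy-by-viewing-duration analysis for the dots task,
* normalized leak differences across coherence / hazard conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import CubicSpline
from scipy.special import expit

from numba import njit

from .fitting import cross_entropy

__all__ = [
    "PsychometricParams",
    "NonparamPsiConfig",
    "DurationBins",
    "fit_psychometric",
    "estimate_psi_nonparametric",
    "tradeoff_table",
    "accuracy_by_duration",
    "normalized_leak_diff",
    "switch_table",
]


@dataclass(frozen=True)
class PsychometricParams:
    """Two-parameter logistic: indifference point phi (LLR units) and slope
    scale beta_slope (LLR units); switch probability is
    ``1 / (1 + exp(-(LLR_change - phi) / beta_slope))`` (increasing in the
    evidence for a change)."""

    phi: float
    beta_slope: float

    def predict(self, llr_change):
        return expit((np.asarray(llr_change, dtype=float) - self.phi) / self.beta_slope)


def fit_psychometric(switch_flags, llr_change, min_abs_prev_llr: float | None = None,
                     prev_abs_llr=None) -> PsychometricParams:
    """Maximum-likelihood logistic fit of switch probability vs change evidence.

    ``llr_change`` is the log-likelihood ratio in favor of the source
    having switched away from the previous choice.  If
    ``min_abs_prev_llr`` and ``prev_abs_llr`` are given, trials are first
    restricted to those following strong evidence
    (``prev_abs_llr > min_abs_prev_llr``), probing the strong-belief
    regime.
    """
    y = np.asarray(switch_flags, dtype=float)
    z = np.asarray(llr_change, dtype=float)
    if y.shape != z.shape:
        raise ValueError("switch_flags and llr_change must have equal length")
    if min_abs_prev_llr is not None:
        if prev_abs_llr is None:
            raise ValueError("prev_abs_llr required when filtering on previous evidence")
        keep = np.asarray(prev_abs_llr, dtype=float) > min_abs_prev_llr
        y, z = y[keep], z[keep]
    if y.size == 0 or y.min() == y.max():
        raise ValueError("degenerate fit: responses are constant (or empty)")

    def nll(u):
        phi, log_b = u
        p = expit((z - phi) / math.exp(min(log_b, 20.0)))
        return cross_entropy(y, p)

    best = None
    for phi0 in (np.median(z), 0.0):
        res = optimize.minimize(nll, np.array([phi0, 0.0]), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return PsychometricParams(phi=float(best.x[0]), beta_slope=float(math.exp(best.x[1])))


@dataclass(frozen=True)
class NonparamPsiConfig:
    """Grid and smoothing for the non-parametric prior-map estimate.

    Nodes span -10..10 in unit log-odds steps; interpolation between
    nodes is a natural cubic spline; ``tikhonov_gamma`` (default 1/20)
    weights the squared-difference penalty on adjacent node values.
    """

    grid: np.ndarray = field(default_factory=lambda: np.arange(-10.0, 10.5, 1.0))
    tikhonov_gamma: float = 1.0 / 20.0
    min_visits: int = 5

    def __post_init__(self):
        if self.tikhonov_gamma < 0:
            raise ValueError("tikhonov_gamma must be >= 0")


def _spline_eval_factory(nodes):
    """Fast scalar natural-cubic-spline evaluation from node values."""
    x0 = nodes[0]
    n = nodes.size

    def make(values):
        cs = CubicSpline(nodes, values, bc_type="natural")
        c = cs.c  # (4, n-1)
        return c

    def ev(c, L):
        # clamp into the node range; unit spacing assumed
        if L <= nodes[0]:
            i, t = 0, 0.0
        elif L >= nodes[-1]:
            i, t = n - 2, nodes[-1] - nodes[n - 2]
        else:
            i = int(L - x0)
            if i > n - 2:
                i = n - 2
            t = L - nodes[i]
        return ((c[0, i] * t + c[1, i]) * t + c[2, i]) * t + c[3, i]

    return make, ev


@njit(cache=True)
def _psi_recursion_nll(llr, y01, c, x0, xlast, spacing, ups):
    """Negative log likelihood of choices under the spline prior map.

    c : (4, n_segments) natural-cubic coefficients; beliefs are clamped to
    the node range before evaluating the spline.
    """
    nseg = c.shape[1]
    inv = 1.0 / (math.sqrt(2.0) * ups)
    L = 0.0
    nll = 0.0
    for i in range(llr.size):
        if L <= x0:
            seg, t = 0, 0.0
        elif L >= xlast:
            seg, t = nseg - 1, spacing
        else:
            seg = int((L - x0) / spacing)
            if seg > nseg - 1:
                seg = nseg - 1
            t = L - (x0 + seg * spacing)
        psi = ((c[0, seg] * t + c[1, seg]) * t + c[2, seg]) * t + c[3, seg]
        L = psi + llr[i]
        p = 0.5 * (1.0 + math.erf(L * inv))
        if p < 1e-9:
            p = 1e-9
        elif p > 1.0 - 1e-9:
            p = 1.0 - 1e-9
        nll -= math.log(p) if y01[i] > 0.5 else math.log(1.0 - p)
    return nll


def estimate_psi_nonparametric(
    data: pd.DataFrame,
    config: NonparamPsiConfig | None = None,
    noise: float | None = None,
    maxiter: int = 400,
) -> pd.DataFrame:
    """Estimate the prior mapping ``psi`` from one block of choices.

    Fits node values ``psi_i`` on the config grid, minimizing the
    cross-entropy of choices under ``L_n = psi(L_{n-1}) + llr_n`` (with
    cubic-spline interpolation between nodes and ``Phi(L / upsilon)``
    choice probabilities) plus the penalty ``gamma * sum (delta psi)^2``.
    The choice noise ``upsilon`` is fit jointly unless given.

    Returns a DataFrame with columns node, psi_hat, visits, masked (nodes
    whose neighborhood was visited fewer than ``min_visits`` times).
    """
    config = config or NonparamPsiConfig()
    if "llr" not in data.columns or "choice" not in data.columns:
        raise ValueError("data must carry 'llr' and 'choice' columns")
    llr = data["llr"].to_numpy(dtype=float)
    y = (data["choice"].to_numpy(dtype=float) + 1.0) / 2.0
    nodes = np.asarray(config.grid, dtype=float)
    nn = nodes.size
    make, ev = _spline_eval_factory(nodes)
    gamma = config.tikhonov_gamma
    fit_noise = noise is None

    spacing = nodes[1] - nodes[0]

    def objective(theta):
        vals = theta[:nn]
        ups = math.exp(min(theta[nn], 10.0)) if fit_noise else noise
        nll = _psi_recursion_nll(llr, y, make(vals), nodes[0], nodes[-1], spacing, ups)
        d = np.diff(vals)
        return nll + gamma * float(d @ d)

    theta0 = np.concatenate([np.zeros(nn), [0.0] if fit_noise else []])
    res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 10 * maxiter * (nn + 1)})
    vals = res.x[:nn]
    # belief trajectory at the estimate, for the node-visit diagnostics
    c = make(vals)
    L = 0.0
    Ls = np.empty(llr.size)
    for i in range(llr.size):
        L = ev(c, L) + llr[i]
        Ls[i] = L
    # visits: previous-trial beliefs landing within half a step of each node
    Lprev = np.concatenate([[0.0], Ls[:-1]])
    visits = np.array([np.sum(np.abs(Lprev - v) <= 0.5) for v in nodes])
    return pd.DataFrame(
        {
            "node": nodes,
            "psi_hat": vals,
            "visits": visits,
            "masked": visits < config.min_visits,
        }
    )


def switch_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per-trial switch variables for psychometric analysis.

    For each trial after the first within a block: whether the choice
    switched sides, the LLR in favor of a change away from the previous
    choice (``-prev_choice * llr``), and the magnitude of the previous
    trial's evidence.
    """
    req = {"block", "choice", "llr"}
    if not req.issubset(data.columns):
        raise ValueError(f"missing columns {sorted(req - set(data.columns))}")
    frames = []
    for b, g in data.groupby("block", sort=True):
        ch = g["choice"].to_numpy()
        llr = g["llr"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "block": b,
                    "switch": (ch[1:] != ch[:-1]).astype(int),
                    "llr_change": -ch[:-1] * llr[1:],
                    "prev_abs_llr": np.abs(llr[:-1]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def tradeoff_table(
    data: pd.DataFrame,
    weak_max_abs_llr: float = 2.0,
    strong_min_abs_llr: float = 4.0,
    min_trials: int = 5,
) -> pd.DataFrame:
    """Per-block accuracy on change-point vs non-change-point trials,
    separately for weak and strong evidence.

    A change-point trial is one on which the source switched from the
    previous trial.  Cells with fewer than ``min_trials`` trials are
    reported as NaN with their counts.
    """
    req = {"block", "source", "choice", "llr", "H_true"}
    if not req.issubset(data.columns):
        raise ValueError(f"missing columns {sorted(req - set(data.columns))}")
    rows = []
    for b, g in data.groupby("block", sort=True):
        src = g["source"].to_numpy()
        ch = g["choice"].to_numpy()
        llr = np.abs(g["llr"].to_numpy())
        cp = np.concatenate([[False], src[1:] != src[:-1]])
        correct = ch == src
        for strength, sel in (
            ("weak", llr < weak_max_abs_llr),
            ("strong", llr > strong_min_abs_llr),
        ):
            for kind, mask in (("change_point", sel & cp), ("non_change_point", sel & ~cp)):
                n = int(mask.sum())
                rows.append(
                    {
                        "block": b,
                        "H_true": float(g["H_true"].iloc[0]),
                        "evidence": strength,
                        "kind": kind,
                        "n": n,
                        "accuracy": float(correct[mask].mean()) if n >= min_trials else np.nan,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DurationBins:
    """Viewing-duration bins (seconds) and inclusion rule for the
    accuracy-by-duration analysis."""

    edges: Sequence[float] = (0.0, 0.2, 0.5, 1.0, 1.5, 3.0)
    min_penultimate: float = 0.3
    n_bootstrap: int = 1000

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")


def accuracy_by_duration(
    trials: pd.DataFrame,
    bins: DurationBins | None = None,
    seed=None,
    paired: bool = False,
):
    """Bootstrap accuracy as a function of post-change viewing duration.

    Includes only trials with at least one direction switch whose
    penultimate-direction duration exceeds the inclusion threshold.
    Cells are coherence-level x hazard x duration-bin; each of
    ``n_bootstrap`` samples resamples subjects (shared across cells) then
    trials within the cell.  Returns per-cell plug-in mean accuracy,
    bootstrap mean and SE, and trial counts.

    With ``paired=True`` also returns a table of hazard-condition
    differences per coherence x bin computed on the shared bootstrap
    samples; a difference is flagged significant when the tail fraction
    of one sign is below 0.05.
    """
    bins = bins or DurationBins()
    req = {"lam", "coh_level", "t_since_last_switch", "n_switches", "t_penultimate", "final_dir", "choice"}
    if not req.issubset(trials.columns):
        raise ValueError(f"missing columns {sorted(req - set(trials.columns))}")
    df = trials.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    df = df[(df["n_switches"] >= 1) & (df["t_penultimate"] >= bins.min_penultimate)]
    df = df.assign(correct=(df["choice"] == df["final_dir"]).astype(float))
    rng = np.random.default_rng(seed)
    edges = np.asarray(bins.edges, dtype=float)
    df = df.assign(bin=pd.cut(df["t_since_last_switch"], edges, right=False))
    subjects = np.sort(df["subject"].unique())
    cells = {}
    for key, cell in df.groupby(["lam", "coh_level", "bin"], observed=True, sort=True):
        if len(cell):
            cells[key] = {s: g["correct"].to_numpy() for s, g in cell.groupby("subject")}
    B = bins.n_bootstrap
    boots = {key: np.empty(B) for key in cells}
    for m in range(B):
        picked = rng.choice(subjects, size=subjects.size, replace=True)
        for key, by_subj in cells.items():
            vals = []
            for s in picked:
                v = by_subj.get(s)
                if v is not None and v.size:
                    vals.append(v[rng.integers(0, v.size, size=v.size)])
            boots[key][m] = np.concatenate(vals).mean() if vals else np.nan
    rows = []
    for (lam, coh, b), by_subj in cells.items():
        n = sum(v.size for v in by_subj.values())
        bs = boots[(lam, coh, b)]
        rows.append(
            {
                "lam": lam,
                "coh_level": coh,
                "bin_left": b.left,
                "bin_right": b.right,
                "n": n,
                "accuracy": float(np.concatenate(list(by_subj.values())).mean()),
                "boot_mean": float(np.nanmean(bs)),
                "boot_se": float(np.nanstd(bs)),
            }
        )
    table = pd.DataFrame(rows)
    if not paired:
        return table
    pair_rows = []
    lams = np.sort(df["lam"].unique())
    for (coh, b) in {(c, bb) for (_, c, bb) in cells}:
        for i in range(len(lams)):
            for j in range(i + 1, len(lams)):
                ki, kj = (lams[i], coh, b), (lams[j], coh, b)
                if ki not in boots or kj not in boots:
                    continue
                diff = boots[ki] - boots[kj]
                ok = ~np.isnan(diff)
                if not ok.any():
                    continue
                p_gt = float(np.mean(diff[ok] > 0))
                p_lt = float(np.mean(diff[ok] < 0))
                pair_rows.append(
                    {
                        "coh_level": coh,
                        "bin_left": b.left,
                        "lam_a": lams[i],
                        "lam_b": lams[j],
                        "mean_diff": float(np.nanmean(diff)),
                        "p_a_gt_b": p_gt,
                        # exactly one tail below the criterion (ties count
                        # toward neither direction)
                        "significant": (p_gt < 0.05) != (p_lt < 0.05),
                    }
                )
    pairs = pd.DataFrame(pair_rows).sort_values(["coh_level", "bin_left"]).reset_index(drop=True)
    return table, pairs


def normalized_leak_diff(K_a: float, K_b: float) -> float:
    """Normalized leak difference ``(K_a - K_b) / (K_a + K_b)``.

    Bounded in (-1, 1) for positive leaks; used with (high, low) coherence
    or (fast, slow) hazard leak pairs.
    """
    if K_a <= 0 or K_b <= 0:
        raise ValueError("leaks must be positive")
    return (K_a - K_b) / (K_a + K_b)
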