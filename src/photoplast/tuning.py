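"""Task-epoch activity, tuning vectors, learning slopes, and CN statistics.

Trials are divided into four epochs: pretrial ((-2, -1] s before trial
start, only following a hit trial), early trial (start to 1 s before
reward), late trial (the final 1 s before reward), and reward ((0, 3] s
after reward). Per-neuron, per-trial epoch means are summarised by a
4-dimensional tuning vector (mean over trials) and its per-epoch OLS slope
over trials (the "delta" components of the 8-dimensional tuning vector).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .session import SessionRecord

__all__ = [
    "EpochWindows",
    "EPOCHS",
    "epoch_activity",
    "tuning_and_delta",
    "cn_sparsity_bootstrap",
    "candidate_cn_mask",
    "epoch_weighted_average",
    "pretrial_performance_regression",
]

EPOCHS = ("pre", "early", "late", "rew")
DELTA_COLS = tuple("d_" + e for e in EPOCHS)


@dataclass(frozen=True)
class EpochWindows:
    """Epoch windows (s), relative to trial start (pretrial/early start) or
    reward (late/reward)."""

    pretrial_start: float = -2.0
    pretrial_end: float = -1.0
    late_duration: float = 1.0
    reward_duration: float = 3.0

    def __post_init__(self) -> None:
        if self.pretrial_end <= self.pretrial_start:
            raise ValueError("pretrial window must have positive length")
        if self.late_duration <= 0 or self.reward_duration <= 0:
            raise ValueError("late/reward durations must be positive")


def _window_mean(trace: np.ndarray, times: np.ndarray, lo: float, hi: float) -> float:
    """Mean of trace over frames with lo < t <= hi; NaN if no frame falls in."""
    sel = (times > lo) & (times <= hi)
    if not np.any(sel):
        return np.nan
    return float(np.mean(trace[..., sel]))


def epoch_activity(
    session: SessionRecord,
    windows: EpochWindows = EpochWindows(),
    max_trials: int = 40,
) -> pd.DataFrame:
    """Per-(neuron, trial, epoch) mean dF/F.

    Returns a long-form frame with columns neuron, trial (1-based), epoch,
    value. Unavailable entries are absent, not zero:

    * pretrial only on trials following a hit trial,
    * early only on hit trials longer than the late-epoch duration,
    * late and reward only on hit trials.

    Analysis is restricted to the first ``max_trials`` trials.
    """
    ev = session.events
    times = session.times
    dff = session.dff
    n_trials = min(len(ev), max_trials)
    if ev.n_hits == 0:
        warnings.warn("session has no hit trials; late/reward columns empty")

    rows: list[tuple[int, str, float, float]] = []  # (trial, epoch, lo, hi)
    for k in range(n_trials):
        start = ev.trial_start_times[k]
        hit = ev.outcomes[k] == "hit"
        if k > 0 and ev.outcomes[k - 1] == "hit":
            rows.append((k + 1, "pre",
                         start + windows.pretrial_start,
                         start + windows.pretrial_end))
        if hit:
            rew = ev.reward_times[k]
            if rew - start > windows.late_duration:
                rows.append((k + 1, "early", start, rew - windows.late_duration))
            rows.append((k + 1, "late", rew - windows.late_duration, rew))
            rows.append((k + 1, "rew", rew, rew + windows.reward_duration))

    out = {"neuron": [], "trial": [], "epoch": [], "value": []}
    neuron_ids = np.arange(session.n_neurons)
    for trial, epoch, lo, hi in rows:
        sel = (times > lo) & (times <= hi)
        if not np.any(sel):
            continue
        vals = dff[:, sel].mean(axis=1)
        out["neuron"].extend(neuron_ids)
        out["trial"].extend([trial] * len(neuron_ids))
        out["epoch"].extend([epoch] * len(neuron_ids))
        out["value"].extend(vals)
    return pd.DataFrame(out)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    denom = np.sum(xc**2)
    if denom == 0:
        return np.nan
    return float(np.sum(xc * y) / denom)


def tuning_and_delta(table: pd.DataFrame, n_neurons: int | None = None) -> pd.DataFrame:
    """Tuning vectors from an epoch-activity table.

    Returns a frame indexed by neuron with base components (pre, early,
    late, rew) = trial-mean of available entries and delta components
    (d_pre, ...) = OLS slope of the entry on trial index (NaN when fewer
    than 2 trials are available).
    """
    if n_neurons is None:
        n_neurons = int(table["neuron"].max()) + 1 if len(table) else 0
    res = pd.DataFrame(
        index=pd.RangeIndex(n_neurons, name="neuron"),
        columns=list(EPOCHS) + list(DELTA_COLS),
        dtype=float,
    )
    for (neuron, epoch), grp in table.groupby(["neuron", "epoch"]):
        res.loc[neuron, epoch] = grp["value"].mean()
        if len(grp) >= 2:
            res.loc[neuron, "d_" + epoch] = _ols_slope(
                grp["trial"].to_numpy(), grp["value"].to_numpy()
            )
    return res


def cn_sparsity_bootstrap(
    deltas_by_session: list[np.ndarray],
    cn_ids: list[int],
    n_draws: int,
    seed: int,
    candidate_masks: list[np.ndarray] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Bootstrap test of how extreme the CN's learning slope is.

    ``deltas_by_session[s]`` holds one epoch's delta (e.g. d_late) for every
    neuron of session s. The null distribution is formed by ``n_draws``
    medians across sessions of one randomly drawn non-CN neuron per session
    (optionally restricted to candidate-CN neurons). Returns
    (cn_median_percentile, one-sided p for null >= CN median, null draws).
    """
    if len(deltas_by_session) < 2:
        raise ValueError("need at least 2 sessions")
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    pools = []
    for s, deltas in enumerate(deltas_by_session):
        deltas = np.asarray(deltas, float)
        if candidate_masks is not None:
            mask = np.asarray(candidate_masks[s], bool).copy()
            if not mask.any():
                raise ValueError(f"candidate mask empty in session {s}")
        else:
            mask = np.ones(deltas.size, bool)
        mask[cn_ids[s]] = False
        pool = deltas[mask]
        pool = pool[np.isfinite(pool)]
        if pool.size == 0:
            raise ValueError(f"no finite deltas in session {s}")
        pools.append(pool)

    cn_median = float(np.median(
        [deltas_by_session[s][cn_ids[s]] for s in range(len(cn_ids))]
    ))
    draws = np.stack(
        [pool[rng.integers(0, pool.size, size=n_draws)] for pool in pools]
    )
    null = np.median(draws, axis=0)
    percentile = float(np.mean(null < cn_median) + 0.5 * np.mean(null == cn_median))
    p_value = float(np.mean(null >= cn_median))
    return percentile, p_value, null


def _trial_start_tuning(session: SessionRecord, windows: EpochWindows) -> np.ndarray:
    """Mean activity from trial start to trial end minus mean in the
    pretrial window before start, averaged across trials."""
    times = session.times
    diffs = np.zeros((session.n_neurons,))
    count = 0
    ev = session.events
    for k in range(len(ev)):
        start = ev.trial_start_times[k]
        end = start + ev.durations[k]
        sel_t = (times > start) & (times <= end)
        sel_p = (times > start + windows.pretrial_start) & (
            times <= start + windows.pretrial_end
        )
        if not (sel_t.any() and sel_p.any()):
            continue
        diffs += session.dff[:, sel_t].mean(axis=1) - session.dff[:, sel_p].mean(axis=1)
        count += 1
    if count == 0:
        raise ValueError("no trials with both in-trial and pretrial frames")
    return diffs / count


def candidate_cn_mask(
    session: SessionRecord,
    reference: int | None = None,
    frac: float = 0.05,
    windows: EpochWindows = EpochWindows(),
) -> np.ndarray:
    """Neurons most similar to a reference CN in the two screening statistics.

    Screening statistics, computed on the (prior) session: activity
    modulation = fraction of time each neuron spends above its own activity
    s.d., and trial-start tuning = mean in-trial activity minus mean
    pretrial activity. Both are rank-transformed across neurons and the
    top ``frac`` of neurons nearest the reference in rank space (Euclidean
    distance, reference included) form the candidate pool.
    """
    if reference is None:
        reference = session.cn_index
    dff = session.dff
    sd = dff.std(axis=1)
    modulation = np.mean(dff > sd[:, None], axis=1)
    start_tuning = _trial_start_tuning(session, windows)

    r_mod = stats.rankdata(modulation)
    r_tun = stats.rankdata(start_tuning)
    d2 = (r_mod - r_mod[reference]) ** 2 + (r_tun - r_tun[reference]) ** 2
    k = max(1, int(np.ceil(frac * session.n_neurons)))
    order = np.argsort(d2, kind="stable")
    mask = np.zeros(session.n_neurons, dtype=bool)
    mask[order[:k]] = True
    return mask


def epoch_weighted_average(
    session: SessionRecord, tuning: pd.DataFrame, epoch: str
) -> np.ndarray:
    """Population trace weighted by one tuning component.

    sum_i w_i h_i(t) / sum_i |w_i| with w_i the epoch's tuning component;
    neurons with undefined tuning are excluded.
    """
    if epoch not in tuning.columns:
        raise KeyError(f"unknown epoch column {epoch!r}")
    w = tuning[epoch].to_numpy(float)
    ok = np.isfinite(w)
    denom = np.sum(np.abs(w[ok]))
    if denom == 0:
        raise ValueError("all-zero tuning weights")
    return (w[ok] @ session.dff[ok]) / denom


def pretrial_performance_regression(
    session: SessionRecord,
    windows: EpochWindows = EpochWindows(),
    max_trials: int = 40,
) -> tuple[float, float]:
    """OLS of trial duration on population pretrial activity.

    Returns (slope, one-sided Wald p for slope < 0): shorter trials with
    higher pretrial activity mean better performance.
    """
    ev = session.events
    times = session.times
    x, y = [], []
    n_trials = min(len(ev), max_trials)
    for k in range(1, n_trials):
        if ev.outcomes[k - 1] != "hit":
            continue
        start = ev.trial_start_times[k]
        sel = (times > start + windows.pretrial_start) & (
            times <= start + windows.pretrial_end
        )
        if not sel.any():
            continue
        x.append(session.dff[:, sel].mean())  # population pretrial activity
        y.append(ev.durations[k])
    if len(x) < 10:
        raise ValueError("need >= 10 trials with defined pretrial activity")
    x = np.asarray(x)
    y = np.asarray(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        if np.ptp(y) == 0:
            return 0.0, 1.0
        raise ValueError("degenerate pretrial-activity variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    # one-sided: H1 slope < 0
    p = float(stats.t.cdf(fit.tvalues[1], fit.df_resid))
    return slope, p
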