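"""Photostimulation response statistics and (Δ)causal connectivity.

For each photostimulation of a group of sites, the repeat response of a
neuron is the baseline-normalised difference between its mean activity in
a 300 ms window after stimulus offset and a 200 ms window before onset
(the 100 ms stimulation period is laser-contaminated and excluded). The PS
response W~_{i,g} is the repeat-mean normalised by the repeat s.d.; its
across-day difference uses error propagation. Neurons within 20 um of a
stimulation site are targets (directly driven); neurons 30-100 um away are
non-targets, and only their PS responses are called causal connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhotostimGroupSet",
    "RepeatResponseTensor",
    "PSResponseSet",
    "NeuronMasks",
    "ConnectivityMatrices",
    "WindowSpec",
    "repeat_response",
    "ps_response",
    "delta_ps_response",
    "classify_neurons",
    "connectivity_matrices",
]

TARGET_RADIUS_UM = 20.0
NONTARGET_INNER_UM = 30.0
NONTARGET_OUTER_UM = 100.0


@dataclass(frozen=True)
class WindowSpec:
    """Response windows (s) around each stimulation onset."""

    before: float = 0.2
    stim: float = 0.1
    after: float = 0.3


@dataclass
class PhotostimGroupSet:
    """Stimulation-site coordinates and repeat onsets per group.

    ``sites[g]`` is an (n_sites, 2) array of um coordinates; ``onsets`` is a
    DataFrame with columns group_id, onset_s, one row per stimulation event.
    """

    sites: dict[int, np.ndarray]
    onsets: pd.DataFrame
    max_separation_um: float = 400.0
    isi_s: float = 0.6
    stim_duration_s: float = 0.1

    def __post_init__(self) -> None:
        for g, xy in self.sites.items():
            xy = np.asarray(xy, float)
            if xy.ndim != 2 or xy.shape[1] != 2:
                raise ValueError(f"group {g}: sites must be (n, 2)")
            if len(xy) > 1:
                d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
                if d.max() >= self.max_separation_um:
                    raise ValueError(
                        f"group {g}: max pairwise site distance {d.max():.1f} um "
                        f">= {self.max_separation_um} um"
                    )
            self.sites[g] = xy

    @property
    def group_ids(self) -> list[int]:
        return sorted(self.sites)

    def repeat_counts(self) -> pd.Series:
        return self.onsets.groupby("group_id").size()

    def sites_frame(self) -> pd.DataFrame:
        rows = [
            (g, x, y) for g in self.group_ids for x, y in self.sites[g]
        ]
        return pd.DataFrame(rows, columns=["group_id", "site_x_um", "site_y_um"])

    @classmethod
    def from_frames(cls, sites: pd.DataFrame, onsets: pd.DataFrame, **kw):
        d = {
            int(g): grp[["site_x_um", "site_y_um"]].to_numpy(float)
            for g, grp in sites.groupby("group_id")
        }
        return cls(sites=d, onsets=onsets.copy(), **kw)


@dataclass
class RepeatResponseTensor:
    """w_rep[(i, g, a)] repeat responses (NaN = absent) and baselines b[(i, g)]."""

    w_rep: np.ndarray          # (n_neurons, n_groups, max_repeats)
    b: np.ndarray              # (n_neurons, n_groups)
    group_ids: np.ndarray
    window: WindowSpec


@dataclass
class PSResponseSet:
    """Per-(neuron, group) PS response statistics.

    w_ps = mu / sigma is defined only where at least ``min_repeats`` repeat
    responses exist and sigma > 0; elsewhere it is NaN.
    """

    mu: np.ndarray
    sigma: np.ndarray
    w_ps: np.ndarray
    n_rep: np.ndarray
    group_ids: np.ndarray
    min_repeats: int = 10

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.w_ps)


@dataclass
class NeuronMasks:
    """Distance-based target / non-target classification per group."""

    d: np.ndarray              # (n_neurons, n_groups) min distance to a site, um
    targets: np.ndarray        # bool (n_neurons, n_groups)
    non_targets: np.ndarray    # bool (n_neurons, n_groups)
    group_ids: np.ndarray
    cross_day: bool = False


@dataclass
class ConnectivityMatrices:
    """Masked causal-connectivity matrices and group totals (NaN = absent)."""

    W: np.ndarray | None
    dW: np.ndarray | None
    dps_all: np.ndarray | None
    group_total: np.ndarray | None       # W~_g  = sum of target PS responses
    group_total_delta: np.ndarray | None  # dW~_g = sum of target dPS responses
    group_ids: np.ndarray

    def to_long(self, which: str = "W") -> pd.DataFrame:
        mat = getattr(self, which)
        if mat is None:
            raise ValueError(f"{which} not computed")
        ii, gg = np.nonzero(np.isfinite(mat))
        return pd.DataFrame(
            {"neuron_id": ii, "group_id": self.group_ids[gg], "value": mat[ii, gg]}
        )


def repeat_response(
    traces: np.ndarray,
    frame_rate: float,
    groups: PhotostimGroupSet,
    masks: NeuronMasks | None = None,
    window: WindowSpec = WindowSpec(),
) -> RepeatResponseTensor:
    """Repeat responses from raw fluorescence traces.

    w_rep = (after-window mean - before-window mean) / b, with b the
    repeat-averaged before-window mean per (neuron, group). Windows are
    half-open: before = [-before, 0) relative to onset; after =
    (stim, stim + after]. A neuron that was a target of the immediately
    preceding stimulation event is excluded from the current one (it often
    remains elevated). Non-positive baselines invalidate the (i, g) entry.
    Repeats whose windows extend past the trace are dropped.
    """
    traces = np.asarray(traces, float)
    n_neurons, n_frames = traces.shape
    times = np.arange(n_frames) / frame_rate
    gids = np.asarray(groups.group_ids)
    gpos = {g: k for k, g in enumerate(gids)}
    counts = groups.onsets.groupby("group_id").size()
    max_rep = int(counts.max())

    diffs = np.full((n_neurons, len(gids), max_rep), np.nan)
    befores = np.full_like(diffs, np.nan)
    rep_counter = {g: 0 for g in gids}

    onsets = groups.onsets.sort_values("onset_s")
    prev_targets: np.ndarray | None = None
    n_dropped = 0
    for _, row in onsets.iterrows():
        g = int(row["group_id"])
        onset = float(row["onset_s"])
        a = rep_counter[g]
        rep_counter[g] += 1
        sel_before = (times >= onset - window.before) & (times < onset)
        off = onset + window.stim
        sel_after = (times > off) & (times <= off + window.after)
        if not (sel_before.any() and sel_after.any()) or off + window.after > times[-1]:
            n_dropped += 1
            prev_targets = masks.targets[:, gpos[g]] if masks is not None else None
            continue
        before = traces[:, sel_before].mean(axis=1)
        after = traces[:, sel_after].mean(axis=1)
        d = after - before
        bef = before.copy()
        if prev_targets is not None:
            d[prev_targets] = np.nan
            bef[prev_targets] = np.nan
        diffs[:, gpos[g], a] = d
        befores[:, gpos[g], a] = bef
        prev_targets = masks.targets[:, gpos[g]] if masks is not None else None
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} repeats with windows outside the trace")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        b = np.nanmean(befores, axis=2)
    bad_b = ~(b > 0)
    w_rep = diffs / np.where(bad_b, np.nan, b)[:, :, None]
    return RepeatResponseTensor(w_rep=w_rep, b=b, group_ids=gids, window=window)


def ps_response(tensor: RepeatResponseTensor, min_repeats: int = 10) -> PSResponseSet:
    """PS response: repeat mean / repeat s.d. (sample, n-1), thresholded on
    the number of available repeats."""
    w = tensor.w_rep
    n_rep = np.sum(np.isfinite(w), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(w, axis=2)
        sigma = np.nanstd(w, axis=2, ddof=1)
    ok = (n_rep >= min_repeats) & (sigma > 0)
    w_ps = np.where(ok, mu / np.where(sigma > 0, sigma, np.nan), np.nan)
    return PSResponseSet(
        mu=mu, sigma=sigma, w_ps=w_ps, n_rep=n_rep,
        group_ids=tensor.group_ids, min_repeats=min_repeats,
    )


def delta_ps_response(day_a: PSResponseSet, day_b: PSResponseSet) -> np.ndarray:
    """ΔPS response (mu_b - mu_a) / sqrt(sigma_a^2 + sigma_b^2).

    Defined only where both days pass the minimum-repeat threshold. The
    result is antisymmetric under swapping the two days.
    """
    if not np.array_equal(day_a.group_ids, day_b.group_ids):
        common = np.intersect1d(day_a.group_ids, day_b.group_ids)
        if common.size == 0:
            raise ValueError("no common groups between days")
        ia = np.searchsorted(day_a.group_ids, common)
        ib = np.searchsorted(day_b.group_ids, common)
    else:
        ia = ib = slice(None)
    mu_a, mu_b = day_a.mu[:, ia], day_b.mu[:, ib]
    s2 = day_a.sigma[:, ia] ** 2 + day_b.sigma[:, ib] ** 2
    ok = (
        (day_a.n_rep[:, ia] >= day_a.min_repeats)
        & (day_b.n_rep[:, ib] >= day_b.min_repeats)
        & (s2 > 0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = (mu_b - mu_a) / np.sqrt(s2)
    return np.where(ok, delta, np.nan)


def classify_neurons(
    positions: np.ndarray,
    groups: PhotostimGroupSet,
    pair_groups: PhotostimGroupSet | None = None,
) -> NeuronMasks:
    """Target (d < 20 um) / non-target (30 < d < 100 um) masks per group.

    ``d`` is the minimum 2-D Euclidean distance from a neuron to any site of
    the group. With ``pair_groups`` (a second session stimulating the same
    groups) the criterion must hold on both sessions; neurons meeting it on
    only one day are omitted from both masks.
    """
    positions = np.asarray(positions, float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n_neurons, 2)")
    if not np.all(np.isfinite(positions)):
        raise ValueError("missing/non-finite neuron positions")

    def _dist(gs: PhotostimGroupSet) -> np.ndarray:
        cols = []
        for g in gs.group_ids:
            diff = positions[:, None, :] - gs.sites[g][None, :, :]
            cols.append(np.linalg.norm(diff, axis=-1).min(axis=1))
        return np.stack(cols, axis=1)

    d = _dist(groups)
    targets = d < TARGET_RADIUS_UM
    non_targets = (d > NONTARGET_INNER_UM) & (d < NONTARGET_OUTER_UM)
    cross_day = pair_groups is not None
    if cross_day:
        if pair_groups.group_ids != groups.group_ids:
            raise ValueError("paired sessions must stimulate the same groups")
        d2 = _dist(pair_groups)
        targets &= d2 < TARGET_RADIUS_UM
        non_targets &= (d2 > NONTARGET_INNER_UM) & (d2 < NONTARGET_OUTER_UM)
    return NeuronMasks(
        d=d, targets=targets, non_targets=non_targets,
        group_ids=np.asarray(groups.group_ids), cross_day=cross_day,
    )


def _group_total(values: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Sum of target-neuron values per group, skipping absent entries."""
    tot = np.zeros(values.shape[1])
    for k in range(values.shape[1]):
        v = values[targets[:, k], k]
        v = v[np.isfinite(v)]
        if v.size == 0:
            warnings.warn(f"group index {k}: no responding target neurons; total 0")
        else:
            tot[k] = v.sum()
    return tot


def connectivity_matrices(
    ps_sets: PSResponseSet | tuple[PSResponseSet, PSResponseSet],
    masks: NeuronMasks,
) -> ConnectivityMatrices:
    """Causal connectivity: PS responses restricted to non-target neurons.

    With a single PS set, returns W and the target group totals W~_g. With
    a pair (day a, day b), additionally returns dW (ΔPS restricted to
    non-targets), dps_all (ΔPS for any neuron) and dW~_g.
    """
    if isinstance(ps_sets, PSResponseSet):
        ps = ps_sets
        W = np.where(masks.non_targets, ps.w_ps, np.nan)
        return ConnectivityMatrices(
            W=W, dW=None, dps_all=None,
            group_total=_group_total(ps.w_ps, masks.targets),
            group_total_delta=None, group_ids=masks.group_ids,
        )
    ps_a, ps_b = ps_sets
    delta = delta_ps_response(ps_a, ps_b)
    W = np.where(masks.non_targets, ps_a.w_ps, np.nan)
    dW = np.where(masks.non_targets, delta, np.nan)
    return ConnectivityMatrices(
        W=W, dW=dW, dps_all=delta,
        group_total=_group_total(ps_a.w_ps, masks.targets),
        group_total_delta=_group_total(delta, masks.targets),
        group_ids=masks.group_ids,
    )
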