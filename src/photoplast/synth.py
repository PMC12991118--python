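"""Ground-truth synthetic circuits, BCI sessions, and photostimulation blocks.

The generator emulates the statistical structure the analysis stages
assume, with every quantity of interest known exactly:

* distance-dependent connectivity -- excitatory within an excitation
  radius (~60 um), weak/negative beyond, plus optional planted structure
  (like-to-like coupling between reward-tuned neurons; broad excitation
  from pretrial-tuned neurons) that the regression stage should recover;
* epoch-tuned trial activity tiling the trial (pretrial / early / late /
  reward / untuned neurons);
* within-session CN activity growth via a per-trial gain schedule, with
  trial events produced by the actual closed loop;
* photostimulation blocks: direct drive to targets, one-step propagation
  of the true weights to everyone else, repeat-to-repeat noise.

Calcium indicator dynamics are approximated by a causal exponential
filter (GCaMP6s-like decay, default 1 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import bci as _bci
from .bci import BCIConfig, Thresholds, compute_thresholds, run_closed_loop
from .connectivity import PhotostimGroupSet, TARGET_RADIUS_UM
from .session import SessionRecord

__all__ = [
    "CircuitConfig",
    "SyntheticCircuit",
    "SessionSimConfig",
    "PhotostimSimConfig",
    "sample_circuit",
    "simulate_session",
    "sample_groups",
    "simulate_photostim_block",
    "simulate_paired_blocks",
    "default_schedule",
]

EPOCH_LABELS = ("pre", "early", "late", "rew", "untuned")


@dataclass(frozen=True)
class CircuitConfig:
    n_neurons: int = 500
    fov_um: float = 1000.0
    excitation_radius: float = 60.0   # um; mean weight changes sign here
    w_amp: float = 0.3                # kernel amplitude at distance 0
    w_sigma_exc: float = 25.0         # um, excitatory Gaussian width
    w_sigma_inh: float = 80.0         # um, inhibitory surround Gaussian width
    weight_noise: float = 0.05
    # planted regression structure
    like_to_like_rew: float = 0.05    # extra weight ~ rew_i * rew_j
    pretrial_target_gain: float = 0.05  # extra weight from pretrial-tuned senders
    epoch_probs: tuple = (0.15, 0.2, 0.15, 0.2, 0.3)  # pre/early/late/rew/untuned
    tuning_amp_mean: float = 0.6
    tuning_amp_sd: float = 0.2


@dataclass
class SyntheticCircuit:
    positions: np.ndarray       # (n, 2) um
    weights: np.ndarray         # (n, n), weights[i, j] = influence of j on i
    epoch_label: np.ndarray     # (n,) in EPOCH_LABELS
    tuning_amp: np.ndarray      # (n,) drive amplitude of the tuned epoch
    cn_index: int
    cfg: CircuitConfig
    seed: int

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    def epoch_amp(self, epoch: str) -> np.ndarray:
        """Per-neuron drive amplitude for one epoch (0 if tuned elsewhere)."""
        return np.where(self.epoch_label == epoch, self.tuning_amp, 0.0)


def _distance_kernel(d: np.ndarray, cfg: CircuitConfig) -> np.ndarray:
    """Mean weight vs distance: Gaussian center-surround, crossing zero at
    the excitation radius."""
    r2 = cfg.excitation_radius**2
    c = np.exp(-r2 / (2 * cfg.w_sigma_exc**2)) / np.exp(-r2 / (2 * cfg.w_sigma_inh**2))
    return cfg.w_amp * (
        np.exp(-(d**2) / (2 * cfg.w_sigma_exc**2))
        - c * np.exp(-(d**2) / (2 * cfg.w_sigma_inh**2))
    )


def sample_circuit(cfg: CircuitConfig = CircuitConfig(), seed: int = 0) -> SyntheticCircuit:
    """Sample positions, distance-dependent ground-truth weights, and epoch
    tuning assignments; fully reproducible from the seed."""
    rng = np.random.default_rng(seed)
    n = cfg.n_neurons
    positions = rng.uniform(0, cfg.fov_um, size=(n, 2))
    labels = rng.choice(EPOCH_LABELS, size=n, p=cfg.epoch_probs)
    amps = np.abs(rng.normal(cfg.tuning_amp_mean, cfg.tuning_amp_sd, size=n))
    amps[labels == "untuned"] = 0.0

    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    W = _distance_kernel(d, cfg) + cfg.weight_noise * rng.standard_normal((n, n))
    rew = np.where(labels == "rew", amps, 0.0)
    pre = np.where(labels == "pre", amps, 0.0)
    W += cfg.like_to_like_rew * np.outer(rew, rew)
    W += cfg.pretrial_target_gain * pre[None, :]  # broad excitation from pretrial senders
    np.fill_diagonal(W, 0.0)

    late_idx = np.nonzero(labels == "late")[0]
    cn = int(late_idx[0]) if late_idx.size else 0
    return SyntheticCircuit(
        positions=positions, weights=W, epoch_label=labels,
        tuning_amp=amps, cn_index=cn, cfg=cfg, seed=seed,
    )


@dataclass(frozen=True)
class SessionSimConfig:
    frame_rate: float = 20.0
    spont_duration_s: float = 60.0
    n_trials: int = 30
    cn_peak_dff: float = 0.5          # CN drive at schedule gain 1, dF/F units
    cn_ramp_s: float = 1.5
    drive_noise: float = 0.05         # per-frame drive noise, dF/F units
    amp_jitter: float = 0.2           # trial-to-trial epoch amplitude jitter
    recurrent_gain: float = 0.3       # one-step propagation strength
    calcium_tau_s: float = 1.0        # indicator decay (GCaMP6s-like)
    f0_lo: float = 80.0
    f0_hi: float = 120.0
    rew_drive_s: float = 1.2          # reward-consumption drive duration; kept
                                      # shorter than the ITI so the next
                                      # trial's pretrial window stays clean
    spont_event_rate_hz: float = 0.1
    spont_event_amp: float = 1.0
    bci: BCIConfig = field(default_factory=BCIConfig)


def default_schedule(n_trials: int, lo: float = 0.05, hi: float = 1.0) -> np.ndarray:
    """Rising CN gain schedule emulating within-session learning."""
    return np.linspace(lo, hi, n_trials)


def _calcium_filter(x: np.ndarray, tau_s: float, frame_rate: float) -> np.ndarray:
    """Causal exponential filter along the last axis, unit DC gain."""
    a = np.exp(-1.0 / (tau_s * frame_rate))
    return lfilter([1 - a], [1, -a], x, axis=-1)


def _spontaneous_activity(
    rng: np.random.Generator, n: int, n_frames: int, cfg: SessionSimConfig
) -> np.ndarray:
    """Sparse transients, calcium-filtered; dF/F units, baseline 0."""
    p = cfg.spont_event_rate_hz / cfg.frame_rate
    events = rng.random((n, n_frames)) < p
    amp = cfg.spont_event_amp * rng.exponential(1.0, size=(n, n_frames))
    drive = np.where(events, amp, 0.0) / (1.0 / (cfg.calcium_tau_s * cfg.frame_rate))
    act = _calcium_filter(drive, cfg.calcium_tau_s, cfg.frame_rate)
    return act + 0.5 * cfg.drive_noise * rng.standard_normal((n, n_frames))


def _simulate_cn_trace(
    rng: np.random.Generator,
    schedule: np.ndarray,
    thr_dff: tuple[float, float],
    cfg: SessionSimConfig,
) -> np.ndarray:
    """Frame-by-frame CN dF/F trace driven through the BCI state machine.

    Replicates the closed-loop trial sequencing so that the CN is ramped
    while a trial is open and silenced between trials; the authoritative
    trial events are re-derived afterwards by running the actual closed
    loop over the returned trace.
    """
    b = cfg.bci
    dt = 1.0 / cfg.frame_rate
    fl, fu = thr_dff
    n_trials = len(schedule)
    decay = np.exp(-dt / 0.3)         # fast post-trial shutoff of the drive
    filt_a = np.exp(-dt / (cfg.calcium_tau_s * cfg.frame_rate * dt))  # = exp(-1/(tau*fr))

    max_frames = int(
        (n_trials + 1)
        * (b.timeout + b.fl_dwell + b.intertrial_delay + b.port_return_time + 1.0)
        * cfg.frame_rate
    )
    trace = np.zeros(max_frames)
    dwell_frames = max(1, int(round(b.fl_dwell / dt)))
    timeout_frames = int(round(b.timeout / dt))

    state = "trial"
    trial = 0
    frame_in_trial = 0
    displacement = 0.0
    dwell = 0
    delay_left = 0
    level = 0.0                        # filtered CN activity (dF/F)
    k = 0
    while trial < n_trials and k < max_frames:
        if state == "trial":
            peak = schedule[trial] * cfg.cn_peak_dff
            ramp = min(1.0, (frame_in_trial + 1) * dt / cfg.cn_ramp_s)
            target = peak * ramp
            level = filt_a * level + (1 - filt_a) * target
        else:
            level *= decay
        h = level + 0.3 * cfg.drive_noise * rng.standard_normal()
        trace[k] = h

        if state == "trial":
            v = np.clip(b.v_max * (h - fl) / (fu - fl), 0.0, b.v_max)
            displacement += b.step_size * 1e-3 * b.gain * v * dt
            frame_in_trial += 1
            if displacement >= b.reward_distance:
                state = "dwell"
                dwell = 0
                trial += 1
            elif frame_in_trial >= timeout_frames:
                state = "delay"
                delay_left = int(round(b.port_return_time / dt))
                trial += 1
        elif state == "dwell":
            dwell = dwell + 1 if h < fl else 0
            if dwell >= dwell_frames:
                state = "delay"
                delay_left = int(round((b.intertrial_delay + b.port_return_time) / dt))
        else:
            delay_left -= 1
            if delay_left <= 0:
                state = "trial"
                frame_in_trial = 0
                displacement = 0.0
        k += 1
    return trace[: k + int(2 * cfg.frame_rate)]


def simulate_session(
    circuit: SyntheticCircuit,
    schedule: np.ndarray | None = None,
    cfg: SessionSimConfig = SessionSimConfig(),
    seed: int = 0,
    session_id: str = "synthetic",
) -> SessionRecord:
    """Simulate a closed-loop BCI session over a ground-truth circuit.

    The CN trace is generated through the trial state machine with a
    per-trial gain schedule (a rising schedule produces within-session CN
    growth and an increasing hit rate); trial events are then produced by
    the actual closed loop. Epoch-tuned neurons receive drives tiling each
    realized trial, filtered through the true weights (one-step
    propagation), calcium dynamics, and noise.
    """
    rng = np.random.default_rng(seed)
    n = circuit.n_neurons
    fr = cfg.frame_rate
    if schedule is None:
        schedule = default_schedule(cfg.n_trials)
    schedule = np.asarray(schedule, float)

    f0 = rng.uniform(cfg.f0_lo, cfg.f0_hi, size=n)

    # spontaneous period -> thresholds from the CN's raw trace
    n_spont = int(cfg.spont_duration_s * fr)
    spont = _spontaneous_activity(rng, n, n_spont, cfg)
    spont_raw = f0[:, None] * (1.0 + spont)
    thr = compute_thresholds(spont_raw[circuit.cn_index])
    # dF/F-space thresholds for the generator's internal loop
    fl_dff = thr.FL / f0[circuit.cn_index] - 1.0
    fu_dff = thr.FU / f0[circuit.cn_index] - 1.0

    cn_trace = _simulate_cn_trace(rng, schedule, (fl_dff, fu_dff), cfg)
    T = len(cn_trace)
    cn_raw = f0[circuit.cn_index] * (1.0 + cn_trace)
    events, _ = run_closed_loop(cn_raw, thr, cfg.bci)
    if len(events) == 0:
        raise RuntimeError("generator produced no completed trials")

    # epoch-tuned drives aligned to the realized events
    times = np.arange(T) / fr
    drive = np.zeros((n, T))
    amp = {e: circuit.epoch_amp(e) for e in ("pre", "early", "late", "rew")}
    for k in range(len(events)):
        start = events.trial_start_times[k]
        hit = events.outcomes[k] == "hit"
        rew = events.reward_times[k]
        end = rew if hit else start + events.durations[k]
        jit = 1.0 + cfg.amp_jitter * rng.standard_normal(4)
        wins = {
            # preparatory drive spans the whole pre-start period; the
            # analysis window (-2, -1) s samples its plateau
            "pre": (start - 2.5, start - 0.3),
            "early": (start, (rew - 1.0) if hit else end),
            "late": (rew - 1.0, rew) if hit else None,
            "rew": (rew, rew + cfg.rew_drive_s) if hit else None,
        }
        for j, epoch in enumerate(("pre", "early", "late", "rew")):
            w = wins[epoch]
            if w is None or w[1] <= w[0]:
                continue
            sel = (times > w[0]) & (times <= w[1])
            drive[:, sel] += np.outer(amp[epoch] * jit[j], np.ones(sel.sum()))

    # one-step propagation through the true weights, then calcium + noise
    act = drive + cfg.recurrent_gain * (circuit.weights @ drive)
    act = _calcium_filter(act, cfg.calcium_tau_s, fr)
    act += cfg.drive_noise * rng.standard_normal((n, T))
    act[circuit.cn_index] = cn_trace

    raw = f0[:, None] * (1.0 + act)
    return SessionRecord.from_raw(
        raw=raw, frame_rate=fr, events=events, cn_index=circuit.cn_index,
        positions=circuit.positions, session_id=session_id, spont_raw=spont_raw,
    )


def sample_groups(
    positions: np.ndarray,
    n_groups: int = 100,
    group_size: int = 10,
    max_sep_um: float = 400.0,
    seed: int = 0,
    isi_s: float = 0.6,
    max_tries: int = 10_000,
) -> PhotostimGroupSet:
    """Random stimulation groups with the pairwise-separation constraint.

    Each group picks a random seed neuron and draws the remaining sites
    from neurons within max_sep/2 of it, guaranteeing every pairwise
    distance < max_sep. Raises if the constraint cannot be met.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, float)
    n = len(positions)
    sites: dict[int, np.ndarray] = {}
    tries = 0
    g = 0
    while g < n_groups:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not sample {n_groups} groups of {group_size} under "
                f"max separation {max_sep_um} um after {max_tries} tries"
            )
        center = rng.integers(n)
        d = np.linalg.norm(positions - positions[center], axis=1)
        cand = np.nonzero(d < 0.499 * max_sep_um)[0]
        if cand.size < group_size:
            continue
        chosen = rng.choice(cand, size=group_size, replace=False)
        sites[g] = positions[chosen]
        g += 1
    onsets = pd.DataFrame({"group_id": [], "onset_s": []})
    return PhotostimGroupSet(
        sites=sites, onsets=onsets, max_separation_um=max_sep_um, isi_s=isi_s,
    )


@dataclass(frozen=True)
class PhotostimSimConfig:
    frame_rate: float = 20.0
    isi_s: float = 0.6
    stim_duration_s: float = 0.1
    pre_pad_s: float = 2.0
    direct_amp: float = 0.5           # dF/F response of a target neuron
    direct_amp_jitter: float = 0.1
    prop_gain: float = 1.0            # scales one-step propagation to non-targets
    repeat_noise: float = 0.1         # per-(neuron, event) response noise, dF/F
    frame_noise: float = 0.02
    f0_lo: float = 80.0
    f0_hi: float = 120.0


def simulate_photostim_block(
    circuit: SyntheticCircuit,
    groups: PhotostimGroupSet,
    repeats: int = 20,
    cfg: PhotostimSimConfig = PhotostimSimConfig(),
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, PhotostimGroupSet]:
    """Raw traces for a photostimulation session.

    Groups are stimulated sequentially every ``isi_s`` within each repeat
    cycle. Targets (within 20 um of a site) receive the direct drive;
    every other neuron responds with prop_gain * sum over targets of the
    true weight from that target, plus repeat-to-repeat Gaussian noise.
    Returns (raw traces, group set with populated onset times).
    """
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = circuit.weights
    n = circuit.n_neurons
    fr = cfg.frame_rate
    gids = groups.group_ids
    n_events = repeats * len(gids)
    T = int((cfg.pre_pad_s + n_events * cfg.isi_s + 2.0) * fr)
    times = np.arange(T) / fr

    target_masks = {}
    expected = {}
    for g in gids:
        d = np.linalg.norm(
            circuit.positions[:, None] - groups.sites[g][None], axis=-1
        ).min(axis=1)
        tm = d < TARGET_RADIUS_UM
        target_masks[g] = tm
        expected[g] = cfg.prop_gain * weights[:, tm].sum(axis=1)

    dff = cfg.frame_noise * rng.standard_normal((n, T))
    rows = []
    e = 0
    for _ in range(repeats):
        for g in gids:
            onset = cfg.pre_pad_s + e * cfg.isi_s
            rows.append((g, onset))
            tm = target_masks[g]
            resp = expected[g] + cfg.repeat_noise * rng.standard_normal(n)
            resp = resp.copy()
            resp[tm] = cfg.direct_amp * (
                1.0 + cfg.direct_amp_jitter * rng.standard_normal(tm.sum())
            )
            off = onset + cfg.stim_duration_s
            sel = (times > onset) & (times <= off + 0.3)
            dff[:, sel] += resp[:, None]
            e += 1
    onsets = pd.DataFrame(rows, columns=["group_id", "onset_s"])
    out_groups = PhotostimGroupSet(
        sites=dict(groups.sites), onsets=onsets,
        max_separation_um=groups.max_separation_um, isi_s=cfg.isi_s,
        stim_duration_s=cfg.stim_duration_s,
    )
    f0 = rng.uniform(cfg.f0_lo, cfg.f0_hi, size=n)
    raw = f0[:, None] * (1.0 + dff)
    return raw, out_groups


def simulate_paired_blocks(
    circuit: SyntheticCircuit,
    groups: PhotostimGroupSet,
    true_dw: np.ndarray | None = None,
    repeats: int = 20,
    cfg: PhotostimSimConfig = PhotostimSimConfig(),
    seed: int = 0,
):
    """Two-day photostimulation mode: day b uses weights + true_dw.

    Returns ((raw_a, groups_a), (raw_b, groups_b)).
    """
    if true_dw is None:
        true_dw = np.zeros_like(circuit.weights)
    day_a = simulate_photostim_block(circuit, groups, repeats, cfg, seed=seed)
    day_b = simulate_photostim_block(
        circuit, groups, repeats, cfg, seed=seed + 1,
        weights=circuit.weights + true_dw,
    )
    return day_a, day_b
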