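"""Hand-wired preparatory circuit model of BCI learning.

A small rectified-linear rate network captures the transition from
preparatory (pretrial) to trial-period dynamics:

    h_{t+1} = h_t + (dt/tau) * (-h_t + W_rec phi(h_t) + W_inp x_{t+1}),
    phi(x) = max(x, 0).

Populations: a pretrial population (10 neurons) holding low-dimensional
preparatory activity through recurrent self-excitation, a downstream TRIAL
population (10 neurons) driven by the trial input and by the pretrial
population, five identical 4-neuron modules that are initially untuned,
and one reward neuron. The conditioned neuron (CN) sits inside the first
module, outside the preparatory-to-trial pathway, with a weak trial
response that stays below the reward-port movement threshold before
learning.

Learning is not trained online: connectivity is edited directly.

* ``broadcast``: (1) connections from the pretrial population onto one
  neuron per module are increased, making those neurons pretrial-tuned
  ("Δpretrial" neurons); (2) connections from the Δpretrial neurons onto
  all downstream populations are strengthened.
* ``feedback``: (1) as above, plus strengthened connections from the
  Δpretrial neurons back onto the pretrial population, which incorporates
  them into the preparatory subnetwork; because pretrial neurons project
  broadly, Δpretrial neurons then effectively project broadly as well.

Either edit pushes the CN's late-trial activity above the movement
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import regression
from .connectivity import NeuronMasks

__all__ = [
    "PreparatoryConfig",
    "PreparatoryNetwork",
    "PopulationTrace",
    "build_network",
    "apply_learning",
    "simulate_trial",
    "cn_late_activity",
    "insilico_photostim_rect",
    "model_delta_connectivity_fit",
]

MANIPULATIONS = ("none", "broadcast", "feedback")


@dataclass(frozen=True)
class PreparatoryConfig:
    n_pretrial: int = 10
    n_trial: int = 10
    n_modules: int = 5
    module_size: int = 4
    n_reward: int = 1
    dt: float = 0.01
    tau: float = 0.1
    pretrial_steps: int = 100          # 1 s per period
    trial_steps: int = 100
    movement_threshold: float = 0.6    # CN late activity required for port movement
    # baseline wiring (total summed weight per projection)
    j_pre_self: float = 0.8            # pretrial recurrent self-excitation
    j_pre_to_trial: float = 0.5
    j_pre_broadcast: float = 0.1       # weak widespread pretrial excitation
    j_trial_self: float = 0.5
    j_trial_to_cn: float = 0.3
    j_trial_to_reward: float = 0.5
    input_pre: float = 0.2             # drive to the pretrial population, pretrial period
    input_trial: float = 0.5           # drive to the TRIAL population, trial period
    # learning increments (total summed weight per projection)
    q_pre_to_dpre: float = 0.6         # manipulation 1
    q_dpre_broadcast: float = 0.15     # manipulation 2, per Δpretrial neuron
    q_dpre_feedback: float = 0.09      # alternative variant, per Δpretrial neuron

    @property
    def n_neurons(self) -> int:
        return (
            self.n_pretrial + self.n_trial
            + self.n_modules * self.module_size + self.n_reward
        )

    @property
    def alpha(self) -> float:
        return self.dt / self.tau


@dataclass
class PreparatoryNetwork:
    cfg: PreparatoryConfig
    W_rec: np.ndarray
    W_inp: np.ndarray                  # (n, 2): channel 0 pretrial, 1 trial
    pre: np.ndarray                    # index arrays per population
    trial: np.ndarray
    modules: list[np.ndarray]
    reward: np.ndarray
    dpre: np.ndarray                   # Δpretrial designates, one per module
    cn: int
    manipulation: str = "none"

    def copy(self) -> "PreparatoryNetwork":
        return PreparatoryNetwork(
            cfg=self.cfg, W_rec=self.W_rec.copy(), W_inp=self.W_inp.copy(),
            pre=self.pre, trial=self.trial, modules=self.modules,
            reward=self.reward, dpre=self.dpre, cn=self.cn,
            manipulation=self.manipulation,
        )

    @property
    def downstream(self) -> np.ndarray:
        """Everything below the preparatory population."""
        return np.concatenate([self.trial, np.concatenate(self.modules), self.reward])


@dataclass
class PopulationTrace:
    """Per-population mean activity over a simulated trial."""

    time_s: np.ndarray
    traces: pd.DataFrame               # columns: pre, trial, dpre, cn, reward
    h: np.ndarray                      # full (T+1, n) trajectory


def build_network(cfg: PreparatoryConfig = PreparatoryConfig()) -> PreparatoryNetwork:
    """Wire the baseline (pre-learning) circuit.

    The pretrial population self-excites (preparatory persistence) and
    drives the TRIAL population; the TRIAL population weakly drives the CN
    and the reward neuron. Modules receive nothing, hence are untuned, and
    the CN's late response stays below the movement threshold.
    """
    n = cfg.n_neurons
    i0 = 0
    pre = np.arange(i0, i0 + cfg.n_pretrial)
    i0 += cfg.n_pretrial
    trial = np.arange(i0, i0 + cfg.n_trial)
    i0 += cfg.n_trial
    modules = []
    for m in range(cfg.n_modules):
        modules.append(np.arange(i0, i0 + cfg.module_size))
        i0 += cfg.module_size
    reward = np.arange(i0, i0 + cfg.n_reward)
    dpre = np.array([mod[0] for mod in modules])
    cn = int(modules[0][1])

    W = np.zeros((n, n))
    W[np.ix_(pre, pre)] = cfg.j_pre_self / cfg.n_pretrial
    # widespread (weak) pretrial excitation of the whole downstream circuit
    downstream = np.concatenate([trial, np.concatenate(modules), reward])
    W[np.ix_(downstream, pre)] = cfg.j_pre_broadcast / cfg.n_pretrial
    W[np.ix_(trial, pre)] = cfg.j_pre_to_trial / cfg.n_pretrial
    W[np.ix_(trial, trial)] = cfg.j_trial_self / cfg.n_trial
    W[cn, trial] = cfg.j_trial_to_cn / cfg.n_trial
    W[np.ix_(reward, trial)] = cfg.j_trial_to_reward / cfg.n_trial
    np.fill_diagonal(W, 0.0)

    W_inp = np.zeros((n, 2))
    W_inp[pre, 0] = cfg.input_pre
    W_inp[trial, 1] = cfg.input_trial
    return PreparatoryNetwork(
        cfg=cfg, W_rec=W, W_inp=W_inp, pre=pre, trial=trial,
        modules=modules, reward=reward, dpre=dpre, cn=cn,
    )


def apply_learning(
    network: PreparatoryNetwork, manipulation: str
) -> PreparatoryNetwork:
    """Return a learned copy of the network; only the enumerated weight
    entries change."""
    if manipulation not in MANIPULATIONS:
        raise ValueError(f"manipulation must be one of {MANIPULATIONS}")
    net = network.copy()
    net.manipulation = manipulation
    if manipulation == "none":
        return net
    cfg = net.cfg
    # manipulation 1: pretrial population -> one neuron per module
    net.W_rec[np.ix_(net.dpre, net.pre)] += cfg.q_pre_to_dpre / cfg.n_pretrial
    if manipulation == "broadcast":
        # manipulation 2: Δpretrial -> all downstream populations
        ds = net.downstream
        for j in net.dpre:
            rows = ds[ds != j]
            net.W_rec[rows, j] += cfg.q_dpre_broadcast
    else:  # feedback variant
        net.W_rec[np.ix_(net.pre, net.dpre)] += cfg.q_dpre_feedback
    return net


def _step(net: PreparatoryNetwork, h: np.ndarray, x: np.ndarray) -> np.ndarray:
    cfg = net.cfg
    h_next = h + cfg.alpha * (-h + net.W_rec @ np.maximum(h, 0.0) + net.W_inp @ x)
    if not np.all(np.isfinite(h_next)):
        raise FloatingPointError("non-finite state in preparatory model")
    return h_next


def simulate_trial(net: PreparatoryNetwork) -> PopulationTrace:
    """Deterministic trial: pretrial drive then trial drive, 1 s each."""
    cfg = net.cfg
    T = cfg.pretrial_steps + cfg.trial_steps
    h = np.zeros(cfg.n_neurons)
    H = np.zeros((T + 1, cfg.n_neurons))
    for t in range(T):
        x = np.array([1.0, 0.0]) if t < cfg.pretrial_steps else np.array([0.0, 1.0])
        h = _step(net, h, x)
        H[t + 1] = h
    time_s = np.arange(T + 1) * cfg.dt
    traces = pd.DataFrame(
        {
            "pre": H[:, net.pre].mean(axis=1),
            "trial": H[:, net.trial].mean(axis=1),
            "dpre": H[:, net.dpre].mean(axis=1),
            "cn": H[:, net.cn],
            "reward": H[:, net.reward].mean(axis=1),
        }
    )
    return PopulationTrace(time_s=time_s, traces=traces, h=H)


def _period_means(trace: PopulationTrace, cfg: PreparatoryConfig):
    pre_win = slice(1, cfg.pretrial_steps + 1)
    late_win = slice(cfg.pretrial_steps + 1 + cfg.trial_steps // 2, None)
    return trace.h[pre_win].mean(axis=0), trace.h[late_win].mean(axis=0)


def cn_late_activity(net: PreparatoryNetwork) -> float:
    """Mean CN activity over the second half of the trial period."""
    trace = simulate_trial(net)
    _, late = _period_means(trace, net.cfg)
    return float(late[net.cn])


def insilico_photostim_rect(
    net: PreparatoryNetwork,
    h_pert: float = 1.0,
    before_steps: int = 100,
    clamp_steps: int = 100,
) -> np.ndarray:
    """Deterministic single-neuron photostimulation map for the rectified
    network (no task input): W~[i, g] = during-clamp mean minus preceding
    mean of neuron i when neuron g is clamped to h_pert. Diagonal is NaN."""
    cfg = net.cfg
    n = cfg.n_neurons
    x0 = np.zeros(2)
    out = np.zeros((n, n))
    for g in range(n):
        h = np.zeros(n)
        before_acc = np.zeros(n)
        for _ in range(before_steps):
            h = _step(net, h, x0)
            before_acc += h
        h[g] = h_pert
        during_acc = np.zeros(n)
        for _ in range(clamp_steps):
            h = _step(net, h, x0)
            h[g] = h_pert
            during_acc += h
        out[:, g] = during_acc / clamp_steps - before_acc / before_steps
    np.fill_diagonal(out, np.nan)
    return out


def model_delta_connectivity_fit(
    net_pre: PreparatoryNetwork,
    net_post: PreparatoryNetwork,
    seed: int = 0,
) -> "regression.MLRFit":
    """Lasso MLR of the model's Δcausal connectivity on tuning regressors.

    Tuning components are (pre, late) period means before learning plus
    their learning-related changes (d_pre, d_late); groups are single
    neurons so no target-response weighting is used. The key signatures of
    the learning edits are positive coefficients on Y:d_pre|X:pre
    (pretrial targets excite Δpretrial non-targets more after learning)
    and on Y:1|X:d_pre (Δpretrial targets excite everything more).
    """
    cfg = net_pre.cfg
    tr_pre = simulate_trial(net_pre)
    tr_post = simulate_trial(net_post)
    p0, l0 = _period_means(tr_pre, cfg)
    p1, l1 = _period_means(tr_post, cfg)
    tuning = pd.DataFrame(
        {"pre": p0, "late": l0, "d_pre": p1 - p0, "d_late": l1 - l0}
    )
    if np.allclose(tuning.std(), 0.0):
        raise ValueError("degenerate tuning variance")

    W0 = insilico_photostim_rect(net_pre)
    W1 = insilico_photostim_rect(net_post)
    dW = W1 - W0

    n = cfg.n_neurons
    eye = np.eye(n, dtype=bool)
    masks = NeuronMasks(
        d=np.where(eye, 0.0, 1e9),
        targets=eye,
        non_targets=~eye,
        group_ids=np.arange(n),
    )
    table = regression.build_tuning_regressors(
        tuning, ps=None, masks=masks, response=dW,
        target_weighting=False, components=("pre", "late", "d_pre", "d_late"),
    )
    X = table.drop(columns=["neuron", "group", "y"])
    return regression.fit_lasso_cv(table["y"].to_numpy(), X, folds=10, seed=seed)
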