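"""Rate-RNN models of BCI learning with selectable plasticity locus.

A vanilla rate network (n hidden "motor cortex" neurons, d upstream input
channels) is trained with backpropagation through time to raise the
activity of a conditioned neuron (CN) toward a target during the late
period of each trial:

    h_{t+1} = h_t + (dt/tau) * (-h_t + phi(a ⊙ (W_rec h_t + W_inp x_{t+1})) + n_t)

with phi = tanh, per-step Gaussian input noise n_t, and excitability a = 1
except in the excitability variant. Credit is routed through a feedback
vector w_back = w_bci + w~ (feedback misalignment, w~ zero at the CN so
w_back·w_bci = 1), which broadens which neurons change while the loss
itself remains the MSE of the true readout w_bci·h against the target.
Plasticity can be restricted to the input weights ("upstream" hypothesis),
the recurrent weights ("local MC" hypothesis), both, per-neuron
excitability, or the recurrent weights of a separate upstream RNN.

In-silico photostimulation clamps one neuron at a time and measures evoked
changes in all others, the model analog of two-photon photostimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .regression import wald_positive_test

__all__ = [
    "RNNConfig",
    "RNNModel",
    "TrainingLog",
    "init_model",
    "step_dynamics",
    "simulate_trial",
    "run_stabilization",
    "select_model_cn",
    "attach_feedback",
    "train_bptt",
    "insilico_photostim",
    "stabilization_correlations",
    "model_connectivity_analysis",
    "loop_input_ratio",
    "scan_learning_rate",
    "run_locus_experiment",
]

LOCI = ("input", "recurrent", "both", "excitability", "upstream_recurrent")


@dataclass(frozen=True)
class RNNConfig:
    n: int = 100
    d: int = 10
    dt: float = 0.01
    tau: float = 0.1
    noise_scale: float = 0.01
    w_rec_scale: float = 0.5
    w_inp_scale: float = 0.1
    nonlinearity: str = "tanh"        # tanh | linear
    h_pert: float = 1.0
    ps_repeats: int = 5
    stabilization_trials: int = 10
    plasticity_locus: str = "recurrent"
    feedback_noise_scale: float = 0.25
    lr: float = 0.05
    pretrial_steps: int = 100         # 1 s of model time at dt = 0.01
    late_steps: int = 100
    input_drive_scale: float = 1.0
    n_upstream: int = 20
    w_csc_scale: float = 0.0          # 0 disables the cortical-subcortical loop

    def __post_init__(self) -> None:
        if self.dt >= self.tau:
            raise ValueError("dt must be smaller than tau")
        if self.n <= 0 or self.d <= 0:
            raise ValueError("n and d must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.plasticity_locus not in LOCI:
            raise ValueError(f"plasticity_locus must be one of {LOCI}")
        if self.nonlinearity not in ("tanh", "linear"):
            raise ValueError("nonlinearity must be 'tanh' or 'linear'")

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    @property
    def trial_steps(self) -> int:
        return self.pretrial_steps + self.late_steps


def _phi(cfg: RNNConfig):
    if cfg.nonlinearity == "tanh":
        return np.tanh, lambda u: 1.0 - np.tanh(u) ** 2
    return (lambda u: u), (lambda u: np.ones_like(u))


@dataclass
class RNNModel:
    cfg: RNNConfig
    W_rec: np.ndarray
    W_inp: np.ndarray
    a_exc: np.ndarray
    x_pre: np.ndarray                  # constant pretrial input drive
    x_late: np.ndarray                 # constant late-period input drive
    cn: int | None = None
    gamma_hat: float | None = None
    w_bci: np.ndarray | None = None
    w_back: np.ndarray | None = None
    # upstream-RNN variant (Eq. 14-style): x -> g (20 units) -> h
    W_rec_up: np.ndarray | None = None
    W_inp_up: np.ndarray | None = None     # g -> h
    W_inp_up_in: np.ndarray | None = None  # x -> g
    # cortical-subcortical loop variant
    W_csc: np.ndarray | None = None

    def copy(self) -> "RNNModel":
        return RNNModel(
            cfg=self.cfg,
            W_rec=self.W_rec.copy(),
            W_inp=self.W_inp.copy(),
            a_exc=self.a_exc.copy(),
            x_pre=self.x_pre.copy(),
            x_late=self.x_late.copy(),
            cn=self.cn,
            gamma_hat=self.gamma_hat,
            w_bci=None if self.w_bci is None else self.w_bci.copy(),
            w_back=None if self.w_back is None else self.w_back.copy(),
            W_rec_up=None if self.W_rec_up is None else self.W_rec_up.copy(),
            W_inp_up=None if self.W_inp_up is None else self.W_inp_up.copy(),
            W_inp_up_in=None if self.W_inp_up_in is None else self.W_inp_up_in.copy(),
            W_csc=None if self.W_csc is None else self.W_csc.copy(),
        )


def init_model(cfg: RNNConfig, seed: int) -> RNNModel:
    """Initialize weights scale/sqrt(fan-in) * N(0, 1) and the two constant
    trial input drives."""
    rng = np.random.default_rng(seed)
    n, d = cfg.n, cfg.d
    W_rec = cfg.w_rec_scale / np.sqrt(n) * rng.standard_normal((n, n))
    W_inp = cfg.w_inp_scale / np.sqrt(d) * rng.standard_normal((n, d))
    x_pre = cfg.input_drive_scale * rng.standard_normal(d)
    x_late = cfg.input_drive_scale * rng.standard_normal(d)
    model = RNNModel(
        cfg=cfg, W_rec=W_rec, W_inp=W_inp, a_exc=np.ones(n),
        x_pre=x_pre, x_late=x_late,
    )
    if cfg.plasticity_locus == "upstream_recurrent":
        m = cfg.n_upstream
        model.W_rec_up = cfg.w_rec_scale / np.sqrt(m) * rng.standard_normal((m, m))
        model.W_inp_up = cfg.w_inp_scale / np.sqrt(m) * rng.standard_normal((n, m))
        model.W_inp_up_in = cfg.w_inp_scale / np.sqrt(d) * rng.standard_normal((m, d))
    if cfg.w_csc_scale > 0:
        model.W_csc = cfg.w_csc_scale / np.sqrt(n) * rng.standard_normal((d, n))
    return model


def step_dynamics(
    model: RNNModel,
    h: np.ndarray,
    x: np.ndarray,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """One Euler step of the rate dynamics (no upstream/loop variants)."""
    cfg = model.cfg
    phi, _ = _phi(cfg)
    if noise is None:
        noise = np.zeros_like(h)
    u = model.a_exc * (model.W_rec @ h + model.W_inp @ x)
    h_next = h + cfg.alpha * (-h + phi(u) + noise)
    if not np.all(np.isfinite(h_next)):
        raise FloatingPointError("non-finite hidden state")
    return h_next


def _trial_inputs(model: RNNModel) -> np.ndarray:
    cfg = model.cfg
    X = np.empty((cfg.trial_steps, cfg.d))
    X[: cfg.pretrial_steps] = model.x_pre
    X[cfg.pretrial_steps:] = model.x_late
    return X


def simulate_trial(model: RNNModel, rng: np.random.Generator, record: bool = False):
    """Forward pass of one trial (hidden state reset to 0 at trial start).

    Returns (H, cache): H is the (T+1, n) hidden trajectory; cache holds
    intermediate quantities for BPTT when ``record`` is True.
    """
    cfg = model.cfg
    phi, _ = _phi(cfg)
    T, n = cfg.trial_steps, cfg.n
    X = _trial_inputs(model)
    noise = cfg.noise_scale * rng.standard_normal((T, n)) if cfg.noise_scale else np.zeros((T, n))

    upstream = model.W_rec_up is not None
    loop = model.W_csc is not None
    H = np.zeros((T + 1, n))
    PRE = np.zeros((T, n))          # W_rec h + (input term), before a ⊙
    G = np.zeros((T + 1, cfg.n_upstream)) if upstream else None
    PREG = np.zeros((T, cfg.n_upstream)) if upstream else None
    XEFF = np.zeros((T, cfg.d)) if loop else None
    VX = np.zeros((T, cfg.d)) if loop else None

    h = H[0]
    g = G[0] if upstream else None
    for t in range(T):
        x = X[t]
        if loop:
            v = model.W_csc @ h + x
            VX[t] = v
            x = np.tanh(v)
            XEFF[t] = x
        if upstream:
            pg = model.W_rec_up @ g + model.W_inp_up_in @ x
            PREG[t] = pg
            g = g + cfg.alpha * (-g + phi(pg))
            G[t + 1] = g
            pre = model.W_rec @ h + model.W_inp_up @ g
        else:
            pre = model.W_rec @ h + model.W_inp @ x
        PRE[t] = pre
        h = h + cfg.alpha * (-h + phi(model.a_exc * pre) + noise[t])
        H[t + 1] = h
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite hidden trajectory")
    cache = {"X": X, "PRE": PRE, "G": G, "PREG": PREG, "XEFF": XEFF, "VX": VX} if record else None
    return H, cache


def run_stabilization(model: RNNModel, rng: np.random.Generator, n_trials: int | None = None):
    """Simulate trials with no weight updates; returns (trials, T+1, n) activity."""
    cfg = model.cfg
    if n_trials is None:
        n_trials = cfg.stabilization_trials
    out = np.empty((n_trials, cfg.trial_steps + 1, cfg.n))
    for k in range(n_trials):
        out[k], _ = simulate_trial(model, rng)
    return out


def select_model_cn(model: RNNModel, stab: np.ndarray) -> tuple[int, float]:
    """CN selection from stabilization activity.

    Eligible neurons have above-median mean pretrial AND late activity; the
    CN minimizes |pretrial - late| among them (ties -> lowest index). The
    target gamma_hat is the 95th percentile of CN activity over the
    stabilization period.
    """
    cfg = model.cfg
    pre = stab[:, 1: cfg.pretrial_steps + 1, :].mean(axis=(0, 1))
    late = stab[:, cfg.pretrial_steps + 1:, :].mean(axis=(0, 1))
    eligible = (pre > np.median(pre)) & (late > np.median(late))
    if not eligible.any():
        raise ValueError("no neuron exceeds both activity medians")
    idx = np.nonzero(eligible)[0]
    cn = int(idx[np.argmin(np.abs(pre[idx] - late[idx]))])
    gamma_hat = float(np.percentile(stab[:, 1:, cn], 95))
    return cn, gamma_hat


def attach_feedback(model: RNNModel, cn: int, gamma_hat: float, seed: int) -> None:
    """Set the readout and the misaligned feedback vector.

    w_bci is one-hot at the CN; w_back = w_bci + w~ with w~ ~ 0.25 N(0,1)
    for all non-CN entries and exactly 0 at the CN, so w_back·w_bci = 1.
    """
    rng = np.random.default_rng(seed)
    cfg = model.cfg
    w_bci = np.zeros(cfg.n)
    w_bci[cn] = 1.0
    w_tilde = cfg.feedback_noise_scale * rng.standard_normal(cfg.n)
    w_tilde[cn] = 0.0
    model.cn = cn
    model.gamma_hat = gamma_hat
    model.w_bci = w_bci
    model.w_back = w_bci + w_tilde


@dataclass
class TrainingLog:
    loss: np.ndarray                   # per trial
    cn_late_activity: np.ndarray       # per trial, mean late-period CN activity
    weight_change_per_neuron: np.ndarray  # sum_j |dW_ij| incoming, total over training
    completion_trial: float            # first trial with CN late >= 0.9 gamma_hat (NaN if never)
    rejected: bool                     # no decrease in loss over the run
    layer_change_norms: dict


def _backward_trial(model: RNNModel, H: np.ndarray, cache: dict):
    """BPTT gradients for one trial with feedback-misaligned credit.

    The loss is the late-period MSE of w_bci·h_t against gamma_hat, but the
    per-step gradient w.r.t. h is routed through w_back.
    """
    cfg = model.cfg
    phi, dphi = _phi(cfg)
    T = cfg.trial_steps
    a = cfg.alpha
    late0 = cfg.pretrial_steps
    X, PRE = cache["X"], cache["PRE"]
    upstream = model.W_rec_up is not None
    loop = model.W_csc is not None

    err = H[1:, model.cn] - model.gamma_hat
    err[:late0] = 0.0
    coef = 2.0 / cfg.late_steps

    Gh = np.zeros((T + 1, cfg.n))              # dL/dh_t
    DELTA = np.zeros((T, cfg.n))               # a_exc ⊙ phi'(u_t) ⊙ dL/dh_t ⊙ alpha
    if upstream:
        Gg = np.zeros((T + 1, cfg.n_upstream))
        DELTAG = np.zeros((T, cfg.n_upstream))
    for t in range(T, 0, -1):
        direct = coef * err[t - 1] * model.w_back
        Gh[t] += direct
        u = model.a_exc * PRE[t - 1]
        delta = a * model.a_exc * dphi(u) * Gh[t]
        DELTA[t - 1] = delta
        back = (1 - a) * Gh[t] + model.W_rec.T @ delta
        if loop:
            dx = model.W_inp.T @ delta
            back += model.W_csc.T @ ((1.0 - cache["XEFF"][t - 1] ** 2) * dx)
        Gh[t - 1] = back
        if upstream:
            Gg[t] += model.W_inp_up.T @ delta
            dg = a * dphi(cache["PREG"][t - 1]) * Gg[t]
            DELTAG[t - 1] = dg
            Gg[t - 1] = (1 - a) * Gg[t] + model.W_rec_up.T @ dg

    grads: dict[str, np.ndarray] = {}
    locus = cfg.plasticity_locus
    if locus in ("recurrent", "both"):
        grads["W_rec"] = DELTA.T @ H[:-1]
    if locus in ("input", "both"):
        xin = cache["XEFF"] if loop else X
        grads["W_inp"] = DELTA.T @ xin
    if locus == "excitability":
        grads["a_exc"] = np.sum(a * dphi(model.a_exc * PRE) * Gh[1:] * PRE, axis=0)
    if locus == "upstream_recurrent":
        grads["W_rec_up"] = DELTAG.T @ cache["G"][:-1]
    loss = float(np.mean((H[late0 + 1:, model.cn] - model.gamma_hat) ** 2))
    return loss, grads


def train_bptt(
    model: RNNModel,
    n_trials: int,
    lr: float,
    rng: np.random.Generator,
    completion_fraction: float = 0.9,
) -> TrainingLog:
    """Train one trial at a time (batch size 1), updating only the weights
    selected by the plasticity locus.

    For the 'both' locus the two learning rates are matched on the first
    trial so the per-trial weight-change norms of W_inp and W_rec are
    comparable. A run whose smoothed loss does not decrease is flagged
    rejected.
    """
    cfg = model.cfg
    if model.cn is None or model.w_back is None:
        raise ValueError("attach_feedback must be called before training")
    losses = np.empty(n_trials)
    cn_late = np.empty(n_trials)
    wchange = np.zeros(cfg.n)
    layer_norms: dict[str, float] = {}
    lr_scale: dict[str, float] = {}

    for trial in range(n_trials):
        H, cache = simulate_trial(model, rng, record=True)
        loss, grads = _backward_trial(model, H, cache)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at trial {trial}")
        losses[trial] = loss
        cn_late[trial] = H[cfg.pretrial_steps + 1:, model.cn].mean()
        if trial == 0 and cfg.plasticity_locus == "both":
            nrm_rec = np.linalg.norm(grads["W_rec"])
            nrm_inp = np.linalg.norm(grads["W_inp"])
            lr_scale["W_inp"] = nrm_rec / nrm_inp if nrm_inp > 0 else 1.0
        for name, grad in grads.items():
            step = lr * lr_scale.get(name, 1.0) * grad
            arr = getattr(model, name)
            arr -= step
            layer_norms[name] = layer_norms.get(name, 0.0) + float(np.linalg.norm(step))
            if name in ("W_rec", "W_inp"):
                wchange += np.abs(step).sum(axis=1)

    k = max(1, min(5, n_trials // 2))
    rejected = bool(np.mean(losses[-k:]) >= np.mean(losses[:k]))
    reached = np.nonzero(cn_late >= completion_fraction * model.gamma_hat)[0]
    completion = float(reached[0] + 1) if reached.size else np.nan
    return TrainingLog(
        loss=losses,
        cn_late_activity=cn_late,
        weight_change_per_neuron=wchange,
        completion_trial=completion,
        rejected=rejected,
        layer_change_norms=layer_norms,
    )


def insilico_photostim(
    model: RNNModel,
    h_pert: float | None = None,
    repeats: int | None = None,
    rng: np.random.Generator | None = None,
    before_steps: int = 100,
    clamp_steps: int = 100,
    clamp_settle: int = 0,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """In-silico photostimulation map W~[i, g].

    Each "group" is a single hidden neuron g whose activity is clamped to
    ``h_pert`` after every update step for ``clamp_steps`` steps; the
    response of neuron i is its mean activity during the clamp minus its
    mean over the preceding ``before_steps`` steps, averaged over repeats.
    Noise enters through the dynamics as during training; no task input is
    given. Diagonal entries (the targets) are NaN. All groups are run as a
    batch, with independent noise. ``clamp_settle`` initial clamp steps can
    be excluded from the during-window average (useful to read out the
    steady state on linear toys).
    """
    cfg = model.cfg
    if h_pert is None:
        h_pert = cfg.h_pert
    if repeats is None:
        repeats = cfg.ps_repeats
    if rng is None:
        rng = np.random.default_rng(0)
    phi, _ = _phi(cfg)
    n = cfg.n
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups, int)
    if np.any((groups < 0) | (groups >= n)):
        raise IndexError("photostimulation group index out of range")
    B = len(groups)
    gsel = (np.arange(B), groups)
    a = cfg.alpha
    x0 = np.zeros(cfg.d)

    resp = np.zeros((n, B))
    for _ in range(repeats):
        H = np.zeros((B, n))
        before_acc = np.zeros((B, n))
        for t in range(before_steps):
            noise = cfg.noise_scale * rng.standard_normal((B, n))
            u = model.a_exc * (H @ model.W_rec.T + x0 @ model.W_inp.T)
            H = H + a * (-H + phi(u) + noise)
            before_acc += H
        before = before_acc / before_steps
        during_acc = np.zeros((B, n))
        H[gsel] = h_pert
        for t in range(clamp_steps):
            noise = cfg.noise_scale * rng.standard_normal((B, n))
            u = model.a_exc * (H @ model.W_rec.T + x0 @ model.W_inp.T)
            H = H + a * (-H + phi(u) + noise)
            H[gsel] = h_pert
            if t >= clamp_settle:
                during_acc += H
        during = during_acc / (clamp_steps - clamp_settle)
        resp += (during - before).T
    resp /= repeats
    resp[groups, np.arange(B)] = np.nan
    return resp


def stabilization_correlations(stab: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of hidden activity over stabilization
    trials (time series concatenated across trials)."""
    n = stab.shape[-1]
    flat = stab[:, 1:, :].reshape(-1, n).T
    return np.corrcoef(flat)


def _offdiag_pairs(C: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = C.shape[0]
    mask = ~np.eye(n, dtype=bool) & np.isfinite(W) & np.isfinite(C)
    return C[mask], W[mask]


def model_connectivity_analysis(
    pairs_before: list[tuple[np.ndarray, np.ndarray]],
    pairs_delta: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict:
    """Positive Wald tests of correlation vs causal connectivity, pooled
    over seeds.

    ``pairs_before`` is a list of (C, W~) matrices per seed;
    ``pairs_delta`` of (ΔC, ΔW~). No control column is needed: direct
    drive is identical for all single-neuron groups.
    """
    xs, ys = [], []
    for C, W in pairs_before:
        c, w = _offdiag_pairs(C, W)
        xs.append(c)
        ys.append(w)
    slope, p = wald_positive_test(np.concatenate(ys), np.concatenate(xs))
    out = {"corr_vs_W": {"slope": slope, "p": p, "n": sum(map(len, xs))}}
    if pairs_delta is not None:
        xs, ys = [], []
        for dC, dW in pairs_delta:
            c, w = _offdiag_pairs(dC, dW)
            xs.append(c)
            ys.append(w)
        slope, p = wald_positive_test(np.concatenate(ys), np.concatenate(xs))
        out["dcorr_vs_dW"] = {"slope": slope, "p": p, "n": sum(map(len, xs))}
    return out


def loop_input_ratio(model: RNNModel, H: np.ndarray, X_task: np.ndarray) -> float:
    """Relative drive of the loop feedback vs the unmodified task inputs:
    sum_t ||W_csc h_t|| / sum_t ||x~_t||."""
    if model.W_csc is None:
        raise ValueError("model has no cortical-subcortical loop (W_csc)")
    denom = float(np.sum(np.linalg.norm(X_task, axis=1)))
    if denom == 0:
        raise ValueError("zero-norm task input")
    num = float(np.sum(np.linalg.norm(H @ model.W_csc.T, axis=1)))
    return num / denom


def _prepare_model(cfg: RNNConfig, seed: int) -> RNNModel:
    model = init_model(cfg, seed)
    rng = np.random.default_rng(seed + 1_000_003)
    stab = run_stabilization(model, rng)
    cn, gamma_hat = select_model_cn(model, stab)
    attach_feedback(model, cn, gamma_hat, seed + 2_000_003)
    return model


def scan_learning_rate(
    cfg: RNNConfig,
    lr_grid: np.ndarray | None = None,
    scan_seeds: tuple[int, ...] = (0, 1, 2),
    n_trials: int = 40,
    max_completion: float = 30.0,
    target_completion: float | None = None,
) -> float:
    """Select the training rate from a log grid.

    Rates are eligible when their median loss decreases and their median
    completion trial (CN late activity reaching 90% of target) is at most
    ``max_completion``. By default the largest eligible rate wins (robust
    across seeds); passing ``target_completion`` instead picks the
    eligible rate whose median completion is closest to that pace, for
    calibrating learning speed against behaviour. If none qualifies, the
    largest rate with a decreasing median loss is used.
    """
    if lr_grid is None:
        lr_grid = np.geomspace(1e-3, 10.0, 9)
    stats = []
    for lr in lr_grid:
        comps, decs = [], []
        for s in scan_seeds:
            model = _prepare_model(cfg, s)
            try:
                log = train_bptt(model, n_trials, lr, np.random.default_rng(s + 7))
            except FloatingPointError:
                comps.append(np.nan)
                decs.append(False)
                continue
            comps.append(log.completion_trial)
            decs.append(not log.rejected)
        stats.append((lr, np.nanmedian(comps) if np.any(np.isfinite(comps)) else np.nan,
                      np.median(decs) > 0))
    eligible = [(lr, med) for lr, med, dec in stats
                if dec and np.isfinite(med) and med <= max_completion]
    if eligible:
        if target_completion is None:
            return float(max(lr for lr, _ in eligible))
        return float(min(eligible, key=lambda t: (abs(t[1] - target_completion),
                                                  -t[0]))[0])
    fallback = [lr for lr, _, dec in stats if dec]
    if not fallback:
        raise RuntimeError("no learning rate produced decreasing loss")
    warnings.warn("no rate met the completion criterion; using largest stable rate")
    return float(max(fallback))


def run_locus_experiment(
    locus: str,
    seeds: range | list[int],
    cfg: RNNConfig | None = None,
    n_trials: int = 40,
    lr: float | None = None,
    photostim: bool = True,
) -> dict:
    """Full per-locus experiment over seeds.

    For each seed: stabilize, pick the CN and target, (optionally) map
    in-silico photostim and correlations before training, train, remap
    after. Returns per-seed completion trials, rejection flags, and the
    (C, W) / (ΔC, ΔW) pairs for discrimination analysis.
    """
    if cfg is None:
        cfg = RNNConfig(plasticity_locus=locus)
    else:
        cfg = replace(cfg, plasticity_locus=locus)
    if lr is None:
        lr = scan_learning_rate(cfg)
    completions, rejected = [], []
    pairs_before, pairs_delta = [], []
    losses, layer_norms = [], []
    for s in seeds:
        model = _prepare_model(cfg, s)
        rng = np.random.default_rng(s + 11)
        if photostim:
            stab_pre = run_stabilization(model, np.random.default_rng(s + 13))
            C_pre = stabilization_correlations(stab_pre)
            W_pre = insilico_photostim(model, rng=np.random.default_rng(s + 17))
        log = train_bptt(model, n_trials, lr, rng)
        completions.append(log.completion_trial)
        rejected.append(log.rejected)
        losses.append(log.loss)
        layer_norms.append(log.layer_change_norms)
        if photostim:
            stab_post = run_stabilization(model, np.random.default_rng(s + 19))
            C_post = stabilization_correlations(stab_post)
            W_post = insilico_photostim(model, rng=np.random.default_rng(s + 23))
            pairs_before.append((C_pre, W_pre))
            pairs_delta.append((C_post - C_pre, W_post - W_pre))
    out = {
        "locus": locus,
        "lr": lr,
        "completion_trials": np.asarray(completions, float),
        "median_completion": float(np.nanmedian(completions)),
        "rejected": np.asarray(rejected, bool),
        "rejection_fraction": float(np.mean(rejected)),
        "loss_curves": np.asarray(losses),
        "layer_change_norms": {
            k: float(np.mean([d[k] for d in layer_norms]))
            for k in (layer_norms[0] if layer_norms else {})
        },
    }
    if photostim:
        out["pairs_before"] = pairs_before
        out["pairs_delta"] = pairs_delta
        out["analysis"] = model_connectivity_analysis(pairs_before, pairs_delta)
    return out
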