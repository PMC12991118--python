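"""End-to-end experiment drivers over synthetic ground truth.

Each driver derives per-stage seeds deterministically from one global
seed, runs the relevant modules, and returns a JSON-serializable report.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import regression, rnn, synth, tuning

__all__ = [
    "ExperimentConfig",
    "stage_seed",
    "run_full_synthetic",
    "run_model_comparison",
    "run_group_size_experiment",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage name mixed with the
    global seed, reduced mod 2^31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class ExperimentConfig:
    n_neurons: int = 300
    n_sessions: int = 3
    n_trials: int = 30
    photostim_repeats: int = 20
    n_groups: int = 100
    group_size: int = 10
    n_bootstrap: int = 2000
    regression_mode: str = "base4"
    # learning-related true weight change for the paired-day block:
    # broad strengthening from pretrial-tuned senders, the motif the
    # Δ-connectivity regression should recover
    dw_pretrial_gain: float = 0.15
    circuit: synth.CircuitConfig = field(default_factory=synth.CircuitConfig)
    session: synth.SessionSimConfig = field(default_factory=synth.SessionSimConfig)
    photostim: synth.PhotostimSimConfig = field(default_factory=synth.PhotostimSimConfig)

    def __post_init__(self) -> None:
        self.circuit = replace(self.circuit, n_neurons=self.n_neurons)
        self.session = replace(self.session, n_trials=self.n_trials)

    def to_dict(self) -> dict:
        def listify(x):
            if isinstance(x, tuple):
                return [listify(v) for v in x]
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            return x

        return listify(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("circuit"), dict) and "epoch_probs" in d["circuit"]:
            d["circuit"]["epoch_probs"] = tuple(d["circuit"]["epoch_probs"])
        for key, sub in (
            ("circuit", synth.CircuitConfig),
            ("session", synth.SessionSimConfig),
            ("photostim", synth.PhotostimSimConfig),
        ):
            if key in d and isinstance(d[key], dict):
                dd = dict(d[key])
                if key == "session" and isinstance(dd.get("bci"), dict):
                    from .bci import BCIConfig

                    dd["bci"] = BCIConfig(**dd["bci"])
                d[key] = sub(**dd)
        return cls(**d)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item(), ndigits)
    return obj


def run_full_synthetic(cfg: ExperimentConfig, seed: int = 0, out: str | None = None) -> dict:
    """Synthetic session(s) -> tuning -> photostim -> W/ΔW -> regression.

    Produces tuning tables, connectivity matrices, MLR fits, and a JSON
    summary with coefficient signs, held-out correlations, and the CN
    bootstrap p-value. Deterministic given the seed.
    """
    circuit = synth.sample_circuit(cfg.circuit, seed=stage_seed(seed, "circuit"))

    # --- sessions and tuning -------------------------------------------------
    sessions, tuning_tables = [], []
    for s in range(cfg.n_sessions):
        rec = synth.simulate_session(
            circuit, cfg=cfg.session,
            seed=stage_seed(seed, f"session{s}"), session_id=f"s{s}",
        )
        table = tuning.epoch_activity(rec)
        if table.empty:
            raise RuntimeError("tuning stage failed: empty epoch-activity table")
        tv = tuning.tuning_and_delta(table, n_neurons=rec.n_neurons)
        sessions.append(rec)
        tuning_tables.append(tv)

    deltas = [tv["d_late"].to_numpy() for tv in tuning_tables]
    cn_ids = [rec.cn_index for rec in sessions]
    percentile, boot_p, _ = tuning.cn_sparsity_bootstrap(
        deltas, cn_ids, n_draws=cfg.n_bootstrap, seed=stage_seed(seed, "bootstrap")
    )

    # --- photostimulation pair ----------------------------------------------
    groups = synth.sample_groups(
        circuit.positions, n_groups=cfg.n_groups, group_size=cfg.group_size,
        seed=stage_seed(seed, "groups"),
    )
    pre_amp = circuit.epoch_amp("pre")
    true_dw = cfg.dw_pretrial_gain * np.tile(pre_amp, (circuit.n_neurons, 1))
    (raw_a, groups_a), (raw_b, groups_b) = synth.simulate_paired_blocks(
        circuit, groups, true_dw=true_dw, repeats=cfg.photostim_repeats,
        cfg=cfg.photostim, seed=stage_seed(seed, "photostim"),
    )
    masks = conn.classify_neurons(circuit.positions, groups_a)
    ps_a = conn.ps_response(conn.repeat_response(raw_a, cfg.photostim.frame_rate, groups_a, masks))
    ps_b = conn.ps_response(conn.repeat_response(raw_b, cfg.photostim.frame_rate, groups_b, masks))
    mats = conn.connectivity_matrices((ps_a, ps_b), masks)

    # --- regression ----------------------------------------------------------
    rec0, tv0 = sessions[0], tuning_tables[0]
    C = regression.pairwise_correlations(rec0.dff)
    a_rho = regression.correlation_regressor(C, ps_a, masks)

    table_w = regression.build_tuning_regressors(
        tv0, ps_a, masks, mode=cfg.regression_mode,
        response=mats.W, control=mats.group_total, correlation_column=a_rho,
    )
    Xw = table_w.drop(columns=["neuron", "group", "y", "A_rho"])
    fit_w = regression.fit_lasso_cv(
        table_w["y"].to_numpy(), Xw, seed=stage_seed(seed, "lasso_w")
    )
    corr_slope, corr_p = regression.wald_positive_test(
        table_w["y"].to_numpy(), table_w["A_rho"].to_numpy(),
        controls=table_w["control"].to_numpy(),
    )

    table_dw = regression.build_tuning_regressors(
        tv0, ps_a, masks, mode="full8",
        response=mats.dW, control=mats.group_total_delta,
    )
    Xdw = table_dw.drop(columns=["neuron", "group", "y"])
    fit_dw = regression.fit_lasso_cv(
        table_dw["y"].to_numpy(), Xdw, seed=stage_seed(seed, "lasso_dw")
    )
    dw_slope, dw_p = regression.wald_positive_test(
        table_dw["y"].to_numpy(), table_dw["Y:1|X:pre"].to_numpy(),
        controls=table_dw["control"].to_numpy(),
    )

    report = {
        "seed": seed,
        "n_sessions": cfg.n_sessions,
        "hit_rates": [rec.events.hit_rate for rec in sessions],
        "cn_bootstrap": {"percentile": percentile, "p": boot_p},
        "W_fit": {
            "heldout_correlation": fit_w.heldout_correlation,
            "penalty": fit_w.penalty,
            "coefficient_signs": {
                k: int(np.sign(v)) for k, v in fit_w.coefficients.items() if v != 0
            },
        },
        "dW_fit": {
            "heldout_correlation": fit_dw.heldout_correlation,
            "penalty": fit_dw.penalty,
            "coefficient_signs": {
                k: int(np.sign(v)) for k, v in fit_dw.coefficients.items() if v != 0
            },
        },
        "correlation_regressor": {"slope": corr_slope, "p": corr_p},
        "planted": {
            "like_to_like_rew_coef": float(fit_w.coefficients.get("Y:rew|X:rew", 0.0)),
            "pretrial_target_coef": float(fit_w.coefficients.get("Y:1|X:pre", 0.0)),
            "dw_pretrial_coef": float(fit_dw.coefficients.get("Y:1|X:pre", 0.0)),
            "dw_pretrial_wald": {"slope": dw_slope, "p": dw_p},
        },
    }
    report = _round_floats(report)
    if out is not None:
        with open(out, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_model_comparison(
    loci: tuple[str, ...] = ("recurrent", "input"),
    n_seeds: int = 10,
    seed: int = 0,
    cfg: rnn.RNNConfig | None = None,
    n_trials: int = 40,
) -> dict:
    """Per-locus RNN experiments pooled over seeds.

    Reports learning speed, rejection fractions, and the pooled positive
    Wald tests of correlation vs connectivity (and their changes), which
    discriminate local recurrent from upstream input plasticity.
    """
    base = stage_seed(seed, "model_comparison") % (2**20)
    out: dict = {"loci": {}}
    for locus in loci:
        res = rnn.run_locus_experiment(
            locus, seeds=range(base, base + n_seeds), cfg=cfg, n_trials=n_trials
        )
        out["loci"][locus] = {
            "lr": res["lr"],
            "median_completion": res["median_completion"],
            "rejection_fraction": res["rejection_fraction"],
            "corr_vs_W": res["analysis"]["corr_vs_W"],
            "dcorr_vs_dW": res["analysis"]["dcorr_vs_dW"],
            "layer_change_norms": res["layer_change_norms"],
        }
    if {"recurrent", "input"} <= set(out["loci"]):
        rec = out["loci"]["recurrent"]
        inp = out["loci"]["input"]
        out["discrimination"] = {
            "corr_vs_W_both_significant": bool(
                rec["corr_vs_W"]["p"] < 1e-4 and inp["corr_vs_W"]["p"] < 1e-4
            ),
            "dcorr_vs_dW_recurrent_significant": bool(rec["dcorr_vs_dW"]["p"] < 1e-4),
            "dcorr_vs_dW_input_nonsignificant": bool(inp["dcorr_vs_dW"]["p"] >= 0.01),
        }
    return _round_floats(out)


def run_group_size_experiment(
    sizes: tuple[int, ...] = (1, 2, 5, 10, 20),
    n_groups: int = 100,
    repeats: int = 20,
    n_neurons: int = 300,
    seed: int = 0,
    ridge: float = 1.0,
) -> dict:
    """Reconstruction fidelity of the true weights vs stimulation group size
    at a fixed total number of stimulation events.

    For each size, ``n_groups`` groups are stimulated ``repeats`` times;
    per-pair weights are recovered by ridge-regressing each non-target
    neuron's mean repeat response on the group target-membership matrix,
    and fidelity is the Pearson correlation between recovered and true
    weights over all probed pairs.
    """
    ccfg = synth.CircuitConfig(n_neurons=n_neurons)
    circuit = synth.sample_circuit(ccfg, seed=stage_seed(seed, "gs_circuit"))
    pcfg = synth.PhotostimSimConfig()
    fidelity = {}
    for size in sizes:
        if size >= n_neurons:
            warnings.warn(f"group size {size} leaves no non-targets; skipped")
            fidelity[size] = np.nan
            continue
        groups = synth.sample_groups(
            circuit.positions, n_groups=n_groups, group_size=size,
            seed=stage_seed(seed, f"gs_groups{size}"),
        )
        raw, groups = synth.simulate_photostim_block(
            circuit, groups, repeats=repeats, cfg=pcfg,
            seed=stage_seed(seed, f"gs_block{size}"),
        )
        masks = conn.classify_neurons(circuit.positions, groups)
        ps = conn.ps_response(
            conn.repeat_response(raw, pcfg.frame_rate, groups, masks)
        )
        fidelity[size] = _reconstruction_fidelity(
            ps.mu, masks, circuit.weights, pcfg.prop_gain, ridge
        )
    return {"sizes": list(sizes), "fidelity": _round_floats(list(fidelity.values()))}


def _reconstruction_fidelity(
    mu: np.ndarray, masks, true_w: np.ndarray, prop_gain: float, ridge: float
) -> float:
    """Ridge reconstruction of the full weight matrix from group responses.

    Pairs never probed (the receiver was not a valid non-target of any
    group containing the sender) keep the prior estimate 0, so the score
    rewards both per-pair accuracy and coverage at the fixed event budget.
    """
    n, G = mu.shape
    M = masks.targets.T.astype(float)          # (G, n) membership
    est = np.zeros_like(true_w)
    for i in range(n):
        rows = masks.non_targets[i] & np.isfinite(mu[i])
        if rows.sum() < 2:
            continue
        A = M[rows]
        cols = np.nonzero(A.sum(axis=0) > 0)[0]
        cols = cols[cols != i]
        if cols.size == 0:
            continue
        A = A[:, cols]
        y = mu[i, rows] / prop_gain
        est[i, cols] = np.linalg.solve(
            A.T @ A + ridge * np.eye(len(cols)), A.T @ y
        )
    off = ~np.eye(n, dtype=bool)
    return float(np.corrcoef(est[off], true_w[off])[0, 1])
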