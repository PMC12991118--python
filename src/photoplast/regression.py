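"""Regressor algebra and cross-validated lasso fits of causal connectivity.

Causal connectivity W_{i,g} (and its across-day change) is regressed on
products of non-target tuning Y_i and PS-response-weighted group tuning
X_g = sum_{j in targets(g)} X_j W~_{j,g}:

    A^{X,Y}_{i,g} = Y_i * X_g,

with Y and X ranging over {1} and the tuning components (the (1,1) column
is the intercept and is excluded): 24 candidate columns for 4-dimensional
tuning, 80 for 8-dimensional. A correlation regressor A^rho uses pairwise
Pearson correlations in place of X_j, and a control column (the total
target response W~_g, or its change for ΔW fits) absorbs the dependence of
non-target responses on stimulation strength. Lasso with a 10-fold
cross-validated penalty selects a sparse model; Wald inference is done on
an OLS refit (lasso p-values are ill-defined).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

from .connectivity import NeuronMasks, PSResponseSet

__all__ = [
    "MLRFit",
    "pairwise_correlations",
    "correlation_regressor",
    "delta_correlation_regressor",
    "build_tuning_regressors",
    "fit_lasso_cv",
    "wald_positive_test",
    "single_regressor_scan",
]

BASE4 = ("pre", "early", "late", "rew")
FULL8 = BASE4 + ("d_pre", "d_early", "d_late", "d_rew")


def pairwise_correlations(dff: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of neuron activity traces.

    Constant traces yield NaN rows/columns (with a warning) rather than an
    arbitrary value.
    """
    dff = np.asarray(dff, float)
    if dff.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    sd = dff.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant trace(s); correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(dff)
    C[const, :] = np.nan
    C[:, const] = np.nan
    np.fill_diagonal(C, np.where(const, np.nan, 1.0))
    return C


def correlation_regressor(
    C: np.ndarray, ps: PSResponseSet, masks: NeuronMasks
) -> np.ndarray:
    """A^rho_{i,g} = sum_{j in targets(g)} C_ij W~_{j,g} for non-targets i.

    Target neurons with absent PS response are skipped (equivalently
    weighted 0). Entries needing an undefined correlation are NaN.
    """
    n, G = ps.w_ps.shape
    out = np.full((n, G), np.nan)
    for k in range(G):
        tj = np.nonzero(masks.targets[:, k])[0]
        w = ps.w_ps[tj, k]
        keep = np.isfinite(w)
        tj, w = tj[keep], w[keep]
        ii = np.nonzero(masks.non_targets[:, k])[0]
        if tj.size == 0:
            out[ii, k] = 0.0
            continue
        vals = C[np.ix_(ii, tj)] @ w
        bad = np.any(~np.isfinite(C[np.ix_(ii, tj)]), axis=1)
        vals[bad] = np.nan
        out[ii, k] = vals
    return out


def delta_correlation_regressor(
    C_a: np.ndarray, C_b: np.ndarray,
    ps_a: PSResponseSet, ps_b: PSResponseSet,
    masks: NeuronMasks,
) -> np.ndarray:
    """ΔA^rho_{i,g} = sum_j (C^b_ij W~^b_{j,g} - C^a_ij W~^a_{j,g})."""
    return correlation_regressor(C_b, ps_b, masks) - correlation_regressor(
        C_a, ps_a, masks
    )


def build_tuning_regressors(
    tuning: pd.DataFrame,
    ps: PSResponseSet | None,
    masks: NeuronMasks,
    mode: str = "base4",
    response: np.ndarray | None = None,
    control: np.ndarray | None = None,
    correlation_column: np.ndarray | None = None,
    target_weighting: bool = True,
    components: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Long-form regressor table over (non-target i, group g) pairs.

    Columns ``Y:<y>|X:<x>`` hold Y_i * X_g where X_g is the PS-weighted
    group tuning (or the plain sum over targets when ``target_weighting``
    is False, as for single-neuron in-silico groups), X_g = 1 for x='1',
    and Y_i = 1 for y='1'; the (1,1) combination is excluded. Optional
    extra columns: the response ``y`` (from a W or dW matrix), the control
    (total target response per group) and the correlation regressor.
    Rows with absent tuning or response are dropped.
    """
    if components is not None:
        comps = tuple(components)
    elif mode == "base4":
        comps = BASE4
    elif mode == "full8":
        comps = FULL8
    else:
        raise ValueError("mode must be 'base4' or 'full8'")
    n = len(tuning)
    G = masks.targets.shape[1]
    tun = tuning[list(comps)].to_numpy(float)

    # X_g per component: sum over targets of X_j * W~_{j,g} (or plain sum)
    Xg = np.zeros((len(comps), G))
    for k in range(G):
        tj = np.nonzero(masks.targets[:, k])[0]
        if target_weighting:
            w = ps.w_ps[tj, k]
            keep = np.isfinite(w)
            tj, w = tj[keep], w[keep]
        else:
            w = np.ones(tj.size)
        if tj.size:
            Xg[:, k] = tun[tj].T @ w

    ii, gg = np.nonzero(masks.non_targets)
    if response is not None:
        keep = np.isfinite(response[ii, gg])
        ii, gg = ii[keep], gg[keep]
    data: dict[str, np.ndarray] = {
        "neuron": ii,
        "group": masks.group_ids[gg],
    }
    names_y = ("1",) + comps
    names_x = ("1",) + comps
    for yi, yname in enumerate(names_y):
        Y = np.ones(len(ii)) if yname == "1" else tun[ii, yi - 1]
        for xi, xname in enumerate(names_x):
            if yname == "1" and xname == "1":
                continue
            X = np.ones(len(gg)) if xname == "1" else Xg[xi - 1, gg]
            data[f"Y:{yname}|X:{xname}"] = Y * X
    if response is not None:
        data["y"] = response[ii, gg]
    if control is not None:
        data["control"] = control[gg]
    if correlation_column is not None:
        data["A_rho"] = correlation_column[ii, gg]
    df = pd.DataFrame(data)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        warnings.warn(f"dropped {n_before - len(df)} rows with absent entries")
    return df.reset_index(drop=True)


@dataclass
class MLRFit:
    """Cross-validated lasso fit with OLS-refit Wald inference."""

    coefficients: pd.Series        # standardized-predictor units
    intercept: float
    penalty: float
    fold_assignments: np.ndarray
    oof_predictions: np.ndarray
    heldout_correlation: float
    wald: pd.DataFrame             # slope, se, z, p_one_sided (OLS refit)
    column_means: pd.Series
    column_scales: pd.Series

    def raw_scale_coefficients(self) -> pd.Series:
        """Back-transform standardized coefficients to raw predictor units."""
        return self.coefficients / self.column_scales

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "heldout_correlation": self.heldout_correlation,
            "wald": self.wald.to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def lasso_at_penalty(y: np.ndarray, X: pd.DataFrame, lam: float) -> pd.Series:
    """Lasso coefficients (standardized-predictor units) at a fixed penalty."""
    y = np.asarray(y, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((X - mu) / sd).to_numpy()
    model = Lasso(alpha=lam, fit_intercept=True, tol=1e-8, max_iter=200_000)
    model.fit(Z, y)
    return pd.Series(model.coef_, index=X.columns)


def _fold_assignments(
    n: int, folds: int, rng: np.random.Generator, groups: np.ndarray | None
) -> np.ndarray:
    if groups is None:
        idx = rng.permutation(n)
        out = np.empty(n, int)
        out[idx] = np.arange(n) % folds
        return out
    # grouped assignment: whole groups (e.g. sessions) share a fold
    uniq = rng.permutation(np.unique(groups))
    gmap = {g: k % folds for k, g in enumerate(uniq)}
    return np.array([gmap[g] for g in groups])


def fit_lasso_cv(
    y: np.ndarray,
    X: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    n_penalties: int = 50,
) -> MLRFit:
    """Lasso with the L1 penalty chosen by cross-validation.

    Predictors are z-scored; the penalty grid spans [1e-4, 1] times the
    smallest penalty that zeroes all slopes, over ``n_penalties`` log-spaced
    values. The selected penalty minimizes the mean out-of-fold squared
    error; out-of-fold predictions cover every row exactly once. Wald
    statistics come from an OLS refit on the lasso-selected columns (plus
    the control column if present).
    """
    y = np.asarray(y, float)
    n, p = X.shape
    if n < folds:
        raise ValueError(f"{n} rows < {folds} folds")
    if n < 10 * p:
        warnings.warn(f"only {n} rows for {p} columns; fit may be unstable")
    rng = np.random.default_rng(seed)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((X - mu) / sd).to_numpy()
    yc = y - y.mean()

    lam_max = np.max(np.abs(Z.T @ yc)) / n
    if lam_max <= 0:  # response carries no signal at all
        lam_max = 1e-12
    lams = np.geomspace(lam_max * 1e-4, lam_max, n_penalties)
    fold_id = _fold_assignments(n, folds, rng, groups)

    cv_err = np.zeros(len(lams))
    order = np.argsort(lams)[::-1]  # descending for warm starts
    for f in range(folds):
        tr, te = fold_id != f, fold_id == f
        if te.sum() == 0:
            continue
        model = Lasso(alpha=lams[order[0]], fit_intercept=True, tol=1e-3,
                      max_iter=2000, warm_start=True)
        for li in order:
            model.set_params(alpha=lams[li])
            model.fit(Z[tr], y[tr])
            pred = model.predict(Z[te])
            cv_err[li] += np.sum((pred - y[te]) ** 2)
    best = int(np.argmin(cv_err / n))
    lam = float(lams[best])

    final = Lasso(alpha=lam, fit_intercept=True, tol=1e-4, max_iter=20000)
    final.fit(Z, y)
    oof = np.empty(n)
    for f in range(folds):
        tr, te = fold_id != f, fold_id == f
        m = Lasso(alpha=lam, fit_intercept=True, tol=1e-3, max_iter=5000)
        m.fit(Z[tr], y[tr])
        oof[te] = m.predict(Z[te])
    if np.std(oof) > 0 and np.std(y) > 0:
        heldout_r = float(np.corrcoef(oof, y)[0, 1])
    else:
        heldout_r = np.nan

    coefs = pd.Series(final.coef_, index=X.columns)
    selected = list(coefs.index[coefs != 0])
    if "control" in X.columns and "control" not in selected:
        selected.append("control")
    wald_rows = {}
    if selected:
        Zs = Z[:, [X.columns.get_loc(c) for c in selected]]
        A = np.column_stack([np.ones(n), Zs])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        dof = max(n - A.shape[1], 1)
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.pinv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        for k, c in enumerate(selected, start=1):
            z = beta[k] / se[k] if se[k] > 0 else np.nan
            wald_rows[c] = {
                "slope": beta[k],
                "se": se[k],
                "z": z,
                "p_one_sided": float(stats.t.sf(z, dof)) if np.isfinite(z) else np.nan,
            }
    wald = pd.DataFrame.from_dict(wald_rows, orient="index") if wald_rows else \
        pd.DataFrame(columns=["slope", "se", "z", "p_one_sided"])

    return MLRFit(
        coefficients=coefs,
        intercept=float(final.intercept_),
        penalty=lam,
        fold_assignments=fold_id,
        oof_predictions=oof,
        heldout_correlation=heldout_r,
        wald=wald,
        column_means=mu,
        column_scales=sd,
    )


def wald_positive_test(
    y: np.ndarray,
    focal: np.ndarray,
    controls: np.ndarray | None = None,
    max_condition: float = 1e8,
) -> tuple[float, float]:
    """One-sided Wald test that the focal slope is positive.

    OLS of y on intercept + controls + focal; returns (slope, one-sided p
    for slope > 0). Raises on (near-)collinear designs.
    """
    y = np.asarray(y, float)
    focal = np.asarray(focal, float)
    cols = [np.ones_like(y)]
    if controls is not None:
        controls = np.asarray(controls, float)
        if controls.ndim == 1:
            controls = controls[:, None]
        if controls.shape[0] != y.size:
            raise ValueError("controls must have one row per observation")
        cols.extend(controls.T)
    cols.append(focal)
    A = np.column_stack(cols)
    keep = np.all(np.isfinite(A), axis=1) & np.isfinite(y)
    A, yk = A[keep], y[keep]
    cond = np.linalg.cond(A)
    if cond > max_condition:
        raise ValueError(f"collinear design (condition number {cond:.3g})")
    beta, *_ = np.linalg.lstsq(A, yk, rcond=None)
    resid = yk - A @ beta
    dof = max(len(yk) - A.shape[1], 1)
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    se = float(np.sqrt(cov[-1, -1]))
    slope = float(beta[-1])
    if se == 0:
        return slope, 0.0 if slope > 0 else 1.0
    t = slope / se
    return slope, float(stats.t.sf(t, dof))


def single_regressor_scan(
    y: np.ndarray, table: pd.DataFrame, control: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-column Wald test with only the control alongside each regressor."""
    rows = {}
    for c in table.columns:
        slope, p = wald_positive_test(y, table[c].to_numpy(float), controls=control)
        rows[c] = {"slope": slope, "p_one_sided": p}
    return pd.DataFrame.from_dict(rows, orient="index")
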