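"""Self-consistent regression (SCR) and its radial-basis-function extension.

SCR is ridge-stabilized least squares with backward elimination: starting
from all candidate descriptors, the variable with the smallest |t| ratio
(|coefficient| / standard error) is dropped and the model refit, until every
retained variable is significant at the configured threshold.  The ridge
value is chosen per fit by maximizing closed-form leave-one-out Q² over a
small logarithmic grid, so the procedure is fully deterministic.

RBF-SCR reuses the SCR-selected variable subset and fits a ridge-stabilized
Gaussian radial-basis interpolant in that subspace (centers = training
points, width = median pairwise distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = ["SCRConfig", "PartialModel", "fit_scr", "fit_rbf_scr"]


@dataclass(frozen=True)
class SCRConfig:
    #: significance threshold on |coefficient| / SE for keeping a variable
    t_threshold: float = 2.0
    #: ridge grid, per-sample scale (multiplied by n on the standardized design)
    ridge_grid: tuple[float, ...] = (1e-8, 1e-5, 1e-3, 1e-2, 1e-1)
    #: ridge used to stabilize the RBF kernel solve; lower it toward zero to
    #: recover the pure interpolation property at the cost of generalization
    rbf_ridge: float = 1e-2


@dataclass
class PartialModel:
    """One partial regression model of a consensus pool."""

    method: str                       # "SCR" or "RBF-SCR"
    family: str                       # "QNA" or "MNA"
    columns: list[str]                # selected variable names
    coef: np.ndarray                  # linear coefficients, original scale
    intercept: float
    ridge: float
    r2: float
    n_obs: int
    sd: float                         # residual standard error
    f_stat: float
    flags: list[str] = field(default_factory=list)
    # RBF-specific state (None for plain SCR)
    rbf_centers: np.ndarray | None = None
    rbf_weights: np.ndarray | None = None
    rbf_width: float | None = None
    rbf_col_mean: np.ndarray | None = None
    rbf_col_scale: np.ndarray | None = None
    rbf_y_mean: float | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.columns].to_numpy(dtype=float) if self.columns else np.zeros((len(X), 0))
        if self.method == "SCR":
            return self.intercept + (Z @ self.coef if Z.size else np.zeros(len(X)))
        return _rbf_predict(self, Z)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "family": self.family,
            "columns": self.columns,
            "coef": np.asarray(self.coef).tolist(),
            "intercept": self.intercept,
            "ridge": self.ridge,
            "r2": self.r2,
            "n_obs": self.n_obs,
            "sd": self.sd,
            "f_stat": self.f_stat,
            "flags": self.flags,
        }
        if self.method == "RBF-SCR":
            d.update(
                rbf_centers=self.rbf_centers.tolist(),
                rbf_weights=self.rbf_weights.tolist(),
                rbf_width=self.rbf_width,
                rbf_col_mean=self.rbf_col_mean.tolist(),
                rbf_col_scale=self.rbf_col_scale.tolist(),
                rbf_y_mean=self.rbf_y_mean,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PartialModel":
        kw = dict(d)
        kw["coef"] = np.asarray(kw["coef"], dtype=float)
        for key in ("rbf_centers", "rbf_weights", "rbf_col_mean", "rbf_col_scale"):
            if key in kw and kw[key] is not None:
                kw[key] = np.asarray(kw[key], dtype=float)
        return cls(**kw)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    keep = scale > 0
    Z = np.zeros_like(X)
    Z[:, keep] = (X[:, keep] - mean[keep]) / scale[keep]
    return Z, mean, scale, keep


def _loo_q2(Z: np.ndarray, yc: np.ndarray, lam: float) -> float:
    n, p = Z.shape
    A = Z.T @ Z + lam * np.eye(p)
    c, low = cho_factor(A)
    coef = cho_solve((c, low), Z.T @ yc)
    resid = yc - Z @ coef
    S = cho_solve((c, low), Z.T)              # (p, n)
    h = np.einsum("ij,ji->i", Z, S)
    # near-interpolating fits make the shortcut 0/0-unstable (the intercept
    # is fit separately, outside the identity); treat them as unassessable
    if np.any(h > 1.0 - 1e-8) or h.sum() > 0.9 * (n - 1):
        return -np.inf
    h = np.clip(h, 0.0, 1.0 - 1e-8)
    loo = resid / (1.0 - h)
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        return -np.inf
    return 1.0 - float(loo @ loo) / ss_tot


def _select_ridge(Z: np.ndarray, yc: np.ndarray, grid: tuple[float, ...]) -> float:
    # duplicated rows (bootstrap resamples) make plain LOO optimistic — the
    # twin stays in the fit — so Q² is assessed on the deduplicated design
    uniq = np.unique(np.column_stack([Z, yc]), axis=0)
    Zu, ycu = uniq[:, :-1], uniq[:, -1]
    n = Z.shape[0]
    best_lam, best_q2 = None, -np.inf
    for g in grid:
        lam = g * n
        q2 = _loo_q2(Zu, ycu, lam)
        if q2 > best_q2 + 1e-12:
            best_lam, best_q2 = lam, q2
    if best_lam is None:
        # nothing assessable: fall back to the strongest regularization
        best_lam = max(grid) * n
    return best_lam


def fit_scr(X: pd.DataFrame, y: np.ndarray | list[float], config: SCRConfig | None = None) -> PartialModel:
    """Fit one SCR partial model on a named design matrix.

    Deterministic: no randomness enters the fit.  If every variable is
    eliminated the result is a flagged intercept-only model.
    """
    config = config or SCRConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")

    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    Z_all, mean, scale, keep = _standardize(Xm)
    flags: list[str] = []
    if not keep.all():
        flags.append(f"dropped {int((~keep).sum())} constant column(s)")
    active = [j for j in range(len(names)) if keep[j]]

    y_mean = float(y.mean())
    yc = y - y_mean
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        raise ValueError("constant response")

    lam = _select_ridge(Z_all[:, active], yc, config.ridge_grid) if active else 0.0

    coef_std = np.zeros(0)
    rss = ss_tot
    tr_h = 0.0
    while active:
        Z = Z_all[:, active]
        p = len(active)
        A = Z.T @ Z + lam * np.eye(p)
        c, low = cho_factor(A)
        coef_std = cho_solve((c, low), Z.T @ yc)
        resid = yc - Z @ coef_std
        rss = float(resid @ resid)
        a_inv = cho_solve((c, low), np.eye(p))
        tr_h = float(np.einsum("ij,jk,ik->", Z, a_inv, Z))
        df = max(1.0, n - tr_h - 1.0)
        sigma2 = max(rss / df, 1e-30)
        se = np.sqrt(sigma2 * np.clip(np.diag(a_inv), 1e-300, None))
        t = np.abs(coef_std) / se
        worst = int(np.argmin(t))
        if t[worst] >= config.t_threshold:
            break
        active.pop(worst)
    else:
        flags.append("all variables eliminated; intercept-only model")
        rss = ss_tot

    # back-transform to the original descriptor scale
    sel_names = [names[j] for j in active]
    coef = np.array([coef_std[k] / scale[j] for k, j in enumerate(active)])
    intercept = y_mean - float(sum(coef[k] * mean[j] for k, j in enumerate(active)))

    r2 = 1.0 - rss / ss_tot
    k = len(active)
    if 0 < k and n - k - 1 > 0 and r2 < 1.0:
        f_stat = (r2 / k) / ((1.0 - r2) / (n - k - 1))
        sd = float(np.sqrt(rss / (n - k - 1)))
    else:
        f_stat = float("inf") if k else 0.0
        sd = float(np.sqrt(rss / n))

    return PartialModel(
        method="SCR", family="", columns=sel_names, coef=coef,
        intercept=intercept, ridge=lam, r2=r2, n_obs=n, sd=sd,
        f_stat=f_stat, flags=flags,
    )


def _pairwise_width(Z: np.ndarray) -> tuple[float, list[str]]:
    from scipy.spatial.distance import pdist

    flags: list[str] = []
    if Z.shape[0] < 2 or Z.shape[1] == 0:
        return 1.0, ["degenerate RBF geometry; unit width"]
    d = pdist(Z)
    width = float(np.median(d))
    if width == 0:
        width = float(np.mean(d))
        flags.append("zero median pairwise distance; width fallback to mean")
    if width == 0:
        width = 1.0
        flags.append("all training points coincide; unit width")
    return width, flags


def _rbf_kernel(Z: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * width ** 2))


def _rbf_predict(model: PartialModel, Zraw: np.ndarray) -> np.ndarray:
    Z = (Zraw - model.rbf_col_mean) / model.rbf_col_scale
    K = _rbf_kernel(Z, model.rbf_centers, model.rbf_width)
    return model.rbf_y_mean + K @ model.rbf_weights


def fit_rbf_scr(X: pd.DataFrame, y: np.ndarray | list[float], config: SCRConfig | None = None) -> PartialModel:
    """SCR variable selection followed by a Gaussian RBF interpolant.

    With negligible ridge the training predictions reproduce y (pure
    interpolation), so the training R² is near 1 by construction.
    """
    config = config or SCRConfig()
    base = fit_scr(X, y, config)
    y = np.asarray(y, dtype=float)
    n = len(y)

    cols = base.columns
    Zraw = X[cols].to_numpy(dtype=float) if cols else np.zeros((n, 0))
    col_mean = Zraw.mean(axis=0) if Zraw.size else np.zeros(0)
    col_scale = Zraw.std(axis=0) if Zraw.size else np.zeros(0)
    col_scale = np.where(col_scale > 0, col_scale, 1.0)
    Z = (Zraw - col_mean) / col_scale

    width, wflags = _pairwise_width(Z)
    K = _rbf_kernel(Z, Z, width)
    y_mean = float(y.mean())
    weights = np.linalg.solve(K + config.rbf_ridge * np.eye(n), y - y_mean)
    pred = y_mean + K @ weights
    resid = y - pred
    ss_tot = float(((y - y_mean) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot else 0.0

    return PartialModel(
        method="RBF-SCR", family=base.family, columns=cols,
        coef=base.coef, intercept=base.intercept, ridge=base.ridge,
        r2=r2, n_obs=n, sd=float(np.sqrt((resid @ resid) / n)),
        f_stat=base.f_stat, flags=base.flags + wflags,
        rbf_centers=Z, rbf_weights=weights, rbf_width=width,
        rbf_col_mean=col_mean, rbf_col_scale=col_scale, rbf_y_mean=y_mean,
    )
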