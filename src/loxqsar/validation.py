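"""External-validation statistics for observed/predicted activity pairs.

The report collects the r²-family agreement measures (Pearson r², the two
through-origin coefficients r0² and r0'², the rm² pair with its average and
absolute difference), the concordance correlation coefficient CCC, the
external predictivity coefficients QF1²/QF2², and the error measures RMSE,
MAE, the standard deviation of absolute errors and the combined criterion
B = MAE + 3·SD.  The rm² convention uses |r² - r0²| under the square root so
the metric stays real when the through-origin fit exceeds the ordinary one.
All moments use the population (n-denominator) form; rounding happens only
at reporting time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricReport",
    "AbilityClass",
    "external_metrics",
    "trim_worst",
    "classify_ability",
    "prediction_window_report",
    "systematic_error_check",
    "b_criterion",
]


@dataclass
class MetricReport:
    n: int
    r2: float
    r0_2: float        # predicted regressed on observed, through origin
    r0p_2: float       # observed regressed on predicted, through origin
    rm2: float
    rm2_prime: float
    rm2_mean: float
    rm2_delta: float
    ccc: float
    qf1_2: float | None
    qf2_2: float
    rmse: float
    mae: float
    sd_abs_err: float
    b: float

    def rounded(self, digits: int = 3) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, digits) if isinstance(v, float) else v
        return out


def _through_origin_r2(y: np.ndarray, x: np.ndarray) -> float:
    """R² of predicting y by k·x with k from least squares through the origin."""
    k = float(x @ y) / float(x @ x)
    resid = y - k * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / ss_tot


def b_criterion(mae: float, sd: float) -> float:
    """Combined error criterion B = MAE + 3·SD."""
    return mae + 3.0 * sd


def external_metrics(
    y_obs: np.ndarray | list[float],
    y_pred: np.ndarray | list[float],
    train_mean: float | None = None,
) -> MetricReport:
    """Full validation statistic set for one (observed, predicted) pairing.

    ``train_mean`` is the training-set activity mean used by QF1²; when not
    given QF1² is reported as ``None`` (QF2², normalized by the test mean,
    is always available).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed/predicted length mismatch")
    n = len(y_obs)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(y_obs) == 0:
        raise ValueError("constant observed values")

    err = y_obs - y_pred
    press = float(err @ err)
    mean_obs = float(y_obs.mean())
    mean_pred = float(y_pred.mean())

    if np.ptp(y_pred) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y_obs, y_pred)[0, 1]) ** 2

    r0_2 = _through_origin_r2(y_pred, y_obs)   # pred vs obs through origin
    r0p_2 = _through_origin_r2(y_obs, y_pred)  # obs vs pred through origin

    rm2 = r2 * (1.0 - math.sqrt(abs(r2 - r0_2)))
    rm2p = r2 * (1.0 - math.sqrt(abs(r2 - r0p_2)))

    var_obs = float(((y_obs - mean_obs) ** 2).mean())
    var_pred = float(((y_pred - mean_pred) ** 2).mean())
    cov = float(((y_obs - mean_obs) * (y_pred - mean_pred)).mean())
    ccc = 2.0 * cov / (var_obs + var_pred + (mean_obs - mean_pred) ** 2)

    qf1 = None
    if train_mean is not None:
        qf1 = 1.0 - press / float(((y_obs - train_mean) ** 2).sum())
    qf2 = 1.0 - press / float(((y_obs - mean_obs) ** 2).sum())

    abs_err = np.abs(err)
    mae = float(abs_err.mean())
    sd = float(abs_err.std())  # population form
    return MetricReport(
        n=n, r2=r2, r0_2=r0_2, r0p_2=r0p_2,
        rm2=rm2, rm2_prime=rm2p,
        rm2_mean=0.5 * (rm2 + rm2p), rm2_delta=abs(rm2 - rm2p),
        ccc=ccc, qf1_2=qf1, qf2_2=qf2,
        rmse=float(np.sqrt(press / n)), mae=mae, sd_abs_err=sd,
        b=b_criterion(mae, sd),
    )


def trim_worst(
    y_obs: np.ndarray | list[float],
    y_pred: np.ndarray | list[float],
    fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Drop the worst-predicted pairs (largest |error|).

    Removes ``round(fraction*n)`` pairs, at least one whenever
    ``fraction > 0``; ties are broken by observation order.  Returns the
    reduced arrays and the removed indices.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_obs)
    if fraction == 0.0:
        return y_obs, y_pred, []
    k = max(1, round(fraction * n))
    order = sorted(range(n), key=lambda i: (-abs(y_obs[i] - y_pred[i]), i))
    removed = sorted(order[:k])
    keep = [i for i in range(n) if i not in set(removed)]
    return y_obs[keep], y_pred[keep], removed


@dataclass
class AbilityClass:
    level: str  # high / moderate / low
    triggered: list[str] = field(default_factory=list)


_LEVELS = {"high": 0, "moderate": 1, "low": 2}


def classify_ability(report: MetricReport, train_range: float) -> AbilityClass:
    """Band a metric report against the training-range-anchored thresholds.

    MAE bands at 0.1Δ/0.15Δ and B bands at 0.2Δ/0.25Δ (Δ = training
    activity range), combined with the conventional r²-family thresholds;
    the overall level is the worst band triggered, with the triggering
    criteria listed.
    """
    if not train_range > 0:
        raise ValueError("train_range must be positive")
    d = train_range
    checks: list[tuple[str, str]] = []

    def band(value: float, hi_limit: float, mod_limit: float, name: str,
             larger_is_better: bool) -> None:
        if larger_is_better:
            level = "high" if value > hi_limit else ("moderate" if value > mod_limit else "low")
        else:
            level = "high" if value <= hi_limit else ("moderate" if value <= mod_limit else "low")
        checks.append((level, f"{name}={value:.3f} -> {level}"))

    band(report.mae, 0.1 * d, 0.15 * d, "MAE", larger_is_better=False)
    band(report.b, 0.2 * d, 0.25 * d, "B", larger_is_better=False)
    band(report.r2, 0.8, 0.6, "r2", larger_is_better=True)
    band(report.ccc, 0.8, 0.7, "CCC", larger_is_better=True)
    band(report.qf2_2, 0.7, 0.6, "QF2_2", larger_is_better=True)
    if report.qf1_2 is not None:
        band(report.qf1_2, 0.7, 0.6, "QF1_2", larger_is_better=True)

    worst = max(checks, key=lambda c: _LEVELS[c[0]])[0]
    triggered = [msg for lvl, msg in checks if lvl == worst]
    return AbilityClass(level=worst, triggered=triggered)


def prediction_window_report(
    rmsep: float,
    predictions: np.ndarray | list[float],
    experimentals: np.ndarray | list[float],
    ids: list[str] | None = None,
) -> list[dict]:
    """Per-compound |pred - exp| against the ±2·RMSEP confidence window.

    The window bound is inclusive: a deviation exactly equal to 2·RMSEP
    counts as within.
    """
    if not rmsep > 0:
        raise ValueError("rmsep must be positive")
    predictions = np.asarray(predictions, dtype=float)
    experimentals = np.asarray(experimentals, dtype=float)
    ids = ids or [str(i + 1) for i in range(len(predictions))]
    window = 2.0 * rmsep
    rows = []
    for cid, p, e in zip(ids, predictions, experimentals):
        delta = abs(p - e)
        rows.append({
            "id": cid,
            "predicted": float(p),
            "experimental": float(e),
            "delta": float(delta),
            "window": window,
            "within": bool(delta <= window),
        })
    return rows


def systematic_error_check(
    y_obs: np.ndarray | list[float],
    y_pred: np.ndarray | list[float],
) -> dict:
    """Flag directional bias: large mean signed error or one-sided residuals."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) < 5:
        raise ValueError("need at least 5 pairs")
    resid = y_pred - y_obs
    mse_signed = float(resid.mean())
    mae = float(np.abs(resid).mean())
    frac_pos = float((resid > 0).mean())
    flags = []
    if mae > 0 and abs(mse_signed) > 0.5 * mae:
        flags.append("mean signed error exceeds 0.5*MAE")
    if frac_pos > 0.8 or frac_pos < 0.2:
        flags.append("more than 80% of residuals share a sign")
    return {
        "mean_signed_error": mse_signed,
        "fraction_positive": frac_pos,
        "mae": mae,
        "flags": flags,
        "systematic": bool(flags),
    }
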