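"""Spectrophotometric 15-LOX inhibition assay arithmetic.

Percent inhibition from optical densities, replicate averaging, and IC50 by
linear interpolation between the two curve points bracketing 50% inhibition
— the half-maximal concentration is read off the straight line through the
last point below 50% and the next point at or above it.  No sigmoidal (Hill
/ 4PL) fitting is attempted: the method is deliberately the simple
two-point interpolation used when curves are sampled at a few
concentrations.

The package ships ``data/assay_curves_1_8.tsv``, the measured
dose-inhibition panel for eight 2H-(benzo)pyran-2-one-type inhibitors
(mean inhibition over triplicates per concentration, with each compound's
reported IC50 for cross-checking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .dataset import pic50_from_ic50

__all__ = [
    "InhibitionCurve",
    "percent_inhibition",
    "ic50_interpolate",
    "read_curves",
    "bundled_curve_path",
    "assay_table",
]

logger = logging.getLogger(__name__)


@dataclass
class InhibitionCurve:
    compound_id: str
    points: list[tuple[float, float]]          # (concentration µM, mean inhibition %)
    replicate_count: int = 1
    sd: list[float] | None = None              # per-point inhibition SD
    reported_ic50: float | None = None

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError(f"{self.compound_id}: concentrations must be strictly increasing")
        for _, i in self.points:
            if not -10.0 <= i <= 110.0:
                raise ValueError(f"{self.compound_id}: inhibition {i}% outside [-10, 110]")
            if i < 0 or i > 100:
                logger.warning("%s: inhibition %.2f%% outside [0, 100]", self.compound_id, i)


def percent_inhibition(dc: float, dt: float) -> float:
    """I = (Dc - Dt)/Dc * 100 from control and treated optical densities."""
    if not dc > 0:
        raise ValueError("control optical density must be positive")
    if dt < 0:
        raise ValueError("treated optical density must be non-negative")
    return (dc - dt) / dc * 100.0


def ic50_interpolate(curve: InhibitionCurve) -> float:
    """IC50 (µmol/L, 1 decimal) by linear interpolation around 50% inhibition.

    The bracketing pair around the first upward crossing is used; a point
    exactly at 50% returns its concentration.  With multiple crossings
    (noisy, non-monotone data) the crossing whose two points are jointly
    closest to 50% is taken and a warning logged.
    """
    pts = curve.points
    for c, i in pts:
        if i == 50.0:
            return round(c, 1)
    crossings = [
        k for k in range(len(pts) - 1)
        if pts[k][1] < 50.0 <= pts[k + 1][1]
    ]
    if not crossings:
        raise ValueError(f"{curve.compound_id}: IC50 outside tested range")
    if len(crossings) > 1:
        logger.warning("%s: %d crossings of 50%%; using the closest pair",
                       curve.compound_id, len(crossings))
        crossings.sort(key=lambda k: abs(pts[k][1] - 50.0) + abs(pts[k + 1][1] - 50.0))
    k = crossings[0]
    (c_lo, i_lo), (c_hi, i_hi) = pts[k], pts[k + 1]
    ic50 = c_lo + (50.0 - i_lo) * (c_hi - c_lo) / (i_hi - i_lo)
    return round(ic50, 1)


def read_curves(path: str | Path) -> list[InhibitionCurve]:
    """Read dose-inhibition curves from delimited text.

    Expected header: ``id, conc_uM, inhibition_pct`` with optional
    ``replicate`` and ``ic50_reported_umol`` columns.  Replicate rows are
    averaged per (id, concentration); curves come back sorted by
    concentration, compounds in first-appearance order.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    df["id"] = df["id"].astype(str)
    if "replicate" in df.columns:
        dup = df.duplicated(["id", "conc_uM", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate replicate row: id={row['id']} conc={row['conc_uM']} "
                f"replicate={row['replicate']}"
            )
    curves = []
    for cid in pd.unique(df["id"]):
        sub = df[df["id"] == cid]
        grouped = sub.groupby("conc_uM")["inhibition_pct"]
        means = grouped.mean().sort_index()
        sds = grouped.std(ddof=0).sort_index()
        n_rep = int(grouped.size().max())
        reported = None
        if "ic50_reported_umol" in sub.columns and sub["ic50_reported_umol"].notna().any():
            reported = float(sub["ic50_reported_umol"].iloc[0])
        curves.append(InhibitionCurve(
            compound_id=str(cid),
            points=[(float(c), float(v)) for c, v in means.items()],
            replicate_count=n_rep,
            sd=[float(s) for s in sds],
            reported_ic50=reported,
        ))
    return curves


def bundled_curve_path() -> Path:
    """Path to the shipped eight-compound inhibition panel."""
    with resources.as_file(resources.files("loxqsar.data") / "assay_curves_1_8.tsv") as p:
        return p


def assay_table(curves: list[InhibitionCurve]) -> pd.DataFrame:
    """IC50 (1 decimal) and pIC50 (3 decimals) per compound.

    Curves that never cross 50% are reported with an error note instead of
    aborting the run.
    """
    rows = []
    for c in curves:
        try:
            ic50 = ic50_interpolate(c)
            rows.append({
                "id": c.compound_id,
                "ic50_umol": ic50,
                "pic50": round(pic50_from_ic50(ic50), 3),
                "error": "",
            })
        except ValueError as exc:
            rows.append({"id": c.compound_id, "ic50_umol": None, "pic50": None,
                         "error": str(exc)})
    return pd.DataFrame(rows, columns=["id", "ic50_umol", "pic50", "error"])
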