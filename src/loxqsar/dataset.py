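"""Activity data handling: pIC50 conversion, ranked splitting, set statistics.

The modeled response is pIC50 = -log10(IC50 in mol/L); assay tables carry
IC50 in µmol/L.  Training/test partitioning follows the ranked 1-in-``period``
scheme: compounds are sorted by ascending pIC50 and every ``period``-th
(1-based) goes to the test set, giving a 5:1 split at the default period 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .molgraph import MolecularGraph

__all__ = [
    "ActivityRecord",
    "ActivityDataSet",
    "SplitResult",
    "SetStatistics",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "ranked_split",
    "set_statistics",
    "check_modeling_precondition",
]

PIC50_CONSISTENCY_TOL = 5e-4
WINDOW_WIDTHS = (0.5, 1.0, 1.5, 2.0)
THRESHOLD_FRACTIONS = (0.10, 0.15, 0.20, 0.25)


def pic50_from_ic50(ic50_umol: float) -> float:
    """pIC50 from IC50 in µmol/L: -log10(IC50 * 1e-6)."""
    if not ic50_umol > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_umol}")
    return -math.log10(ic50_umol * 1e-6)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse conversion, returning µmol/L."""
    return 10.0 ** (-pic50) * 1e6


@dataclass
class ActivityRecord:
    compound_id: str
    pic50: float
    ic50_umol: float | None = None
    structure: MolecularGraph | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.pic50):
            raise ValueError(f"{self.compound_id}: pIC50 must be finite")
        if self.ic50_umol is not None:
            expected = pic50_from_ic50(self.ic50_umol)
            if abs(expected - self.pic50) > PIC50_CONSISTENCY_TOL:
                raise ValueError(
                    f"{self.compound_id}: pIC50 {self.pic50} inconsistent with "
                    f"IC50 {self.ic50_umol} µmol/L (expected {expected:.4f})"
                )


@dataclass
class ActivityDataSet:
    """Ordered compound records with activities plus free-form metadata."""

    records: list[ActivityRecord]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def pic50_values(self) -> list[float]:
        return [r.pic50 for r in self.records]

    @property
    def structures(self) -> list[MolecularGraph]:
        return [r.structure for r in self.records]  # type: ignore[misc]

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "pic50": [round(r.pic50, 3) for r in self.records],
                "ic50_umol": [r.ic50_umol for r in self.records],
            }
        )

    def write_table(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SplitResult:
    train: ActivityDataSet
    test: ActivityDataSet
    period: int


def ranked_split(dataset: ActivityDataSet, period: int = 6) -> SplitResult:
    """Rank by ascending pIC50 and transfer every ``period``-th to the test set.

    Sorting is stable, so ties preserve input order; positions period,
    2*period, ... (1-based in the ranked order) form the test set.
    """
    if period < 2:
        raise ValueError("period must be >= 2")
    if len(dataset) < period:
        raise ValueError(f"need at least {period} records, got {len(dataset)}")
    ranked = sorted(dataset.records, key=lambda r: r.pic50)
    test = [r for k, r in enumerate(ranked, start=1) if k % period == 0]
    train = [r for k, r in enumerate(ranked, start=1) if k % period != 0]
    return SplitResult(
        train=ActivityDataSet(train, meta=dict(dataset.meta)),
        test=ActivityDataSet(test, meta=dict(dataset.meta)),
        period=period,
    )


@dataclass
class SetStatistics:
    n: int
    mean_pic50: float
    delta_pic50: float
    thresholds: dict[float, float]      # fraction -> fraction * delta (3 dp)
    window_fractions: dict[float, float]  # half-width -> % within reference ± width
    reference_mean: float

    def __post_init__(self) -> None:
        vals = [self.thresholds[f] for f in sorted(self.thresholds)]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be strictly increasing")


def set_statistics(dataset: ActivityDataSet, reference_mean: float | None = None) -> SetStatistics:
    """Descriptive statistics: Δ-range thresholds and distribution windows."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 records")
    y = dataset.pic50_values
    delta = max(y) - min(y)
    if delta == 0:
        raise ValueError("activity range is zero")
    ref = sum(y) / len(y) if reference_mean is None else reference_mean
    thresholds = {f: round(f * delta, 3) for f in THRESHOLD_FRACTIONS}
    windows = {
        w: round(100.0 * sum(abs(v - ref) <= w for v in y) / len(y), 3)
        for w in WINDOW_WIDTHS
    }
    return SetStatistics(
        n=len(y),
        mean_pic50=round(sum(y) / len(y), 3),
        delta_pic50=round(delta, 3),
        thresholds=thresholds,
        window_fractions=windows,
        reference_mean=ref,
    )


def check_modeling_precondition(dataset: ActivityDataSet) -> bool:
    """True iff the activity range strictly exceeds 3 pIC50 units."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 records")
    y = dataset.pic50_values
    return (max(y) - min(y)) > 3.0


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited activity table (id + smiles/ic50_umol/pic50 columns)."""
    df = pd.read_csv(path, sep="\t")
    if "pic50" not in df.columns and "ic50_umol" in df.columns:
        df["pic50"] = df["ic50_umol"].map(pic50_from_ic50)
    return df


def write_split_manifest(split: SplitResult, path: str | Path) -> None:
    rows = [(r.compound_id, "train") for r in split.train] + [
        (r.compound_id, "test") for r in split.test
    ]
    pd.DataFrame(rows, columns=["id", "subset"]).to_csv(path, sep="\t", index=False)
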