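"""Consensus models: pools of partial regressions with an applicability domain.

A consensus model averages many partial regression models.  Partial-model
diversity comes from seeded bootstrap resamples of the training compounds
combined with seeded random subsets (50-90%) of the candidate descriptor
columns; the three whole-molecule descriptors are candidates in every
partial.  Single-family pools hold 20 partials by default; mixed QNA+MNA
pools hold 320 (half per family).  The selection method is SCR, RBF-SCR, or
"Both" (alternating).

Summary statistics (R̄², Q̄²_LMO, F̄, SD̄, V) are arithmetic means over the
partials.  Q̄²_LMO is leave-many-out cross-validation (20 rounds, 20% held
out) run per partial with its selected variables held fixed and the model
weights refit per round; SD̄ is the per-partial LMO prediction error.  The
standalone :func:`lmo_cross_validation` re-runs the full fit, including
variable selection, each round.

The applicability domain (AD) combines two rules anchored to the training
set: Tanimoto similarity of a compound's MNA descriptor set to the nearest
training compound must reach 0.3, and every whole-molecule descriptor must
lie within the training min/max expanded by 10% of the range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .dataset import ActivityDataSet, check_modeling_precondition
from .descriptors import WHOLE_MOLECULE_NAMES, DescriptorConfig, Featurizer
from .molgraph import MolecularGraph
from .scr import PartialModel, SCRConfig, fit_rbf_scr, fit_scr

__all__ = [
    "ConsensusConfig",
    "ConsensusModel",
    "PredictionResult",
    "build_consensus",
    "predict",
    "lmo_cross_validation",
    "stability",
    "stability_class",
]

METHODS = ("SCR", "RBF-SCR", "Both")
FAMILIES = ("QNA", "MNA", "both")


@dataclass(frozen=True)
class ConsensusConfig:
    n_partials: int = 20
    col_fraction_low: float = 0.5
    col_fraction_high: float = 0.9
    lmo_rounds: int = 20
    lmo_fraction: float = 0.2
    ad_tanimoto: float = 0.3
    ad_range_expand: float = 0.1


@dataclass
class PredictionResult:
    compound_id: str
    predicted: float | None
    in_ad: bool
    spread: float | None = None
    forced: bool = False
    note: str = ""


@dataclass
class ConsensusModel:
    method: str
    families: str
    seed: int
    partials: list[PartialModel]
    featurizer: Featurizer
    summary: dict
    ad_whole_min: np.ndarray
    ad_whole_max: np.ndarray
    ad_mna_sets: list[frozenset[str]]
    training_ids: list[str]
    config: ConsensusConfig
    rmsep: float | None = None   # stored external RMSEP once evaluated

    def partial_matrix(self, graphs: list[MolecularGraph]) -> dict[str, pd.DataFrame]:
        fams = {p.family for p in self.partials}
        return {fam: self.featurizer.transform(graphs, fam) for fam in fams}

    def consensus_coefficients(self) -> dict[str, float]:
        """Per-variable mean linear coefficient over partials that had the
        variable among their candidates (SCR partials only)."""
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for p in self.partials:
            if p.method != "SCR":
                continue
            candidates = p.flags_candidates if hasattr(p, "flags_candidates") else None
            cand = candidates or p.columns
            coefs = dict(zip(p.columns, p.coef))
            for name in cand:
                sums[name] = sums.get(name, 0.0) + coefs.get(name, 0.0)
                counts[name] = counts.get(name, 0) + 1
        return {k: sums[k] / counts[k] for k in sums}

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "families": self.families,
            "seed": self.seed,
            "summary": self.summary,
            "featurizer": self.featurizer.to_dict(),
            "partials": [p.to_dict() for p in self.partials],
            "partial_candidates": [getattr(p, "flags_candidates", None) for p in self.partials],
            "ad_whole_min": self.ad_whole_min.tolist(),
            "ad_whole_max": self.ad_whole_max.tolist(),
            "ad_mna_sets": [sorted(s) for s in self.ad_mna_sets],
            "training_ids": self.training_ids,
            "config": self.config.__dict__,
            "rmsep": self.rmsep,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusModel":
        partials = [PartialModel.from_dict(p) for p in d["partials"]]
        for p, cand in zip(partials, d.get("partial_candidates", [])):
            if cand is not None:
                p.flags_candidates = cand  # type: ignore[attr-defined]
        return cls(
            method=d["method"], families=d["families"], seed=d["seed"],
            partials=partials,
            featurizer=Featurizer.from_dict(d["featurizer"]),
            summary=d["summary"],
            ad_whole_min=np.asarray(d["ad_whole_min"], dtype=float),
            ad_whole_max=np.asarray(d["ad_whole_max"], dtype=float),
            ad_mna_sets=[frozenset(s) for s in d["ad_mna_sets"]],
            training_ids=list(d["training_ids"]),
            config=ConsensusConfig(**d["config"]),
            rmsep=d.get("rmsep"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConsensusModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def stability(r2_mean: float, q2_lmo_mean: float) -> float:
    """Stability criterion A = R̄² - Q̄²_LMO."""
    for v in (r2_mean, q2_lmo_mean):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"statistic {v} outside [-1, 1]")
    return r2_mean - q2_lmo_mean


def stability_class(a: float) -> str:
    """Band the stability value: <0.1 high, ≤0.2 acceptable, ≤0.3 low, else unstable."""
    if a > 0.3:
        return "unstable"
    if a < 0.1:
        return "high"
    if a <= 0.2:
        return "acceptable"
    return "low"


def _partial_family(i: int, families: str) -> str:
    if families in ("QNA", "MNA"):
        return families
    return "QNA" if i % 2 == 0 else "MNA"


def _partial_method(i: int, method: str, families: str) -> str:
    if method in ("SCR", "RBF-SCR"):
        return method
    # "Both": alternate so every family x method combination appears
    idx = i // 2 if families == "both" else i
    return "SCR" if idx % 2 == 0 else "RBF-SCR"


def _fit_partial(method: str, X: pd.DataFrame, y: np.ndarray, scr_config: SCRConfig) -> PartialModel:
    if method == "SCR":
        return fit_scr(X, y, scr_config)
    return fit_rbf_scr(X, y, scr_config)


def _fixed_refit_predict(
    partial: PartialModel,
    X: pd.DataFrame,
    y: np.ndarray,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    scr_config: SCRConfig,
) -> np.ndarray:
    """Refit a partial's weights on a row subset with selection held fixed."""
    cols = partial.columns
    Ztr = X.iloc[train_rows][cols].to_numpy(dtype=float) if cols else np.zeros((len(train_rows), 0))
    Zte = X.iloc[test_rows][cols].to_numpy(dtype=float) if cols else np.zeros((len(test_rows), 0))
    ytr = y[train_rows]
    if partial.method == "SCR":
        if not cols:
            return np.full(len(test_rows), float(ytr.mean()))
        mean = Ztr.mean(axis=0)
        scale = Ztr.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        Zs = (Ztr - mean) / scale
        yc = ytr - ytr.mean()
        p = Zs.shape[1]
        A = Zs.T @ Zs + partial.ridge * np.eye(p)
        coef = np.linalg.solve(A, Zs.T @ yc)
        return float(ytr.mean()) + ((Zte - mean) / scale) @ coef
    # RBF: rebuild the interpolant on the fold with the stored width scale
    from .scr import _pairwise_width, _rbf_kernel

    mean = Ztr.mean(axis=0) if Ztr.size else np.zeros(0)
    scale = Ztr.std(axis=0) if Ztr.size else np.zeros(0)
    scale = np.where(scale > 0, scale, 1.0)
    Zs = (Ztr - mean) / scale
    width, _ = _pairwise_width(Zs)
    K = _rbf_kernel(Zs, Zs, width)
    w = np.linalg.solve(K + scr_config.rbf_ridge * np.eye(len(ytr)), ytr - ytr.mean())
    Kte = _rbf_kernel((Zte - mean) / scale, Zs, width)
    return float(ytr.mean()) + Kte @ w


def build_consensus(
    dataset: ActivityDataSet,
    method: str = "SCR",
    families: str = "QNA",
    n_partials: int | None = None,
    seed: int = 0,
    config: ConsensusConfig | None = None,
    descriptor_config: DescriptorConfig | None = None,
    scr_config: SCRConfig | None = None,
    featurizer: Featurizer | None = None,
) -> ConsensusModel:
    """Fit a consensus model on an activity dataset with structures."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if families not in FAMILIES:
        raise ValueError(f"families must be one of {FAMILIES}")
    config = config or ConsensusConfig()
    if n_partials is None:
        n_partials = 320 if families == "both" else config.n_partials
    scr_config = scr_config or SCRConfig()

    if not check_modeling_precondition(dataset):
        raise ValueError("activity range must exceed 3 pIC50 units for modeling")
    structures = dataset.structures
    if any(s is None for s in structures):
        raise ValueError("every record needs a structure")
    y = np.asarray(dataset.pic50_values, dtype=float)
    n = len(y)

    if featurizer is None:
        featurizer = Featurizer(descriptor_config).fit(structures)

    matrices = {
        fam: featurizer.transform(structures, fam)
        for fam in (("QNA", "MNA") if families == "both" else (families,))
    }

    partials: list[PartialModel] = []
    q2_list: list[float] = []
    sd_lmo_list: list[float] = []
    n_hold = max(1, round(config.lmo_fraction * n))
    for i in range(n_partials):
        fam = _partial_family(i, families)
        meth = _partial_method(i, method, families)
        X = matrices[fam]
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        rows = rng.integers(0, n, n)
        candidates = [c for c in X.columns if c not in WHOLE_MOLECULE_NAMES]
        frac = rng.uniform(config.col_fraction_low, config.col_fraction_high)
        m = max(1, round(frac * len(candidates)))
        subset = sorted(rng.choice(len(candidates), size=m, replace=False))
        cols = [candidates[k] for k in subset] + list(WHOLE_MOLECULE_NAMES)
        partial = _fit_partial(meth, X.iloc[rows][cols], y[rows], scr_config)
        partial.family = fam
        partial.flags_candidates = cols  # type: ignore[attr-defined]
        partials.append(partial)

        # fixed-selection LMO over the full training set
        rng_lmo = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i, 1)))
        q2_rounds = []
        sq_errs: list[float] = []
        for _ in range(config.lmo_rounds):
            hold = rng_lmo.choice(n, size=n_hold, replace=False)
            mask = np.ones(n, dtype=bool)
            mask[hold] = False
            train_rows = np.flatnonzero(mask)
            pred = _fixed_refit_predict(partial, X, y, train_rows, hold, scr_config)
            err = y[hold] - pred
            denom = float(((y[hold] - y[train_rows].mean()) ** 2).sum())
            q2_rounds.append(1.0 - float(err @ err) / denom if denom else 0.0)
            sq_errs.extend((err ** 2).tolist())
        q2_list.append(float(np.mean(q2_rounds)))
        sd_lmo_list.append(float(np.sqrt(np.mean(sq_errs))))

    r2_mean = float(np.mean([p.r2 for p in partials]))
    q2_mean = float(np.mean(q2_list))
    finite_f = [min(p.f_stat, 1e6) for p in partials]
    summary = {
        "r2_mean": r2_mean,
        "q2_lmo_mean": q2_mean,
        "f_mean": float(np.mean(finite_f)),
        "sd_mean": float(np.mean(sd_lmo_list)),
        "v_mean": float(np.mean([len(p.columns) for p in partials])),
        "stability_a": stability(min(max(r2_mean, -1.0), 1.0), min(max(q2_mean, -1.0), 1.0)),
    }
    summary["stability_class"] = stability_class(summary["stability_a"])

    whole = featurizer.transform(structures, "QNA")[list(WHOLE_MOLECULE_NAMES)].to_numpy()
    mna_sets = [frozenset(featurizer.mna_multiset(g)) for g in structures]

    return ConsensusModel(
        method=method, families=families, seed=seed, partials=partials,
        featurizer=featurizer, summary=summary,
        ad_whole_min=whole.min(axis=0), ad_whole_max=whole.max(axis=0),
        ad_mna_sets=mna_sets, training_ids=dataset.ids, config=config,
    )


def _tanimoto(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _in_ad(model: ConsensusModel, graph: MolecularGraph, whole: np.ndarray,
           mna_set: frozenset[str]) -> bool:
    sim = max((_tanimoto(mna_set, s) for s in model.ad_mna_sets), default=0.0)
    if sim < model.config.ad_tanimoto:
        return False
    span = model.ad_whole_max - model.ad_whole_min
    pad = model.config.ad_range_expand * span
    lo = model.ad_whole_min - pad
    hi = model.ad_whole_max + pad
    return bool(np.all(whole >= lo) and np.all(whole <= hi))


def predict(
    model: ConsensusModel,
    structures: list[MolecularGraph],
    ids: list[str] | None = None,
    force: bool = False,
) -> list[PredictionResult]:
    """Consensus predictions with applicability-domain flags.

    Out-of-domain compounds get no numeric prediction unless ``force`` is
    set; compounds whose descriptors cannot be computed (unseen element)
    are always out-of-domain.
    """
    ids = ids or [g.name or f"mol{i+1}" for i, g in enumerate(structures)]
    results: list[PredictionResult] = []
    fams = sorted({p.family for p in model.partials})
    for g, cid in zip(structures, ids):
        try:
            rows = {fam: model.featurizer.transform([g], fam) for fam in fams}
            whole = rows[fams[0]][list(WHOLE_MOLECULE_NAMES)].to_numpy()[0]
            mna_set = frozenset(model.featurizer.mna_multiset(g))
        except KeyError as exc:
            if force:
                raise
            results.append(PredictionResult(cid, None, in_ad=False, note=str(exc)))
            continue
        in_ad = _in_ad(model, g, whole, mna_set)
        if not in_ad and not force:
            results.append(PredictionResult(cid, None, in_ad=False,
                                            note="outside applicability domain"))
            continue
        per_partial = np.array([float(p.predict(rows[p.family])[0]) for p in model.partials])
        results.append(PredictionResult(
            cid, float(per_partial.mean()), in_ad=in_ad,
            spread=float(per_partial.std()), forced=not in_ad,
        ))
    return results


def lmo_cross_validation(
    X: pd.DataFrame,
    y: np.ndarray | list[float],
    fit: Callable[[pd.DataFrame, np.ndarray], PartialModel] | None = None,
    n_rounds: int = 20,
    leave_fraction: float = 0.2,
    seed: int = 0,
) -> float:
    """Leave-many-out Q̄² with a full refit (including selection) per round.

    Each round holds out ``leave_fraction`` of the rows at random, refits on
    the rest, and scores Q² = 1 - PRESS/SS_tot on the held-out rows; the
    mean over rounds is returned.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_hold = round(leave_fraction * n)
    if n_hold < 2:
        raise ValueError("held-out fold must contain at least 2 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    fit = fit or (lambda Xt, yt: fit_scr(Xt, yt, SCRConfig()))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    q2s = []
    for _ in range(n_rounds):
        hold = rng.choice(n, size=n_hold, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        model = fit(X.iloc[mask].reset_index(drop=True), y[mask])
        pred = model.predict(X.iloc[hold])
        err = y[hold] - pred
        denom = float(((y[hold] - y[mask].mean()) ** 2).sum())
        q2s.append(1.0 - float(err @ err) / denom if denom else 0.0)
    return float(np.mean(q2s))
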