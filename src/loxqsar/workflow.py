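"""Orchestration of the full consensus-modeling study design.

The central piece is the 18-model grid: three descriptor-selection methods
(SCR, RBF-SCR, Both) crossed with three descriptor-family settings (QNA with
20 partials, MNA with 20, mixed QNA+MNA with 320) on two nested training
sets.  The first training set and external test set come from a ranked
1-in-6 split of the full compound collection; re-splitting the training set
the same way yields the second training set and the internal test set.
Models are numbered M01..M18 in the order (training set) x (method) x
(family), matching the study layout: M01-M09 on the first training set,
M10-M18 on the second.

Every run echoes its configuration into the output directory and derives
all randomness from the single top-level seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import assay_table, read_curves
from .consensus import (
    ConsensusConfig,
    ConsensusModel,
    build_consensus,
    predict,
)
from .dataset import (
    ActivityDataSet,
    check_modeling_precondition,
    ranked_split,
    set_statistics,
)
from .descriptors import DescriptorConfig, Featurizer
from .molgraph import MolecularGraph
from .scr import SCRConfig
from .validation import (
    classify_ability,
    external_metrics,
    prediction_window_report,
    systematic_error_check,
    trim_worst,
)

__all__ = ["RunConfig", "GridResult", "run_grid", "run_assay", "run_evaluate"]

logger = logging.getLogger(__name__)

#: grid cells in study order: (method, families, n_partials)
GRID_CELLS = [
    ("SCR", "QNA", 20),
    ("SCR", "MNA", 20),
    ("SCR", "both", 320),
    ("RBF-SCR", "QNA", 20),
    ("RBF-SCR", "MNA", 20),
    ("RBF-SCR", "both", 320),
    ("Both", "QNA", 20),
    ("Both", "MNA", 20),
    ("Both", "both", 320),
]

_KNOWN_KEYS = {
    "seed", "split_period", "trim_fraction", "mna_level", "qna_degree",
    "mna_min_count", "mna_max_columns", "n_partials_single", "n_partials_mixed",
    "lmo_rounds", "lmo_fraction", "t_threshold", "output_dir", "save_models",
}


@dataclass
class RunConfig:
    seed: int = 0
    split_period: int = 6
    trim_fraction: float = 0.05
    mna_level: int = 2
    qna_degree: int = 3
    mna_min_count: int = 3
    mna_max_columns: int = 150
    n_partials_single: int = 20
    n_partials_mixed: int = 320
    lmo_rounds: int = 20
    lmo_fraction: float = 0.2
    t_threshold: float = 2.0
    output_dir: str = "results/grid"
    save_models: bool = False

    def descriptor_config(self) -> DescriptorConfig:
        return DescriptorConfig(
            mna_level=self.mna_level,
            qna_degree=self.qna_degree,
            mna_min_count=self.mna_min_count,
            mna_max_columns=self.mna_max_columns,
        )

    def consensus_config(self, n_partials: int) -> ConsensusConfig:
        return ConsensusConfig(
            n_partials=n_partials,
            lmo_rounds=self.lmo_rounds,
            lmo_fraction=self.lmo_fraction,
        )

    def scr_config(self) -> SCRConfig:
        return SCRConfig(t_threshold=self.t_threshold)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class GridResult:
    models: dict[str, ConsensusModel]           # "M01".."M18"
    summaries: pd.DataFrame                     # per-model training summary
    metric_reports: pd.DataFrame                # per model/set/coverage metrics
    splits: dict[str, ActivityDataSet]          # TrS1/TS1/TrS2/TS2
    config: RunConfig


def _metric_block(y_obs, y_pred, train_mean, train_range, trim_fraction):
    rows = {}
    rep100 = external_metrics(y_obs, y_pred, train_mean=train_mean)
    rows["100"] = rep100
    yo, yp, removed = trim_worst(y_obs, y_pred, trim_fraction)
    rep95 = external_metrics(yo, yp, train_mean=train_mean)
    rows["95"] = rep95
    return rows, removed


def run_grid(config: RunConfig, dataset: ActivityDataSet) -> GridResult:
    """Fit the full model grid and compute validation reports.

    ``dataset`` must carry structures and pass the activity-range
    precondition (Δ > 3 pIC50 units).
    """
    if not check_modeling_precondition(dataset):
        raise ValueError("activity range must exceed 3 pIC50 units")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json(), encoding="utf-8")

    split1 = ranked_split(dataset, config.split_period)
    split2 = ranked_split(split1.train, config.split_period)
    sets = {
        "TrS1": split1.train, "TS1": split1.test,
        "TrS2": split2.train, "TS2": split2.test,
    }
    logger.info("splits: TrS1=%d TS1=%d TrS2=%d TS2=%d",
                *(len(sets[k]) for k in ("TrS1", "TS1", "TrS2", "TS2")))

    models: dict[str, ConsensusModel] = {}
    summary_rows = []
    metric_rows = []
    model_idx = 0
    for train_name, test_names in (("TrS1", ("TrS1", "TS1")), ("TrS2", ("TrS2", "TS1", "TS2"))):
        train = sets[train_name]
        train_mean = float(np.mean(train.pic50_values))
        train_range = float(np.ptp(train.pic50_values))
        featurizer = Featurizer(config.descriptor_config()).fit(train.structures)
        for method, families, n_partials in GRID_CELLS:
            model_idx += 1
            mid = f"M{model_idx:02d}"
            n_p = (config.n_partials_mixed if families == "both"
                   else config.n_partials_single)
            logger.info("fitting %s: %s / %s / %d partials on %s",
                        mid, method, families, n_p, train_name)
            model = build_consensus(
                train, method=method, families=families, n_partials=n_p,
                seed=int(np.random.SeedSequence(entropy=config.seed,
                                                spawn_key=(model_idx,)).generate_state(1)[0] % (2**31)),
                config=config.consensus_config(n_p),
                scr_config=config.scr_config(),
                featurizer=featurizer,
            )
            models[mid] = model
            s = model.summary
            summary_rows.append({
                "model": mid, "training_set": train_name, "method": method,
                "families": families, "n": len(train), "n_partials": n_p,
                "r2_mean": s["r2_mean"], "q2_lmo_mean": s["q2_lmo_mean"],
                "f_mean": s["f_mean"], "sd_mean": s["sd_mean"],
                "v_mean": s["v_mean"], "stability_a": s["stability_a"],
                "stability_class": s["stability_class"],
            })

            mdir = out_dir / mid
            mdir.mkdir(exist_ok=True)
            for set_name in test_names:
                eval_set = sets[set_name]
                preds = predict(model, eval_set.structures, ids=eval_set.ids, force=True)
                y_pred = np.array([p.predicted for p in preds])
                y_obs = np.array(eval_set.pic50_values)
                blocks, removed = _metric_block(
                    y_obs, y_pred, train_mean, train_range, config.trim_fraction
                )
                if set_name == "TS1" and model.rmsep is None:
                    model.rmsep = blocks["100"].rmse
                sysdiag = systematic_error_check(y_obs, y_pred)
                for coverage, rep in blocks.items():
                    ability = classify_ability(rep, train_range)
                    row = {"model": mid, "set": set_name, "coverage": coverage}
                    row.update(rep.rounded())
                    row["ability"] = ability.level
                    row["systematic_error"] = sysdiag["systematic"]
                    metric_rows.append(row)
                pd.DataFrame(
                    {"id": eval_set.ids, "observed": y_obs, "predicted": y_pred}
                ).to_csv(mdir / f"predictions_{set_name}.tsv", sep="\t", index=False)
            if config.save_models:
                model.save(mdir / "model.json")

    summaries = pd.DataFrame(summary_rows)
    metric_reports = pd.DataFrame(metric_rows)
    summaries.round(3).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    metric_reports.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    stats = set_statistics(sets["TrS1"])
    (out_dir / "set_statistics.json").write_text(json.dumps({
        "TrS1": {"n": len(sets["TrS1"]), "mean": stats.mean_pic50,
                 "delta": stats.delta_pic50, "thresholds": stats.thresholds},
    }, default=str), encoding="utf-8")
    return GridResult(models=models, summaries=summaries,
                      metric_reports=metric_reports, splits=sets, config=config)


def run_assay(curves_path: str | Path, output_path: str | Path | None = None) -> pd.DataFrame:
    """Process dose-inhibition curves into an IC50/pIC50 table."""
    curves = read_curves(curves_path)
    table = assay_table(curves)
    if output_path is not None:
        table.to_csv(output_path, sep="\t", index=False)
    return table


def run_evaluate(
    model: ConsensusModel | str | Path,
    structures: list[MolecularGraph],
    experimentals: list[float],
    ids: list[str] | None = None,
    rmsep: float | None = None,
) -> dict:
    """Evaluate external compounds against a stored confidence window.

    Returns prediction rows (with |pred - exp| against the ±2·RMSEP window)
    and the out-of-domain compounds listed separately.
    """
    if not isinstance(model, ConsensusModel):
        model = ConsensusModel.load(model)
    rmsep = rmsep if rmsep is not None else model.rmsep
    if rmsep is None:
        raise ValueError("no RMSEP stored on the model; pass rmsep explicitly")
    preds = predict(model, structures, ids=ids)
    in_dom = [(p, e) for p, e in zip(preds, experimentals) if p.predicted is not None]
    out_dom = [p for p in preds if p.predicted is None]
    rows = prediction_window_report(
        rmsep,
        [p.predicted for p, _ in in_dom],
        [e for _, e in in_dom],
        ids=[p.compound_id for p, _ in in_dom],
    )
    for row, (p, _) in zip(rows, in_dom):
        row["in_ad"] = p.in_ad
        row["spread"] = p.spread
    return {
        "window": 2.0 * rmsep,
        "rows": rows,
        "out_of_domain": [p.compound_id for p in out_dom],
    }
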