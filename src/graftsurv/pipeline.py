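"""End-to-end workflow: simulate -> preprocess -> select -> train -> evaluate.

Each stage writes plain-text artifacts (CSV tables, a JSON model file, a
run log) into the output directory, together with a manifest recording the
configuration hash and seed, so a rerun with the same configuration
reproduces byte-identical outputs. Every randomized stage derives its own
seed deterministically from the single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ann, preprocessing
from .abo import ABOConfig
from .cohort import CohortTable
from .errors import ConfigurationError
from .features import (
    BinningConfig,
    ClassifierConfig,
    SelectionConfig,
    SelectionResult,
    hybrid_select,
)
from .metrics import MetricsReport, compute_report
from .synthetic import CohortSpec, GroundTruth, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full run needs; precedence CLI flag > file > default."""

    seed: int = 0
    output_dir: str = "graftsurv_run"
    input_csv: str | None = None  # simulate a cohort when None
    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(n_patients=2000))
    horizon_days: int = preprocessing.DEFAULT_HORIZON_DAYS
    max_row_missing_fraction: float = 0.3
    train_fraction: float = 0.7
    stratify: bool = True
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_hidden: int | None = None
    hidden_activation: str = "tanh"
    output_function: str = "logistic"
    train_abo: ABOConfig = field(
        default_factory=lambda: ABOConfig(
            n_buffalo=40, max_iterations=1000, bounds=(-2.0, 2.0),
            restart_patience=5,
        )
    )
    scope: str = "all_weights"
    cutoff: float = 0.5

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, np.ndarray):
                return [float(v) for v in obj.tolist()]
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return {
            f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)
        }

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("output_dir", None)  # relocating a run keeps its hash
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            raw["cohort"] = CohortSpec(**raw["cohort"])
        if "selection" in raw and isinstance(raw["selection"], dict):
            sel = dict(raw["selection"])
            if isinstance(sel.get("binning"), dict):
                sel["binning"] = BinningConfig(**sel["binning"])
            if isinstance(sel.get("classifier"), dict):
                sel["classifier"] = ClassifierConfig(**sel["classifier"])
            if isinstance(sel.get("wrapper_abo"), dict):
                sel["wrapper_abo"] = _abo_from_dict(sel["wrapper_abo"])
            raw["selection"] = SelectionConfig(**sel)
        if "train_abo" in raw and isinstance(raw["train_abo"], dict):
            raw["train_abo"] = _abo_from_dict(raw["train_abo"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def _abo_from_dict(raw: dict) -> ABOConfig:
    raw = dict(raw)
    if "bounds" in raw:
        raw["bounds"] = tuple(raw["bounds"])
    return ABOConfig(**raw)


@dataclass
class PipelineResult:
    config: RunConfig
    report: MetricsReport
    selection: SelectionResult
    model: ann.TrainedNetwork
    truth: GroundTruth | None
    output_dir: Path


# ---------------------------------------------------------------------------
# stages


def load_or_simulate(config: RunConfig) -> tuple[CohortTable, GroundTruth | None]:
    if config.input_csv is not None:
        return CohortTable.from_csv(config.input_csv), None
    spec = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, 0))
    table, truth = generate_cohort(spec)
    return table, truth


def preprocess(
    config: RunConfig, table: CohortTable, run_log: list[str] | None = None
) -> CohortTable:
    """Clean, drop over-sparse rows, impute, re-derive the censoring label."""
    table = preprocessing.clean_table(table, run_log)
    table = preprocessing.drop_sparse_rows(
        table, config.max_row_missing_fraction, run_log
    )
    table = preprocessing.impute_table(table, run_log)
    return preprocessing.attach_labels(table, config.horizon_days)


def _features_and_labels(table: CohortTable) -> tuple[pd.DataFrame, np.ndarray]:
    X = table.frame[table.columns_by_tag("preop")]
    y = table.frame[table.outcome_column].to_numpy()
    return X, y


def select_features(config: RunConfig, train: CohortTable) -> SelectionResult:
    X, y = _features_and_labels(train)
    sel_cfg = dataclasses.replace(config.selection, seed=stage_seed(config.seed, 2))
    return hybrid_select(X, y, sel_cfg)


def train_model(
    config: RunConfig, train: CohortTable, mask_columns: list[str]
) -> ann.TrainedNetwork:
    X = train.frame[mask_columns].to_numpy(dtype=float)
    y = train.frame[train.outcome_column].to_numpy()
    if config.n_hidden is not None:
        arch = ann.NetworkArch(
            n_inputs=X.shape[1],
            n_hidden=config.n_hidden,
            hidden_activation=config.hidden_activation,
            output_function=config.output_function,
        )
    else:
        arch = ann.default_arch(
            X.shape[1],
            hidden_activation=config.hidden_activation,
            output_function=config.output_function,
        )
    abo_cfg = dataclasses.replace(config.train_abo, seed=stage_seed(config.seed, 3))
    return ann.train_with_abo(X, y, arch=arch, abo_config=abo_cfg, scope=config.scope)


def evaluate_model(
    config: RunConfig,
    model: ann.TrainedNetwork,
    test: CohortTable,
    mask_columns: list[str],
) -> MetricsReport:
    X = test.frame[mask_columns].to_numpy(dtype=float)
    y = test.frame[test.outcome_column].to_numpy()
    scores = ann.predict_proba(model, X)
    pred = (scores >= config.cutoff).astype(int)
    return compute_report(y, pred, scores=scores)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the whole workflow and (optionally) write all artifacts."""
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    run_log: list[str] = []

    cohort, truth = load_or_simulate(config)
    processed = preprocess(config, cohort, run_log)
    train, test = preprocessing.split_train_test(
        processed,
        config.train_fraction,
        seed=stage_seed(config.seed, 1),
        stratify=config.stratify,
    )
    selection = select_features(config, train)
    mask_columns = selection.mask.selected_names()
    model = train_model(config, train, mask_columns)
    report = evaluate_model(config, model, test, mask_columns)

    if write:
        cohort.to_csv(outdir / "cohort.csv")
        if truth is not None:
            truth.to_json(outdir / "ground_truth.json")
        processed.to_csv(outdir / "processed.csv")
        (outdir / "run_log.txt").write_text("\n".join(run_log) + "\n")
        selection.ranking.to_frame().to_csv(outdir / "ranking.csv", index=False)
        selection.mask.to_frame().to_csv(outdir / "mask.csv", index=False)
        model.to_json(outdir / "model.json")
        pd.DataFrame({"best_objective": model.history}).to_csv(
            outdir / "training_history.csv", index_label="iteration"
        )
        report.to_csv(outdir / "metrics.csv")
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_train": train.n_patients,
            "n_test": test.n_patients,
            "n_features_selected": selection.mask.n_selected,
            "stages": sorted(selection.stage_masks),
            "artifacts": [
                "cohort.csv", "processed.csv", "run_log.txt", "ranking.csv",
                "mask.csv", "model.json", "training_history.csv", "metrics.csv",
            ],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return PipelineResult(
        config=config,
        report=report,
        selection=selection,
        model=model,
        truth=truth,
        output_dir=outdir,
    )
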