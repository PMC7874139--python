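"""End-to-end orchestration: extract -> balance -> rank -> IFS -> train -> evaluate.

A run is driven by a fully-serializable :class:`PipelineConfig` (YAML on
disk); every stage writes its artifact into the run directory so a run can
be audited and reproduced from the archived config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import classify
from .balancing import FeatureMatrix, smote_balance
from .errors import ConfigError, InputError, LyticPredError
from .evaluation import EvaluationReport, accuracy_evaluator, jackknife, kfold
from .features import (
    ACSTable,
    BLOCK_NAMES,
    NUCLEI,
    EncoderConfig,
    encode_combined,
)
from .io import LabeledDataset, load_dataset
from .selection import fscore_rank, ifs_select

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a run.

    Defaults mirror the published operating point: all four feature blocks,
    lg=28, lambda=17, all four nuclei, SMOTE to parity applied once before
    evaluation (``smote_mode="outside"``), jackknife protocol.
    """

    pos_fasta: str = "pos.fasta"
    neg_fasta: str = "neg.fasta"
    manifest: str | None = None
    acs_table: str | None = None
    blocks: tuple[str, ...] = BLOCK_NAMES
    lg: int = 28
    lam: int = 17
    nuclei: tuple[str, ...] = NUCLEI
    acacs_variant: str = "difference"
    smote_mode: str = "outside"
    smote_k: int = 5
    seed: int = 1
    fscore_variant: str = "symmetric"
    run_ifs: bool = True
    ifs_step: int = 1
    ifs_folds: int = 3
    do_grid_search: bool = False
    svm_c: float = 1.0
    svm_gamma: float | None = None
    svm_folds: int = 5
    protocol: str = "jackknife"
    eval_k: int = 5

    def __post_init__(self):
        if self.protocol not in ("jackknife", "kfold"):
            raise ConfigError("protocol must be 'jackknife' or 'kfold'")
        if self.smote_mode not in ("none", "outside", "inside"):
            raise ConfigError("smote_mode must be none/outside/inside")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["blocks"] = list(self.blocks)
        d["nuclei"] = list(self.nuclei)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "blocks" in d:
            d["blocks"] = tuple(d["blocks"])
        if "nuclei" in d:
            d["nuclei"] = tuple(d["nuclei"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # -- derived pieces ----------------------------------------------------

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            lg=self.lg,
            lam=self.lam,
            nuclei=self.nuclei,
            acacs_variant=self.acacs_variant,
        )

    def svm_config(self) -> classify.SVMConfig:
        return classify.SVMConfig(c=self.svm_c, gamma=self.svm_gamma)


def build_feature_matrix(
    dataset: LabeledDataset,
    config: PipelineConfig,
    table: ACSTable | None = None,
) -> FeatureMatrix:
    """Encode every record of a dataset into one feature matrix."""
    if "acACS" in config.blocks and table is None:
        table = (
            ACSTable.from_file(config.acs_table)
            if config.acs_table
            else ACSTable.default()
        )
    enc = config.encoder_config()
    vectors = []
    for rec in dataset.records:
        vectors.append(
            encode_combined(
                rec,
                profile=dataset.profiles.get(rec.id),
                track=dataset.tracks.get(rec.id),
                table=table,
                config=enc,
                blocks=config.blocks,
            )
        )
    return FeatureMatrix.from_vectors(
        ids=[r.id for r in dataset.records],
        vectors=vectors,
        labels=[r.label for r in dataset.records],
    )


def _evaluate(
    matrix: FeatureMatrix, config: PipelineConfig, trainer
) -> EvaluationReport:
    if config.protocol == "jackknife":
        return jackknife(
            matrix,
            trainer,
            smote_mode=config.smote_mode,
            seed=config.seed,
            smote_k=config.smote_k,
        )
    return kfold(
        matrix,
        trainer,
        k=config.eval_k,
        smote_mode=config.smote_mode,
        seed=config.seed,
        smote_k=config.smote_k,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> EvaluationReport:
    """Execute all stages, writing artifacts into ``outdir``.

    Artifacts: ``config.yaml``, ``features.csv``, ``balanced.csv``,
    ``ranking.csv``, ``ifs_curve.csv`` (when IFS runs), ``model.joblib``,
    ``report.json``. Any stage failure is re-raised with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    chash = config.config_hash()

    def _stage(name):
        logger.info("[%s] stage %s", chash, name)
        return time.perf_counter()

    try:
        stage = "extract"
        t0 = _stage(stage)
        dataset = load_dataset(config.pos_fasta, config.neg_fasta, config.manifest)
        matrix = build_feature_matrix(dataset, config)
        matrix.to_csv(outdir / "features.csv")

        stage = "balance"
        t0 = _stage(stage)
        working = (
            smote_balance(matrix, k=config.smote_k, seed=config.seed)
            if config.smote_mode == "outside"
            else matrix
        )
        working.to_csv(outdir / "balanced.csv")

        stage = "rank"
        t0 = _stage(stage)
        ranking = fscore_rank(working, variant=config.fscore_variant)
        ranking.to_csv(outdir / "ranking.csv")

        stage = "ifs"
        t0 = _stage(stage)
        trainer = classify.svm_trainer(config.svm_config())
        if config.run_ifs:
            evaluator = accuracy_evaluator(
                trainer, k=config.ifs_folds, seed=config.seed
            )
            curve = ifs_select(working, ranking, evaluator, step=config.ifs_step)
            curve.to_csv(outdir / "ifs_curve.csv")
            selected = ranking.top(curve.selected_d)
        else:
            selected = ranking.names

        stage = "train"
        t0 = _stage(stage)
        train_matrix = working.subset_features(selected)
        svm_cfg = config.svm_config()
        if config.do_grid_search:
            svm_cfg = classify.grid_search(
                train_matrix, svm_cfg, folds=config.svm_folds, seed=config.seed
            )
            trainer = classify.svm_trainer(svm_cfg)
        model = classify.train(train_matrix, svm_cfg)
        model.save(outdir / "model.joblib")

        stage = "evaluate"
        t0 = _stage(stage)
        report = _evaluate(matrix.subset_features(selected), config, trainer)
        report.to_json(outdir / "report.json")
        (outdir / "report.tsv").write_text(report.to_tsv_line() + "\n")
        return report
    except LyticPredError as exc:
        raise LyticPredError(f"stage {stage!r} failed: {exc}") from exc


def _nonempty_nuclei_subsets() -> list[tuple[str, ...]]:
    subsets: list[tuple[str, ...]] = []
    for mask in range(1, 16):
        subsets.append(
            tuple(nuc for i, nuc in enumerate(NUCLEI) if mask & (1 << i))
        )
    return subsets


def sweep(
    config: PipelineConfig,
    parameter: str,
    values: Sequence | str,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Evaluate one configuration per parameter value.

    ``parameter`` is one of ``lg``, ``lam`` or ``nuclei``; for ``nuclei``
    the string ``"all"`` expands to the 15 non-empty subsets of the four
    nuclei. Each point runs extract -> balance -> train -> evaluate (IFS
    and grid search are skipped for speed). Per-value failures are recorded
    in the ``error`` column and the sweep continues.
    """
    if parameter not in ("lg", "lam", "nuclei"):
        raise ConfigError("parameter must be 'lg', 'lam' or 'nuclei'")
    if parameter == "lg" and "PSSM-AC" not in config.blocks:
        raise ConfigError("lg sweep requires the PSSM-AC block")
    if parameter in ("lam", "nuclei") and "acACS" not in config.blocks:
        raise ConfigError(f"{parameter} sweep requires the acACS block")
    if parameter == "nuclei" and values == "all":
        values = _nonempty_nuclei_subsets()
    values = list(values)
    if not values:
        raise InputError("empty sweep value list")

    dataset = load_dataset(config.pos_fasta, config.neg_fasta, config.manifest)
    rows = []
    for value in values:
        cfg = replace(
            config,
            run_ifs=False,
            do_grid_search=False,
            **{("nuclei" if parameter == "nuclei" else parameter): (
                tuple(value) if parameter == "nuclei" else int(value)
            )},
        )
        label = "+".join(value) if parameter == "nuclei" else value
        try:
            matrix = build_feature_matrix(dataset, cfg)
            trainer = classify.svm_trainer(cfg.svm_config())
            report = _evaluate(matrix, cfg, trainer)
            rows.append({"value": label, "accuracy": report.acc, "error": ""})
        except LyticPredError as exc:
            rows.append({"value": label, "accuracy": float("nan"), "error": str(exc)})
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"sweep_{parameter}.csv", index=False)
        _plot_sweep(table, parameter, outdir / f"sweep_{parameter}.png")
    return table


def _plot_sweep(table: pd.DataFrame, parameter: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = table[table["error"] == ""]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ok["value"].astype(str), ok["accuracy"], marker="o", ms=4)
    ax.set_xlabel(parameter)
    ax.set_ylabel("accuracy (%)")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
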