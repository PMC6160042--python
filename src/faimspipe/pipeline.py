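"""End-to-end pipeline orchestration.

The recommended configuration — run 2, full 2-D DWT, sigma = 0, filter
selection with nKeep = 2, no PCA, all five classifiers — is the
default.  Alternative run selectors (single run, run subtraction, run
averaging, probability ensembling across runs) and demographic feature
modes (off / only / combined) cover the pipeline's comparison modes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io import (
    FAIMSRun,
    FeatureTable,
    SampleRecord,
    build_table,
    combine_mean,
    combine_subtract,
    read_metadata,
    read_run,
)
from .metrics import ROCSummary, roc_points, roc_summary
from .models import CVSpec, ModelSpec, CVResult, MODEL_KINDS, cross_validate, probability_ensemble
from .selection import SelectionSpec
from .simulate import SynthSpec, generate_cohort
from .wavelets import WaveletSpec, transform_table

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "demographics_table"]

logger = logging.getLogger(__name__)

RUN_SELECTORS = ("run1", "run2", "run3", "subtract13", "subtract31", "run_mean", "prob_ensemble")


@dataclass
class PipelineConfig:
    """One pipeline execution, fully specified.

    Exactly one of ``data_dir`` (run files + metadata.csv in the
    package's text dialect) or ``synth`` (a synthetic-cohort spec) must
    be given.
    """

    run_selector: str = "run2"
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    selection: SelectionSpec = field(default_factory=SelectionSpec)
    cv: CVSpec = field(default_factory=CVSpec)
    models: tuple[str, ...] = MODEL_KINDS
    demographics: str = "off"  # off | only | combined
    n_boot: int = 2000
    data_dir: str | None = None
    synth: SynthSpec | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.run_selector not in RUN_SELECTORS:
            raise ValueError(f"run_selector must be one of {RUN_SELECTORS}")
        if self.demographics not in ("off", "only", "combined"):
            raise ValueError("demographics must be off/only/combined")
        if (self.data_dir is None) == (self.synth is None):
            raise ValueError("give exactly one of data_dir or synth")
        for m in self.models:
            if m not in MODEL_KINDS:
                raise ValueError(f"unknown model {m!r}")


@dataclass
class PipelineReport:
    """Predictions and metrics for every model in one pipeline run."""

    predictions: dict[str, np.ndarray]
    labels: list[str]
    sample_ids: list[str]
    summaries: dict[str, ROCSummary]
    selected_features: list[list[str]]
    fold_assignment: np.ndarray
    config: PipelineConfig


def demographics_table(records: list[SampleRecord]) -> FeatureTable:
    """The four demographic covariates as a feature table (sex as 0/1)."""
    values = np.array(
        [[1.0 if r.sex == "M" else 0.0, r.age, r.alcohol, r.bmi] for r in records]
    )
    ids = [r.sample_id for r in records]
    return FeatureTable(ids, ["sex", "age", "alcohol", "bmi"], values, "demographics")


def _load_inputs(config: PipelineConfig) -> tuple[list[FAIMSRun], list[SampleRecord]]:
    if config.synth is not None:
        return generate_cohort(config.synth)
    data_dir = Path(config.data_dir)
    records = read_metadata(data_dir / "metadata.csv")
    runs = [read_run(p) for p in sorted(data_dir.glob("*.faims.tsv"))]
    if not runs:
        raise FileNotFoundError(f"no *.faims.tsv run files under {data_dir}")
    return runs, records


def _wavelet_stage(table: FeatureTable, config: PipelineConfig, rows: int, cols: int) -> FeatureTable:
    return transform_table(table, config.wavelet, rows, cols)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute input assembly → wavelets → fold-safe CV → ROC summaries."""
    runs, records = _load_inputs(config)
    order = {r.sample_id: i for i, r in enumerate(records)}
    rows, cols = runs[0].shape
    labels = [r.label for r in records]
    demo = demographics_table(records)
    model_specs = [ModelSpec(kind) for kind in config.models]

    def features_for(run_index: int) -> FeatureTable:
        raw = build_table(runs, run_index)
        raw = raw.take_rows([raw.sample_ids.index(r.sample_id) for r in records])
        return _wavelet_stage(raw, config, rows, cols)

    extra = demo if config.demographics == "combined" else None

    if config.run_selector == "prob_ensemble" and config.demographics != "only":
        per_run_results = [
            cross_validate(
                features_for(idx), labels, model_specs, config.selection, config.cv, extra
            )
            for idx in (1, 2, 3)
        ]
        predictions = {
            kind: probability_ensemble([r.predictions[kind] for r in per_run_results])
            for kind in config.models
        }
        result = CVResult(
            predictions,
            per_run_results[1].selected_features,
            per_run_results[0].fold_assignment,
        )
    else:
        if config.demographics == "only":
            table = demo
            selection = SelectionSpec(
                sigma=config.selection.sigma,
                nkeep=demo.n_features,
                method="filter",
            )
        else:
            selection = config.selection
            if config.run_selector in ("run1", "run2", "run3"):
                table = features_for(int(config.run_selector[-1]))
            elif config.run_selector == "subtract13":
                table = _subtract(runs, records, config, rows, cols, 1, 3)
            elif config.run_selector == "subtract31":
                table = _subtract(runs, records, config, rows, cols, 3, 1)
            else:  # run_mean
                raws = [build_table(runs, i) for i in (1, 2, 3)]
                raws = [
                    t.take_rows([t.sample_ids.index(r.sample_id) for r in records])
                    for t in raws
                ]
                table = _wavelet_stage(combine_mean(raws), config, rows, cols)
        result = cross_validate(table, labels, model_specs, selection, config.cv, extra)

    summaries = {
        kind: roc_summary(
            labels, result.predictions[kind].probabilities, config.n_boot, config.cv.seed
        )
        for kind in config.models
    }
    report = PipelineReport(
        predictions={k: result.predictions[k].probabilities for k in config.models},
        labels=labels,
        sample_ids=[r.sample_id for r in records],
        summaries=summaries,
        selected_features=result.selected_features,
        fold_assignment=result.fold_assignment,
        config=config,
    )
    if config.outdir is not None:
        _write_outputs(report, Path(config.outdir))
    return report


def _subtract(runs, records, config, rows, cols, a: int, b: int) -> FeatureTable:
    ta, tb = build_table(runs, a), build_table(runs, b)
    idx = [ta.sample_ids.index(r.sample_id) for r in records]
    ta, tb = ta.take_rows(idx), tb.take_rows(idx)
    return _wavelet_stage(combine_subtract(ta, tb), config, rows, cols)


def _write_outputs(report: PipelineReport, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for kind, probs in report.predictions.items():
        for sid, label, fold, p in zip(
            report.sample_ids, report.labels, report.fold_assignment, probs
        ):
            rows.append(dict(sample_id=sid, model=kind, fold=int(fold), probability=p, label=label))
    pd.DataFrame(rows).to_csv(outdir / "predictions.csv", index=False)

    metrics = {kind: s.to_dict() for kind, s in report.summaries.items()}
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))

    for kind, probs in report.predictions.items():
        roc_points(report.labels, probs).to_csv(
            outdir / f"roc_{kind}.tsv", sep="\t", index=False
        )

    sel_rows = [
        dict(fold=f, feature_id=fid)
        for f, feats in enumerate(report.selected_features)
        for fid in feats
    ]
    pd.DataFrame(sel_rows).to_csv(outdir / "selected_features.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": _config_to_dict(report.config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _config_to_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["models"] = list(config.models)
    if config.synth is not None:
        d["synth"] = asdict(config.synth)
        d["synth"]["marker_peaks"] = list(config.synth.marker_peaks)
        d["synth"]["volatile_peaks"] = list(config.synth.volatile_peaks)
        d["synth"]["peak_width"] = list(config.synth.peak_width)
    return d
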