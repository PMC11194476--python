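"""End-to-end orchestration of the two-stage subtyping pipeline.

Stage 1 standardizes the genomics views, builds per-view patient
graphs, trains the genomics-to-protein translation GCNs on the
protein-observed samples and predicts protein expression for all
samples. Stage 2 rebuilds a patient graph from the predicted protein
matrix, trains the deep subspace contrastive clustering model and
spectrally clusters the learned coefficients. Evaluation (log-rank
survival separation and clinical enrichment) runs when a clinical
table is supplied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .datamodel import (
    ClinicalTable,
    MultiOmicsDataset,
    OmicsMatrix,
    align_dataset,
    read_clinical_table,
    read_omics_matrix,
    standardize,
    write_labels,
    write_omics_matrix,
)
from .evaluation import EvaluationReport, count_enriched_clinical, logrank_neglog10_p, write_report
from .subspace import DsccConfig, SelfExpressionModel, ClusterResult, cluster_coefficients, train_dscc
from .translation import (
    TranslationConfig,
    TranslationModel,
    predict_proteins,
    train_translation,
    write_training_log,
)

__all__ = ["RunConfig", "PipelineResult", "run_from_dataset", "run_pipeline"]

logger = logging.getLogger("omicsubtypes")


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    view_paths: list[str]
    protein_path: str
    out_dir: str
    clinical_path: str | None = None
    orientation: str = "rows"
    n_clusters: int = 3
    translation: TranslationConfig = dataclasses.field(default_factory=TranslationConfig)
    clustering: DsccConfig = dataclasses.field(default_factory=DsccConfig)
    evaluate: bool = True
    seed: int = 0

    @staticmethod
    def from_yaml(path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        data = raw.get("data", {})
        clustering_raw = dict(raw.get("clustering", {}))
        n_clusters = int(clustering_raw.pop("n_clusters", raw.get("n_clusters", 3)))
        translation_raw = dict(raw.get("translation", {}))
        if "hidden_dim" in translation_raw:
            translation_raw["hidden_dim"] = int(translation_raw["hidden_dim"])
        if "encoder_dims" in clustering_raw:
            clustering_raw["encoder_dims"] = tuple(clustering_raw["encoder_dims"])
        kwargs = dict(
            view_paths=list(data.get("views", [])),
            protein_path=data.get("protein", ""),
            clinical_path=data.get("clinical"),
            orientation=data.get("orientation", "rows"),
            out_dir=data.get("out_dir", "runs/latest"),
            n_clusters=n_clusters,
            translation=TranslationConfig(**translation_raw),
            clustering=DsccConfig(**clustering_raw),
            evaluate=bool(raw.get("evaluation", {}).get("enabled", True)),
            seed=int(raw.get("seed", 0)),
        )
        kwargs.update(overrides)
        return RunConfig(**kwargs)


@dataclasses.dataclass
class PipelineResult:
    """In-memory outputs of one pipeline run."""

    dataset: MultiOmicsDataset
    translation_model: TranslationModel
    predicted_protein: OmicsMatrix
    dscc_model: SelfExpressionModel
    cluster_result: ClusterResult
    report: EvaluationReport | None


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_from_dataset(
    dataset: MultiOmicsDataset,
    n_clusters: int,
    clinical: ClinicalTable | None = None,
    translation_config: TranslationConfig | None = None,
    clustering_config: DsccConfig | None = None,
    seed: int = 0,
    pre_standardized: bool = False,
) -> PipelineResult:
    """Run translation, clustering and (optionally) evaluation on a dataset."""
    tcfg = translation_config or TranslationConfig()
    ccfg = clustering_config or DsccConfig()
    if tcfg.n_clusters is None:
        tcfg = dataclasses.replace(tcfg, n_clusters=n_clusters)
    if ccfg.n_clusters is None:
        ccfg = dataclasses.replace(ccfg, n_clusters=n_clusters)
    seed_t, seed_c, seed_s = _derived_seeds(seed, 3)

    if not pre_standardized:
        views = [standardize(v) for v in dataset.views]
        protein = _standardize_observed(dataset.protein, dataset.protein_mask)
        dataset = MultiOmicsDataset(views, protein, dataset.protein_mask)
    logger.info(
        "stage=translate n=%d views=%s observed=%d",
        dataset.n_samples,
        [v.n_features for v in dataset.views],
        dataset.n_observed,
    )
    model = train_translation(dataset, tcfg, seed=seed_t)
    predicted = predict_proteins(model, dataset)
    logger.info("stage=cluster predicted_shape=%s k=%d", predicted.values.shape, n_clusters)
    dscc = train_dscc(predicted, ccfg, seed=seed_c)
    clusters = cluster_coefficients(
        dscc, n_clusters, seed=seed_s, kmeans_restarts=ccfg.kmeans_restarts
    )
    report = None
    if clinical is not None:
        neglog = logrank_neglog10_p(
            clinical.survival_time, clinical.event, clusters.labels
        )
        n_enriched, per_param = count_enriched_clinical(clinical, clusters.labels)
        report = EvaluationReport(
            neglog10_p=neglog, n_enriched=n_enriched, per_parameter=per_param
        )
        logger.info(
            "stage=evaluate neglog10_p=%.3f n_enriched=%d", neglog, n_enriched
        )
    return PipelineResult(
        dataset=dataset,
        translation_model=model,
        predicted_protein=predicted,
        dscc_model=dscc,
        cluster_result=clusters,
        report=report,
    )


def _standardize_observed(protein: OmicsMatrix, mask: np.ndarray) -> OmicsMatrix:
    """Z-score protein columns using observed rows only; masked rows -> 0."""
    obs = protein.values[mask]
    mu = obs.mean(axis=0)
    sd = obs.std(axis=0, ddof=1) if obs.shape[0] > 1 else np.zeros(obs.shape[1])
    out = np.where(sd > 0, (protein.values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    out[~mask] = 0.0
    return OmicsMatrix(protein.name, list(protein.sample_ids), list(protein.feature_ids), out)


def _config_manifest(config: RunConfig) -> dict:
    blob = {
        "data": {
            "views": list(config.view_paths),
            "protein": config.protein_path,
            "clinical": config.clinical_path,
            "orientation": config.orientation,
            "out_dir": config.out_dir,
        },
        "n_clusters": config.n_clusters,
        "translation": dataclasses.asdict(config.translation),
        "clustering": dataclasses.asdict(config.clustering),
        "evaluation": {"enabled": config.evaluate},
        "seed": config.seed,
    }
    digest = hashlib.sha256(
        json.dumps(blob, sort_keys=True, default=str).encode()
    ).hexdigest()
    blob["config_sha256"] = digest
    return blob


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline from files and write all outputs.

    Writes labels.tsv, predicted_protein.tsv, loss logs, the evaluation
    report and a manifest capturing the resolved configuration and seed.
    On failure a FAILED marker naming the stage is left in the run
    directory and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        views = [
            read_omics_matrix(p, orientation=config.orientation)
            for p in config.view_paths
        ]
        protein = read_omics_matrix(config.protein_path, name="protein",
                                    orientation=config.orientation)
        clinical = (
            read_clinical_table(config.clinical_path)
            if config.clinical_path
            else None
        )
        stage = "align"
        dataset, clinical = align_dataset(views, protein, clinical)
        stage = "pipeline"
        result = run_from_dataset(
            dataset,
            n_clusters=config.n_clusters,
            clinical=clinical if config.evaluate else None,
            translation_config=config.translation,
            clustering_config=config.clustering,
            seed=config.seed,
        )
        stage = "write"
        write_labels(dataset.sample_ids, result.cluster_result.labels, out / "labels.tsv")
        write_omics_matrix(result.predicted_protein, out / "predicted_protein.tsv")
        write_training_log(
            result.translation_model.training_log, out / "translation_loss.tsv"
        )
        _write_dscc_log(result.dscc_model.training_log, out / "clustering_loss.tsv")
        if result.report is not None:
            write_report(result.report, out / "report.tsv", out / "parameters.tsv")
        manifest = _config_manifest(config)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _write_dscc_log(log: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("phase\tepoch\ttotal\trec\tcnorm\tcontrastive\n")
        for row in log:
            fh.write(
                f"{row['phase']}\t{row['epoch']}\t{row['total']:.10g}\t"
                f"{row['rec']:.10g}\t{row['cnorm']:.10g}\t{row['contrastive']:.10g}\n"
            )
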