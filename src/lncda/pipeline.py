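"""End-to-end orchestration: complement -> similarities -> features ->
autoencoder -> balanced sampling -> cross-validated forest -> ranking.

All stage seeds are derived deterministically from a single pipeline
seed, so two runs with the same configuration and inputs produce
identical reports and rankings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .complement import ComplementedAssociation, complement_pipeline
from .features import FeatureTable, build_raw_features, compress_features
from .network import BipartiteAdjacency, align_layers, read_adjacency
from .predictor import (
    EvaluationReport,
    ForestParams,
    RankedPredictions,
    SampleSet,
    _fold_metrics,
    _pair_features,
    build_samples,
    cross_validate,
    rank_candidates,
    score_pairs,
    train_forest,
)
from .similarity import SimilarityMatrix, fused_similarity, gip_profiles, jaccard_profiles

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Fully serialisable configuration of one pipeline run."""

    ld_path: str | None = None
    md_path: str | None = None
    lm_path: str | None = None
    # similarity options
    lambda_tilde: float = 1.0
    jaccard_denominator: Literal["union", "sum"] = "union"
    similarity_source: Literal["ld", "ld_new"] = "ld"
    # autoencoder options (shared by both entity kinds)
    lnc_latent_dim: int = 256
    dis_latent_dim: int = 256
    ae_epochs: int = 200
    ae_batch_size: int = 32
    ae_learning_rate: float = 1e-3
    # forest / CV options
    ntree: int = 500
    mtry: int | None = None
    cv_folds: int = 5
    per_fold_negatives: bool = False
    strict_features: bool = False
    # ranking
    rank_diseases: list[str] = field(default_factory=list)
    top_n: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: EvaluationReport
    rankings: list[RankedPredictions]
    comp: ComplementedAssociation
    lnc_similarity: SimilarityMatrix
    dis_similarity: SimilarityMatrix
    lnc_encoded: FeatureTable
    dis_encoded: FeatureTable
    samples: SampleSet
    config: PipelineConfig


def _similarities(
    cfg: PipelineConfig, comp: ComplementedAssociation
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    if cfg.similarity_source == "ld":
        lfj = fused_similarity(
            comp.ld, "lncRNA-rows", cfg.lambda_tilde, cfg.jaccard_denominator
        )
        dsj = fused_similarity(
            comp.ld, "disease-columns", cfg.lambda_tilde, cfg.jaccard_denominator
        )
        return lfj, dsj
    # ld_new mode: GIP on the real-valued profiles, Jaccard on their support
    lnc_p, dis_p = comp.ld_new, comp.ld_new.T
    lfj = SimilarityMatrix(
        comp.ld.row_registry,
        np.maximum(
            jaccard_profiles(lnc_p, cfg.jaccard_denominator),
            gip_profiles(lnc_p, cfg.lambda_tilde),
        ),
        "fused",
    )
    dsj = SimilarityMatrix(
        comp.ld.col_registry,
        np.maximum(
            jaccard_profiles(dis_p, cfg.jaccard_denominator),
            gip_profiles(dis_p, cfg.lambda_tilde),
        ),
        "fused",
    )
    return lfj, dsj


def _encode_tables(
    cfg: PipelineConfig,
    comp: ComplementedAssociation,
    lfj: SimilarityMatrix,
    dsj: SimilarityMatrix,
) -> tuple[FeatureTable, FeatureTable]:
    lnc_raw, dis_raw = build_raw_features(comp, lfj, dsj)
    lnc_enc, _ = compress_features(
        lnc_raw,
        latent_dim=cfg.lnc_latent_dim,
        seed=cfg.seed + 11,
        epochs=cfg.ae_epochs,
        batch_size=cfg.ae_batch_size,
        learning_rate=cfg.ae_learning_rate,
    )
    dis_enc, _ = compress_features(
        dis_raw,
        latent_dim=cfg.dis_latent_dim,
        seed=cfg.seed + 12,
        epochs=cfg.ae_epochs,
        batch_size=cfg.ae_batch_size,
        learning_rate=cfg.ae_learning_rate,
    )
    return lnc_enc, dis_enc


def _strict_cross_validate(
    cfg: PipelineConfig,
    ld: BipartiteAdjacency,
    lm: BipartiteAdjacency,
    md: BipartiteAdjacency,
    samples: SampleSet,
    params: ForestParams,
) -> EvaluationReport:
    """Leakage-free CV: features are rebuilt per fold from a copy of LD
    with the held-out fold's positive pairs removed."""
    from sklearn.metrics import precision_recall_curve, roc_curve
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed + 31)
    assignments = np.full(len(samples), -1, dtype=int)
    pooled = np.zeros(len(samples))
    fold_metrics = []
    for fold, (train_idx, test_idx) in enumerate(
        skf.split(samples.features, samples.labels)
    ):
        masked = ld.values.copy()
        for q in test_idx:
            if samples.labels[q] == 1:
                i, j = samples.pairs[q]
                masked[i, j] = 0
        ld_fold = BipartiteAdjacency(ld.row_registry, ld.col_registry, masked)
        comp = complement_pipeline(ld_fold, lm, md)
        lfj, dsj = _similarities(cfg, comp)
        lnc_enc, dis_enc = _encode_tables(cfg, comp, lfj, dsj)
        train_feats = _pair_features(
            [samples.pairs[q] for q in train_idx], lnc_enc, dis_enc
        )
        test_feats = _pair_features(
            [samples.pairs[q] for q in test_idx], lnc_enc, dis_enc
        )
        from .predictor import _make_forest

        clf = _make_forest(
            ForestParams(params.ntree, params.mtry, params.seed + fold),
            train_feats.shape[1],
        )
        clf.fit(train_feats, samples.labels[train_idx])
        scores = score_pairs(clf, test_feats)
        pooled[test_idx] = scores
        assignments[test_idx] = fold
        fold_metrics.append(_fold_metrics(samples.labels[test_idx], scores))
    fpr, tpr, _ = roc_curve(samples.labels, pooled)
    prec, rec, _ = precision_recall_curve(samples.labels, pooled)
    return EvaluationReport(
        fold_metrics=fold_metrics,
        fold_assignments=assignments,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec, prec]),
        pooled_scores=pooled,
        params={"strict_features": True, "ntree": params.ntree, "k": cfg.cv_folds},
        notes=["features rebuilt per fold from training-fold positives only"],
    )


def run_pipeline(
    cfg: PipelineConfig,
    ld: BipartiteAdjacency | None = None,
    md: BipartiteAdjacency | None = None,
    lm: BipartiteAdjacency | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full pipeline and optionally write all artifacts.

    Inputs come either from the config's file paths or as in-memory
    adjacency objects.  When ``strict_features`` is off, similarities
    and autoencoders are computed once from the full LD matrix; the
    report then carries a note that held-out positive pairs contribute
    to the features (the leakage-free alternative is ``strict_features``).
    """
    t0 = time.time()
    stage = "load"
    try:
        if ld is None:
            if not (cfg.ld_path and cfg.md_path and cfg.lm_path):
                raise PipelineError("no adjacency inputs: set paths or pass matrices")
            ld = read_adjacency(cfg.ld_path, row_kind="lncRNA", col_kind="disease")
            md = read_adjacency(cfg.md_path, row_kind="miRNA", col_kind="disease")
            lm = read_adjacency(cfg.lm_path, row_kind="lncRNA", col_kind="miRNA")
        ld, md, lm = align_layers(ld, md, lm)

        stage = "complement"
        comp = complement_pipeline(ld, lm, md)
        logger.info("complement done (%.1fs)", time.time() - t0)

        stage = "similarity"
        lfj, dsj = _similarities(cfg, comp)

        stage = "autoencoder"
        lnc_enc, dis_enc = _encode_tables(cfg, comp, lfj, dsj)
        logger.info("features encoded (%.1fs)", time.time() - t0)

        stage = "sampling"
        samples = build_samples(ld, lnc_enc, dis_enc, seed=cfg.seed + 21)

        stage = "cross-validation"
        params = ForestParams(ntree=cfg.ntree, mtry=cfg.mtry, seed=cfg.seed + 41)
        if cfg.strict_features:
            report = _strict_cross_validate(cfg, ld, lm, md, samples, params)
        else:
            report = cross_validate(samples, params, k=cfg.cv_folds, seed=cfg.seed + 31)
            report.notes.append(
                "similarities and autoencoders were computed from the full LD "
                "matrix, so held-out positive pairs contribute to the features; "
                "use strict_features for a leakage-free estimate"
            )
        report.params["config_hash"] = cfg.config_hash()
        logger.info("cross-validation done (%.1fs)", time.time() - t0)

        stage = "ranking"
        rankings: list[RankedPredictions] = []
        if cfg.rank_diseases:
            clf = train_forest(samples, params)
            rankings = [
                rank_candidates(clf, ld, lnc_enc, dis_enc, name, cfg.top_n)
                for name in cfg.rank_diseases
            ]
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        report=report,
        rankings=rankings,
        comp=comp,
        lnc_similarity=lfj,
        dis_similarity=dsj,
        lnc_encoded=lnc_enc,
        dis_encoded=dis_enc,
        samples=samples,
        config=cfg,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ld = res.comp.ld
    rows, cols = list(ld.row_registry.names), list(ld.col_registry.names)
    meta = {"config": res.config.to_dict(), "config_hash": res.config.config_hash()}
    (outdir / "config.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    pd.DataFrame(res.comp.lmd, index=rows, columns=cols).to_csv(outdir / "lmd.csv")
    pd.DataFrame(res.comp.ld_new, index=rows, columns=cols).to_csv(outdir / "ld_new.csv")
    pd.DataFrame(res.lnc_similarity.values, index=rows, columns=rows).to_csv(
        outdir / "lnc_similarity.csv"
    )
    pd.DataFrame(res.dis_similarity.values, index=cols, columns=cols).to_csv(
        outdir / "dis_similarity.csv"
    )
    res.lnc_encoded.to_frame().to_csv(outdir / "lnc_encoded.csv")
    res.dis_encoded.to_frame().to_csv(outdir / "dis_encoded.csv")
    res.report.save(outdir / "report.json")
    pd.DataFrame(res.report.roc_points, columns=["fpr", "tpr"]).to_csv(
        outdir / "roc_points.csv", index=False
    )
    pd.DataFrame(res.report.pr_points, columns=["recall", "precision"]).to_csv(
        outdir / "pr_points.csv", index=False
    )
    for ranking in res.rankings:
        safe = ranking.disease.replace("/", "_").replace(" ", "_")
        ranking.to_tsv(outdir / f"ranking_{safe}.tsv")


def run_dimension_sweep(
    cfg: PipelineConfig,
    lnc_dims: Sequence[int],
    dis_dims: Sequence[int],
    ld: BipartiteAdjacency | None = None,
    md: BipartiteAdjacency | None = None,
    lm: BipartiteAdjacency | None = None,
) -> pd.DataFrame:
    """Grid of mean CV AUC over latent-dimension pairs.

    Cells whose dimension reaches or exceeds the raw feature width are
    recorded as NaN and the sweep continues.  Heavy intermediate stages
    (complement, similarities, per-dimension encoders) are computed once
    and shared across the grid.
    """
    if ld is None:
        ld = read_adjacency(cfg.ld_path, row_kind="lncRNA", col_kind="disease")
        md = read_adjacency(cfg.md_path, row_kind="miRNA", col_kind="disease")
        lm = read_adjacency(cfg.lm_path, row_kind="lncRNA", col_kind="miRNA")
    ld, md, lm = align_layers(ld, md, lm)
    comp = complement_pipeline(ld, lm, md)
    lfj, dsj = _similarities(cfg, comp)
    lnc_raw, dis_raw = build_raw_features(comp, lfj, dsj)

    def _encodings(raw: FeatureTable, dims: Sequence[int], seed: int):
        out: dict[int, FeatureTable | None] = {}
        for dim in dims:
            if dim >= raw.width:
                logger.warning(
                    "latent dim %d >= raw width %d: cell skipped", dim, raw.width
                )
                out[dim] = None
                continue
            enc, _ = compress_features(
                raw,
                latent_dim=dim,
                seed=seed,
                epochs=cfg.ae_epochs,
                batch_size=cfg.ae_batch_size,
                learning_rate=cfg.ae_learning_rate,
            )
            out[dim] = enc
        return out

    lnc_encs = _encodings(lnc_raw, lnc_dims, cfg.seed + 11)
    dis_encs = _encodings(dis_raw, dis_dims, cfg.seed + 12)
    grid = pd.DataFrame(index=list(lnc_dims), columns=list(dis_dims), dtype=float)
    params = ForestParams(ntree=cfg.ntree, mtry=cfg.mtry, seed=cfg.seed + 41)
    for li in lnc_dims:
        for dj in dis_dims:
            if lnc_encs[li] is None or dis_encs[dj] is None:
                grid.loc[li, dj] = np.nan
                continue
            samples = build_samples(ld, lnc_encs[li], dis_encs[dj], seed=cfg.seed + 21)
            report = cross_validate(samples, params, k=cfg.cv_folds, seed=cfg.seed + 31)
            grid.loc[li, dj] = report.mean_metrics["auc"]
    grid.index.name = "lnc_dim"
    grid.columns.name = "dis_dim"
    return grid
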