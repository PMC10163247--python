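"""End-to-end recognition pipeline.

Orchestrates: equidistant modelling/validation split -> spectral-index
construction -> association screening (top-10 sensitive indices) -> one
1-D cloud model per sensitive index -> 3-D cloud model on the three indices
with the best 1-D validation accuracy -> GLCM texture branch (windows 3/5/7,
per-species best window) with its own 1-D/3-D cloud models -> RBF-SVM
baselines (1-D per sensitive index and 3-D on the optimal triple) -> a
consolidated accuracy comparison table.

Everything is seeded end-to-end; in deterministic membership mode a rerun
with the same config reproduces every number bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cloud, indices, screen, svm, texture
from .synthetic import (
    BAND_COLUMNS,
    ConfigurationError,
    LabeledRaster,
    gen_labeled_raster,
    gen_pixel_samples,
    get_preset,
    raster_to_samples,
    read_raster_tiff,
    read_samples_csv,
)

logger = logging.getLogger("treecloud")


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Equidistant 2/3 modelling / 1/3 validation split."""

    modelling_fraction: float = 2.0 / 3.0
    rule: str = "equidistant"


def equidistant_split(
    n: int, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Every third sample (0-based positions 2, 5, 8, ...) to validation.

    Deterministic; the two partitions cover 0..n-1 exactly once.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if spec.rule != "equidistant":
        raise ConfigurationError(f"unknown split rule {spec.rule!r}")
    idx = np.arange(n)
    validation = idx[2::3]
    modelling = np.setdiff1d(idx, validation)
    return modelling, validation


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Recognition accuracies of one fitted model on validation samples."""

    per_species: dict[str, float]  # fractions in [0, 1]
    overall: float  # micro average: correct / total
    macro: float  # unweighted mean of per-species accuracies
    confusion: pd.DataFrame  # rows true, columns predicted
    descriptor: dict = field(default_factory=dict)

    @property
    def overall_pct(self) -> float:
        return round(100.0 * self.overall, 2)

    def species_pct(self, sp: str) -> float:
        return round(100.0 * self.per_species[sp], 2)

    def __str__(self) -> str:
        per = ", ".join(
            f"{sp}={self.species_pct(sp):.2f}%" for sp in sorted(self.per_species)
        )
        return f"overall={self.overall_pct:.2f}% ({per})"


def evaluate(predicted, true, descriptor: Optional[dict] = None) -> EvalReport:
    """Exact confusion matrix and accuracies for one prediction vector."""
    predicted = np.asarray(predicted).astype(str)
    true = np.asarray(true).astype(str)
    if predicted.shape != true.shape or true.size == 0:
        raise ValueError("predicted and true labels must match and be nonempty")
    confusion = pd.crosstab(
        pd.Series(true, name="true"), pd.Series(predicted, name="predicted")
    )
    per = {
        sp: float(np.mean(predicted[true == sp] == sp)) for sp in np.unique(true)
    }
    overall = float(np.mean(predicted == true))
    macro = float(np.mean(list(per.values())))
    return EvalReport(per, overall, macro, confusion, descriptor or {})


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def select_best_features_by_1d(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    candidates: Sequence[str],
    model_family: str = "cloud",
    mode: str = "deterministic",
    seed: int = 0,
) -> tuple[list[str], dict[str, EvalReport]]:
    """Rank candidate features by 1-D validation accuracy; return the top 3.

    Fits one single-feature model per candidate on the modelling partition
    and evaluates on the validation partition.  Ties break lexicographically
    on the feature id.
    """
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate features")
    reports: dict[str, EvalReport] = {}
    for fid in candidates:
        if model_family == "cloud":
            clf = cloud.fit_classifier(train, (fid,), mode=mode, seed=seed)
            pred = cloud.predict_cloud(clf, validation)
        elif model_family == "svm":
            model = svm.fit_svm(train, (fid,))
            pred = svm.predict_svm(model, validation)
        else:
            raise ConfigurationError(f"unknown model family {model_family!r}")
        reports[fid] = evaluate(
            pred,
            validation["label"],
            {"model": model_family, "dimension": 1, "features": (fid,)},
        )
    ranked = sorted(candidates, key=lambda f: (-reports[f].overall, f))
    return ranked[:3], reports


# ---------------------------------------------------------------------------
# Run configuration and result container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    preset: Optional[str] = "winter"  # or None with explicit file inputs
    samples_csv: Optional[str] = None
    raster_tiff: Optional[str] = None
    labels_tiff: Optional[str] = None
    n_per_class: int = 1000
    raster_shape: tuple[int, int] = (96, 96)
    seed: int = 0
    k_sensitive: int = 10
    screen_method: str = "pointbiserial"
    windows: tuple[int, ...] = (3, 5, 7)
    glcm_levels: int = 32
    texture_band: int = 4
    membership_mode: str = "deterministic"
    m_draws: int = 1000
    run_texture: bool = True
    run_svm: bool = True


@dataclass
class PipelineResult:
    config: PipelineConfig
    sensitive: pd.DataFrame  # screening report of the selected indices
    reports: list[EvalReport]
    comparison: pd.DataFrame  # one row per fitted model
    cloud_classifier_3d: Optional[cloud.CloudClassifier] = None

    def best_overall(self, block: str, model: str) -> float:
        """Best overall validation accuracy (%) of a feature block/model."""
        sub = self.comparison.query("block == @block and model == @model")
        if sub.empty:
            raise KeyError(f"no models for block={block!r} model={model!r}")
        return float(sub["overall_pct"].max())

    def accuracy(self, block: str, model: str, dimension: int) -> float:
        sub = self.comparison.query(
            "block == @block and model == @model and dimension == @dimension"
        )
        if sub.empty:
            raise KeyError((block, model, dimension))
        return float(sub["overall_pct"].max())


def _comparison_row(report: EvalReport) -> dict:
    d = report.descriptor
    row = {
        "block": d.get("block", ""),
        "model": d.get("model", ""),
        "dimension": d.get("dimension", 0),
        "features": "+".join(d.get("features", ())),
        "window": d.get("window", ""),
        "overall_pct": report.overall_pct,
        "macro_pct": round(100 * report.macro, 2),
    }
    for sp, acc in report.per_species.items():
        row[f"acc_{sp}_pct"] = round(100 * acc, 2)
    return row


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def _load_samples(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.samples_csv:
        return read_samples_csv(cfg.samples_csv)
    if cfg.preset is None:
        raise ConfigurationError("either a preset or a samples CSV is required")
    return gen_pixel_samples(get_preset(cfg.preset), cfg.n_per_class, cfg.seed)


def _load_raster(cfg: PipelineConfig) -> LabeledRaster:
    if cfg.raster_tiff:
        if not cfg.labels_tiff:
            raise ConfigurationError("a label TIFF must accompany the raster")
        return read_raster_tiff(cfg.raster_tiff, cfg.labels_tiff)
    if cfg.preset is None:
        raise ConfigurationError("either a preset or raster paths are required")
    h, w = cfg.raster_shape
    return gen_labeled_raster(get_preset(cfg.preset), h, w, cfg.seed + 1)


def _split_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mod_idx, val_idx = equidistant_split(len(df))
    return df.iloc[mod_idx].reset_index(drop=True), df.iloc[val_idx].reset_index(
        drop=True
    )


def _spectral_stage(
    cfg: PipelineConfig, reports: list[EvalReport]
) -> tuple[pd.DataFrame, list[str], Optional[cloud.CloudClassifier]]:
    samples = _load_samples(cfg)
    features = indices.build_feature_matrix(samples)
    n_missing = int(features.isna().sum().sum())
    logger.info(
        "spectral features: %d samples x %d indices (%d missing values)",
        *features.shape,
        n_missing,
    )
    table = pd.concat([samples[["label"]], features], axis=1)
    train, validation = _split_frame(table)

    corr = screen.screen_features(
        train[features.columns], train["label"], method=cfg.screen_method
    )
    sensitive = screen.rank_select(corr, cfg.k_sensitive)
    sens_ids = [r.feature_id for r in sensitive]
    logger.info("sensitive indices: %s", sens_ids)

    top3, one_d = select_best_features_by_1d(
        train, validation, sens_ids, "cloud", cfg.membership_mode, cfg.seed
    )
    for fid in sens_ids:
        rep = one_d[fid]
        rep.descriptor["block"] = "spectral"
        reports.append(rep)

    clf3 = cloud.fit_classifier(
        train, tuple(top3), mode=cfg.membership_mode, seed=cfg.seed
    )
    rep3 = evaluate(
        cloud.predict_cloud(clf3, validation),
        validation["label"],
        {"block": "spectral", "model": "cloud", "dimension": 3, "features": tuple(top3)},
    )
    reports.append(rep3)

    if cfg.run_svm:
        for fid in sens_ids:
            m = svm.fit_svm(train, (fid,))
            reports.append(
                evaluate(
                    svm.predict_svm(m, validation),
                    validation["label"],
                    {
                        "block": "spectral",
                        "model": "svm",
                        "dimension": 1,
                        "features": (fid,),
                    },
                )
            )
        m3 = svm.fit_svm(train, tuple(top3))
        reports.append(
            evaluate(
                svm.predict_svm(m3, validation),
                validation["label"],
                {
                    "block": "spectral",
                    "model": "svm",
                    "dimension": 3,
                    "features": tuple(top3),
                },
            )
        )
    return screen.reports_to_frame(sensitive), top3, clf3


def _texture_stage(cfg: PipelineConfig, reports: list[EvalReport]) -> None:
    raster = _load_raster(cfg)
    for window in cfg.windows:
        gcfg = texture.GLCMConfig(
            window=window, levels=cfg.glcm_levels, band=cfg.texture_band
        )
        tmap = texture.texture_map(raster, gcfg)
        h, w, _ = tmap.planes.shape
        table = pd.DataFrame(
            tmap.planes.reshape(h * w, 8), columns=texture.PARAM_IDS
        )
        table.insert(0, "label", raster.labels.ravel())
        train, validation = _split_frame(table)
        top3, one_d = select_best_features_by_1d(
            train,
            validation,
            list(texture.PARAM_IDS),
            "cloud",
            cfg.membership_mode,
            cfg.seed,
        )
        for fid in texture.PARAM_IDS:
            rep = one_d[fid]
            rep.descriptor.update({"block": "texture", "window": window})
            reports.append(rep)
        clf3 = cloud.fit_classifier(
            train, tuple(top3), mode=cfg.membership_mode, seed=cfg.seed
        )
        reports.append(
            evaluate(
                cloud.predict_cloud(clf3, validation),
                validation["label"],
                {
                    "block": "texture",
                    "model": "cloud",
                    "dimension": 3,
                    "features": tuple(top3),
                    "window": window,
                },
            )
        )


def best_window_per_species(comparison: pd.DataFrame) -> dict[str, int]:
    """For each species, the window whose best texture model recognizes it
    most accurately (per-species validation accuracy)."""
    tex = comparison[comparison.block == "texture"]
    out: dict[str, int] = {}
    for col in [c for c in tex.columns if c.startswith("acc_")]:
        sp = col[len("acc_") : -len("_pct")]
        by_window = tex.groupby("window")[col].max()
        out[sp] = int(by_window.idxmax())
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full recognition study for one phase configuration."""
    reports: list[EvalReport] = []
    sensitive, top3, clf3 = _spectral_stage(cfg, reports)
    if cfg.run_texture:
        _texture_stage(cfg, reports)
    comparison = pd.DataFrame([_comparison_row(r) for r in reports])
    logger.info("fitted %d models", len(reports))
    return PipelineResult(cfg, sensitive, reports, comparison, clf3)


def compare_presets(
    seed: int = 0, n_per_class: int = 1000, **kwargs
) -> dict[str, PipelineResult]:
    """Run both phenological presets under one seed."""
    return {
        name: run_pipeline(
            PipelineConfig(preset=name, seed=seed, n_per_class=n_per_class, **kwargs)
        )
        for name in ("autumn", "winter")
    }
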