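"""End-to-end flow: preprocess images, extract texture features, cluster with
the UDLM, align clusters to classes, and score — plus supervised RF/SVM
baselines and the resolution sweep.

The unsupervised path never reads class labels before the alignment/metrics
stage: clustering consumes the feature matrix only.  The 80/20 train/test
split applies only to the supervised baselines; the UDLM clusters every
sample it is given.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import metrics as M
from .errors import EmptyDatasetError, InvalidInputError
from .texture import GLCMParams, GrayImage, extract_feature_vector, quantize_image
from .udlm import UDLMConfig, SwarmState, assign_labels, run_udlm

FEATURE_COLUMNS = ("asm", "con", "idm", "cor")
OPTIONAL_COLUMNS = ("ent", "coarseness")
CLASS_DIRS = (M.BENIGN, M.MALIGNANT)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one run needs: resolution, GLCM conventions, swarm
    hyperparameters, baseline split, and feature scaling."""

    resolution: int = 40
    glcm: GLCMParams = field(default_factory=GLCMParams)
    udlm: UDLMConfig = field(default_factory=lambda: UDLMConfig(seed=0))
    include_optional: bool = False
    split_fraction: float = 0.8
    split_seed: int = 0
    feature_scaling: str = "minmax"

    def __post_init__(self):
        if self.resolution < 8:
            raise InvalidInputError("resolution must be >= 8")
        if not (0.0 < self.split_fraction < 1.0):
            raise InvalidInputError("split_fraction must lie in (0, 1)")
        if self.feature_scaling not in ("none", "minmax", "zscore"):
            raise InvalidInputError("feature_scaling must be none, minmax or zscore")


@dataclass(frozen=True)
class ImageRecord:
    path: Path
    label: str
    subtype: str | None = None

    @property
    def image_id(self) -> str:
        return self.path.stem


@dataclass
class LabeledImageSet:
    records: list[ImageRecord]
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]


@dataclass
class BcicmResult:
    """Artifacts of one unsupervised run."""

    features: pd.DataFrame
    assignments: pd.DataFrame
    centers: tuple[np.ndarray, np.ndarray]
    state: SwarmState
    mapping: dict[int, str] | None
    report: M.MetricsReport | None
    roc: M.RocCurve | None
    warnings: list[str] = field(default_factory=list)


def load_image_folder(root: str | Path) -> LabeledImageSet:
    """Walk a benign/ malignant/ class-per-directory tree (BreakHis layout).

    Labels come from the top-level directory name; the next directory level,
    when present, is recorded as the subtype.  Files under unrecognized
    top-level directories go to a skip report rather than aborting.  The
    record order is deterministic (lexicographic by path).
    """
    root = Path(root)
    if not root.is_dir():
        raise EmptyDatasetError(f"{root} is not a directory")
    records, skipped = [], []
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    for path in sorted(root.rglob("*")):
        if not (path.is_file() and path.suffix.lower() in exts):
            continue
        rel = path.relative_to(root).parts
        label = rel[0].lower()
        if label not in CLASS_DIRS:
            skipped.append(str(path))
            continue
        subtype = rel[1] if len(rel) > 2 else None
        records.append(ImageRecord(path=path, label=label, subtype=subtype))
    if not records:
        raise EmptyDatasetError(f"no class-labeled images found under {root}")
    return LabeledImageSet(records=records, skipped=skipped)


def preprocess_image(source: str | Path | Image.Image, resolution: int, n_levels: int = 8) -> GrayImage:
    """Grayscale (ITU-R 601 luma), bilinear resize to a square, quantize."""
    if resolution < 8:
        raise InvalidInputError("resolution must be >= 8")
    img = source if isinstance(source, Image.Image) else Image.open(source)
    gray = img.convert("L").resize((resolution, resolution), Image.Resampling.BILINEAR)
    return quantize_image(np.asarray(gray), n_levels)


def extract_features(images: LabeledImageSet, config: ExperimentConfig) -> pd.DataFrame:
    """Per-image texture feature table.

    Columns: ``image_id, resolution, asm, con, idm, cor[, ent, coarseness],
    label`` — label is the empty string when unknown.
    """
    rows = []
    for rec in images.records:
        gray = preprocess_image(rec.path, config.resolution, config.glcm.n_levels)
        vec = extract_feature_vector(gray, config.glcm, include_optional=config.include_optional)
        row = {"image_id": rec.image_id, "resolution": config.resolution,
               "asm": vec.asm, "con": vec.con, "idm": vec.idm, "cor": vec.cor}
        if config.include_optional:
            row["ent"] = vec.ent
            row["coarseness"] = vec.coarseness
        row["label"] = rec.label or ""
        rows.append(row)
    return pd.DataFrame(rows)


def scale_features(X: np.ndarray, method: str) -> np.ndarray:
    """Column-wise feature scaling; zero-spread columns map to 0."""
    X = np.asarray(X, dtype=float)
    if method == "none":
        return X
    if method == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        return (X - lo) / span
    if method == "zscore":
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (X - mu) / sd
    raise InvalidInputError(f"unknown scaling method {method!r}")


def feature_matrix(features: pd.DataFrame, config: ExperimentConfig) -> np.ndarray:
    cols = [c for c in FEATURE_COLUMNS + OPTIONAL_COLUMNS if c in features.columns]
    return scale_features(features[cols].to_numpy(dtype=float), config.feature_scaling)


def cluster_features(features: pd.DataFrame, config: ExperimentConfig):
    """Run the UDLM on a (scaled) feature table. Label-blind by construction."""
    X = feature_matrix(features, config)
    centers, state = run_udlm(X, config.udlm)
    clusters = assign_labels(X, centers)
    return X, centers, state, clusters


def run_bcicm(images_or_features, config: ExperimentConfig) -> BcicmResult:
    """The full unsupervised flow on an image folder set or a feature table.

    Features are extracted (or taken as given), scaled, clustered by the
    UDLM; when ground-truth labels are present the clusters are aligned to
    classes and the six headline metrics plus the margin-score ROC are
    computed.  Fully reproducible from the seeds in ``config``.
    """
    if isinstance(images_or_features, pd.DataFrame):
        features = images_or_features.copy()
    else:
        features = extract_features(images_or_features, config)
    if len(features) < 2:
        raise EmptyDatasetError("need at least 2 samples to cluster")
    warns: list[str] = []
    X, centers, state, clusters = cluster_features(features, config)

    labels = features["label"].astype(str).tolist() if "label" in features.columns else []
    have_labels = bool(labels) and all(l in (M.BENIGN, M.MALIGNANT) for l in labels)
    mapping = report = roc = None
    margins = np.full(len(features), np.nan)
    mapped = [""] * len(features)
    if have_labels:
        mapping = M.align_clusters(clusters, labels)
        mapped = [mapping[c] for c in clusters]
        benign_center = centers[0] if mapping[0] == M.BENIGN else centers[1]
        malignant_center = centers[1] if mapping[1] == M.MALIGNANT else centers[0]
        margins = M.margin_score(X, benign_center, malignant_center)
        if len(set(labels)) < 2:
            warns.append("single-class input: ROC/AUC and class-conditional metrics unavailable")
            cm = M.confusion(labels, mapped)
            report = None
        else:
            cm = M.confusion(labels, mapped)
            roc, auc = M.roc_auc(margins, labels)
            report = M.report(cm, auc=auc)
    assignments = pd.DataFrame(
        {
            "image_id": features["image_id"] if "image_id" in features.columns else np.arange(len(features)),
            "cluster": clusters,
            "mapped_label": mapped,
            "margin_score": margins,
        }
    )
    return BcicmResult(
        features=features,
        assignments=assignments,
        centers=centers,
        state=state,
        mapping=mapping,
        report=report,
        roc=roc,
        warnings=warns,
    )


def run_baselines(images_or_features, config: ExperimentConfig) -> dict[str, dict]:
    """Supervised RF and SVM controls on the same texture features.

    Stratified 80/20 split by ``split_seed``; both models use library-default
    hyperparameters (recorded verbatim in the returned report).  AUC follows
    the hard-classifier trapezoid identity, as for the unsupervised model.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split
    from sklearn.svm import SVC

    if isinstance(images_or_features, pd.DataFrame):
        features = images_or_features
    else:
        features = extract_features(images_or_features, config)
    labels = features["label"].astype(str).to_numpy()
    if len(set(labels)) < 2:
        raise InvalidInputError("baselines require both classes present")
    X = feature_matrix(features, config)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        labels,
        test_size=1.0 - config.split_fraction,
        random_state=config.split_seed,
        stratify=labels,
    )
    out: dict[str, dict] = {}
    for name, model in (
        ("rf", RandomForestClassifier(random_state=config.split_seed)),
        ("svm", SVC(random_state=config.split_seed)),
    ):
        model.fit(X_tr, y_tr)
        y_hat = model.predict(X_te)
        cm = M.confusion(y_te.tolist(), y_hat.tolist())
        out[name] = {
            "metrics": M.report(cm),
            "confusion": cm,
            "hyperparameters": model.get_params(),
            "n_train": len(y_tr),
            "n_test": len(y_te),
        }
    return out


def resolution_sweep(
    images: LabeledImageSet,
    resolutions: list[int],
    config: ExperimentConfig,
) -> pd.DataFrame:
    """Mean feature values, wall time, and (when labeled) accuracy per resolution.

    One row per resolution with columns resolution, asm, con, idm, ent,
    runtime_ms (feature extraction wall time per image), and acc.
    """
    if not resolutions:
        raise InvalidInputError("at least one resolution is required")
    rows = []
    for res in resolutions:
        cfg = replace(config, resolution=res, include_optional=True)
        t0 = time.perf_counter()
        features = extract_features(images, cfg)
        elapsed_ms = (time.perf_counter() - t0) * 1000.0 / max(len(features), 1)
        row = {
            "resolution": res,
            "asm": features["asm"].mean(),
            "con": features["con"].mean(),
            "idm": features["idm"].mean(),
            "ent": features["ent"].mean(),
            "runtime_ms": elapsed_ms,
        }
        labels = set(features["label"])
        if labels >= {M.BENIGN, M.MALIGNANT}:
            result = run_bcicm(features, cfg)
            row["acc"] = result.report.acc if result.report else np.nan
        else:
            row["acc"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
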