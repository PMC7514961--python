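"""End-to-end orchestration: feature assembly, train/test protocol, artifacts.

Each record is windowed to a fixed length (10,000 samples at 2 kHz) and
summarized by one of three nested descriptors:

* ``wavelet`` (16): two-norms of the 16 level-4 db6 wavelet-packet nodes;
* ``wavelet+entropy`` (17): the 16 norms plus the subband energy entropy;
* ``wavelet+entropy+fractal`` (18): the above plus the box-counting
  fractal dimension.

The feature order is fixed (norms in node order, then entropy, then
dimension), so the shorter sets are literal prefixes of the longer ones.
``run_experiment`` performs the full protocol: a seeded stratified
train/test split, optional cross-validated hyperparameter selection on the
training rows only, a final fit, and a test-set metric report, writing all
artifacts (features, model, predictions, report, config echo) to disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .signal_io import HeartSoundRecord, window_record, DEFAULT_WINDOW, NORMAL, ABNORMAL
from .wavelet_features import (
    wpt_decompose, node_norms, energy_spectrum, energy_entropy,
    DEFAULT_WAVELET, DEFAULT_LEVEL,
)
from .fractal import box_dimension
from .twsvm import TrainingSet, TwinSVM
from .metrics import confusion, report, cross_validate, MetricReport, ConfusionCounts

FEATURE_SETS = {
    "wavelet": 16,
    "wavelet+entropy": 17,
    "wavelet+entropy+fractal": 18,
}
_ALIASES = {"16": "wavelet", "17": "wavelet+entropy", "18": "wavelet+entropy+fractal"}

LABEL_TO_INT = {ABNORMAL: 1, NORMAL: -1}
INT_TO_LABEL = {1: ABNORMAL, -1: NORMAL}


def canonical_feature_set(name: str) -> str:
    name = str(name)
    name = _ALIASES.get(name, name)
    if name not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {name!r}; "
                         f"choose from {sorted(FEATURE_SETS)} or 16/17/18")
    return name


@dataclass(frozen=True)
class FeatureVector:
    record_id: str
    values: np.ndarray
    feature_set: str
    label: str | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        expected = FEATURE_SETS[self.feature_set]
        if values.size != expected:
            raise ValueError(
                f"{self.feature_set} expects {expected} values, got {values.size}"
            )
        object.__setattr__(self, "values", values)


def extract_features(
    record: HeartSoundRecord,
    feature_set: str = "wavelet+entropy+fractal",
    window: int = DEFAULT_WINDOW,
    wavelet: str = DEFAULT_WAVELET,
    level: int = DEFAULT_LEVEL,
    i_max: int | None = None,
) -> FeatureVector:
    """Compute one record's feature vector (deterministic)."""
    feature_set = canonical_feature_set(feature_set)
    rec = window_record(record, window)
    if not np.any(rec.samples):
        raise ValueError(f"record {record.record_id!r}: zero-energy window")
    table = wpt_decompose(rec, wavelet=wavelet, level=level)
    values = list(node_norms(table))
    if feature_set != "wavelet":
        values.append(energy_entropy(energy_spectrum(table)))
    if feature_set == "wavelet+entropy+fractal":
        values.append(box_dimension(rec, i_max=i_max).slope)
    return FeatureVector(record_id=record.record_id, values=np.array(values),
                         feature_set=feature_set, label=record.label)


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame: record_id, f1..fk, label."""
    if not features:
        raise ValueError("no features given")
    k = features[0].values.size
    rows = []
    for fv in features:
        if fv.values.size != k:
            raise ValueError("mixed feature-set lengths")
        rows.append([fv.record_id, *fv.values, fv.label])
    cols = ["record_id"] + [f"f{i + 1}" for i in range(k)] + ["label"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_xy(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a features frame into (ids, X, y) with y in {+1, -1}."""
    ids = frame["record_id"].to_numpy()
    fcols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    X = frame[fcols].to_numpy(dtype=float)
    if frame["label"].isna().any():
        raise ValueError("missing labels in features frame")
    y = frame["label"].map(LABEL_TO_INT).to_numpy(dtype=int)
    return ids, X, y


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment, seeds included."""

    feature_set: str = "wavelet+entropy+fractal"
    classifier: str = "twsvm"            # or "reference-svm"
    c1: float = 3.5
    c2: float = 3.5
    sigma1: float = 3.5
    sigma2: float = 3.5
    window: int = DEFAULT_WINDOW
    wavelet: str = DEFAULT_WAVELET
    level: int = DEFAULT_LEVEL
    i_max: int | None = None
    folds: int = 10
    train_size: int = 200
    test_size: int = 150
    split_seed: int | None = None
    cv_seed: int = 0
    hyper_grid: tuple = ()               # () = no search, use c/sigma above

    def __post_init__(self):
        object.__setattr__(self, "feature_set",
                           canonical_feature_set(self.feature_set))
        if self.classifier not in ("twsvm", "reference-svm"):
            raise ValueError("classifier must be 'twsvm' or 'reference-svm'")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hyper_grid" in raw:
            raw["hyper_grid"] = tuple(dict(g) for g in raw["hyper_grid"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hyper_grid"] = [dict(g) for g in self.hyper_grid]
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class ExperimentResult:
    """Test-set evaluation of one experiment, with full provenance."""

    config: ExperimentConfig
    counts: ConfusionCounts
    report: MetricReport
    best_params: dict
    cv_mean_accuracy: float | None
    predictions: pd.DataFrame   # record_id, predicted_label, d1, d2
    n_train: int
    n_test: int

    def summary(self) -> str:
        """Aligned plain-text report table."""
        r = self.report
        lines = [
            f"classifier     : {self.config.classifier}",
            f"feature set    : {self.config.feature_set} "
            f"({FEATURE_SETS[self.config.feature_set]} features)",
            f"train / test   : {self.n_train} / {self.n_test}"
            f"  (split seed {self.config.split_seed})",
            f"hyperparams    : {self.best_params}",
            f"config hash    : {self.config.config_hash}",
            "",
            f"{'measure':<12}{'percent':>9}",
            f"{'accuracy':<12}{r.accuracy:>9.2f}",
            f"{'sensitivity':<12}{r.sensitivity:>9.2f}",
            f"{'specificity':<12}{r.specificity:>9.2f}",
            f"{'precision':<12}{r.precision:>9.2f}",
            f"{'F1':<12}{r.f1:>9.2f}",
            "",
            f"confusion      : TP={self.counts.TP} FN={self.counts.FN} "
            f"TN={self.counts.TN} FP={self.counts.FP}",
        ]
        return "\n".join(lines)


def _make_classifier(config: ExperimentConfig, params: dict):
    if config.classifier == "twsvm":
        return TwinSVM(**params)
    # reference soft-margin SVM baseline via scikit-learn; gamma matches
    # the same kernel convention exp(-||x-y||^2 / (2 sigma^2))
    c = params.get("c1", config.c1)
    sigma = params.get("sigma1", config.sigma1)
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    return make_pipeline(StandardScaler(),
                         SVC(C=c, gamma=1.0 / (2.0 * sigma**2)))


def run_experiment(
    features: pd.DataFrame,
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Split, select, fit and evaluate; optionally write all artifacts.

    ``features`` is a features frame (see :func:`features_to_frame`) whose
    width must match ``config.feature_set``. The split is stratified with
    ``config.split_seed`` (mandatory: the protocol is random and results are
    meaningless without a recorded seed). When the frame holds fewer records
    than ``train_size + test_size``, the same train:test proportion is kept.
    """
    if config.split_seed is None:
        raise ValueError("config.split_seed must be set: the train/test split "
                         "is random and must be reproducible")
    ids, X, y = frame_to_xy(features)
    k = FEATURE_SETS[config.feature_set]
    if X.shape[1] != k:
        raise ValueError(f"features frame has {X.shape[1]} columns but "
                         f"{config.feature_set} needs {k}")
    m = len(y)
    want = config.train_size + config.test_size
    if m >= want:
        n_train, n_test = config.train_size, config.test_size
    else:
        n_test = max(1, int(round(m * config.test_size / want)))
        n_train = m - n_test
    idx_train, idx_test = train_test_split(
        np.arange(m), train_size=n_train, test_size=n_test,
        stratify=y, random_state=config.split_seed,
    )

    base_params = dict(c1=config.c1, c2=config.c2,
                       sigma1=config.sigma1, sigma2=config.sigma2)
    if config.classifier != "twsvm":
        base_params = dict(c1=config.c1, sigma1=config.sigma1)

    cv_mean = None
    best_params = base_params
    if config.hyper_grid:
        cv = cross_validate(
            TrainingSet(X[idx_train], y[idx_train]),
            folds=config.folds,
            hyper_grid=[dict(base_params, **g) for g in config.hyper_grid],
            seed=config.cv_seed,
            model_factory=lambda **p: _make_classifier(config, p),
        )
        best_params, cv_mean = cv.best_params, cv.best_mean_accuracy

    model = _make_classifier(config, best_params)
    model.fit(X[idx_train], y[idx_train])
    pred = model.predict(X[idx_test])
    counts = confusion(pred, y[idx_test])
    rep = report(counts)

    if isinstance(model, TwinSVM):
        d = model.decision_distances(X[idx_test])
    else:
        d = np.full((len(idx_test), 2), np.nan)
    predictions = pd.DataFrame({
        "record_id": ids[idx_test],
        "predicted_label": [INT_TO_LABEL[p] for p in pred],
        "d1": d[:, 0],
        "d2": d[:, 1],
    })

    result = ExperimentResult(
        config=config, counts=counts, report=rep, best_params=best_params,
        cv_mean_accuracy=cv_mean, predictions=predictions,
        n_train=n_train, n_test=n_test,
    )
    if out_dir is not None:
        _write_artifacts(result, features, model, Path(out_dir))
    return result


def _write_artifacts(result: ExperimentResult, features: pd.DataFrame,
                     model, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    stamp = {"config": cfg.to_dict(), "config_hash": cfg.config_hash,
             "split_seed": cfg.split_seed, "cv_seed": cfg.cv_seed}
    features.to_csv(out_dir / "features.csv", index=False)
    result.predictions.to_csv(out_dir / "predictions.csv", index=False)
    rep = dict(stamp)
    rep["metrics"] = result.report.as_dict()
    rep["confusion"] = asdict(result.counts)
    rep["best_params"] = result.best_params
    rep["cv_mean_accuracy"] = result.cv_mean_accuracy
    with open(out_dir / "report.json", "w") as fh:
        json.dump(rep, fh, indent=2)
    pd.DataFrame([dict(result.report.as_dict(),
                       classifier=cfg.classifier,
                       feature_set=cfg.feature_set,
                       config_hash=cfg.config_hash)]).to_csv(
        out_dir / "report.csv", index=False)
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(result.summary() + "\n")
    if isinstance(model, TwinSVM):
        model.save(out_dir / "model.joblib")
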