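"""Spectral-temporal features, tree-ensemble classification, accuracy metrics.

The feature set is the seven per-pixel statistics (median, sample standard
deviation, minimum, maximum, 25th/50th/75th percentiles) applied to every
spectral band and vegetation index of a seasonal image stack; with 6 bands and
the 3 indices this yields 63 feature layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core import LulcMap, substream
from .errors import ConfigurationError, SamplingError, ValidationError
from .synthetic import ImageCollection

# EVI parameterization (gain, aerosol resistance terms, canopy adjustment)
EVI_G = 2.5
EVI_C1 = 6.0
EVI_C2 = 7.5
EVI_L = 1.0

INDEX_NAMES = ("dvi", "ndvi", "evi")

#: statistic name -> per-pixel reducer over the scene axis (axis 0).
#: Percentiles use linear interpolation between order statistics; the
#: standard deviation uses the sample (n-1) denominator.
STM_STATISTICS = ("median", "sd", "min", "max", "p25", "p50", "p75")


def vegetation_indices(
    scene: np.ndarray, band_names: tuple[str, ...]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Append DVI, NDVI and EVI bands to a multiband scene.

    NDVI = (NIR - R) / (NIR + R); DVI = NIR - R;
    EVI = G * (NIR - R) / (NIR + C1*R - C2*B + L).
    Pixels where an index denominator is zero are flagged NaN.
    """
    names = [n.lower() for n in band_names]
    for required in ("red", "nir", "blue"):
        if required not in names:
            raise ConfigurationError(f"band {required!r} not found in {band_names}")
    red = scene[names.index("red")]
    nir = scene[names.index("nir")]
    blue = scene[names.index("blue")]

    dvi = nir - red
    ndvi_den = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(ndvi_den != 0, (nir - red) / ndvi_den, np.nan)
        evi_den = nir + EVI_C1 * red - EVI_C2 * blue + EVI_L
        evi = np.where(evi_den != 0, EVI_G * (nir - red) / evi_den, np.nan)
    out = np.concatenate([scene, np.stack([dvi, ndvi, evi])], axis=0)
    return out, tuple(band_names) + INDEX_NAMES


@dataclass
class STMFeatureCube:
    """Per-pixel temporal statistics, one raster per (series, statistic)."""

    features: np.ndarray  # (n_features, rows, cols)
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.feature_names):
            raise ValidationError("feature count must match names")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.features.shape[1:]

    def as_table(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Feature values at given pixel coordinates, one pixel per row."""
        return pd.DataFrame(
            self.features[:, rows, cols].T, columns=list(self.feature_names)
        )


def compute_stm(
    collection: ImageCollection, append_indices: bool = True
) -> STMFeatureCube:
    """Reduce a scene stack to the seven spectral-temporal statistics.

    Scenes with nodata (NaN) are excluded pixel-wise from every statistic.
    """
    if collection.n_scenes < 1:
        raise ValidationError("empty image collection")
    if append_indices:
        appended = [vegetation_indices(s, collection.band_names) for s in collection.scenes]
        stacks = [a[0] for a in appended]
        series_names = appended[0][1]
    else:
        stacks = list(collection.scenes)
        series_names = tuple(collection.band_names)
    cube = np.stack(stacks)  # (scenes, series, rows, cols)

    feats, names = [], []
    with np.errstate(invalid="ignore"):
        for si, series in enumerate(series_names):
            x = cube[:, si]  # (scenes, rows, cols)
            n_valid = np.sum(np.isfinite(x), axis=0)
            stats = {
                "median": np.nanmedian(x, axis=0),
                "sd": np.nanstd(x, axis=0, ddof=1) if cube.shape[0] > 1 else np.zeros(x.shape[1:]),
                "min": np.nanmin(x, axis=0),
                "max": np.nanmax(x, axis=0),
                "p25": np.nanpercentile(x, 25, axis=0),
                "p50": np.nanpercentile(x, 50, axis=0),
                "p75": np.nanpercentile(x, 75, axis=0),
            }
            for stat in STM_STATISTICS:
                layer = np.where(n_valid > 0, stats[stat], np.nan)
                feats.append(layer)
                names.append(f"{series}_{stat}")
    return STMFeatureCube(np.stack(feats), tuple(names))


def split_samples(
    samples: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> pd.DataFrame:
    """Assign train/test roles, stratified per class.

    Per stratum the train count is ``floor(n * train_fraction)``; the
    remainder goes to test.  Deterministic for a fixed seed.
    """
    if not 0 < train_fraction <= 1:
        raise SamplingError("train_fraction must be in (0, 1]")
    rng = substream(seed, "split_samples")
    out = samples.copy().reset_index(drop=True)
    out["role"] = "test"
    for _, grp in out.groupby("class_code"):
        n_train = int(np.floor(len(grp) * train_fraction))
        chosen = rng.choice(grp.index.to_numpy(), size=n_train, replace=False)
        out.loc[chosen, "role"] = "train"
    return out


@dataclass
class ClassifierModel:
    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    class_codes: tuple[int, ...]
    settings: dict


def train_classifier(
    cube: STMFeatureCube,
    train_samples: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierModel:
    """Fit a seeded random-forest classifier on STM features at sample pixels.

    Hyperparameters other than the tree count stay at library defaults and are
    echoed in ``settings`` for the run log.
    """
    labels = train_samples["class_code"].to_numpy()
    present = np.unique(labels)
    if present.size < 2:
        raise ValidationError("need at least 2 classes in training data")
    X = cube.as_table(
        train_samples["row"].to_numpy(), train_samples["col"].to_numpy()
    ).to_numpy()
    if np.isnan(X).any():
        raise SamplingError("training samples fall on nodata pixels")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, labels)
    settings = {
        "n_trees": n_trees,
        "seed": seed,
        "max_depth": rf.max_depth,
        "max_features": rf.max_features,
    }
    return ClassifierModel(rf, cube.feature_names, tuple(int(c) for c in present), settings)


def classify(
    model: ClassifierModel,
    cube: STMFeatureCube,
    class_codes: tuple[int, ...],
    nodata: int = 255,
    pixel_size: float = 30.0,
) -> LulcMap:
    """Predict one class code per valid pixel; nodata propagates."""
    if cube.feature_names != model.feature_names:
        raise ValidationError("feature names do not match the trained model")
    rows, cols = cube.grid_shape
    flat = cube.features.reshape(cube.n_features, -1).T
    valid = np.isfinite(flat).all(axis=1)
    data = np.full(rows * cols, nodata, dtype=np.uint8)
    if valid.any():
        data[valid] = model.estimator.predict(flat[valid]).astype(np.uint8)
    return LulcMap(data.reshape(rows, cols), class_codes, nodata=nodata, pixel_size=pixel_size)


@dataclass
class AccuracyReport:
    confusion_matrix: pd.DataFrame  # rows = reference, cols = predicted
    overall_accuracy: float
    kappa: float
    per_class_f1: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "per_class_f1": {str(k): v for k, v in self.per_class_f1.items()},
            "confusion_matrix": self.confusion_matrix.to_dict(),
        }


def accuracy_from_confusion(cm: np.ndarray, class_codes: tuple[int, ...]) -> AccuracyReport:
    """Overall accuracy, Cohen's kappa and per-class F1 from a counts matrix."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    oa = np.trace(cm) / total
    pe = float((cm.sum(axis=1) / total) @ (cm.sum(axis=0) / total))
    kappa = (oa - pe) / (1 - pe) if pe < 1 else 1.0
    f1 = {}
    for i, code in enumerate(class_codes):
        tp = cm[i, i]
        prec_den = cm[:, i].sum()
        rec_den = cm[i, :].sum()
        precision = tp / prec_den if prec_den else 0.0
        recall = tp / rec_den if rec_den else 0.0
        f1[code] = (
            2 * precision * recall / (precision + recall) if precision + recall else 0.0
        )
    frame = pd.DataFrame(cm.astype(int), index=list(class_codes), columns=list(class_codes))
    return AccuracyReport(frame, float(oa), float(kappa), f1)


def assess_accuracy(predicted: LulcMap, test_samples: pd.DataFrame) -> AccuracyReport:
    """Confusion-matrix accuracy of a map against labelled test pixels."""
    if len(test_samples) == 0:
        raise ValidationError("empty test set")
    pred = predicted.data[test_samples["row"].to_numpy(), test_samples["col"].to_numpy()]
    if np.any(pred == predicted.nodata):
        raise ValidationError("test samples fall on nodata pixels")
    truth = test_samples["class_code"].to_numpy()
    codes = predicted.class_codes
    idx = {c: i for i, c in enumerate(codes)}
    cm = np.zeros((len(codes), len(codes)), dtype=int)
    for t, p in zip(truth, pred):
        cm[idx[int(t)], idx[int(p)]] += 1
    return accuracy_from_confusion(cm, codes)


def binarize_forest(lulc: LulcMap, forest_code: int = 1) -> LulcMap:
    """Collapse the legend to forest (1) / non-forest (0); nodata preserved."""
    if forest_code not in lulc.class_codes:
        raise ConfigurationError(f"forest code {forest_code} not in class set")
    data = np.full(lulc.shape, lulc.nodata, dtype=np.uint8)
    valid = lulc.valid_mask
    data[valid] = (lulc.data[valid] == forest_code).astype(np.uint8)
    return LulcMap(data, (0, 1), nodata=lulc.nodata, pixel_size=lulc.pixel_size)
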