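"""Morphometric nucleus classification: human vs chicken (CAM) tissue.

Xenograft tissue excised from the chicken chorioallantoic membrane contains
three nuclear populations: (1) human tumour cells, (2) chicken cells in the
dense membranous rim at the section edge (the CAM itself), and (3) chicken
cells infiltrated into the human tissue. Three features separate them —
nuclear area (human nuclei are large), eccentricity (chicken erythrocyte
nuclei are elongated), and k-3 density (mean centroid distance to the three
nearest neighbouring nuclei; the CAM rim is dense, so it scores low). A
linear classifier over standardized features assigns each nucleus a class,
and CAM-rim nuclei are excluded from all human-cell analyses.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops_table
from sklearn.linear_model import LogisticRegression

from .segmentation import NucleusLabelMap

logger = logging.getLogger(__name__)

CLASS_HUMAN = "human"
CLASS_CHICKEN_PERIPHERAL = "chicken_peripheral"
CLASS_CHICKEN_INFILTRATING = "chicken_infiltrating"
UNCLASSIFIED = "unclassified"

FEATURE_COLUMNS = ["area_px", "eccentricity", "k3_density_px"]

MODEL_FORMAT_VERSION = 1


def eccentricity_from_coords(rows: np.ndarray, cols: np.ndarray) -> float:
    """Moment-based eccentricity of a pixel set (0 = circle, ->1 = line)."""
    pts = np.stack([np.asarray(rows, float), np.asarray(cols, float)])
    if pts.shape[1] < 2:
        return 0.0
    cov = np.cov(pts, ddof=0)
    evals = np.linalg.eigvalsh(cov)
    l_min, l_max = float(evals[0]), float(evals[1])
    if l_max <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - l_min / l_max)))


def k3_density(centroids: np.ndarray, k: int = 3) -> np.ndarray:
    """Mean Euclidean distance from each point to its k nearest other points.

    Returns NaN for every point when fewer than k+1 points exist. Ties in
    neighbour distance are harmless: only the k smallest distances enter the
    mean, and tied distances contribute the same value whichever neighbour is
    taken.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    n = len(centroids)
    if n < k + 1:
        return np.full(n, np.nan)
    tree = cKDTree(centroids)
    dist, _ = tree.query(centroids, k=k + 1)
    return dist[:, 1:].mean(axis=1)


def compute_features(label_map: NucleusLabelMap) -> pd.DataFrame:
    """Per-nucleus feature table: label, centroid, area, eccentricity, k3 density.

    k3_density_px is NaN (flagged, never fabricated) when fewer than 4 nuclei
    are present. All nuclei start unclassified.
    """
    labels = label_map.labels
    if label_map.n_labels < 1:
        return pd.DataFrame(
            columns=["label", "centroid_row", "centroid_col", *FEATURE_COLUMNS, "class"]
        )
    props = regionprops_table(
        labels, properties=("label", "centroid", "area", "eccentricity")
    )
    df = pd.DataFrame(
        {
            "label": props["label"].astype(int),
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
            "area_px": props["area"].astype(float),
            "eccentricity": props["eccentricity"],
        }
    )
    df["k3_density_px"] = k3_density(df[["centroid_row", "centroid_col"]].to_numpy())
    df["class"] = UNCLASSIFIED
    return df


@dataclass(frozen=True)
class LinearClassifierModel:
    """Affine-scored linear classifier over standardized nuclear features.

    Prediction is argmax over per-class scores ``(x - mean) / sd @ w + b``;
    deterministic given features. Serializes to a versioned JSON document.
    """

    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    weights: np.ndarray     # shape (n_classes, n_features)
    intercepts: np.ndarray  # shape (n_classes,)
    training_fingerprint: str = ""

    def scores(self, features: np.ndarray) -> np.ndarray:
        x = (np.asarray(features, dtype=np.float64) - self.feature_mean) / self.feature_sd
        # missing k3 density: impute the training mean (0 after standardization)
        x = np.nan_to_num(x, nan=0.0)
        return x @ self.weights.T + self.intercepts

    def predict(self, features: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.scores(features), axis=1)
        return np.asarray(self.classes, dtype=object)[idx]

    def to_json(self) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
            "training_fingerprint": self.training_fingerprint,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearClassifierModel":
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {doc.get('format_version')}")
        return cls(
            classes=tuple(doc["classes"]),
            feature_names=tuple(doc["feature_names"]),
            feature_mean=np.asarray(doc["feature_mean"], dtype=np.float64),
            feature_sd=np.asarray(doc["feature_sd"], dtype=np.float64),
            weights=np.asarray(doc["weights"], dtype=np.float64),
            intercepts=np.asarray(doc["intercepts"], dtype=np.float64),
            training_fingerprint=doc.get("training_fingerprint", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "LinearClassifierModel":
        return cls.from_json(Path(path).read_text())


def _fingerprint(table: pd.DataFrame) -> str:
    canon = table[[*FEATURE_COLUMNS, "class"]].sort_values(
        [*FEATURE_COLUMNS, "class"], kind="mergesort"
    )
    return hashlib.sha256(canon.to_csv(index=False).encode()).hexdigest()[:16]


def train_classifier(table: pd.DataFrame, seed: int = 0) -> LinearClassifierModel:
    """Fit the linear nucleus classifier on a labeled feature table.

    ``table`` needs columns area_px, eccentricity, k3_density_px and class.
    Features are z-scored before the fit (area and eccentricity live on
    incommensurate scales). Training is deterministic for a given table.
    """
    missing = [c for c in (*FEATURE_COLUMNS, "class") if c not in table.columns]
    if missing:
        raise ValueError(f"training table missing columns: {missing}")
    x = table[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    y = table["class"].to_numpy()
    if not np.all(np.isfinite(x)):
        bad = np.where(~np.isfinite(x).all(axis=1))[0]
        raise ValueError(f"non-finite features in training rows {bad.tolist()[:10]}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training table must contain at least 2 classes")
    counts = pd.Series(y).value_counts()
    if (counts < 10).any():
        logger.warning("classes with <10 training examples: %s",
                       counts[counts < 10].to_dict())

    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xs = (x - mean) / sd

    clf = LogisticRegression(C=100.0, max_iter=5000, random_state=seed)
    clf.fit(xs, y)
    coef, intercept = clf.coef_, clf.intercept_
    if coef.shape[0] == 1:  # binary fit: expand to two-row argmax form
        coef = np.vstack([np.zeros_like(coef[0]), coef[0]])
        intercept = np.array([0.0, intercept[0]])
    return LinearClassifierModel(
        classes=tuple(clf.classes_),
        feature_names=tuple(FEATURE_COLUMNS),
        feature_mean=mean,
        feature_sd=sd,
        weights=coef,
        intercepts=intercept,
        training_fingerprint=_fingerprint(table),
    )


def classify_nuclei(records: pd.DataFrame, model: LinearClassifierModel) -> pd.DataFrame:
    """Assign every nucleus exactly one class; returns a new DataFrame.

    Records with missing k3_density_px are classified from the remaining
    features (the missing feature is imputed at the training mean) with a
    logged warning.
    """
    out = records.copy()
    if out.empty:
        return out
    feats = out[list(model.feature_names)].to_numpy(dtype=np.float64)
    n_missing = int(np.isnan(feats).any(axis=1).sum())
    if n_missing:
        logger.warning(
            "%d records have missing features; classifying on the remainder", n_missing
        )
    out["class"] = model.predict(feats)
    return out


def exclude_cam(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition classified records for human-cell analysis.

    Returns (human_analysis_set, excluded_set): CAM-rim (chicken_peripheral)
    nuclei are excluded; infiltrating chicken nuclei stay in the record set,
    flagged by their class, and are dropped later by per-class aggregation.
    Nothing is deleted — both frames are views onto the input rows.
    """
    is_cam = records["class"] == CLASS_CHICKEN_PERIPHERAL
    return records[~is_cam], records[is_cam]


# --- separable feature preset --------------------------------------------

SEPARABLE_PRESET = {
    CLASS_HUMAN: {"area": (120.0, 15.0), "ecc": (0.30, 0.05), "k3": (15.0, 3.0)},
    CLASS_CHICKEN_PERIPHERAL: {"area": (35.0, 8.0), "ecc": (0.85, 0.05), "k3": (6.0, 1.5)},
    CLASS_CHICKEN_INFILTRATING: {"area": (35.0, 8.0), "ecc": (0.85, 0.05), "k3": (28.0, 4.0)},
}


def sample_separable_features(n_per_class: int, seed: int = 0) -> pd.DataFrame:
    """Draw a labeled feature table from the separable three-class preset.

    Human nuclei: area ~ N(120, 15²) px², eccentricity ~ N(0.30, 0.05²);
    chicken nuclei: area ~ N(35, 8²), eccentricity ~ N(0.85, 0.05²), with the
    CAM rim at low k-3 density (dense packing) and infiltrating chicken at
    high k-3 density (sparse). Values are clipped to their physical ranges.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for cls, p in SEPARABLE_PRESET.items():
        frames.append(
            pd.DataFrame(
                {
                    "area_px": np.clip(rng.normal(*p["area"], n_per_class), 5.0, None),
                    "eccentricity": np.clip(rng.normal(*p["ecc"], n_per_class), 0.0, 0.99),
                    "k3_density_px": np.clip(rng.normal(*p["k3"], n_per_class), 0.5, None),
                    "class": cls,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_model(seed: int = 0, n_per_class: int = 200) -> LinearClassifierModel:
    """The shipped default classifier: trained on the separable preset."""
    return train_classifier(sample_separable_features(n_per_class, seed=seed), seed=seed)
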