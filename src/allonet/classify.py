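"""Random-forest classification of conformational states from 16 descriptors.

The training protocol: stratified 80/20 split at frame level, Min–Max
scaling fitted on the training split only, SMOTE oversampling of the
minority class at a 0.5 minority/majority ratio (training data only),
then a 1000-tree random forest with unrestricted depth.  Importances are
reported both as Gini (mean impurity decrease) and as permutation
importance (mean drop in held-out AUC over repeated shuffles).

SMOTE is implemented in-package: each synthetic sample interpolates a
minority point toward one of its k=5 nearest minority neighbours at a
uniform random fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (confusion_matrix, precision_recall_fscore_support,
                             roc_auc_score)
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler

from .descriptors import geometry_series
from .io import DomainMap, Ensemble, SystemManifest, REGIONS

__all__ = [
    "SMOTESampler",
    "ClassifierReport",
    "FittedClassifier",
    "default_feature_spec",
    "assemble_features",
    "train_classifier",
    "feature_importance",
]


class SMOTESampler:
    """Synthetic minority oversampling by k-NN interpolation.

    ``sampling_strategy`` is the target minority/majority count ratio after
    resampling (no-op if the data already satisfy it).
    """

    def __init__(self, sampling_strategy: float = 0.5, k_neighbors: int = 5,
                 random_state: int | None = None):
        if not 0 < sampling_strategy <= 1:
            raise ValueError("sampling_strategy must be in (0, 1]")
        self.sampling_strategy = sampling_strategy
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X: np.ndarray, y: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE here supports binary labels only")
        minority = classes[np.argmin(counts)]
        majority = classes[np.argmax(counts)]
        n_min, n_maj = counts.min(), counts.max()
        target = int(np.floor(self.sampling_strategy * n_maj))
        n_new = target - n_min
        if n_new <= 0:
            return X.copy(), y.copy()
        Xm = X[y == minority]
        k = min(self.k_neighbors, len(Xm) - 1)
        if k < 1:
            raise ValueError("minority class too small for SMOTE")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)      # column 0 is the point itself
        rng = np.random.default_rng(self.random_state)
        base = rng.integers(0, len(Xm), size=n_new)
        pick = rng.integers(1, k + 1, size=n_new)
        gap = rng.random((n_new, 1))
        neighbors = Xm[idx[base, pick]]
        synth = Xm[base] + gap * (neighbors - Xm[base])
        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out


# ---------------------------------------------------------------------------
# feature assembly


def default_feature_spec(domain_map: DomainMap) -> list[dict]:
    """A 16-descriptor geometry spec derived from the domain map.

    10 region-centroid distances (all region pairs), 5 region span
    distances (first–last residue of each region), and one interdomain
    angle over the SH3, linker and SH1C centroids (an R-spine-like
    orientation descriptor).  Works on any five-region protein; studies
    with named residue pairs (e.g. the catalytic-lysine salt bridges)
    should supply their own spec.
    """
    present = [r for r in REGIONS if len(domain_map.residues_in(r))]
    spec: list[dict] = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            spec.append({"kind": "centroid_distance",
                         "regions": (present[i], present[j]),
                         "name": f"dc_{present[i]}_{present[j]}"})
    for r in present:
        rids = domain_map.residues_in(r)
        spec.append({"kind": "distance",
                     "residues": (int(rids[0]), int(rids[-1])),
                     "name": f"span_{r}"})
    a = int(domain_map.residues_in(present[0])[0])
    mid_region = present[len(present) // 2]
    m_ids = domain_map.residues_in(mid_region)
    b = int(m_ids[len(m_ids) // 2])
    c = int(domain_map.residues_in(present[-1])[-1])
    spec.append({"kind": "angle", "residues": (a, b, c), "name": "spine_angle"})
    return spec[:16]


def assemble_features(ensembles: dict[str, list[Ensemble]],
                      manifest: SystemManifest,
                      feature_spec: list[dict],
                      domain_map: DomainMap | None = None) -> pd.DataFrame:
    """Per-frame feature table over all systems and replicates."""
    parts = []
    for name, entry in manifest.entries.items():
        for ens in ensembles[name]:
            df = geometry_series(ens, feature_spec, domain_map=domain_map)
            df["label"] = entry.label
            df["system"] = name
            parts.append(df)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# training and evaluation


@dataclass
class ClassifierReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    auc: float
    confusion: np.ndarray
    gini_importance: np.ndarray
    feature_names: list[str]
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "gini_importance": dict(zip(self.feature_names,
                                        self.gini_importance.tolist())),
            "params": self.params,
        }


@dataclass
class FittedClassifier:
    scaler: MinMaxScaler
    forest: RandomForestClassifier
    feature_names: list[str]
    X_test: np.ndarray            # scaled held-out features
    y_test: np.ndarray
    report: ClassifierReport


def train_classifier(table: pd.DataFrame, seed: int = 0,
                     n_estimators: int = 1000, max_depth: int | None = None,
                     smote_ratio: float = 0.5, test_size: float = 0.2,
                     class_weight=None) -> FittedClassifier:
    """Train and evaluate the state classifier on a feature table.

    ``table`` must have feature columns plus ``label`` (and optionally
    ``system``).  Scaling and SMOTE see the training split only; metrics
    are computed on the held-out stratified 20%.
    """
    feature_names = [c for c in table.columns if c not in ("label", "system")]
    X = table[feature_names].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed, shuffle=True)
    if min(np.bincount(y_tr)) < 2:
        raise ValueError("a class has fewer than 2 training samples")
    scaler = MinMaxScaler().fit(X_tr)
    X_trs, X_tes = scaler.transform(X_tr), scaler.transform(X_te)
    counts = np.bincount(y_tr)
    if counts.min() / counts.max() < smote_ratio:
        X_trs, y_tr = SMOTESampler(smote_ratio, random_state=seed
                                   ).fit_resample(X_trs, y_tr)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        class_weight=class_weight, random_state=seed, n_jobs=1,
    ).fit(X_trs, y_tr)
    y_pred = forest.predict(X_tes)
    y_prob = forest.predict_proba(X_tes)[:, list(forest.classes_).index(1)]
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_te, y_pred, labels=[0, 1], zero_division=0)
    prec_m, rec_m, f1_m, _ = precision_recall_fscore_support(
        y_te, y_pred, average="macro", zero_division=0)
    prec_w, rec_w, f1_w, _ = precision_recall_fscore_support(
        y_te, y_pred, average="weighted", zero_division=0)
    report = ClassifierReport(
        accuracy=float((y_pred == y_te).mean()),
        precision={"inactive-like": float(prec[0]), "active-like": float(prec[1]),
                   "macro": float(prec_m), "weighted": float(prec_w)},
        recall={"inactive-like": float(rec[0]), "active-like": float(rec[1]),
                "macro": float(rec_m), "weighted": float(rec_w)},
        f1={"inactive-like": float(f1[0]), "active-like": float(f1[1]),
            "macro": float(f1_m), "weighted": float(f1_w)},
        auc=float(roc_auc_score(y_te, y_prob)),
        confusion=confusion_matrix(y_te, y_pred, labels=[0, 1]),
        gini_importance=forest.feature_importances_,
        feature_names=feature_names,
        params={"n_estimators": n_estimators, "max_depth": max_depth,
                "smote_ratio": smote_ratio, "test_size": test_size,
                "seed": seed},
    )
    return FittedClassifier(scaler, forest, feature_names, X_tes, y_te, report)


def feature_importance(fitted: FittedClassifier, method: str = "permutation",
                       repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Ranked feature importances.

    ``gini``: the forest's normalised mean impurity decrease.
    ``permutation``: mean (± sd) drop in held-out AUC when a feature column
    is shuffled, over ``repeats`` shuffles.
    """
    if method == "gini":
        df = pd.DataFrame({
            "feature": fitted.feature_names,
            "importance": fitted.report.gini_importance,
        })
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        X, y = fitted.X_test, fitted.y_test
        pos = list(fitted.forest.classes_).index(1)
        base = roc_auc_score(y, fitted.forest.predict_proba(X)[:, pos])
        means, sds = [], []
        for j in range(X.shape[1]):
            drops = []
            for _ in range(repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops.append(base - roc_auc_score(
                    y, fitted.forest.predict_proba(Xp)[:, pos]))
            means.append(np.mean(drops))
            sds.append(np.std(drops))
        df = pd.DataFrame({"feature": fitted.feature_names,
                           "importance": means, "sd": sds})
    else:
        raise ValueError("method must be 'gini' or 'permutation'")
    return df.sort_values("importance", ascending=False).reset_index(drop=True)
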