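"""Symptomatic/asymptomatic classification of VAG feature vectors.

Two classifiers are provided:

- **KNN** — k-nearest neighbors (default k=10, Euclidean distance) on
  standardized features, evaluated with stratified 10-fold cross-validation.
  Standardization parameters are fit on each training split only, so no
  information leaks into the test split (a ``global_standardize`` option
  reproduces the standardize-then-split reading). Majority-vote ties are
  broken by the single nearest neighbor's label.

- **JVA-style decision tree** — a fixed threshold tree over the spectral
  features, configurable via YAML. The shipped default is a labelled
  approximation of the published joint-vibration-analysis tree (its exact
  form is proprietary); its thresholds are in the JVA device's units, so a
  scale factor converts from the local acquisition chain's units.

Reports carry the confusion matrix (symptomatic = positive class) and the
derived TPR (sensitivity), TNR (specificity) and ACC rates.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from vagkit.features import FEATURE_NAMES, FeatureVector, feature_table
from vagkit.spectral import compute_spectrum, normalized_spectrum
from vagkit.features import extract_features

POSITIVE, NEGATIVE = "symptomatic", "asymptomatic"

_COMPARATORS = {
    "gt": lambda x, t: x > t,
    "ge": lambda x, t: x >= t,
    "lt": lambda x, t: x < t,
    "le": lambda x, t: x <= t,
}


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature location/scale learned from a training set (ddof=1 SDs)."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    dropped: tuple[str, ...] = ()

    def apply(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        return (X - self.means) / self.sds


@dataclass(frozen=True)
class JvaThresholds:
    """Threshold decision tree: named nodes, leaf labels, unit scale factor."""

    root: str
    nodes: dict[str, dict]
    scale: float = 1.0

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        leaves = {POSITIVE, NEGATIVE}
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in leaves:
                continue
            if name in seen:
                raise ValueError(f"cycle or repeated node {name!r} in tree")
            seen.add(name)
            node = self.nodes.get(name)
            if node is None:
                raise ValueError(f"node {name!r} referenced but not defined")
            if node["comparator"] not in _COMPARATORS:
                raise ValueError(f"unknown comparator {node['comparator']!r}")
            if not np.isfinite(node["threshold"]):
                raise ValueError("thresholds must be finite")
            stack += [node["if_true"], node["if_false"]]

    def paths(self) -> list[list[tuple[str, bool]]]:
        """All root-to-leaf paths as [(node_name, branch_taken), ...] lists."""
        out: list[list[tuple[str, bool]]] = []

        def walk(name: str, prefix: list[tuple[str, bool]]) -> None:
            if name in (POSITIVE, NEGATIVE):
                out.append(prefix + [(name, True)])
                return
            node = self.nodes[name]
            walk(node["if_true"], prefix + [(name, True)])
            walk(node["if_false"], prefix + [(name, False)])

        walk(self.root, [])
        return out


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion-matrix counts and rates (symptomatic = positive)."""

    tp: int
    fp: int
    tn: int
    fn: int
    seed: int | None = None
    fold_assignments: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.total


def report_from_predictions(y_true, y_pred, seed: int | None = None,
                            fold_assignments: dict[str, int] | None = None
                            ) -> ClassificationReport:
    """Build a confusion-matrix report from true and predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE)))
    fn = int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE)))
    tn = int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE)))
    fp = int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE)))
    return ClassificationReport(tp=tp, fp=fp, tn=tn, fn=fn, seed=seed,
                                fold_assignments=fold_assignments or {})


def standardize(train_features: pd.DataFrame,
                feature_names: list[str] | None = None) -> StandardizationParams:
    """Learn per-feature mean/SD; zero-variance features are dropped with a warning."""
    feature_names = feature_names or FEATURE_NAMES
    X = train_features[feature_names]
    if len(X) < 2:
        raise ValueError("need at least 2 training rows to standardize")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dropped = tuple(sds.index[sds == 0])
    if dropped:
        warnings.warn(f"zero-variance feature(s) dropped: {dropped}", stacklevel=2)
    kept = [f for f in feature_names if f not in dropped]
    return StandardizationParams(
        feature_names=tuple(kept),
        means=means[kept].to_numpy(),
        sds=sds[kept].to_numpy(),
        dropped=dropped,
    )


def knn_predict(train_X: np.ndarray, train_y, query_X: np.ndarray,
                k: int = 10) -> np.ndarray:
    """Majority vote over the k Euclidean-nearest training rows.

    Ties are broken by the nearest neighbor's label, which keeps the decision
    deterministic and distance-respecting for even k.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    train_y = np.asarray(train_y)
    if k > len(train_X):
        raise ValueError(f"k={k} exceeds the {len(train_X)} training rows")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(train_X)
    _, idx = nn.kneighbors(query_X)
    out = np.empty(len(query_X), dtype=train_y.dtype)
    for q, neighbors in enumerate(idx):
        labels = train_y[neighbors]
        values, counts = np.unique(labels, return_counts=True)
        winners = values[counts == counts.max()]
        out[q] = labels[0] if len(winners) > 1 else winners[0]
    return out


def cross_validate(features: pd.DataFrame, labels=None, folds: int = 10,
                   k: int = 10, seed: int = 0,
                   feature_names: list[str] | None = None,
                   global_standardize: bool = False) -> ClassificationReport:
    """Stratified k-fold cross-validated KNN over a feature table.

    Fold assignment is stratified by class and seeded. By default the
    standardization is re-fit on each training split; `global_standardize`
    fits it once on the full table before splitting.
    """
    y = np.asarray(labels if labels is not None else features["group"])
    feature_names = feature_names or FEATURE_NAMES
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(f"need at least {folds} samples per class for "
                         f"{folds}-fold stratification")

    global_params = standardize(features, feature_names) if global_standardize else None
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=y.dtype)
    fold_of: dict[str, int] = {}
    ids = (features["subject_id"].astype(str).to_numpy()
           if "subject_id" in features else np.arange(len(y)).astype(str))

    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"a class is absent from training fold {fold}")
        params = global_params or standardize(features.iloc[train_idx], feature_names)
        train_X = params.apply(features.iloc[train_idx])
        test_X = params.apply(features.iloc[test_idx])
        y_pred[test_idx] = knn_predict(train_X, y[train_idx], test_X, k=k)
        for i in test_idx:
            fold_of[ids[i]] = fold

    return report_from_predictions(y, y_pred, seed=seed, fold_assignments=fold_of)


def default_jva_thresholds() -> JvaThresholds:
    """Load the shipped default JVA-style tree (a documented approximation)."""
    text = (importlib.resources.files("vagkit") / "data" /
            "jva_tree_default.yaml").read_text()
    return load_jva_thresholds_from_text(text)


def load_jva_thresholds_from_text(text: str) -> JvaThresholds:
    cfg = yaml.safe_load(text)
    return JvaThresholds(root=cfg["root"], nodes=cfg["nodes"],
                         scale=float(cfg.get("scale", 1.0)))


def load_jva_thresholds(path) -> JvaThresholds:
    with open(path) as fh:
        return load_jva_thresholds_from_text(fh.read())


def jva_tree_classify(feature_vector: FeatureVector | dict,
                      thresholds: JvaThresholds | None = None) -> str:
    """Traverse the threshold tree to a symptomatic/asymptomatic leaf.

    Integral and amplitude features (ti, ib3, ia3, pa) are multiplied by the
    tree's `scale` before comparison (unit conversion to the thresholds'
    device units). A non-finite feature value (e.g. IBAR = +inf when nothing
    lies above 300 Hz) is treated as exceeding any threshold.
    """
    thresholds = thresholds or default_jva_thresholds()
    fv = feature_vector.as_dict() if isinstance(feature_vector, FeatureVector) \
        else dict(feature_vector)
    scaled_feats = {"ti", "ib3", "ia3", "pa"}

    name = thresholds.root
    while name not in (POSITIVE, NEGATIVE):
        node = thresholds.nodes[name]
        feat = node["feature"]
        if feat not in fv:
            raise KeyError(f"feature {feat!r} required by node {name!r} is missing")
        value = float(fv[feat])
        if feat in scaled_feats:
            value *= thresholds.scale
        if np.isnan(value):
            raise ValueError(f"feature {feat!r} is NaN at node {name!r}")
        if np.isinf(value):
            branch = value > 0  # +inf exceeds any threshold
        else:
            branch = bool(_COMPARATORS[node["comparator"]](value, node["threshold"]))
        name = node["if_true"] if branch else node["if_false"]
    return name


def extract_feature_tables(manifest: pd.DataFrame, recordings,
                           normalizations=("raw", "norm1", "norm2")
                           ) -> dict[str, pd.DataFrame]:
    """Feature table per requested normalization for a cohort of recordings."""
    tables: dict[str, pd.DataFrame] = {}
    raw_spectra = [compute_spectrum(rec) for rec in recordings]
    meta = manifest.to_dict("records")
    for norm in normalizations:
        vectors = [extract_features(normalized_spectrum(s, norm)) for s in raw_spectra]
        tables[norm] = feature_table(meta, vectors)
    return tables


def compare_classifiers(manifest: pd.DataFrame, recordings,
                        normalizations=("raw", "norm1", "norm2"),
                        seed: int = 0, folds: int = 10, k: int = 10,
                        thresholds: JvaThresholds | None = None) -> pd.DataFrame:
    """Per-session comparison of the JVA tree (all normalizations) vs KNN (raw).

    One row per (classifier setup, session) with TPR/TNR/ACC — 8 rows for the
    standard three-normalization, two-session configuration.
    """
    thresholds = thresholds or default_jva_thresholds()
    tables = extract_feature_tables(manifest, recordings, normalizations)
    sessions = sorted(manifest["session"].unique())
    rows = []
    for norm in normalizations:
        for sess in sessions:
            sub = tables[norm][tables[norm]["session"] == sess].reset_index(drop=True)
            y_pred = [jva_tree_classify(row[FEATURE_NAMES].to_dict(), thresholds)
                      for _, row in sub.iterrows()]
            rep = report_from_predictions(sub["group"], y_pred)
            rows.append({"classifier": "jva", "normalization": norm, "session": sess,
                         "tpr": rep.tpr, "tnr": rep.tnr, "acc": rep.acc})
    if "raw" in normalizations:
        for sess in sessions:
            sub = tables["raw"][tables["raw"]["session"] == sess].reset_index(drop=True)
            rep = cross_validate(sub, folds=folds, k=k, seed=seed)
            rows.append({"classifier": "knn", "normalization": "raw", "session": sess,
                         "tpr": rep.tpr, "tnr": rep.tnr, "acc": rep.acc})
    return pd.DataFrame(rows, columns=["classifier", "normalization", "session",
                                       "tpr", "tnr", "acc"])
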