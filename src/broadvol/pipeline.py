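"""End-to-end orchestration: manifest -> preprocess -> extract -> BLS ->
evaluation, plus the hyperparameter-stability sweep and model archives.

A *manifest* is a CSV with columns ``path,label`` (label in {AD, MCI, NC})
and optionally ``subject``; when ``subject`` is absent each image is its
own subject.  Splitting is stratified by class at a 0.7:0.3 ratio and, by
default, grouped at the *subject* level so repeat scans of one subject
never straddle the train/test boundary (image-level splitting, which
reproduces the published protocol but can leak subjects, is available via
``split_level="image"``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import bls_core, deep_features
from ._archive import load_arrays, save_arrays
from ._exceptions import ConfigurationError, StructuralError
from .bls_core import BLSConfig, BLSParams, LabelMatrix
from .deep_features import ExtractorConfig, ExtractorParams, init_extractor
from .preprocess import PreprocessConfig, preprocess_volume

log = logging.getLogger(__name__)

__all__ = [
    "TaskSpec",
    "EvaluationReport",
    "SweepGrid",
    "EnsembleModel",
    "FeatureCache",
    "split_dataset",
    "run_task",
    "compute_metrics",
    "sweep",
    "export_features",
    "read_manifest",
]

VALID_LABELS = ("AD", "MCI", "NC")

#: task name -> (classes, positive class).  "CN" in the source protocol is
#: the same group as "NC" (Normal Control).
TASKS = {
    "AD_vs_NC": (("AD", "NC"), "AD"),
    "AD_vs_MCI": (("AD", "MCI"), "AD"),
    "MCI_vs_NC": (("MCI", "NC"), "MCI"),
    "three_class": (("AD", "MCI", "NC"), None),
}


@dataclass
class TaskSpec:
    """A classification task with its split protocol."""

    name: str = "AD_vs_NC"
    split_ratio: float = 0.7
    split_seed: int = 0
    split_level: str = "subject"  # "subject" (grouped, default) or "image"

    def __post_init__(self):
        if self.name not in TASKS:
            raise ConfigurationError(f"unknown task {self.name!r}; choose from {sorted(TASKS)}")
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigurationError("split_ratio must be in (0, 1)")
        if self.split_level not in ("subject", "image"):
            raise ConfigurationError("split_level must be 'subject' or 'image'")

    @property
    def classes(self) -> tuple:
        return TASKS[self.name][0]

    @property
    def positive_class(self):
        return TASKS[self.name][1]


@dataclass
class EvaluationReport:
    """Per-task confusion matrix, scalar metrics and ROC points.

    ``wall_time_s`` entries are informational only and are excluded from
    the serialized report by default so identical runs produce
    byte-identical files.
    """

    task: str
    class_names: list
    confusion: list
    accuracy: float
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    roc_points: list = field(default_factory=list)
    auc: float | None = None
    n_train: int | None = None
    n_test: int | None = None
    split_seed: int | None = None
    wall_time_s: dict = field(default_factory=dict)

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d.pop("wall_time_s")
        return d

    def to_json(self, include_timing: bool = False) -> str:
        d = asdict(self) if include_timing else self.canonical_dict()
        return json.dumps(d, sort_keys=True, indent=2)

    def save(self, path, include_timing: bool = False) -> None:
        Path(path).write_text(self.to_json(include_timing=include_timing) + "\n")


@dataclass
class SweepGrid:
    """Hyperparameter grid of the stability sweep, kept inside the
    published ranges (feature nodes 500-4000, enhancement nodes 100-1000,
    sparsity 0.4-0.7)."""

    feature_node_values: tuple = (500, 2000, 4000)
    enh_node_values: tuple = (500,)
    sparsity_values: tuple = (0.5,)
    seeds: tuple = (0, 1, 2)

    def __post_init__(self):
        lo, hi = bls_core.SWEEP_FEATURE_RANGE
        if not all(lo <= v <= hi for v in self.feature_node_values):
            raise ConfigurationError(f"feature_node_values must lie in [{lo}, {hi}]")
        lo, hi = bls_core.SWEEP_ENH_RANGE
        if not all(lo <= v <= hi for v in self.enh_node_values):
            raise ConfigurationError(f"enh_node_values must lie in [{lo}, {hi}]")
        lo, hi = bls_core.SWEEP_SPARSITY_RANGE
        if not all(lo <= v <= hi for v in self.sparsity_values):
            raise ConfigurationError(f"sparsity_values must lie in [{lo}, {hi}]")

    @property
    def repeats(self) -> int:
        return len(self.seeds)


def read_manifest(path_or_df) -> pd.DataFrame:
    """Load and validate a manifest (CSV path or DataFrame)."""
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if not {"path", "label"}.issubset(df.columns):
        raise StructuralError("manifest must have columns 'path' and 'label'")
    bad = set(df["label"]) - set(VALID_LABELS)
    if bad:
        raise StructuralError(f"manifest has unknown labels {sorted(bad)}")
    if "subject" not in df.columns:
        df["subject"] = [Path(p).name for p in df["path"]]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_dataset(manifest, task: TaskSpec):
    """Stratified random split into (train, test) DataFrames.

    Stratification is by class; grouping is by subject unless
    ``task.split_level == "image"``.  Per class, ``round(ratio * n_groups)``
    groups go to training.  The two sets are disjoint and exhaustive over
    the task's classes; subject disjointness is asserted at runtime.
    """
    df = read_manifest(manifest)
    df = df[df["label"].isin(task.classes)].reset_index(drop=True)
    rng = np.random.default_rng(task.split_seed)
    train_parts, test_parts = [], []
    for cls in task.classes:
        cls_df = df[df["label"] == cls]
        if task.split_level == "subject":
            groups = cls_df["subject"].unique()
        else:
            groups = cls_df.index.to_numpy()
        if len(groups) < 2:
            raise ValueError(f"class {cls!r} has {len(groups)} group(s); need >= 2 to split")
        perm = rng.permutation(len(groups))
        n_train = int(round(task.split_ratio * len(groups)))
        n_train = min(max(n_train, 1), len(groups) - 1)  # both sides non-empty
        train_g = set(np.asarray(groups)[perm[:n_train]].tolist())
        if task.split_level == "subject":
            in_train = cls_df["subject"].isin(train_g)
        else:
            in_train = cls_df.index.isin(train_g)
        train_parts.append(cls_df[in_train])
        test_parts.append(cls_df[~in_train])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    overlap = set(train["subject"]) & set(test["subject"])
    if overlap:  # structurally impossible for subject-level; guards image-level misuse
        if task.split_level == "subject":
            raise AssertionError(f"subject leakage across split: {sorted(overlap)[:5]}")
        log.warning("image-level split: %d subject(s) appear in both sets", len(overlap))
    assert len(train) + len(test) == len(df)
    return train.reset_index(drop=True), test.reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature extraction with caching
# ---------------------------------------------------------------------------


class FeatureCache:
    """In-memory cache of extracted feature pairs.

    Keys combine a hash of the preprocessed voxel data with a hash of the
    extractor configuration; the extractor is frozen, so caching is
    lossless.
    """

    def __init__(self):
        self._store = {}

    @staticmethod
    def key(volume_data: np.ndarray, extractor_cfg: ExtractorConfig) -> str:
        h = hashlib.sha256()
        arr = np.ascontiguousarray(volume_data)
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
        h.update(json.dumps(asdict(extractor_cfg), sort_keys=True).encode())
        return h.hexdigest()

    def get_or_compute(self, volume_data, params: ExtractorParams):
        k = self.key(volume_data, params.config)
        if k not in self._store:
            pair = deep_features.extract_features(volume_data, params)
            self._store[k] = (pair.x_d, pair.x_e)
        return self._store[k]

    def __len__(self):
        return len(self._store)


def _extract_for(df: pd.DataFrame, params: ExtractorParams,
                 preprocess_cfg: PreprocessConfig, cache: FeatureCache | None):
    cache = cache if cache is not None else FeatureCache()
    xd_rows, xe_rows = [], []
    for path in df["path"]:
        vol = preprocess_volume(path, preprocess_cfg)
        x_d, x_e = cache.get_or_compute(vol.data, params)
        xd_rows.append(x_d)
        xe_rows.append(x_e)
    return np.stack(xd_rows), np.stack(xe_rows)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _safe_div(num, den, name):
    if den == 0:
        log.warning("metric %s has zero denominator; reporting 0 by convention", name)
        return 0.0
    return num / den


def compute_metrics(confusion, scores=None, truth=None, class_names=None,
                    task: str = "", positive_index: int = 0,
                    n_train=None, split_seed=None) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from a confusion matrix.

    The confusion matrix is laid out rows = truth, columns = prediction,
    with the positive class at ``positive_index`` (0 for reports built by
    :func:`run_task`).  For binary tasks the scalar metrics are

        ACC  = (TP+TN)/n          SEN = TP/(TP+FN)   SPEC = TN/(TN+FP)
        PREC = TP/(TP+FP)         F1  = 2*PREC*SEN/(PREC+SEN)

    with a zero denominator reported as 0 (logged).  When real-valued
    ``scores`` (positive-class score margin) and boolean/int ``truth`` are
    given, the ROC curve is swept over score thresholds and AUC computed by
    the trapezoid rule.  Multi-class reports carry accuracy and the k x k
    confusion only.
    """
    C = np.asarray(confusion, dtype=int)
    n = int(C.sum())
    accuracy = _safe_div(np.trace(C), n, "accuracy")
    sen = spec = prec = f1 = None
    if C.shape == (2, 2):
        pi = positive_index
        ni = 1 - pi
        tp, fn = C[pi, pi], C[pi, ni]
        fp, tn = C[ni, pi], C[ni, ni]
        sen = _safe_div(tp, tp + fn, "sensitivity")
        spec = _safe_div(tn, tn + fp, "specificity")
        prec = _safe_div(tp, tp + fp, "precision")
        f1 = _safe_div(2 * prec * sen, prec + sen, "f1")
    roc_points, auc_val = [], None
    if scores is not None and truth is not None and C.shape == (2, 2):
        fpr, tpr, _ = _sk_roc_curve(np.asarray(truth).astype(int), np.asarray(scores))
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
        auc_val = float(_sk_auc(fpr, tpr))
    return EvaluationReport(
        task=task,
        class_names=list(class_names) if class_names is not None else [],
        confusion=C.tolist(),
        accuracy=float(accuracy),
        sensitivity=None if sen is None else float(sen),
        specificity=None if spec is None else float(spec),
        precision=None if prec is None else float(prec),
        f1=None if f1 is None else float(f1),
        roc_points=roc_points,
        auc=auc_val,
        n_test=n,
        n_train=n_train,
        split_seed=split_seed,
    )


def _confusion_from_labels(truth, pred, class_order):
    idx = {c: i for i, c in enumerate(class_order)}
    C = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(truth, pred):
        C[idx[t], idx[p]] += 1
    return C


# ---------------------------------------------------------------------------
# the ensemble model container
# ---------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """Frozen extractor + fitted broad learner + preprocessing config."""

    extractor: ExtractorParams
    bls: BLSParams
    preprocess: PreprocessConfig
    task: str = ""

    def save(self, path) -> None:
        arrays = {
            "bls/W_e": self.bls.W_e, "bls/beta_e": self.bls.beta_e,
            "bls/W_h": self.bls.W_h, "bls/beta_h": self.bls.beta_h,
            "bls/W_out": self.bls.W_out,
        }
        for name in ("mu_d", "sd_d", "mu_e", "sd_e"):
            val = getattr(self.bls, name)
            if val is not None:
                arrays[f"bls/{name}"] = val
        import io as _io

        buf = _io.BytesIO()
        deep_features.save_extractor(self.extractor, buf)
        meta = {
            "task": self.task,
            "class_names": list(self.bls.class_names),
            "bls_config": asdict(self.bls.config),
            "preprocess": asdict(self.preprocess),
            "config_hash": hashlib.sha256(
                json.dumps({"bls": asdict(self.bls.config),
                            "extractor": asdict(self.extractor.config),
                            "preprocess": asdict(self.preprocess)},
                           sort_keys=True).encode()
            ).hexdigest(),
        }
        arrays["extractor_archive"] = np.frombuffer(buf.getvalue(), dtype=np.uint8)
        save_arrays(path, arrays, meta)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        import io as _io

        arrays, meta = load_arrays(path)
        extractor = deep_features.load_extractor(
            _io.BytesIO(arrays["extractor_archive"].tobytes())
        )
        cfg = BLSConfig(**meta["bls_config"])
        bls = BLSParams(
            config=cfg,
            W_e=arrays["bls/W_e"], beta_e=arrays["bls/beta_e"],
            W_h=arrays["bls/W_h"], beta_h=arrays["bls/beta_h"],
            W_out=arrays["bls/W_out"],
            class_names=meta["class_names"],
            mu_d=arrays.get("bls/mu_d"), sd_d=arrays.get("bls/sd_d"),
            mu_e=arrays.get("bls/mu_e"), sd_e=arrays.get("bls/sd_e"),
        )
        pp = meta["preprocess"]
        for key in ("intensity_range", "crop_shape", "clip_percentiles"):
            if pp.get(key) is not None:
                pp[key] = tuple(pp[key])
        return cls(extractor=extractor, bls=bls,
                   preprocess=PreprocessConfig(**pp), task=meta["task"])


# ---------------------------------------------------------------------------
# end-to-end runs
# ---------------------------------------------------------------------------


def run_task(manifest, task: TaskSpec, extractor_cfg: ExtractorConfig | None = None,
             bls_cfg: BLSConfig | None = None,
             preprocess_cfg: PreprocessConfig | None = None,
             cache: FeatureCache | None = None,
             model_path=None) -> EvaluationReport:
    """Run one task end to end and return its evaluation report.

    Volumes are preprocessed, features extracted once (cached), the broad
    learner fitted on the training split and evaluated on the test split.
    If ``model_path`` is given the fitted :class:`EnsembleModel` archive is
    written there.
    """
    extractor_cfg = extractor_cfg or ExtractorConfig()
    bls_cfg = bls_cfg or BLSConfig()
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    timings = {}

    t0 = time.perf_counter()
    train_df, test_df = split_dataset(manifest, task)
    if len(test_df) == 0 or len(train_df) == 0:
        raise ValueError("empty train or test set")
    timings["split_s"] = time.perf_counter() - t0

    params = init_extractor(extractor_cfg.seed, extractor_cfg.init_scheme, extractor_cfg)
    cache = cache if cache is not None else FeatureCache()
    t0 = time.perf_counter()
    Xd_tr, Xe_tr = _extract_for(train_df, params, preprocess_cfg, cache)
    Xd_te, Xe_te = _extract_for(test_df, params, preprocess_cfg, cache)
    timings["extract_s"] = time.perf_counter() - t0

    class_order = [c for c in task.classes]
    Y = LabelMatrix.from_labels(train_df["label"].to_numpy(), class_names=class_order)
    t0 = time.perf_counter()
    bls = bls_core.fit(Xd_tr, Xe_tr, Y, bls_cfg)
    timings["fit_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scores, pred = bls_core.predict(bls, Xd_te, Xe_te)
    timings["predict_s"] = time.perf_counter() - t0

    truth = test_df["label"].to_numpy()
    if task.positive_class is not None:
        order = [task.positive_class] + [c for c in class_order if c != task.positive_class]
        pos_col = class_order.index(task.positive_class)
        neg_col = 1 - pos_col
        margin = scores[:, pos_col] - scores[:, neg_col]
        report = compute_metrics(
            _confusion_from_labels(truth, pred, order),
            scores=margin, truth=(truth == task.positive_class),
            class_names=order, task=task.name,
            n_train=len(train_df), split_seed=task.split_seed,
        )
    else:
        report = compute_metrics(
            _confusion_from_labels(truth, pred, class_order),
            class_names=class_order, task=task.name,
            n_train=len(train_df), split_seed=task.split_seed,
        )
    report.wall_time_s = {k: round(v, 4) for k, v in timings.items()}
    for stage, secs in report.wall_time_s.items():
        log.info("task %s: %s = %.3f s", task.name, stage, secs)

    if model_path is not None:
        EnsembleModel(extractor=params, bls=bls, preprocess=preprocess_cfg,
                      task=task.name).save(model_path)
    return report


def sweep(manifest, task: TaskSpec, grid: SweepGrid,
          extractor_cfg: ExtractorConfig | None = None,
          bls_cfg: BLSConfig | None = None,
          preprocess_cfg: PreprocessConfig | None = None):
    """Hyperparameter-stability sweep.

    Every grid point is run once per seed in ``grid.seeds`` (the seed
    drives both the split and the BLS random weights).  Extracted features
    are cached across all grid points, so the frozen extractor runs once
    per volume.  Returns ``(results, summary)``: a long-format DataFrame
    with one row per run, and mean +/- sd accuracy per grid point.
    """
    extractor_cfg = extractor_cfg or ExtractorConfig()
    base_bls = bls_cfg or BLSConfig()
    cache = FeatureCache()
    rows = []
    from dataclasses import replace as _replace

    for nf in grid.feature_node_values:
        for ne in grid.enh_node_values:
            for sp in grid.sparsity_values:
                for seed in grid.seeds:
                    cfg = _replace(
                        base_bls, n_feature_nodes=int(nf),
                        n_feature_groups=_largest_divisor(int(nf), base_bls.n_feature_groups),
                        n_enh_nodes=int(ne),
                        n_enh_groups=_largest_divisor(int(ne), base_bls.n_enh_groups),
                        sparsity=float(sp), seed=int(seed),
                    )
                    t = TaskSpec(name=task.name, split_ratio=task.split_ratio,
                                 split_seed=int(seed), split_level=task.split_level)
                    rep = run_task(manifest, t, extractor_cfg, cfg, preprocess_cfg, cache)
                    rows.append({
                        "n_feature_nodes": int(nf), "n_enh_nodes": int(ne),
                        "sparsity": float(sp), "seed": int(seed),
                        "accuracy": rep.accuracy, "sensitivity": rep.sensitivity,
                        "f1": rep.f1, "auc": rep.auc,
                    })
    results = pd.DataFrame(rows)
    summary = (
        results.groupby(["n_feature_nodes", "n_enh_nodes", "sparsity"])["accuracy"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return results, summary


def _largest_divisor(n, at_most):
    for g in range(min(at_most, n), 0, -1):
        if n % g == 0:
            return g
    return 1


def export_features(manifest, extractor_cfg: ExtractorConfig | None = None,
                    out_path=None, preprocess_cfg: PreprocessConfig | None = None,
                    cache: FeatureCache | None = None) -> pd.DataFrame:
    """Write per-sample feature vectors (x_d || x_e) with labels to CSV.

    One row per manifest entry; columns ``xd_000..``, ``xe_000..``,
    ``label``, ``subject``, ``path``.  Enables external embedding/plotting
    tools (e.g. t-SNE) without rerunning the extractor.
    """
    extractor_cfg = extractor_cfg or ExtractorConfig()
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    df = read_manifest(manifest)
    params = init_extractor(extractor_cfg.seed, extractor_cfg.init_scheme, extractor_cfg)
    X_d, X_e = _extract_for(df, params, preprocess_cfg, cache)
    cols = {f"xd_{i:03d}": X_d[:, i] for i in range(X_d.shape[1])}
    cols.update({f"xe_{i:03d}": X_e[:, i] for i in range(X_e.shape[1])})
    out = pd.DataFrame(cols)
    out["label"] = df["label"].to_numpy()
    out["subject"] = df["subject"].to_numpy()
    out["path"] = df["path"].to_numpy()
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out
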