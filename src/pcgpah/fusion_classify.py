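"""Feature fusion, selection, boosted-tree classification and voting.

Per-cycle time-domain, frequency-domain and (optionally) 64 CNN deep
features are concatenated into a fusion vector. Selection happens on
the training split only and is replayed verbatim at inference: a
variance filter first drops near-constant columns (variance < 0.05),
then an auxiliary boosted-tree model ranks the survivors by total-gain
importance and the top columns are kept, with the 64-dimensional deep
block exempt from removal so the fused vector keeps its full learned
representation. A three-class gradient-boosted ensemble (XGBoost,
600 trees, depth 7, min child weight 1, L1 = 1, L2 = 3, learning rate
0.01) classifies individual cycles; a record's label is the majority
vote of its cycle labels — heart sounds are quasi-periodic, so cycle
errors behave like independent noise the vote averages out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .audio_io import CLASS_ORDER, AudioRecord
from .deep_features import CnnSpec, DeepFeatureExtractor
from .features_freq import assemble_freq_features
from .features_time import assemble_time_features
from .pncc import PnccConfig, PnccImage, pncc_image
from .segmentation import UnsegmentableRecord, extract_cycles, segment_record

DEEP_PREFIX = "deep_"


@dataclass
class BoostConfig:
    """Gradient-boosting hyperparameters (defaults are the tuned optimum)."""

    n_trees: int = 600
    max_depth: int = 7
    min_leaf_weight: float = 1.0
    l1: float = 1.0
    l2: float = 3.0
    learning_rate: float = 0.01
    seed: int = 0

    def make_model(self, n_classes: int) -> XGBClassifier:
        kwargs = dict(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_child_weight=self.min_leaf_weight,
            reg_alpha=self.l1,
            reg_lambda=self.l2,
            learning_rate=self.learning_rate,
            random_state=self.seed,
            tree_method="hist",
            n_jobs=1,
            verbosity=0,
        )
        if n_classes > 2:
            kwargs["objective"] = "multi:softprob"
        return XGBClassifier(**kwargs)


@dataclass
class SelectionMasks:
    """Frozen training-time selection state, replayed at inference."""

    columns: List[str]  # column order entering selection
    variance_keep: np.ndarray  # bool per column
    importance_keep: np.ndarray  # bool per surviving column
    flagged: bool = False  # True when target_dim exceeded availability

    @property
    def selected_columns(self) -> List[str]:
        survivors = [c for c, k in zip(self.columns, self.variance_keep) if k]
        return [c for c, k in zip(survivors, self.importance_keep) if k]

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.selected_columns]

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "variance_keep": self.variance_keep.tolist(),
            "importance_keep": self.importance_keep.tolist(),
            "flagged": self.flagged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionMasks":
        return cls(
            list(d["columns"]),
            np.asarray(d["variance_keep"], dtype=bool),
            np.asarray(d["importance_keep"], dtype=bool),
            bool(d.get("flagged", False)),
        )


def variance_filter(
    table: pd.DataFrame, threshold: float = 0.05
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Drop columns whose (population) variance is strictly below threshold."""
    if table.shape[1] == 0 or table.shape[0] == 0:
        raise ValueError("empty feature table")
    variances = table.to_numpy(dtype=np.float64).var(axis=0, ddof=0)
    keep = variances >= threshold
    if not keep.any():
        raise ValueError("variance filter removed every feature")
    return table.loc[:, keep], keep


def importance_select(
    table: pd.DataFrame,
    labels: Sequence[str],
    config: Optional[BoostConfig] = None,
    target_dim: int = 212,
) -> Tuple[pd.DataFrame, np.ndarray, bool]:
    """Keep the ``target_dim`` most important columns by boosted-tree gain.

    Deep-feature columns (prefix ``deep_``) are exempt from removal, so
    the retained set is (target_dim - n_deep) ranked time-frequency
    columns plus the intact deep block. Ties and never-used features
    rank by original column order, making the mask deterministic.
    Returns (selected table, keep mask, flagged) where flagged marks a
    target larger than the available column count.
    """
    config = config or BoostConfig()
    cols = list(table.columns)
    if target_dim >= len(cols):
        return table, np.ones(len(cols), dtype=bool), target_dim > len(cols)
    classes = _ordered_classes(labels)
    y = np.array([classes.index(l) for l in labels])
    model = config.make_model(len(classes))
    model.fit(table.to_numpy(dtype=np.float64), y)
    gains = model.get_booster().get_score(importance_type="total_gain")
    scores = np.array([gains.get(f"f{i}", 0.0) for i in range(len(cols))])

    deep = np.array([c.startswith(DEEP_PREFIX) for c in cols])
    n_free = target_dim - int(deep.sum())
    if n_free < 0:
        raise ValueError("target_dim smaller than the exempt deep block")
    free_idx = np.flatnonzero(~deep)
    order = free_idx[np.lexsort((free_idx, -scores[free_idx]))]
    keep = deep.copy()
    keep[order[:n_free]] = True
    return table.loc[:, keep], keep, False


def fit_selection(
    table: pd.DataFrame,
    labels: Sequence[str],
    variance_threshold: float = 0.05,
    target_dim: int = 212,
    config: Optional[BoostConfig] = None,
) -> SelectionMasks:
    """Variance filter + importance ranking, fitted on training data only.

    The deep block (columns prefixed ``deep_``) bypasses the variance
    filter as well as importance removal: the fused vector always
    carries the CNN's full 64-dimensional representation, and an
    absolute variance threshold is meaningless on the compressed scale
    of the network's activations.
    """
    deep = np.array([c.startswith(DEEP_PREFIX) for c in table.columns])
    variances = table.to_numpy(dtype=np.float64).var(axis=0, ddof=0)
    var_keep = (variances >= variance_threshold) | deep
    if not var_keep.any():
        raise ValueError("variance filter removed every feature")
    filtered = table.loc[:, var_keep]
    _, imp_keep, flagged = importance_select(filtered, labels, config, target_dim)
    return SelectionMasks(list(table.columns), var_keep, imp_keep, flagged)


def _ordered_classes(labels: Sequence[str]) -> List[str]:
    present = sorted(
        set(labels),
        key=lambda c: (CLASS_ORDER.index(c) if c in CLASS_ORDER else len(CLASS_ORDER), c),
    )
    return present


def train_classifier(
    table: pd.DataFrame,
    labels: Sequence[str],
    config: Optional[BoostConfig] = None,
) -> Tuple[XGBClassifier, List[str]]:
    """Fit the cycle-level boosted-tree classifier; returns (model, classes)."""
    config = config or BoostConfig()
    classes = _ordered_classes(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    y = np.array([classes.index(l) for l in labels])
    model = config.make_model(len(classes))
    model.fit(table.to_numpy(dtype=np.float64), y)
    return model, classes


def majority_vote(labels: Sequence) -> object:
    """Boyer-Moore single-pass majority candidate.

    Guaranteed to return the majority element when one holds a strict
    majority; otherwise the returned candidate must be verified (see
    :func:`vote_record`).
    """
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    candidate, count = None, 0
    for x in labels:
        if count == 0:
            candidate, count = x, 1
        elif x == candidate:
            count += 1
        else:
            count -= 1
    return candidate


def vote_record(
    labels: Sequence[str], class_order: Sequence[str] = CLASS_ORDER
) -> Tuple[str, Dict[str, int]]:
    """Majority vote with a verification pass.

    The Boyer-Moore candidate is confirmed by counting; without a
    strict majority the highest-count class wins, ties broken by
    ``class_order`` (then lexicographically for unknown labels).
    """
    candidate = majority_vote(labels)
    counts: Dict[str, int] = {}
    for x in labels:
        counts[x] = counts.get(x, 0) + 1
    if counts[candidate] * 2 > len(labels):
        return candidate, counts

    def rank(c: str) -> tuple:
        in_order = c in class_order
        return (
            -counts[c],
            class_order.index(c) if in_order else len(class_order),
            c,
        )

    return min(counts, key=rank), counts


@dataclass
class RecordPrediction:
    record_id: str
    cycle_labels: List[str]
    record_label: Optional[str]  # None: record was unsegmentable
    vote_counts: Dict[str, int]

    @property
    def undetermined(self) -> bool:
        return self.record_label is None


@dataclass
class PipelineModel:
    """Everything needed to featurize and classify a new record."""

    masks: SelectionMasks
    classifier: XGBClassifier
    classes: List[str]
    extractor: Optional[DeepFeatureExtractor] = None
    pncc_config: PnccConfig = field(default_factory=PnccConfig)


def featurize_cycles(
    record: AudioRecord,
    pncc_config: Optional[PnccConfig] = None,
    with_images: bool = False,
    annotations=None,
) -> Tuple[pd.DataFrame, List[PnccImage]]:
    """Segment a record and compute per-cycle fusion-vector rows.

    Cycles that defeat a feature contract (e.g. an S2 too short for
    peak analysis after refinement) are skipped rather than poisoning
    the table. Returns the table (indexed by cycle) and, when
    ``with_images``, the matching PNCC images.
    """
    annotations = annotations or segment_record(record)
    pncc_config = pncc_config or PnccConfig()
    rows, images = [], []
    for k, (cycle, s2, ann) in enumerate(extract_cycles(record, annotations)):
        try:
            tf = assemble_time_features(cycle, s2, record.sample_rate)
            ff = assemble_freq_features(cycle, s2, record.sample_rate)
            if with_images:
                img = pncc_image(
                    cycle, pncc_config, record.sample_rate,
                    cycle_id=f"{record.record_id}#{k}",
                )
        except ValueError:
            continue
        row = {"record_id": record.record_id, "cycle_index": k}
        row.update(tf.as_dict())
        row.update(ff.as_dict())
        rows.append(row)
        if with_images:
            images.append(img)
    return pd.DataFrame(rows), images


def split_records(
    record_ids: Sequence[str],
    labels: Sequence[str],
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> Dict[str, str]:
    """Stratified record-level train/val/test assignment.

    Cycles of one record never straddle splits (that would leak
    held-out information through near-identical neighbouring cycles).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, str] = {}
    by_class: Dict[str, List[str]] = {}
    for rid, lab in zip(record_ids, labels):
        by_class.setdefault(lab, []).append(rid)
    for lab, rids in sorted(by_class.items()):
        rids = sorted(rids)
        perm = rng.permutation(len(rids))
        n = len(rids)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        for pos, idx in enumerate(perm):
            split = (
                "train" if pos < n_train
                else "val" if pos < n_train + n_val
                else "test"
            )
            assignment[rids[idx]] = split
    return assignment


def predict_cycles(
    model: PipelineModel, table: pd.DataFrame, images: Sequence[PnccImage] = ()
) -> List[str]:
    feats = _attach_deep(model, table, images)
    x = model.masks.apply(feats).to_numpy(dtype=np.float64)
    idx = model.classifier.predict(x)
    return [model.classes[int(i)] for i in idx]


def _attach_deep(
    model: PipelineModel, table: pd.DataFrame, images: Sequence[PnccImage]
) -> pd.DataFrame:
    feats = table.drop(columns=["record_id", "cycle_index"], errors="ignore")
    if model.extractor is not None:
        deep = model.extractor.transform(list(images))
        deep_df = pd.DataFrame(
            deep,
            columns=[f"{DEEP_PREFIX}{i:02d}" for i in range(deep.shape[1])],
            index=feats.index,
        )
        feats = pd.concat([feats, deep_df], axis=1)
    return feats


class BoosterPredictor:
    """Minimal stand-in for a fitted classifier around a raw booster.

    Used when re-loading a model bundle: only ``predict`` (class
    indices) is needed by the pipeline.
    """

    def __init__(self, booster, n_classes: int):
        self._booster = booster
        self._n_classes = n_classes

    def predict(self, x: np.ndarray) -> np.ndarray:
        import xgboost

        out = self._booster.predict(xgboost.DMatrix(np.asarray(x)))
        if out.ndim == 2:  # multi:softprob
            return np.argmax(out, axis=1)
        if self._n_classes == 2:  # binary:logistic probabilities
            return (out > 0.5).astype(int)
        return out.astype(int)


def save_model_bundle(model: PipelineModel, out_dir) -> None:
    """Write a model bundle directory: booster, masks, CNN, PNCC config."""
    import dataclasses
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    booster = (
        model.classifier.get_booster()
        if hasattr(model.classifier, "get_booster")
        else model.classifier._booster
    )
    booster.save_model(out / "classifier.json")
    (out / "masks.json").write_text(json.dumps(model.masks.to_dict()))
    (out / "meta.json").write_text(
        json.dumps(
            {
                "classes": model.classes,
                "pncc": dataclasses.asdict(model.pncc_config),
                "has_extractor": model.extractor is not None,
            }
        )
    )
    if model.extractor is not None:
        model.extractor.save(out / "extractor.npz")


def load_model_bundle(in_dir) -> PipelineModel:
    import json
    from pathlib import Path

    import xgboost

    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    booster = xgboost.Booster()
    booster.load_model(str(src / "classifier.json"))
    classifier = BoosterPredictor(booster, len(meta["classes"]))
    masks = SelectionMasks.from_dict(json.loads((src / "masks.json").read_text()))
    extractor = (
        DeepFeatureExtractor.load(src / "extractor.npz")
        if meta.get("has_extractor")
        else None
    )
    return PipelineModel(
        masks, classifier, list(meta["classes"]), extractor,
        PnccConfig(**meta["pncc"]),
    )


def train_pipeline(
    records: Sequence[AudioRecord],
    labels: Sequence[str],
    boost_config: Optional[BoostConfig] = None,
    cnn_spec: Optional[CnnSpec] = None,
    pncc_config: Optional[PnccConfig] = None,
    use_deep: bool = False,
    variance_threshold: float = 0.05,
    target_dim: int = 212,
    split_fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> Tuple[PipelineModel, Dict[str, object]]:
    """Fit the full pipeline on labeled records.

    Records are split by record id (stratified) into train/val/test;
    deep-feature training, selection and the classifier see the train
    split only. Returns the fitted model and an info dict with the
    split assignment, per-split cycle tables and counts of records
    that failed segmentation or feature contracts.

    ``target_dim`` caps the post-selection dimensionality at
    ``min(target_dim, available columns)``; with deep features on, the
    64-column deep block is never removed.
    """
    boost_config = boost_config or BoostConfig(seed=seed)
    pncc_config = pncc_config or PnccConfig()
    assignment = split_records(
        [r.record_id for r in records], labels, split_fractions, seed
    )
    tables, image_lists, kept_labels = [], [], []
    skipped: List[str] = []
    label_of: Dict[str, str] = {}
    for rec, lab in zip(records, labels):
        label_of[rec.record_id] = lab
        try:
            table, images = featurize_cycles(rec, pncc_config, with_images=use_deep)
        except UnsegmentableRecord:
            skipped.append(rec.record_id)
            continue
        if table.empty:
            skipped.append(rec.record_id)
            continue
        tables.append(table)
        image_lists.append(images)
    if not tables:
        raise ValueError("no record could be segmented")
    full = pd.concat(tables, ignore_index=True)
    images_flat: List[PnccImage] = [im for lst in image_lists for im in lst]
    cycle_labels = [label_of[r] for r in full["record_id"]]
    cycle_split = np.array([assignment[r] for r in full["record_id"]])
    train_mask = cycle_split == "train"

    extractor = None
    if use_deep:
        spec = cnn_spec or CnnSpec(
            input_shape=(pncc_config.n_frames_out, pncc_config.n_channels),
            seed=seed,
        )
        extractor = DeepFeatureExtractor(spec)
        extractor.fit(
            [images_flat[i] for i in np.flatnonzero(train_mask)],
            [cycle_labels[i] for i in np.flatnonzero(train_mask)],
        )

    proto = PipelineModel(
        masks=None, classifier=None, classes=[],  # type: ignore[arg-type]
        extractor=extractor, pncc_config=pncc_config,
    )
    feats = _attach_deep(proto, full, images_flat)
    train_feats = feats.loc[train_mask]
    train_labels = [l for l, m in zip(cycle_labels, train_mask) if m]
    masks = fit_selection(
        train_feats, train_labels, variance_threshold, target_dim, boost_config
    )
    classifier, classes = train_classifier(
        masks.apply(train_feats), train_labels, boost_config
    )
    model = PipelineModel(masks, classifier, classes, extractor, pncc_config)

    pred = classifier.predict(
        masks.apply(feats).to_numpy(dtype=np.float64)
    )
    full = full.assign(
        true_label=cycle_labels,
        split=cycle_split,
        predicted_label=[classes[int(i)] for i in pred],
    )
    info = {
        "assignment": assignment,
        "cycle_table": full,
        "skipped_records": skipped,
    }
    return model, info


def evaluate_split(
    cycle_table: pd.DataFrame, split: str = "test",
    class_order: Sequence[str] = CLASS_ORDER,
) -> Dict[str, object]:
    """Cycle- and record-level accuracy and confusion matrix on one split."""
    sub = cycle_table[cycle_table["split"] == split]
    if sub.empty:
        raise ValueError(f"no cycles in split {split!r}")
    cycle_acc = float((sub["true_label"] == sub["predicted_label"]).mean())
    rec_rows = []
    for rid, grp in sub.groupby("record_id"):
        label, _ = vote_record(list(grp["predicted_label"]), class_order)
        rec_rows.append({"record_id": rid, "true": grp["true_label"].iloc[0],
                         "predicted": label})
    recs = pd.DataFrame(rec_rows)
    record_acc = float((recs["true"] == recs["predicted"]).mean())
    present = [c for c in class_order if c in set(recs["true"]) | set(recs["predicted"])]
    confusion = pd.DataFrame(0, index=present, columns=present)
    for _, r in recs.iterrows():
        confusion.loc[r["true"], r["predicted"]] += 1
    return {
        "cycle_accuracy": cycle_acc,
        "record_accuracy": record_acc,
        "confusion": confusion,
        "records": recs,
    }


def predict_record(record: AudioRecord, model: PipelineModel) -> RecordPrediction:
    """Segment, featurize, classify every cycle, and vote.

    Unsegmentable records yield an explicit undetermined prediction
    (``record_label`` None) rather than a silent guess.
    """
    try:
        table, images = featurize_cycles(
            record, model.pncc_config, with_images=model.extractor is not None
        )
    except UnsegmentableRecord:
        return RecordPrediction(record.record_id, [], None, {})
    if table.empty:
        return RecordPrediction(record.record_id, [], None, {})
    cycle_labels = predict_cycles(model, table, images)
    label, counts = vote_record(cycle_labels, model.classes)
    return RecordPrediction(record.record_id, cycle_labels, label, counts)
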