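"""Evaluation regimes, calibration, confusion-matrix metrics and k-fold CV.

Three regimes are implemented for both image domains:

* ``person_specific`` — train/validate/test on one subject's images,
  split 70/15/15 stratified by class (random by default; a chronological
  option avoids the heavy source-beat overlap of stride-1 windows).
* ``generic`` — whole subjects held out: test subjects' images appear
  only in the test set; the remaining subjects' pooled images are split
  85/15 into train/validation.
* ``calibrated_generic`` — the generic split plus a fixed fraction
  (default 20%) of each test subject's images, stratified by class, moved
  into the training pool and removed from the test set.

All rounding is floor with the remainder going to training.  Metrics are
accuracy, sensitivity, specificity and precision computed from the test
confusion counts with "stressed" as the positive class; undefined ratios
(zero denominator) are reported as NaN with a flag, never silently 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .classifier import CNNConfig, build_model, predict, train
from .frequency import to_frequency_image
from .io import Condition, IBISequence, PHYSIO_HIGH, PHYSIO_LOW, filter_physiologic
from .spatial import BinningScheme, fit_bins, make_images

REGIMES = ("person_specific", "generic", "calibrated_generic")

#: WESAD-style held-out test triples (subject 12 is absent from WESAD).
WESAD_TRIPLES = (
    ("S2", "S3", "S4"),
    ("S5", "S6", "S7"),
    ("S8", "S9", "S10"),
    ("S11", "S13", "S14"),
    ("S15", "S16", "S17"),
)


# ---------------------------------------------------------------------------
# dataset container


@dataclass(frozen=True)
class ImageDataset:
    """Classifier-ready image stack with per-image provenance."""

    images: np.ndarray  # (N, k, k) float32; frequency images scaled to [0, 1]
    labels: np.ndarray  # (N,) int8, 1 = stressed
    subjects: np.ndarray  # (N,) str
    starts: np.ndarray  # (N,) int64 window start indices
    domain: str  # "spatial" | "frequency"
    window: int = 28

    def __post_init__(self) -> None:
        n = self.images.shape[0]
        if not (self.labels.size == self.subjects.size == self.starts.size == n):
            raise ValueError("provenance arrays must match the number of images")
        if self.domain not in ("spatial", "frequency"):
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def n_images(self) -> int:
        return int(self.images.shape[0])

    def subject_ids(self) -> list[str]:
        return sorted(set(self.subjects.tolist()), key=lambda s: (len(s), s))


def encode_cohort(
    pairs: Sequence[tuple[IBISequence, IBISequence]],
    domain: str = "spatial",
    method: str = "quantile",
    stride: int = 1,
    window: int = 28,
    filter_range: tuple[float, float] = (PHYSIO_LOW, PHYSIO_HIGH),
    bins: BinningScheme | None = None,
) -> tuple[ImageDataset, BinningScheme]:
    """Filter, bin and window a cohort into one :class:`ImageDataset`.

    One binning scheme is fitted on the pooled filtered durations of every
    sequence (both conditions, all subjects) and applied unchanged to all of
    them, so train and test images of any downstream split share bins; a
    pre-fitted scheme may be passed instead.  Frequency images are scaled
    from [0, 255] to [0, 1] for the classifier.
    """
    filtered = [
        (filter_physiologic(s, *filter_range), filter_physiologic(ns, *filter_range))
        for s, ns in pairs
    ]
    if bins is None:
        pooled = np.concatenate(
            [seq.durations for pair in filtered for seq in pair]
        )
        bins = fit_bins(pooled, k=window, method=method, value_range=filter_range)

    pixel_stacks, labels, subjects, starts = [], [], [], []
    for pair in filtered:
        for seq in pair:
            for img in make_images(seq, bins, window=window, stride=stride):
                if domain == "frequency":
                    pixels = to_frequency_image(img).pixels.astype(np.float32) / 255.0
                else:
                    pixels = img.pixels.astype(np.float32)
                pixel_stacks.append(pixels)
                labels.append(1 if img.condition is Condition.STRESSED else 0)
                subjects.append(img.subject_id)
                starts.append(img.start_index)
    if not pixel_stacks:
        raise ValueError("no windows produced; sequences shorter than the window?")
    dataset = ImageDataset(
        images=np.stack(pixel_stacks),
        labels=np.asarray(labels, dtype=np.int8),
        subjects=np.asarray(subjects),
        starts=np.asarray(starts, dtype=np.int64),
        domain=domain,
        window=window,
    )
    return dataset, bins


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class SplitSpec:
    """Index sets of one experiment split; train/val/test are pairwise disjoint."""

    regime: str
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    calibration: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        sets = [set(self.train.tolist()), set(self.val.tolist()), set(self.test.tolist())]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/val/test must be pairwise disjoint")
        if not set(self.calibration.tolist()) <= sets[0]:
            raise ValueError("calibration indices must sit inside the training set")


def _stratified_take(
    idx: np.ndarray, labels: np.ndarray, fractions: Sequence[float], rng: np.random.Generator
) -> list[np.ndarray]:
    """Split ``idx`` per class into len(fractions)+1 parts.

    Each listed fraction receives ``floor(f * n_class)`` items; the leading
    remainder part (training) absorbs the rest.
    """
    parts: list[list[int]] = [[] for _ in range(len(fractions) + 1)]
    for cls in np.unique(labels[idx]):
        cls_idx = idx[labels[idx] == cls]
        cls_idx = rng.permutation(cls_idx)
        n = cls_idx.size
        cuts = [int(np.floor(f * n)) for f in fractions]
        pos = 0
        for part, take in zip(parts[1:], cuts):
            part.extend(cls_idx[pos : pos + take].tolist())
            pos += take
        parts[0].extend(cls_idx[pos:].tolist())
    return [np.asarray(sorted(p), dtype=np.intp) for p in parts]


def _require_two_classes(dataset: ImageDataset, subjects: Iterable[str]) -> None:
    for s in subjects:
        if np.unique(dataset.labels[dataset.subjects == s]).size < 2:
            raise ValueError(f"subject {s!r} lacks one of the two classes")


def make_split(
    dataset: ImageDataset,
    regime: str,
    *,
    subject: str | None = None,
    test_subjects: Sequence[str] = (),
    val_fraction: float = 0.15,
    test_fraction: float = 0.15,
    generic_val_fraction: float = 0.15,
    calibration_fraction: float = 0.20,
    mode: str = "random",
    exclude_overlap: bool = False,
    seed: int = 0,
) -> SplitSpec:
    """Build a :class:`SplitSpec` for one regime (see module docstring).

    ``mode`` applies to the person-specific regime: ``"random"`` samples
    images stratified by class; ``"chronological"`` splits each condition's
    window stream in time order (early 70% train, then 15% val, 15% test).
    ``exclude_overlap`` additionally drops train/val windows sharing source
    beats with a test window of the same subject.
    """
    rng = np.random.default_rng(seed)
    labels = dataset.labels

    if regime == "person_specific":
        if subject is None:
            raise ValueError("person_specific regime needs a subject")
        _require_two_classes(dataset, [subject])
        idx = np.flatnonzero(dataset.subjects == subject)
        if idx.size < 7:
            raise ValueError(f"subject {subject!r} has too few images to split 70/15/15")
        if mode == "random":
            train_i, val_i, test_i = _stratified_take(
                idx, labels, (val_fraction, test_fraction), rng
            )
        elif mode == "chronological":
            tr, va, te = [], [], []
            for cls in np.unique(labels[idx]):
                cls_idx = idx[labels[idx] == cls]
                cls_idx = cls_idx[np.argsort(dataset.starts[cls_idx], kind="stable")]
                n = cls_idx.size
                n_val = int(np.floor(val_fraction * n))
                n_test = int(np.floor(test_fraction * n))
                n_train = n - n_val - n_test
                tr.extend(cls_idx[:n_train].tolist())
                va.extend(cls_idx[n_train : n_train + n_val].tolist())
                te.extend(cls_idx[n_train + n_val :].tolist())
            train_i = np.asarray(sorted(tr), dtype=np.intp)
            val_i = np.asarray(sorted(va), dtype=np.intp)
            test_i = np.asarray(sorted(te), dtype=np.intp)
        else:
            raise ValueError(f"unknown person-specific split mode {mode!r}")
        if exclude_overlap:
            train_i = _drop_overlapping(dataset, train_i, test_i)
            val_i = _drop_overlapping(dataset, val_i, test_i)
        return SplitSpec("person_specific", train_i, val_i, test_i, seed=seed)

    if regime not in ("generic", "calibrated_generic"):
        raise ValueError(f"unknown regime {regime!r}")
    if not test_subjects:
        raise ValueError("generic regimes need test_subjects")
    test_subjects = list(test_subjects)
    all_subjects = dataset.subject_ids()
    missing = [s for s in test_subjects if s not in all_subjects]
    if missing:
        raise ValueError(f"test subjects not in dataset: {missing}")
    _require_two_classes(dataset, all_subjects)

    in_test = np.isin(dataset.subjects, test_subjects)
    test_i = np.flatnonzero(in_test)
    pool = np.flatnonzero(~in_test)
    if pool.size == 0:
        raise ValueError("no training subjects left")
    train_i, val_i = _stratified_take(pool, labels, (generic_val_fraction,), rng)

    if regime == "generic":
        return SplitSpec("generic", train_i, val_i, test_i, seed=seed)

    # calibrated_generic: per test subject per class, floor(fraction * n)
    # images move from test into training.
    cal: list[int] = []
    for s in test_subjects:
        s_idx = np.flatnonzero(dataset.subjects == s)
        taken = _stratified_take(s_idx, labels, (calibration_fraction,), rng)[1]
        cal.extend(taken.tolist())
    cal_i = np.asarray(sorted(cal), dtype=np.intp)
    test_i = np.asarray(sorted(set(test_i.tolist()) - set(cal)), dtype=np.intp)
    train_i = np.asarray(sorted(set(train_i.tolist()) | set(cal)), dtype=np.intp)
    return SplitSpec("calibrated_generic", train_i, val_i, test_i, calibration=cal_i, seed=seed)


def _source_key(dataset: ImageDataset, i: int) -> tuple[str, int]:
    # start indices count beats within one (subject, condition) sequence,
    # so overlap is only meaningful within that stream
    return (f"{dataset.subjects[i]}|{int(dataset.labels[i])}", int(dataset.starts[i]))


def _drop_overlapping(dataset: ImageDataset, keep: np.ndarray, test: np.ndarray) -> np.ndarray:
    """Remove from ``keep`` windows sharing source beats with a test window."""
    out = []
    w = dataset.window
    test_keys = [_source_key(dataset, int(i)) for i in test]
    for i in keep:
        stream, st = _source_key(dataset, int(i))
        if not any(ts == stream and abs(tst - st) < w for ts, tst in test_keys):
            out.append(int(i))
    return np.asarray(out, dtype=np.intp)


def leakage_report(dataset: ImageDataset, split: SplitSpec) -> dict:
    """Quantify source-beat overlap between the test set and train+val.

    Returns the number of test images whose source window shares at least
    one beat with a train/val image from the same (subject, condition)
    stream, plus exact window collisions, which must be empty for generic
    regimes.
    """
    trval = np.concatenate([split.train, split.val])
    keys_trval = {_source_key(dataset, int(i)) for i in trval}
    exact = sum(1 for i in split.test if _source_key(dataset, int(i)) in keys_trval)
    w = dataset.window
    by_stream: dict[str, list[int]] = {}
    for stream, st in keys_trval:
        by_stream.setdefault(stream, []).append(st)
    by_stream = {s: np.sort(np.asarray(v)) for s, v in by_stream.items()}
    n_overlap = 0
    for i in split.test:
        stream, st = _source_key(dataset, int(i))
        starts = by_stream.get(stream)
        if starts is None:
            continue
        j = np.searchsorted(starts, st - w + 1)
        if j < starts.size and starts[j] < st + w:
            n_overlap += 1
    return {"n_test": int(split.test.size), "n_overlapping_test": n_overlap, "n_exact_shared": exact}


# ---------------------------------------------------------------------------
# metrics (Eqs. of the confusion matrix; positive class = stressed)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, precision; NaN + flag when undefined."""

    def ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    undefined: list[str] = []
    out = {
        "accuracy": ratio(c.tp + c.tn, c.total, "accuracy", undefined),
        "sensitivity": ratio(c.tp, c.fn + c.tp, "sensitivity", undefined),
        "specificity": ratio(c.tn, c.tn + c.fp, "specificity", undefined),
        "precision": ratio(c.tp, c.tp + c.fp, "precision", undefined),
    }
    out["undefined"] = undefined
    return out


def evaluate(labels: np.ndarray, predictions: np.ndarray) -> tuple[ConfusionCounts, dict]:
    """Confusion counts and derived metrics for hard binary predictions."""
    y = np.asarray(labels).ravel().astype(np.int64)
    p = np.asarray(predictions).ravel().astype(np.int64)
    if y.size != p.size:
        raise ValueError(f"labels ({y.size}) and predictions ({p.size}) disagree in length")
    counts = ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )
    return counts, metrics_from_counts(counts)


# ---------------------------------------------------------------------------
# running a regime


@dataclass(frozen=True)
class EvalReport:
    """One experiment's accuracies, confusion counts and derived metrics."""

    regime: str
    domain: str
    train_accuracy: float
    val_accuracy: float
    test_accuracy: float
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    precision: float
    undefined: tuple[str, ...]
    n_train: int
    n_val: int
    n_test: int
    test_subjects: tuple[str, ...]
    seed: int

    def to_row(self) -> dict:
        """Percentages rounded to one decimal, table-style."""

        def pct(x: float) -> float:
            return float(round(100.0 * x, 1))

        return {
            "Regime": self.regime,
            "Domain": self.domain,
            "Train %": pct(self.train_accuracy),
            "Valid %": pct(self.val_accuracy),
            "Test %": pct(self.test_accuracy),
            "Sensitivity %": pct(self.sensitivity),
            "Specificity %": pct(self.specificity),
            "Precision %": pct(self.precision),
        }

    def to_json(self) -> str:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return json.dumps(d, indent=2, default=float)


def _subset(dataset: ImageDataset, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return dataset.images[idx], dataset.labels[idx].astype(np.float32)


def run_regime(
    dataset: ImageDataset,
    regime: str,
    config: CNNConfig,
    *,
    split: SplitSpec | None = None,
    return_model: bool = False,
    **split_kwargs,
):
    """Split, train the CNN and evaluate the held-out test set.

    Returns an :class:`EvalReport` (and the trained model when
    ``return_model``).  Any :func:`make_split` keyword is accepted; a
    pre-built split may be passed instead.
    """
    if split is None:
        split = make_split(dataset, regime, seed=split_kwargs.pop("seed", config.seed), **split_kwargs)
    x_tr, y_tr = _subset(dataset, split.train)
    x_va, y_va = _subset(dataset, split.val)
    x_te, y_te = _subset(dataset, split.test)

    model = build_model(config)
    trained = train(model, (x_tr, y_tr), (x_va, y_va) if y_va.size else None, config)

    _, pred_tr = predict(trained, x_tr)
    train_acc = float(np.mean(pred_tr == y_tr))
    if y_va.size:
        _, pred_va = predict(trained, x_va)
        val_acc = float(np.mean(pred_va == y_va))
    else:
        val_acc = float("nan")
    _, pred_te = predict(trained, x_te)
    counts, metrics = evaluate(y_te, pred_te)

    report = EvalReport(
        regime=regime,
        domain=dataset.domain,
        train_accuracy=train_acc,
        val_accuracy=val_acc,
        test_accuracy=metrics["accuracy"],
        counts=counts,
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        precision=metrics["precision"],
        undefined=tuple(metrics["undefined"]),
        n_train=int(split.train.size),
        n_val=int(split.val.size),
        n_test=int(split.test.size),
        test_subjects=tuple(sorted(set(dataset.subjects[split.test].tolist()))),
        seed=split.seed,
    )
    return (report, trained) if return_model else report


def default_test_triples(subject_ids: Sequence[str]) -> list[tuple[str, ...]]:
    """Held-out subject triples: the WESAD groups when IDs match, else contiguous."""
    ids = sorted(set(subject_ids), key=lambda s: (len(s), s))
    if set(ids) == {s for t in WESAD_TRIPLES for s in t}:
        return [t for t in WESAD_TRIPLES]
    return [tuple(ids[i : i + 3]) for i in range(0, len(ids) - len(ids) % 3, 3)]


def kfold_cv(
    images: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig,
    k: int = 5,
    classifier_fn=None,
) -> dict:
    """Stratified k-fold cross-validation on a pooled image set.

    Each fold serves once as the validation set; reports per-fold accuracy,
    the mean +/- sd, and the pooled accuracy over all out-of-fold
    predictions.  Requires both classes in every fold.  ``classifier_fn``
    (train_images, train_labels, val_images) -> predicted labels defaults to
    training the CNN; injectable so the fold mechanics can be exercised with
    a deterministic classifier.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels).ravel().astype(np.int64)
    if min(np.bincount(y)) < k:
        raise ValueError("too few images of one class to fill every fold")

    if classifier_fn is None:

        def classifier_fn(x_tr, y_tr, x_va):
            trained = train(build_model(config), (x_tr, y_tr.astype(np.float32)), None, config)
            return predict(trained, x_va)[1]

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed & 0x7FFFFFFF)
    accs, fold_sizes = [], []
    oof_correct = 0
    for train_idx, val_idx in skf.split(images, y):
        pred = np.asarray(classifier_fn(images[train_idx], y[train_idx], images[val_idx]))
        correct = int(np.sum(pred.ravel() == y[val_idx]))
        accs.append(correct / val_idx.size)
        fold_sizes.append(int(val_idx.size))
        oof_correct += correct
    return {
        "fold_accuracies": accs,
        "fold_sizes": fold_sizes,
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)),
        "pooled_accuracy": oof_correct / y.size,
        "k": k,
    }
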