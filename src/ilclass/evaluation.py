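"""Per-class precision/recall/F1, confusion matrices and the repeated-split
experiment harness.

The headline protocol: repeat ten times — draw a fresh stratified 67/33
split, optionally synthesize an augmentation corpus from the training
partition only, fit the per-bin normalization bounds on the real
training spectra, normalize everything through those bounds, fit each
model family, and score on the untouched all-real test partition.
Per-class precision, recall and F1 are reported as mean ± SD (sample
standard deviation) over the repeats.

Zero-denominator precision or recall is reported as NaN ("undefined")
rather than silently as 0, and aggregation is NaN-aware, so absent
classes cannot bias the averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_dataset import CLASS_LABELS, SpectralDataset, SplitPlan, stratified_split
from .preprocess import LogMinMaxNormalizer
from .synthesis import DrawRecord, SpectrumSynthesizer, SynthesisConfig
from .classifiers import make_classifier


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted, order (BZ, PD, HR)."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise EvaluationError(f"expected {k}x{k} counts, got {counts.shape}")
        if np.any(counts < 0):
            raise EvaluationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, label: str) -> int:
        i = self.class_order.index(label)
        return int(self.counts[i, i])

    def fp(self, label: str) -> int:
        i = self.class_order.index(label)
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, label: str) -> int:
        i = self.class_order.index(label)
        return int(self.counts[i, :].sum() - self.counts[i, i])


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError(
            f"length mismatch: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted"
        )
    if len(true_labels) == 0:
        raise EvaluationError("cannot tabulate an empty prediction set")
    index = {c: i for i, c in enumerate(CLASS_LABELS)}
    counts = np.zeros((len(CLASS_LABELS), len(CLASS_LABELS)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise EvaluationError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts)


def metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean.

    Undefined ratios (zero denominator) are NaN, never a silent zero.
    """
    out: dict[str, dict[str, float]] = {}
    for c in cm.class_order:
        tp, fp, fn = cm.tp(c), cm.fp(c), cm.fn(c)
        precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
        recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        if np.isnan(precision) or np.isnan(recall):
            f1 = float("nan")
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        out[c] = {"precision": precision, "recall": recall, "f1": f1}
    return out


def macro_f1(per_class: Mapping[str, Mapping[str, float]]) -> float:
    """Unweighted mean of the defined per-class F1 values."""
    vals = [m["f1"] for m in per_class.values() if not np.isnan(m["f1"])]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


@dataclass
class ExperimentReport:
    """Per-repeat confusion matrices and metrics with mean ± SD aggregates."""

    per_repeat_metrics: list[dict[str, dict[str, float]]]
    per_repeat_confusion: list[ConfusionMatrix]
    config: dict = field(default_factory=dict)
    incomplete_repeats: list[int] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat_metrics)

    def aggregate(self) -> dict[str, dict[str, dict[str, float]]]:
        """mean and sample SD (ddof=1, NaN-aware) per class and metric."""
        out: dict[str, dict[str, dict[str, float]]] = {}
        for c in CLASS_LABELS:
            out[c] = {}
            for m in ("precision", "recall", "f1"):
                vals = np.array(
                    [rep[c][m] for rep in self.per_repeat_metrics], dtype=float
                )
                defined = vals[~np.isnan(vals)]
                if len(defined) == 0:
                    mean, sd = float("nan"), float("nan")
                else:
                    mean = float(np.mean(defined))
                    sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
                out[c][m] = {"mean": mean, "sd": sd, "n_defined": int(len(defined))}
        return out

    def mean_macro_f1(self) -> float:
        return float(np.mean([macro_f1(rep) for rep in self.per_repeat_metrics]))

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "n_repeats": self.n_repeats,
            "incomplete_repeats": self.incomplete_repeats,
            "per_repeat": [
                {
                    "metrics": rep,
                    "confusion": cm.counts.tolist(),
                }
                for rep, cm in zip(self.per_repeat_metrics, self.per_repeat_confusion)
            ],
            "aggregate": self.aggregate(),
            "mean_macro_f1": self.mean_macro_f1(),
        }


def run_repeat(
    dataset: SpectralDataset,
    model_specs: Mapping[str, dict],
    plan: SplitPlan,
    repeat_index: int,
    augmentation: SynthesisConfig | None = None,
    floor: float = 1.0,
) -> tuple[dict[str, dict[str, dict[str, float]]], dict[str, ConfusionMatrix], list[DrawRecord]]:
    """One pass of the workflow: split, synthesize, normalize, fit, score."""
    train, test = stratified_split(dataset, plan, repeat_index)
    records: list[DrawRecord] = []
    synthetic = None
    if augmentation is not None:
        aug_cfg = SynthesisConfig(
            weight_low=augmentation.weight_low,
            weight_high=augmentation.weight_high,
            n_total=augmentation.n_total,
            class_allocation=augmentation.class_allocation,
            negativity_policy=augmentation.negativity_policy,
            max_redraws=augmentation.max_redraws,
            seed=augmentation.seed + repeat_index,
        )
        synthetic, records = SpectrumSynthesizer(aug_cfg).fit(train).sample()
        train_ids = set(str(s) for s in train.sample_ids)
        for rec in records:
            leaked = set(rec.member_ids) - train_ids
            if leaked:
                raise EvaluationError(f"synthesis leaked non-training ids {leaked}")
    if np.any(test.synthetic):
        raise EvaluationError("test partition contains synthetic spectra")

    bounds = LogMinMaxNormalizer(floor=floor).fit_dataset(train)
    train_norm = bounds.transform_dataset(train)
    test_norm = bounds.transform_dataset(test)
    if synthetic is not None:
        syn_norm = bounds.transform_dataset(synthetic)
        fit_set = SpectralDataset.concat([train_norm, syn_norm])
    else:
        fit_set = train_norm

    per_model_metrics: dict[str, dict[str, dict[str, float]]] = {}
    per_model_cm: dict[str, ConfusionMatrix] = {}
    for name, spec_kwargs in model_specs.items():
        kwargs = dict(spec_kwargs)
        seed = kwargs.pop("seed", plan.seed + repeat_index)
        model = make_classifier(name, seed=seed, **kwargs)
        model.fit(fit_set.values, fit_set.labels)
        pred = model.predict(test_norm.values)
        cm = confusion(test_norm.labels, pred)
        per_model_cm[name] = cm
        per_model_metrics[name] = metrics(cm)
    return per_model_metrics, per_model_cm, records


def run_experiment(
    dataset: SpectralDataset,
    model_specs: Mapping[str, dict],
    plan: SplitPlan,
    augmentation: SynthesisConfig | None = None,
    floor: float = 1.0,
) -> dict[str, ExperimentReport]:
    """The full repeated-split protocol; returns one report per model family.

    Test partitions are all-real by construction: augmentation only ever
    draws from the training side of each split.
    """
    if dataset.normalized:
        raise EvaluationError("run_experiment expects raw spectra")
    reports = {
        name: ExperimentReport(
            per_repeat_metrics=[],
            per_repeat_confusion=[],
            config={
                "model": name,
                "spec": {k: str(v) for k, v in spec.items()},
                "train_fraction": plan.train_fraction,
                "n_repeats": plan.n_repeats,
                "seed": plan.seed,
                "augmented": augmentation is not None,
                "n_synthetic": augmentation.n_total if augmentation else 0,
                "floor": floor,
            },
        )
        for name, spec in model_specs.items()
    }
    for r in range(plan.n_repeats):
        try:
            per_model_metrics, per_model_cm, _ = run_repeat(
                dataset, model_specs, plan, r, augmentation, floor
            )
        except EvaluationError:
            raise
        except Exception as exc:  # stage failure: mark the repeat, keep going
            for rep in reports.values():
                rep.incomplete_repeats.append(r)
                rep.config.setdefault("errors", []).append(f"repeat {r}: {exc}")
            continue
        for name in model_specs:
            reports[name].per_repeat_metrics.append(per_model_metrics[name])
            reports[name].per_repeat_confusion.append(per_model_cm[name])
    return reports


def evaluate_external(
    model,
    bounds: LogMinMaxNormalizer,
    external: SpectralDataset,
) -> tuple[dict[str, dict[str, float]], ConfusionMatrix]:
    """Score a later, independently collected batch with stored bounds.

    Mirrors the transfer path for a validation set that arrives after
    model development: the external raw spectra are normalized with the
    bounds fitted on the original training data — never refitted — and
    scored as-is.  Classes absent from the batch come back with NaN
    recall.
    """
    if external.normalized:
        raise EvaluationError("external data must be raw; bounds are applied here")
    ext_norm = bounds.transform_dataset(external)
    pred = model.predict(ext_norm.values)
    cm = confusion(ext_norm.labels, pred)
    return metrics(cm), cm
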