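"""Reading, writing and splitting of chromatograms and spectrum matrices.

Chromatograms are two-column (time, intensity) CSV tables; digitized
spectra travel as wide CSV matrices with one row per sample and one
column per retention-time bin.  Splitting is stratified per class so
that repeated random 67/33 partitions preserve the class balance of
the full pool.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The closed set of class labels: gasoline (BZ), petroleum distillates
#: (PD) and the heterogeneous rest class (HR), in fixed reporting order.
CLASS_LABELS: tuple[str, ...] = ("BZ", "PD", "HR")


class DatasetError(ValueError):
    """Raised for malformed chromatogram or matrix inputs."""


class SplitError(ValueError):
    """Raised when a dataset cannot be stratified-split as requested."""


def validate_label(label: str) -> str:
    if label not in CLASS_LABELS:
        raise DatasetError(
            f"unknown class label {label!r}; allowed labels are {CLASS_LABELS}"
        )
    return label


@dataclass(frozen=True)
class Chromatogram:
    """A raw detector trace: intensity versus retention time (seconds)."""

    sample_id: str
    times: np.ndarray
    intensities: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or intensities.ndim != 1:
            raise DatasetError("times and intensities must be 1-D")
        if len(times) != len(intensities):
            raise DatasetError(
                f"length mismatch: {len(times)} times vs {len(intensities)} intensities"
            )
        if len(times) and np.any(np.diff(times) <= 0):
            raise DatasetError("acquisition times must be strictly increasing")
        if np.any(intensities < 0):
            raise DatasetError("intensities must be non-negative")
        if self.label is not None:
            validate_label(self.label)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SpectralDataset:
    """A stack of equal-length binned spectra with labels and provenance flags.

    ``values`` is an ``(n_samples, n_bins)`` float array; ``synthetic``
    marks rows produced by the draw-and-combine generator rather than
    measured (or simulated) chromatograms; ``normalized`` records whether
    the log min-max transform has been applied.
    """

    values: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray
    synthetic: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.sample_ids) == len(self.synthetic) == n):
            raise DatasetError("labels, sample_ids and synthetic flags must match values")
        for lab in self.labels:
            validate_label(lab)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASS_LABELS}

    def subset(self, index: Sequence[int] | np.ndarray) -> "SpectralDataset":
        index = np.asarray(index)
        if index.size == 0:
            index = index.astype(int)
        return SpectralDataset(
            values=self.values[index],
            labels=self.labels[index],
            sample_ids=self.sample_ids[index],
            synthetic=self.synthetic[index],
            normalized=self.normalized,
        )

    def restrict_to_class(self, label: str) -> "SpectralDataset":
        validate_label(label)
        return self.subset(np.flatnonzero(self.labels == label))

    @classmethod
    def concat(cls, parts: Iterable["SpectralDataset"]) -> "SpectralDataset":
        parts = list(parts)
        if not parts:
            raise DatasetError("cannot concatenate zero datasets")
        states = {p.normalized for p in parts}
        if len(states) > 1:
            raise DatasetError("cannot mix normalized and un-normalized datasets")
        widths = {p.n_bins for p in parts}
        if len(widths) > 1:
            raise DatasetError(f"inconsistent bin counts: {sorted(widths)}")
        return cls(
            values=np.vstack([p.values for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            sample_ids=np.concatenate([p.sample_ids for p in parts]),
            synthetic=np.concatenate([p.synthetic for p in parts]),
            normalized=parts[0].normalized,
        )


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified train/test split configuration.

    ``train_fraction`` defaults to 0.67 and per-class train counts are
    rounded half away from zero, which maps a (81, 53, 47) pool onto
    train counts (54, 36, 31). Repeat streams are derived from
    ``seed + repeat_index`` so each repetition is reproducible in
    isolation.
    """

    train_fraction: float = 0.67
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise SplitError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise SplitError("n_repeats must be >= 1")


def round_half_away_from_zero(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def train_counts_per_class(
    counts: dict[str, int], train_fraction: float
) -> dict[str, int]:
    """Per-class training-set sizes under the stated rounding rule."""
    return {c: round_half_away_from_zero(n * train_fraction) for c, n in counts.items()}


def stratified_split(
    dataset: SpectralDataset, plan: SplitPlan, repeat_index: int = 0
) -> tuple[SpectralDataset, SpectralDataset]:
    """Partition ``dataset`` into disjoint train/test subsets, per class.

    Deterministic for a fixed ``(plan.seed, repeat_index)`` pair; every
    class must contribute at least two samples so both partitions are
    exercised.
    """
    counts = dataset.class_counts()
    present = {c: n for c, n in counts.items() if n > 0}
    if not present:
        raise SplitError("empty dataset")
    for c, n in present.items():
        if n < 2:
            raise SplitError(f"class {c} has {n} sample(s); need at least 2 to split")
    rng = np.random.default_rng(plan.seed + repeat_index)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in CLASS_LABELS:
        members = np.flatnonzero(dataset.labels == c)
        if len(members) == 0:
            continue
        n_train = round_half_away_from_zero(len(members) * plan.train_fraction)
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(members)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = dataset.subset(np.sort(np.concatenate(train_idx)))
    test = dataset.subset(np.sort(np.concatenate(test_idx)))
    return train, test


# ---------------------------------------------------------------------------
# Chromatogram CSV I/O
# ---------------------------------------------------------------------------

def read_chromatogram(
    path: str | Path, sample_id: str | None = None, label: str | None = None
) -> Chromatogram:
    """Parse a two-column (time_s, intensity) CSV into a Chromatogram.

    A single header row is tolerated; rows are sorted by time and
    duplicate time stamps are rejected.  Errors name the offending line.
    """
    path = Path(path)
    times: list[float] = []
    intensities: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(",")]
            if len(cells) != 2:
                raise DatasetError(
                    f"{path}:{lineno}: expected 2 columns, found {len(cells)}"
                )
            try:
                t, v = float(cells[0]), float(cells[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise DatasetError(
                    f"{path}:{lineno}: non-numeric cell in row {cells!r}"
                ) from None
            if v < 0:
                raise DatasetError(f"{path}:{lineno}: negative intensity {v}")
            times.append(t)
            intensities.append(v)
    if not times:
        raise DatasetError(f"{path}: no data rows")
    order = np.argsort(times, kind="stable")
    t_arr = np.asarray(times)[order]
    v_arr = np.asarray(intensities)[order]
    if np.any(np.diff(t_arr) <= 0):
        dup = int(np.flatnonzero(np.diff(t_arr) <= 0)[0])
        raise DatasetError(
            f"{path}: duplicate acquisition time {t_arr[dup]} after sorting"
        )
    return Chromatogram(
        sample_id=sample_id or path.stem, times=t_arr, intensities=v_arr, label=label
    )


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": chrom.times, "intensity": chrom.intensities})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spectrum-matrix CSV I/O
# ---------------------------------------------------------------------------

def _bin_columns(n_bins: int) -> list[str]:
    return [f"bin_{i + 1:04d}" for i in range(n_bins)]


def write_matrix(dataset: SpectralDataset, path: str | Path) -> None:
    """Write the wide CSV layout: sample_id, label, synthetic, bin_0001.."""
    df = pd.DataFrame(dataset.values, columns=_bin_columns(dataset.n_bins))
    df.insert(0, "synthetic", dataset.synthetic)
    df.insert(0, "label", dataset.labels)
    df.insert(0, "sample_id", dataset.sample_ids)
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_matrix(path: str | Path, normalized: bool = False) -> SpectralDataset:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: empty matrix file") from None
    if df.empty:
        raise DatasetError(f"{path}: matrix has no sample rows")
    required = {"sample_id", "label", "synthetic"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing columns {sorted(missing)}")
    bin_cols = [c for c in df.columns if c.startswith("bin_")]
    if not bin_cols:
        raise DatasetError(f"{path}: no bin_#### columns")
    values = df[bin_cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise DatasetError(f"{path}: non-finite or missing bin values")
    return SpectralDataset(
        values=values,
        labels=df["label"].to_numpy(dtype=object),
        sample_ids=df["sample_id"].astype(str).to_numpy(dtype=object),
        synthetic=df["synthetic"].to_numpy(dtype=bool),
        normalized=normalized,
    )


def write_manifest(dataset: SpectralDataset, path: str | Path, **provenance) -> None:
    """One JSON object describing a dataset: ids, labels, provenance."""
    payload = {
        "n_samples": len(dataset),
        "n_bins": dataset.n_bins,
        "normalized": dataset.normalized,
        "class_counts": dataset.class_counts(),
        "sample_ids": [str(s) for s in dataset.sample_ids],
        "labels": [str(l) for l in dataset.labels],
        "synthetic": [bool(s) for s in dataset.synthetic],
        "provenance": provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
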