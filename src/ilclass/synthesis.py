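"""Draw-and-combine synthesis of class-conditional spectra.

The generator rests on the closure hypothesis that a linear combination
of same-class chromatograms is itself a plausible member of that class
("gasoline + gasoline = gasoline").  For each synthetic spectrum it

1. draws ``k`` uniformly from ``{1..N}`` where ``N`` is the class's
   training-set size,
2. draws ``k`` distinct training spectra (rows of a ``k x n_bins``
   matrix ``X``) uniformly without replacement,
3. draws i.i.d. weights ``W`` uniformly from ``[-4, 4]``, and
4. emits ``W @ X``.

Negative weights can produce negative intensities, which the log
normalization downstream cannot represent; the default policy clamps
them to zero (a redraw policy is available).  All-zero results are
redrawn.  For ``N`` training spectra the number of distinct (k,
member-set) choices is ``2**N - 1``, which is astronomically large for
realistic class sizes.

Synthesis operates on raw (un-normalized) spectra and must only ever see
the training partition; every emitted spectrum carries a DrawRecord so
that leakage can be audited after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from sklearn.base import BaseEstimator

from .io_dataset import CLASS_LABELS, SpectralDataset, validate_label


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters of the draw-and-combine corpus generator.

    Defaults follow the reference workflow: weights uniform on [-4, 4]
    and a 1e5-spectrum corpus.  The class allocation of the corpus is
    configurable and defaults to equal thirds.
    """

    weight_low: float = -4.0
    weight_high: float = 4.0
    n_total: int = 100_000
    class_allocation: dict[str, int] | None = None
    negativity_policy: str = "clamp_zero"
    min_mass_retention: float = 0.5
    max_redraws: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.weight_low < self.weight_high:
            raise SynthesisError("weight_low must be < weight_high")
        if self.n_total < 1:
            raise SynthesisError("n_total must be positive")
        if self.negativity_policy not in ("clamp_zero", "redraw"):
            raise SynthesisError(
                f"unknown negativity_policy {self.negativity_policy!r}"
            )
        if self.class_allocation is not None:
            for c, n in self.class_allocation.items():
                validate_label(c)
                if n < 0:
                    raise SynthesisError(f"negative allocation for class {c}")
            if sum(self.class_allocation.values()) != self.n_total:
                raise SynthesisError("class_allocation must sum to n_total")

    def resolved_allocation(self) -> dict[str, int]:
        if self.class_allocation is not None:
            return dict(self.class_allocation)
        base, rem = divmod(self.n_total, len(CLASS_LABELS))
        return {
            c: base + (1 if i < rem else 0) for i, c in enumerate(CLASS_LABELS)
        }


@dataclass(frozen=True)
class DrawRecord:
    """Provenance of one synthetic spectrum: which rows, which weights."""

    label: str
    member_ids: tuple[str, ...]
    weights: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.member_ids)


def combination_space_size(n: int) -> int:
    """Number of distinct (k, member-set) draws from n spectra: 2^n - 1."""
    if n < 1:
        raise SynthesisError("need at least one spectrum")
    return 2**n - 1


def draw_and_combine(
    class_values: np.ndarray,
    class_ids: np.ndarray,
    label: str,
    cfg: SynthesisConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, DrawRecord]:
    """Emit one synthetic spectrum for a single class.

    ``class_values`` is the (N, n_bins) matrix of that class's raw
    training spectra.  Returns the combined vector (after the negativity
    policy) and its DrawRecord.
    """
    n = class_values.shape[0]
    if n == 0:
        raise SynthesisError(f"class {label} has no training spectra")
    for _ in range(cfg.max_redraws + 1):
        k = int(rng.integers(1, n + 1))
        members = rng.choice(n, size=k, replace=False)
        weights = rng.uniform(cfg.weight_low, cfg.weight_high, size=k)
        # accumulate member by member so provenance replays bit-exactly
        combined = np.zeros(class_values.shape[1])
        for w, row in zip(weights, class_values[members]):
            combined += w * row
        if cfg.negativity_policy == "redraw" and np.any(combined < 0):
            continue
        clamped = np.maximum(combined, 0.0)
        total = np.abs(combined).sum()
        # a draw that loses most of its mass to clamping — or everything —
        # is a blank/chimeric spectrum, not a plausible class member
        if total == 0 or clamped.sum() < cfg.min_mass_retention * total:
            continue
        combined = clamped
        record = DrawRecord(
            label=label,
            member_ids=tuple(str(s) for s in class_ids[members]),
            weights=tuple(float(w) for w in weights),
        )
        return combined, record
    raise SynthesisError(
        f"redraw budget ({cfg.max_redraws}) exhausted for class {label}"
    )


class SpectrumSynthesizer(BaseEstimator):
    """Draw-and-combine corpus generator over a raw training partition.

    ``fit`` memorizes the per-class training spectra; ``stream`` lazily
    yields (spectrum, DrawRecord) pairs so corpora of 1e5 spectra can be
    produced in bounded memory, and ``sample`` materializes a labeled
    SpectralDataset.
    """

    def __init__(self, config: SynthesisConfig | None = None):
        self.config = config

    def _cfg(self) -> SynthesisConfig:
        return self.config if self.config is not None else SynthesisConfig()

    def fit(self, train: SpectralDataset, y=None):
        if train.normalized:
            raise SynthesisError("synthesis operates on raw (un-normalized) spectra")
        cfg = self._cfg()
        self.class_values_ = {}
        self.class_ids_ = {}
        for c in CLASS_LABELS:
            part = train.restrict_to_class(c)
            if len(part):
                self.class_values_[c] = part.values
                self.class_ids_[c] = part.sample_ids
        allocation = cfg.resolved_allocation()
        for c, n in allocation.items():
            if n > 0 and c not in self.class_values_:
                raise SynthesisError(
                    f"allocation requests {n} spectra for class {c}, "
                    "which is absent from the training partition"
                )
        self.allocation_ = allocation
        self.n_bins_ = train.n_bins
        return self

    def stream(
        self, rng: np.random.Generator | None = None
    ) -> Iterator[tuple[np.ndarray, DrawRecord]]:
        if not hasattr(self, "class_values_"):
            raise SynthesisError("synthesizer is not fitted")
        cfg = self._cfg()
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        for c in CLASS_LABELS:
            for _ in range(self.allocation_.get(c, 0)):
                yield draw_and_combine(
                    self.class_values_[c], self.class_ids_[c], c, cfg, rng
                )

    def sample(
        self, rng: np.random.Generator | None = None
    ) -> tuple[SpectralDataset, list[DrawRecord]]:
        cfg = self._cfg()
        values = np.empty((cfg.n_total, self.n_bins_))
        labels = np.empty(cfg.n_total, dtype=object)
        records: list[DrawRecord] = []
        for i, (vec, rec) in enumerate(self.stream(rng)):
            values[i] = vec
            labels[i] = rec.label
            records.append(rec)
        ids = np.array([f"syn_{i:06d}" for i in range(cfg.n_total)], dtype=object)
        dataset = SpectralDataset(
            values=values,
            labels=labels,
            sample_ids=ids,
            synthetic=np.ones(cfg.n_total, dtype=bool),
        )
        return dataset, records


def generate_corpus(
    train: SpectralDataset, cfg: SynthesisConfig | None = None
) -> tuple[SpectralDataset, list[DrawRecord]]:
    """Materialize a synthetic corpus drawn from the training partition only."""
    synth = SpectrumSynthesizer(cfg).fit(train)
    return synth.sample()


def corpus_qc(
    corpus: SpectralDataset, records: list[DrawRecord] | None = None
) -> dict:
    """Summary statistics for a synthetic corpus.

    Reports per-class counts, the distribution of per-spectrum maxima
    (log10 scale) and — when provenance is available — the fraction of
    bins clamped by the negativity policy, flagging corpora where more
    than half of all bins were clamped.
    """
    if len(corpus) == 0:
        raise SynthesisError("empty corpus")
    maxima = corpus.values.max(axis=1)
    out = {
        "n_spectra": len(corpus),
        "class_counts": corpus.class_counts(),
        "log10_max_intensity": {
            "min": float(np.log10(maxima[maxima > 0].min())) if np.any(maxima > 0) else None,
            "median": float(np.log10(np.median(maxima))) if np.median(maxima) > 0 else None,
            "max": float(np.log10(maxima.max())) if maxima.max() > 0 else None,
        },
    }
    # Zero bins in a combined spectrum are overwhelmingly clamp artifacts:
    # a weighted sum of continuous draws is almost surely nonzero.
    zero_frac = np.mean(corpus.values == 0, axis=1)
    out["clamped_bin_fraction"] = {
        "mean": float(zero_frac.mean()),
        "max": float(zero_frac.max()),
        "per_spectrum_over_50pct": int(np.sum(zero_frac > 0.5)),
    }
    out["flag_heavily_clamped"] = bool(zero_frac.mean() > 0.5)
    if records is not None:
        out["k_distribution"] = {
            "min": min(r.k for r in records),
            "mean": float(np.mean([r.k for r in records])),
            "max": max(r.k for r in records),
        }
    return out
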