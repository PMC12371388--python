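"""Digitization of chromatograms and per-bin log min-max normalization.

A chromatogram is reduced to a fixed-length feature vector by summing
detector intensities inside consecutive half-open retention-time bins
(default: 2924 bins of 0.4 s starting at 1 min).  Because raw detector
counts span several orders of magnitude (typically 1e5-1e7), features
are normalized per bin on a log10 scale: the per-bin training minimum
maps to 0, the training maximum to 1, and out-of-range values seen at
prediction time are clamped into [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io_dataset import Chromatogram, SpectralDataset


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class BinningConfig:
    """Retention-time binning grid.

    Bins are the half-open intervals ``[t_start + i*w, t_start + (i+1)*w)``
    for ``i`` in ``0..n_bins-1``; samples outside the window are discarded.
    """

    bin_width: float = 0.4
    t_start: float = 60.0
    n_bins: int = 2924

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise PreprocessError("bin_width must be positive")
        if self.n_bins < 1:
            raise PreprocessError("n_bins must be >= 1")

    @property
    def t_end(self) -> float:
        return self.t_start + self.n_bins * self.bin_width

    def edges(self) -> np.ndarray:
        return self.t_start + self.bin_width * np.arange(self.n_bins + 1)


@dataclass
class BinnedSpectrum:
    """One digitized spectrum: a length-``n_bins`` intensity vector."""

    values: np.ndarray
    binning: BinningConfig
    normalized: bool = False
    label: str | None = None
    synthetic: bool = False
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.binning.n_bins,):
            raise PreprocessError(
                f"expected {self.binning.n_bins} bins, got shape {self.values.shape}"
            )
        if self.normalized:
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise PreprocessError("normalized spectrum must lie in [0, 1]")
        elif not self.synthetic and np.any(self.values < 0):
            raise PreprocessError("raw spectrum intensities must be non-negative")


def digitize(chrom: Chromatogram, cfg: BinningConfig | None = None) -> BinnedSpectrum:
    """Sum chromatogram intensities into fixed-width retention-time bins.

    Signal inside the window is conserved exactly: the output vector sums
    to the total intensity of the in-window samples.  A chromatogram that
    lies entirely outside the window yields an all-zero spectrum with a
    warning rather than an error.
    """
    cfg = cfg or BinningConfig()
    in_window = (chrom.times >= cfg.t_start) & (chrom.times < cfg.t_end)
    if len(chrom) and not np.any(in_window):
        warnings.warn(
            f"chromatogram {chrom.sample_id!r} lies entirely outside "
            f"[{cfg.t_start}, {cfg.t_end}); emitting an all-zero spectrum",
            stacklevel=2,
        )
    idx = np.floor((chrom.times[in_window] - cfg.t_start) / cfg.bin_width).astype(int)
    idx = np.clip(idx, 0, cfg.n_bins - 1)  # guard FP edge at t_end
    values = np.bincount(idx, weights=chrom.intensities[in_window], minlength=cfg.n_bins)
    return BinnedSpectrum(
        values=values,
        binning=cfg,
        label=chrom.label,
        sample_id=chrom.sample_id,
    )


def digitize_dataset(
    chroms: list[Chromatogram], cfg: BinningConfig | None = None
) -> SpectralDataset:
    cfg = cfg or BinningConfig()
    specs = [digitize(c, cfg) for c in chroms]
    return SpectralDataset(
        values=np.stack([s.values for s in specs]),
        labels=np.array([s.label for s in specs], dtype=object),
        sample_ids=np.array([s.sample_id for s in specs], dtype=object),
        synthetic=np.zeros(len(specs), dtype=bool),
    )


class LogMinMaxNormalizer(TransformerMixin, BaseEstimator):
    """Per-bin log10 min-max scaling with clamping, fitted on training data.

    For each bin the log10 of every training value (floored at a pseudo-count
    to avoid log of zero) is taken and its minimum (``lower_log_``) and
    maximum (``upper_log_``) recorded.  ``transform`` then maps

        v  ->  clip((log10(max(v, floor)) - lower) / (upper - lower), 0, 1)

    so training minima/maxima land exactly on 0/1 and any out-of-range
    value — e.g. from a later test set or an external validation batch —
    is clamped into [0, 1].  Bins whose training values are constant carry
    no discriminative information and map to 0.

    Parameters
    ----------
    floor : float, default 1.0
        Pseudo-count applied before the log.  Negligible against raw
        detector counts of 1e5-1e7 but removes log(0).
    """

    def __init__(self, floor: float = 1.0):
        self.floor = floor

    def fit(self, X, y=None):
        if self.floor <= 0:
            raise PreprocessError("floor must be positive")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise PreprocessError("cannot fit normalization bounds on an empty dataset")
        logs = np.log10(np.maximum(X, self.floor))
        self.lower_log_ = logs.min(axis=0)
        self.upper_log_ = logs.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "lower_log_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise PreprocessError(
                f"expected {self.n_features_in_} bins, got {X.shape[1]}"
            )
        logs = np.log10(np.maximum(X, self.floor))
        span = self.upper_log_ - self.lower_log_
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (logs - self.lower_log_) / span
        out[:, span == 0] = 0.0
        return np.clip(out, 0.0, 1.0)

    # -- dataset-level convenience -------------------------------------

    def fit_dataset(self, dataset: SpectralDataset) -> "LogMinMaxNormalizer":
        if dataset.normalized:
            raise PreprocessError("normalization bounds must be fitted on raw spectra")
        return self.fit(dataset.values)

    def transform_dataset(self, dataset: SpectralDataset) -> SpectralDataset:
        if dataset.normalized:
            raise PreprocessError("dataset is already normalized")
        return SpectralDataset(
            values=self.transform(dataset.values),
            labels=dataset.labels,
            sample_ids=dataset.sample_ids,
            synthetic=dataset.synthetic,
            normalized=True,
        )

    # -- persistence ----------------------------------------------------

    def to_json(self, path: str | Path, binning: BinningConfig | None = None) -> None:
        check_is_fitted(self, "lower_log_")
        payload = {
            "lower_log": self.lower_log_.tolist(),
            "upper_log": self.upper_log_.tolist(),
            "floor": self.floor,
            "log_base": 10,
        }
        if binning is not None:
            payload["binning"] = {
                "bin_width": binning.bin_width,
                "t_start": binning.t_start,
                "n_bins": binning.n_bins,
            }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "LogMinMaxNormalizer":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        norm = cls(floor=payload["floor"])
        norm.lower_log_ = np.asarray(payload["lower_log"], dtype=float)
        norm.upper_log_ = np.asarray(payload["upper_log"], dtype=float)
        norm.n_features_in_ = len(norm.lower_log_)
        return norm


def fit_bounds(train: SpectralDataset, floor: float = 1.0) -> LogMinMaxNormalizer:
    """Fit per-bin log bounds on the (raw) training partition."""
    return LogMinMaxNormalizer(floor=floor).fit_dataset(train)


def normalize_dataset(
    dataset: SpectralDataset, bounds: LogMinMaxNormalizer
) -> SpectralDataset:
    """Apply previously fitted bounds; the transfer path for test/external data."""
    return bounds.transform_dataset(dataset)
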