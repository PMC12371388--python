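"""Seeded simulator of class-conditional GC chromatograms.

Stands in for non-public casework data so the full pipeline can be
exercised end to end.  Each class gets a characteristic peak geometry:

* **PD** (petroleum distillates): a homologous series — 12 evenly spaced
  Gaussian peaks under a smooth unimodal envelope, the classic
  diesel/kerosene alkane ladder.
* **BZ** (gasoline): a dense cluster of early-eluting aromatic peaks plus
  a few late markers, subject to weathering — progressive loss of the
  most volatile (earliest) components as the liquid evaporates.
* **HR** (other flammables, e.g. acetone/ethanol): one to three sharp
  early solvent peaks.

On top of the peak train: a smooth substrate background hump, additive
shot noise, retention-time jitter, and a per-sample intensity scale
drawn log-uniformly over 1e5-1e7 so raw traces span several orders of
magnitude (which is what makes the log normalization necessary).  The
peak signal scales with the per-sample draw; the substrate background is
a matrix property at a fixed absolute level, and noise follows counting
statistics (SD grows with the square root of the signal scale).  As in
instrument software, intensities below a detection threshold (a multiple
of the noise SD) are exported as zero baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_dataset import CLASS_LABELS, Chromatogram
from .preprocess import BinningConfig


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PeakTemplate:
    """One Gaussian peak: center (s), sigma (s), height relative to 1."""

    center: float
    width: float
    relative_height: float

    def __post_init__(self):
        if self.width <= 0:
            raise SimulationError("peak width must be positive")
        if self.relative_height <= 0:
            raise SimulationError("peak height must be positive")


@dataclass(frozen=True)
class ClassProfile:
    """Peak geometry and weathering behavior of one class.

    ``weathering_range`` is the interval of evaporation fractions sampled
    per chromatogram; weathering attenuates peaks in ascending retention
    order (light components evaporate first).  ``peak_subset_range``
    optionally draws a random number of the template peaks per sample
    (used for HR, whose casework members show 1-3 solvent peaks).
    """

    label: str
    peaks: tuple[PeakTemplate, ...]
    weathering_range: tuple[float, float] = (0.0, 0.0)
    peak_subset_range: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.peaks:
            raise SimulationError("a class profile needs at least one peak")
        lo, hi = self.weathering_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise SimulationError("weathering_range must be within [0, 1]")
        if self.peak_subset_range is not None:
            a, b = self.peak_subset_range
            if not (1 <= a <= b <= len(self.peaks)):
                raise SimulationError("invalid peak_subset_range")


def _pd_profile() -> ClassProfile:
    # homologous alkane ladder: 12 evenly spaced peaks, unimodal envelope
    centers = np.linspace(300.0, 1100.0, 12)
    envelope = np.exp(-0.5 * ((centers - 700.0) / 260.0) ** 2)
    peaks = tuple(
        PeakTemplate(center=float(c), width=4.0, relative_height=float(h))
        for c, h in zip(centers, 0.25 + 0.75 * envelope)
    )
    return ClassProfile(label="PD", peaks=peaks, weathering_range=(0.0, 0.5))


def _bz_profile() -> ClassProfile:
    # gasoline: dense early aromatic cluster + 3 late markers, eluting
    # after the light-solvent region
    early = np.linspace(150.0, 400.0, 8)
    heights = (1.0, 0.85, 0.95, 0.7, 0.9, 0.6, 0.75, 0.5)
    peaks = [
        PeakTemplate(center=float(c), width=3.0, relative_height=h)
        for c, h in zip(early, heights)
    ]
    peaks += [
        PeakTemplate(center=700.0, width=4.0, relative_height=0.45),
        PeakTemplate(center=850.0, width=4.0, relative_height=0.35),
        PeakTemplate(center=1000.0, width=4.0, relative_height=0.25),
    ]
    return ClassProfile(label="BZ", peaks=tuple(peaks), weathering_range=(0.0, 0.6))


def _hr_profile() -> ClassProfile:
    # light solvents (acetone/ethanol): 1-3 peaks at the very front of the run
    peaks = (
        PeakTemplate(center=75.0, width=4.0, relative_height=1.0),
        PeakTemplate(center=95.0, width=4.0, relative_height=0.8),
        PeakTemplate(center=115.0, width=4.0, relative_height=0.6),
    )
    return ClassProfile(
        label="HR", peaks=peaks, weathering_range=(0.0, 0.2), peak_subset_range=(1, 3)
    )


def default_profiles() -> dict[str, ClassProfile]:
    return {"PD": _pd_profile(), "BZ": _bz_profile(), "HR": _hr_profile()}


@dataclass(frozen=True)
class SimulatorConfig:
    """Cohort-level simulation settings.

    Defaults reproduce the reference cohort sizes (PD 81, BZ 53, HR 47)
    and an intensity scale spanning 1e5-1e7 (log-uniform).  Noise follows
    counting statistics: SD = ``noise_sd`` * base * sqrt(scale / base)
    where ``base`` is the bottom of the intensity range, so noise grows
    with signal amount but sub-linearly.  ``background_level`` sets the
    substrate hump amplitude relative to ``base`` (matrix pyrolysate,
    independent of how much ignitable liquid a sample carries).
    Intensities below ``detection_threshold_sigma`` noise SDs are zeroed,
    as chromatography software does when exporting traces.  Jitter shifts
    all peak centers of a sample rigidly.
    """

    class_profiles: dict[str, ClassProfile] = field(default_factory=default_profiles)
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"PD": 81, "BZ": 53, "HR": 47}
    )
    intensity_scale_range: tuple[float, float] = (1e5, 1e7)
    background_level: float = 0.02
    noise_sd: float = 0.01
    detection_threshold_sigma: float = 3.0
    jitter_sd: float = 1.0
    time_step: float = 0.1
    binning: BinningConfig = field(default_factory=BinningConfig)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.intensity_scale_range
        if lo <= 0 or hi < lo:
            raise SimulationError("intensity_scale_range must be positive, lo <= hi")
        for c, n in self.n_per_class.items():
            if n < 0:
                raise SimulationError(f"negative n_per_class for {c}")


def _weathering_factors(n_peaks: int, fraction: float) -> np.ndarray:
    """Attenuation per peak, ascending retention order.

    The earliest (most volatile) peak is attenuated by (1-f); later peaks
    by (1-f)**v with volatility v falling linearly to 1/n, so full
    evaporation (f=1) removes every peak and f=0 leaves all untouched.
    """
    if fraction == 0.0:
        return np.ones(n_peaks)
    volatility = 1.0 - np.arange(n_peaks) / n_peaks  # in (0, 1]
    return (1.0 - fraction) ** volatility


def simulate_chromatogram(
    profile: ClassProfile,
    cfg: SimulatorConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> Chromatogram:
    """Draw one chromatogram from a class profile.

    intensity(t) = scale * sum of weathered, jittered Gaussian peaks
    + background hump + shot noise, then thresholded: values below
    ``detection_threshold_sigma`` noise SDs are written out as zero, and
    the result is floored at 0.
    """
    window = cfg.binning
    times = np.arange(window.t_start, window.t_end, cfg.time_step)

    peaks = list(profile.peaks)
    if profile.peak_subset_range is not None:
        lo, hi = profile.peak_subset_range
        n_keep = int(rng.integers(lo, hi + 1))
        keep = np.sort(rng.choice(len(peaks), size=n_keep, replace=False))
        peaks = [peaks[i] for i in keep]

    w_lo, w_hi = profile.weathering_range
    weathering = float(rng.uniform(w_lo, w_hi))
    order = np.argsort([p.center for p in peaks])
    factors_sorted = _weathering_factors(len(peaks), weathering)
    factors = np.empty(len(peaks))
    factors[order] = factors_sorted

    shift = float(rng.normal(0.0, cfg.jitter_sd)) if cfg.jitter_sd > 0 else 0.0
    signal = np.zeros_like(times)
    for peak, f in zip(peaks, factors):
        c = peak.center + shift
        signal += (
            f
            * peak.relative_height
            * np.exp(-0.5 * ((times - c) / peak.width) ** 2)
        )

    log_lo, log_hi = np.log10(cfg.intensity_scale_range[0]), np.log10(
        cfg.intensity_scale_range[1]
    )
    scale = 10.0 ** rng.uniform(log_lo, log_hi)
    base_scale = cfg.intensity_scale_range[0]
    intensities = scale * signal

    if cfg.background_level > 0:
        # substrate pyrolysate hump: broad Gaussian + slow linear rise
        hump_center = float(rng.uniform(0.4, 0.6)) * window.t_end
        hump = np.exp(-0.5 * ((times - hump_center) / (0.2 * window.t_end)) ** 2)
        ramp = (times - window.t_start) / (window.t_end - window.t_start)
        intensities = intensities + cfg.background_level * base_scale * (
            hump + 0.5 * ramp
        )
    sigma = cfg.noise_sd * base_scale * np.sqrt(scale / base_scale)
    if cfg.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, sigma, len(times))
        intensities[intensities < cfg.detection_threshold_sigma * sigma] = 0.0
    intensities = np.maximum(intensities, 0.0)
    return Chromatogram(
        sample_id=sample_id, times=times, intensities=intensities, label=profile.label
    )


def simulate_dataset(cfg: SimulatorConfig | None = None) -> list[Chromatogram]:
    """Draw the full labeled cohort; reproducible from (config, seed).

    Each sample gets its own child seed from the config seed, recorded in
    the sample id, so any single chromatogram can be regenerated alone.
    """
    cfg = cfg or SimulatorConfig()
    if not any(n >= 1 for n in cfg.n_per_class.values()):
        raise SimulationError("need n_per_class >= 1 for at least one class")
    master = np.random.default_rng(cfg.seed)
    chroms: list[Chromatogram] = []
    for label in CLASS_LABELS:
        n = cfg.n_per_class.get(label, 0)
        if n == 0:
            continue
        profile = cfg.class_profiles[label]
        for i in range(n):
            child_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(child_seed)
            chroms.append(
                simulate_chromatogram(
                    profile, cfg, rng, sample_id=f"{label}_{i:03d}_s{child_seed}"
                )
            )
    return chroms
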