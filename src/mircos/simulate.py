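"""Two-class synthetic FT-MIR spectra with realistic acquisition artifacts.

The generator emulates powdered plant material measured by ATR FT-MIR:
both classes share the same absorption bands (Gaussian peaks at the
mid-IR positions of carbohydrate, nucleic-acid, lipid/protein and O-H/N-H
vibrations), and differ only in per-band absorbance through class-specific
amplitude multipliers — the same peak positions, different band intensities.
Each recorded scan is distorted by a multiplicative scatter gain, an
additive linear baseline, and iid Gaussian detector noise; each sample may
be scanned r times (replicate records) with independent noise and a small
replicate-to-replicate jitter.

The clean (distortion-free) class spectra are exposed so tests can use them
as oracles for scatter/baseline-correction steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "PeakSpec",
    "SyntheticConfig",
    "ConfigurationError",
    "default_band_table",
    "generate_spectra",
    "clean_class_spectrum",
    "descending_grid",
]

WILD = "wild"
CULTIVATED = "cultivated"


class ConfigurationError(ValueError):
    """Inconsistent synthetic-data configuration."""


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian absorption band.

    center/width in cm^-1 (width is the Gaussian sigma), base_amplitude in
    absorbance units, and a per-class dimensionless multiplier encoding the
    between-class difference in band intensity.
    """

    center: float
    width: float
    base_amplitude: float
    class_multiplier: dict[str, float]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError(f"peak at {self.center}: width must be > 0")
        if self.base_amplitude < 0:
            raise ConfigurationError(f"peak at {self.center}: amplitude must be >= 0")
        if any(m <= 0 for m in self.class_multiplier.values()):
            raise ConfigurationError(f"peak at {self.center}: multipliers must be > 0")


def default_band_table(
    contrast: float = 1.5, classes: tuple[str, str] = (CULTIVATED, WILD)
) -> list[PeakSpec]:
    """Band table for the two-class authentication problem.

    Peak positions follow the mid-IR assignments of dried plant powder:
    1014 cm^-1 (C-O/C-C stretch, C-O-H bend of carbohydrates), 1220 and
    1240 cm^-1 (phosphodiester / PO2- of nucleic acids and phospholipids),
    a broad composite over 1300-1500 cm^-1 (CH2/CH3 bending of lipids and
    proteins), 1635 cm^-1 (amide I C=O), 2921 cm^-1 (CH2 asymmetric
    stretch, within the 2800-3000 aliphatic C-H region) and 3276 cm^-1
    (O-H / amide N-H stretch).

    Both classes share every position and width (shape-preserving); the
    classes differ only through per-band multipliers. The second class
    (by default ``wild``) is enriched in protein/lipid bands and depleted
    in the carbohydrate band; ``contrast`` sets its strongest multiplier
    (default 1.5 at the amide I band) and the remaining multipliers are
    interpolated toward 1 in fixed proportion, so contrast=1 is an exact
    null effect.
    """
    ref, alt = classes
    # fraction of the (contrast - 1) excess applied at each band; the
    # carbohydrate band moves the opposite way (depletion).
    layout = [
        # (center, sigma, base amplitude, fractional effect)
        (1014.0, 18.0, 1.00, -0.40),
        (1220.0, 12.0, 0.45, 0.30),
        (1240.0, 10.0, 0.40, 0.30),
        (1400.0, 55.0, 0.35, 0.60),  # broad 1300-1500 composite
        (1635.0, 22.0, 0.60, 1.00),
        (2921.0, 16.0, 0.30, 0.60),
        (3276.0, 80.0, 0.50, 0.80),
    ]
    excess = contrast - 1.0
    peaks = []
    for center, width, amp, frac in layout:
        mult = 1.0 + excess * frac
        peaks.append(
            PeakSpec(center, width, amp, {ref: 1.0, alt: max(mult, 1e-6)})
        )
    return peaks


def descending_grid(high: float = 4000.0, low: float = 450.0, step: float = 2.0) -> np.ndarray:
    """Wavenumber grid stored high -> low, matching spectrometer output."""
    high, low, step = float(high), float(low), float(step)
    n = int(round((high - low) / step)) + 1
    return high - step * np.arange(n)


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything that defines one synthetic acquisition campaign.

    Defaults mirror the study conditions the pipeline is built around:
    109 cultivated and 63 wild samples, 3 replicate scans each, a
    4000 -> 450 cm^-1 grid at 2 cm^-1 spacing, detector noise at 1% of the
    maximum peak amplitude, and scatter/baseline distortions large enough
    that SNV/MSC have something to remove.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {CULTIVATED: 109, WILD: 63}
    )
    grid: tuple[float, float, float] = (4000.0, 450.0, 2.0)
    peaks: list[PeakSpec] = field(default_factory=default_band_table)
    noise_sd: float = 0.01
    baseline_offset_range: tuple[float, float] = (-0.05, 0.05)
    baseline_slope_range: tuple[float, float] = (-2e-5, 2e-5)
    scatter_range: tuple[float, float] = (0.8, 1.2)
    replicates: int = 3
    replicate_jitter_sd: float = 0.002
    scatter_model: str = "stratified"  # "stratified" | "iid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_class or any(n < 1 for n in self.n_per_class.values()):
            raise ConfigurationError("n_per_class must give every class a count >= 1")
        if self.noise_sd < 0 or self.replicate_jitter_sd < 0:
            raise ConfigurationError("noise levels must be >= 0")
        lo, hi = self.scatter_range
        if not (0 < lo <= hi):
            raise ConfigurationError("scatter_range must lie in (0, inf)")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.scatter_model not in {"stratified", "iid"}:
            raise ConfigurationError("scatter_model must be 'stratified' or 'iid'")
        high, low, step = self.grid
        if step <= 0 or high <= low:
            raise ConfigurationError("grid must be (high, low, step) with high > low, step > 0")

    @property
    def wavenumbers(self) -> np.ndarray:
        return descending_grid(*self.grid)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.n_per_class))


def clean_class_spectrum(config: SyntheticConfig, class_name: str) -> np.ndarray:
    """Noise-free spectrum of a class: the multiplier-scaled peak sum."""
    w = config.wavenumbers
    high, low, _ = config.grid
    out = np.zeros_like(w)
    for p in config.peaks:
        if not (low <= p.center <= high):
            raise ConfigurationError(
                f"peak center {p.center} outside grid [{low}, {high}]"
            )
        if class_name not in p.class_multiplier:
            raise ConfigurationError(
                f"peak at {p.center} lacks a multiplier for class {class_name!r}"
            )
        amp = p.base_amplitude * p.class_multiplier[class_name]
        out += amp * np.exp(-0.5 * ((w - p.center) / p.width) ** 2)
    return out


def generate_spectra(config: SyntheticConfig) -> SpectraSet:
    """Draw one synthetic acquisition campaign.

    Distortion structure mirrors how ATR replicate scans actually vary:
    the additive baseline (offset + slope) is slow instrument drift, so it
    is drawn once per sample and shared by that sample's replicate scans,
    while the multiplicative scatter gain changes with every repack and is
    drawn per record. Under the default ``scatter_model='stratified'`` a
    sample's r repack gains are jittered stratified draws over the scatter
    range in random order — every repack differs appreciably from the
    others, as manual repacking does — while ``'iid'`` draws them
    independently (occasionally yielding near-identical repacks). Detector
    noise is iid Gaussian per point; replicate jitter adds a small extra
    per-record disturbance. Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    w = config.wavenumbers
    r = config.replicates
    rows, sids, labels, reps = [], [], [], []
    for class_name in config.classes:
        clean = clean_class_spectrum(config, class_name)
        n = config.n_per_class[class_name]
        for i in range(n):
            sid = f"{class_name}-{i + 1:03d}"
            offset = rng.uniform(*config.baseline_offset_range)
            slope = rng.uniform(*config.baseline_slope_range)
            lo, hi = config.scatter_range
            if config.scatter_model == "stratified" and r > 1:
                edges = np.linspace(lo, hi, r + 1)
                gains = rng.uniform(edges[:-1], edges[1:])
                gains = gains[rng.permutation(r)]
            else:
                gains = rng.uniform(lo, hi, size=r)
            for k in range(1, r + 1):
                gain = gains[k - 1]
                noise = rng.normal(0.0, config.noise_sd, size=w.size) if config.noise_sd else 0.0
                jitter = (
                    rng.normal(0.0, config.replicate_jitter_sd, size=w.size)
                    if config.replicate_jitter_sd and r > 1
                    else 0.0
                )
                rows.append(gain * clean + offset + slope * w + noise + jitter)
                sids.append(sid)
                labels.append(class_name)
                reps.append(k)
    return SpectraSet(
        w,
        np.vstack(rows),
        tuple(sids),
        tuple(labels),
        tuple(reps) if r > 1 else None,
    )
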