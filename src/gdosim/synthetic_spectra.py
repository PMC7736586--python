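"""Toy HPGe pulse-height spectra for exercising the detectability logic.

Generates Poisson-sampled spectra consisting of Gaussian photopeaks on a
flat (or exponential) continuum, with detector resolution scaling as
FWHM(E) = FWHM(122 keV) * sqrt(E / 122).  This is a parametric stand-in for
a full transport simulation of the emission spectrum of released target
particles: it carries just enough structure (peak areas, widths, continuum,
counting noise) to demonstrate how the Ta-182 lines at 152.5 and 156.4 keV
interfere with the 154.6 keV line of Gd-146 while the 115-keV twin peaks
remain clean.

Net peak areas are estimated by a simple window-minus-sidebands rule; the
detection limit on a net area follows the standard Currie formulation
L_D = 2.71 + 4.65 * sqrt(B).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

REFERENCE_ENERGY_KEV = 122.0


def fwhm_at(energy_kev: float, fwhm_at_122kev: float = 1.0) -> float:
    """Detector resolution (keV FWHM) at ``energy_kev``."""
    if energy_kev <= 0 or fwhm_at_122kev <= 0:
        raise InvalidInputError("energy and FWHM must be > 0")
    return fwhm_at_122kev * math.sqrt(energy_kev / REFERENCE_ENERGY_KEV)


@dataclass(frozen=True)
class SpectrumConfig:
    """Configuration of the toy spectrum generator.

    ``peak_list`` holds (energy keV, total peak counts) pairs;
    ``continuum_level`` is the mean continuum in counts/channel at the low
    edge (constant for the flat shape, decaying with ``continuum_scale_kev``
    for the exponential shape).
    """

    channel_count: int = 800
    kev_per_channel: float = 0.25
    fwhm_at_122kev: float = 1.0
    continuum_level: float = 10.0
    continuum_shape: str = "flat"        # "flat" | "exponential"
    continuum_scale_kev: float = 150.0
    peak_list: tuple[tuple[float, float], ...] = ()
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_count <= 0:
            raise InvalidConfigError("channel_count must be > 0")
        if self.kev_per_channel <= 0:
            raise InvalidConfigError("kev_per_channel must be > 0")
        if self.fwhm_at_122kev <= 0:
            raise InvalidConfigError("fwhm_at_122kev must be > 0")
        if self.continuum_level < 0:
            raise InvalidConfigError("continuum_level must be >= 0")
        if self.continuum_shape not in ("flat", "exponential"):
            raise InvalidConfigError(f"unknown continuum shape {self.continuum_shape!r}")
        e_max = self.channel_count * self.kev_per_channel
        for energy, counts in self.peak_list:
            if counts < 0:
                raise InvalidConfigError(f"peak counts must be >= 0 at {energy} keV")
            if not 0 < energy < e_max:
                raise InvalidConfigError(
                    f"peak at {energy} keV outside spectrum range (0, {e_max}) keV"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "channel_count": self.channel_count,
                "kev_per_channel": self.kev_per_channel,
                "fwhm_at_122kev": self.fwhm_at_122kev,
                "continuum_level": self.continuum_level,
                "continuum_shape": self.continuum_shape,
                "continuum_scale_kev": self.continuum_scale_kev,
                "peak_list": [list(p) for p in self.peak_list],
                "random_seed": self.random_seed,
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class Spectrum:
    """Channel-energy / integer-count pairs of one acquisition."""

    energies: np.ndarray  # keV, channel centres
    counts: np.ndarray    # integer counts per channel
    config: SpectrumConfig | None = field(default=None, compare=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"energy_keV": self.energies, "counts": self.counts})


def generate_spectrum(config: SpectrumConfig) -> Spectrum:
    """Poisson-sample a spectrum from the configured continuum + peaks.

    Reproducible: a fixed ``random_seed`` yields identical spectra.
    """
    energies = (np.arange(config.channel_count) + 0.5) * config.kev_per_channel
    if config.continuum_shape == "flat":
        expected = np.full(config.channel_count, float(config.continuum_level))
    else:
        expected = config.continuum_level * np.exp(-energies / config.continuum_scale_kev)
    for energy, total_counts in config.peak_list:
        sigma = fwhm_at(energy, config.fwhm_at_122kev) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        pdf = np.exp(-0.5 * ((energies - energy) / sigma) ** 2) / (
            sigma * math.sqrt(2.0 * math.pi)
        )
        expected = expected + total_counts * pdf * config.kev_per_channel
    rng = np.random.default_rng(config.random_seed)
    counts = rng.poisson(expected)
    return Spectrum(energies=energies, counts=counts, config=config)


def _window_slice(spectrum: Spectrum, lo: float, hi: float) -> np.ndarray:
    mask = (spectrum.energies >= lo) & (spectrum.energies < hi)
    if not mask.any():
        raise InvalidInputError(f"window [{lo}, {hi}) keV contains no channels")
    return spectrum.counts[mask]


def net_area(spectrum: Spectrum, line_kev: float, window_kev: float | None = None) -> float:
    """Net counts of a peak: window sum minus the flanking-sideband estimate.

    The window is centred on ``line_kev`` (default width 3 FWHM); the
    background under the peak is taken as the average of two adjacent
    sidebands of the same width.
    """
    cfg = spectrum.config or SpectrumConfig()
    if window_kev is None:
        window_kev = 3.0 * fwhm_at(line_kev, cfg.fwhm_at_122kev)
    if window_kev <= 0:
        raise InvalidInputError("window width must be > 0")
    half = window_kev / 2.0
    gross = float(_window_slice(spectrum, line_kev - half, line_kev + half).sum())
    left = float(_window_slice(spectrum, line_kev - 3 * half, line_kev - half).sum())
    right = float(_window_slice(spectrum, line_kev + half, line_kev + 3 * half).sum())
    return gross - 0.5 * (left + right)


def currie_detection_limit(background_counts: float) -> float:
    """Currie net-count detection limit L_D = 2.71 + 4.65 * sqrt(B)."""
    if background_counts < 0:
        raise InvalidInputError("background counts must be >= 0")
    return 2.71 + 4.65 * math.sqrt(background_counts)


def currie_mda(spectrum: Spectrum, line_kev: float, window_kev: float | None = None) -> float:
    """Detection limit (net counts) for a peak at ``line_kev``.

    The background B in the Currie formula is estimated from the two
    flanking sidebands, scaled to the window width.
    """
    cfg = spectrum.config or SpectrumConfig()
    if window_kev is None:
        window_kev = 3.0 * fwhm_at(line_kev, cfg.fwhm_at_122kev)
    if window_kev <= 0:
        raise InvalidInputError("window width must be > 0")
    half = window_kev / 2.0
    left = float(_window_slice(spectrum, line_kev - 3 * half, line_kev - half).sum())
    right = float(_window_slice(spectrum, line_kev + half, line_kev + 3 * half).sum())
    return currie_detection_limit(0.5 * (left + right))


def interference_report(
    peaks: list[tuple[str, float]],
    *,
    fwhm_at_122kev: float = 1.0,
    resolution_multiple: float = 2.0,
) -> list[dict]:
    """Flag photopeak pairs from different nuclides too close to resolve.

    Two lines conflict when their separation is below
    ``resolution_multiple`` * FWHM at their mean energy.  With the default
    1-keV (at 122 keV) resolution this flags both Ta-182 lines (152.5 and
    156.4 keV) against the 154.6 keV line of Gd-146.
    """
    conflicts = []
    for i, (nuc_a, e_a) in enumerate(peaks):
        for nuc_b, e_b in peaks[i + 1:]:
            if nuc_a == nuc_b:
                continue
            window = resolution_multiple * fwhm_at((e_a + e_b) / 2.0, fwhm_at_122kev)
            if abs(e_a - e_b) < window:
                conflicts.append(
                    {
                        "nuclide_a": nuc_a,
                        "line_a_keV": e_a,
                        "nuclide_b": nuc_b,
                        "line_b_keV": e_b,
                        "separation_keV": abs(e_a - e_b),
                        "resolution_window_keV": window,
                    }
                )
    return conflicts
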