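"""Reduce epoch-level EEG power spectra to hourly NREM slow-wave activity.

The canonical input of the downstream analysis is, per mouse, one SWA value
per hour of the 12-h baseline light period: the delta-band power of each
artifact-free NREM 4-s epoch, averaged within the hour.  Hours with too few
usable epochs are flagged undefined rather than imputed; a profile with any
undefined hour is ineligible for profiling or clustering.

Units: spectra carry power per 0.25-Hz bin; band power is reported per
0.5 Hz (the conventional SWA reporting unit), i.e. the band's mean bin power
rescaled by 0.5 / 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    EPOCH_SECONDS,
    FREQ_HIGH,
    FREQ_LOW,
    FREQ_STEP,
    N_HOURS,
    ClassLabel,
    EpochSpectrumSeries,
    SWAProfile,
)

#: Minimum artifact-free NREM epochs (3 min) for an hourly mean to count.
DEFAULT_MIN_EPOCHS = 45


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, inclusive of both edges, aligned to the 0.25-Hz grid."""

    low: float
    high: float
    name: str = "band"

    def __post_init__(self) -> None:
        if not (FREQ_LOW <= self.low < self.high <= FREQ_HIGH):
            raise ValueError(
                f"band edges must satisfy {FREQ_LOW} <= low < high <= {FREQ_HIGH}"
            )
        for edge in (self.low, self.high):
            if abs(edge / FREQ_STEP - round(edge / FREQ_STEP)) > 1e-9:
                raise ValueError(f"band edge {edge} does not align to the {FREQ_STEP}-Hz grid")

    @classmethod
    def parse(cls, text: str, name: str = "band") -> "BandDefinition":
        """Parse ``"0.75:4.0"`` style band strings."""
        lo, _, hi = text.partition(":")
        return cls(float(lo), float(hi), name)


#: The SWA (delta) band, 0.75-4.0 Hz.
SWA_BAND = BandDefinition(0.75, 4.0, "swa")


@dataclass
class HourlySWAResult:
    """Per-mouse hourly SWA with usable-epoch bookkeeping.

    ``values[h]`` is NaN wherever ``defined[h]`` is False, i.e. when fewer
    than the configured minimum of artifact-free NREM epochs fell in hour h.
    """

    mouse_id: str
    values: np.ndarray   # 12 hourly SWA values, uV^2/0.5 Hz (NaN if undefined)
    counts: np.ndarray   # artifact-free NREM epochs per hour
    defined: np.ndarray  # bool per hour

    def to_profile(self, label: ClassLabel) -> SWAProfile:
        if not bool(self.defined.all()):
            bad = [h + 1 for h in range(N_HOURS) if not self.defined[h]]
            raise ValueError(f"{self.mouse_id}: hours {bad} are undefined; profile incomplete")
        return SWAProfile(self.mouse_id, label, self.values.copy())


def band_power(freqs: np.ndarray, power: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Band-integrated power per 0.5 Hz.

    ``power`` holds per-0.25-Hz-bin values along its last axis (a single
    spectrum or a stack of epochs).  Both band edges are inclusive.  The
    band's bin sum is rescaled to power-per-0.5-Hz units:
    ``sum(bins) * 0.5 / (0.25 * n_bins)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    sel = (freqs >= band.low - 1e-9) & (freqs <= band.high + 1e-9)
    n_bins = int(sel.sum())
    expected = round((band.high - band.low) / FREQ_STEP) + 1
    if n_bins != expected:
        raise ValueError(
            f"spectrum grid does not cover band {band.low}-{band.high} Hz "
            f"({n_bins} bins present, {expected} required)"
        )
    width = FREQ_STEP * n_bins
    return power[..., sel].sum(axis=-1) * 0.5 / width


def extract_swa(
    series: EpochSpectrumSeries,
    band: BandDefinition = SWA_BAND,
    min_epochs: int = DEFAULT_MIN_EPOCHS,
) -> HourlySWAResult:
    """Hourly NREM SWA over the 12-h light period.

    For each hour h (half-open windows [h*3600, (h+1)*3600) s from
    lights-on) the band power of epochs that are NREM and artifact-free is
    averaged with equal per-epoch weight.  Hours with fewer than
    ``min_epochs`` such epochs are flagged undefined (value NaN), never
    fabricated.
    """
    if min_epochs < 1:
        raise ValueError("min_epochs must be >= 1")
    span = series.offsets.max() + EPOCH_SECONDS if len(series.offsets) else 0
    if span < N_HOURS * 3600:
        raise ValueError("series does not span the 12-h light period")

    usable = (series.states == "NREM") & (~series.artifact)
    hour = series.offsets // 3600
    bp = band_power(series.freqs, series.power, band)

    values = np.full(N_HOURS, np.nan)
    counts = np.zeros(N_HOURS, dtype=int)
    for h in range(N_HOURS):
        mask = usable & (hour == h)
        counts[h] = int(mask.sum())
        if counts[h] >= min_epochs:
            values[h] = float(bp[mask].mean())
    defined = counts >= min_epochs
    return HourlySWAResult(series.mouse_id, values, counts, defined)
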