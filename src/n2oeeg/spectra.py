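"""Power-spectrum estimation and band-power feature tables.

Spectral power is estimated per 2-s epoch with a Hann-tapered periodogram
(one-sided density scaling, µV²/Hz), averaged across epochs, and read off
at the integer frequencies 1..30 Hz. Band powers are per-frequency means
over the canonical EEG bands, giving the 4-band x 32-channel feature table
(128 features per recording) used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .montage import validate_region_map

FREQ_GRID = np.arange(1, 31)  # integer Hz, 1..30 inclusive


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi) in Hz.

    The highest band closes at its upper edge so the four bands tile the
    1-30 Hz grid exactly once: delta {1,2,3}, theta {4..7}, alpha {8..13},
    beta {14..30}.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    def grid_frequencies(self, include_upper: bool = False) -> np.ndarray:
        """Integer grid frequencies belonging to this band."""
        f = FREQ_GRID
        mask = (f >= self.lo) & ((f <= self.hi) if include_upper else (f < self.hi))
        return f[mask]


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 30.0),
)


def _is_top_band(band: BandDefinition, bands: Sequence[BandDefinition]) -> bool:
    return band.hi >= max(b.hi for b in bands)


@dataclass
class Spectrum:
    """Epoch-averaged power at the integer frequencies 1..30 Hz.

    power has shape (n_channels, 30) in µV²/Hz; channels carries the
    montage labels in signal order.
    """

    frequencies: np.ndarray
    power: np.ndarray
    channels: tuple[str, ...]
    n_epochs_averaged: int

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")
        if not np.array_equal(self.frequencies, FREQ_GRID):
            raise ValueError("frequency grid must be the integers 1..30 Hz")


def estimate_spectrum(
    epochs: np.ndarray, fs: float, channels: Sequence[str] | None = None
) -> Spectrum:
    """Hann-periodogram spectrum of a stack of epochs.

    Parameters
    ----------
    epochs : array (n_epochs, n_channels, n_samples)
        Epoched signal in µV. Epoch duration must be a whole number of
        seconds of at least 1 s, so the native frequency grid contains the
        integers 1..30.
    fs : float
        Sampling rate in Hz, at least 64 so the grid reaches 30 Hz with
        headroom below Nyquist.
    channels : sequence of str, optional
        Channel labels; defaults to ch00, ch01, ...

    Returns
    -------
    Spectrum
        One-sided power spectral density (µV²/Hz) averaged across epochs,
        sampled at 1..30 Hz.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("epochs must be (n_epochs, n_channels, n_samples) with >=1 epoch")
    if fs < 64:
        raise ValueError(f"sampling rate {fs} Hz too low; need >= 64 Hz")
    n_samp = epochs.shape[2]
    duration = n_samp / fs
    if duration < 1.0:
        raise ValueError("epochs shorter than 1 s give a frequency grid coarser than 1 Hz")
    if abs(round(duration) - duration) > 1e-9:
        raise ValueError("epoch length must be a whole number of seconds")

    freqs, pxx = periodogram(
        epochs, fs=fs, window="hann", detrend=False, scaling="density", axis=-1
    )
    mean_pxx = pxx.mean(axis=0)  # (n_channels, n_freqs)
    # Subset the integer frequencies (native grid is fs/n_samp-spaced).
    idx = np.searchsorted(freqs, FREQ_GRID)
    if not np.allclose(freqs[idx], FREQ_GRID):
        raise ValueError("native frequency grid does not contain the integers 1..30")
    if channels is None:
        channels = tuple(f"ch{i:02d}" for i in range(epochs.shape[1]))
    return Spectrum(
        frequencies=FREQ_GRID.copy(),
        power=mean_pxx[:, idx],
        channels=tuple(channels),
        n_epochs_averaged=epochs.shape[0],
    )


def band_power(
    spectrum: Spectrum, bands: Sequence[BandDefinition] = DEFAULT_BANDS
) -> pd.DataFrame:
    """Per-band, per-channel mean power over each band's grid frequencies.

    Returns a DataFrame indexed by band name with one column per channel.
    Each value is the mean of the spectrum over the band's integer
    frequencies (half-open [lo, hi); the top band includes its upper edge).
    """
    rows = {}
    for band in bands:
        grid = band.grid_frequencies(include_upper=_is_top_band(band, bands))
        if grid.size == 0:
            raise ValueError(f"band {band.name} contains no grid frequency")
        idx = np.searchsorted(spectrum.frequencies, grid)
        rows[band.name] = spectrum.power[:, idx].mean(axis=1)
    return pd.DataFrame(rows, index=list(spectrum.channels)).T


ID_COLUMNS = ("participant_id", "condition_pct")


def feature_columns(table: pd.DataFrame) -> List[str]:
    """Names of the band:channel feature columns of a feature table."""
    return [c for c in table.columns if c not in ID_COLUMNS]


def build_feature_table(
    recordings: Iterable,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    relative: bool = False,
    log10: bool = False,
) -> pd.DataFrame:
    """Assemble the (participant x condition) by (band x channel) table.

    One row per recording; feature ``<band>:<channel>`` is the recording's
    epoch-averaged band power. Column order is band-major in montage order,
    giving 4 x 32 = 128 features on the full montage.

    Parameters
    ----------
    recordings : iterable of Recording
        Must share montage and sampling rate; duplicate
        (participant, condition) pairs are rejected.
    relative : bool
        If True, divide each band power by the sum over bands per channel.
    log10 : bool
        If True, take log10 of the (possibly relative) power.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings given")
    montage = recordings[0].channels
    fs = recordings[0].fs
    rows = []
    seen = set()
    for rec in recordings:
        if rec.channels != montage:
            raise ValueError(
                f"inconsistent montage for {rec.participant_id}/{rec.condition}"
            )
        if rec.fs != fs:
            raise ValueError(f"inconsistent sampling rate for {rec.participant_id}")
        key = (rec.participant_id, rec.condition)
        if key in seen:
            raise ValueError(f"duplicate (participant, condition) observation {key}")
        seen.add(key)
        spec = estimate_spectrum(rec.epochs, rec.fs, rec.channels)
        bp = band_power(spec, bands)  # bands x channels
        if relative:
            bp = bp / bp.sum(axis=0)
        if log10:
            bp = np.log10(bp)
        row: Dict[str, object] = {
            "participant_id": rec.participant_id,
            "condition_pct": rec.condition,
        }
        for band in bands:
            for ch in montage:
                row[f"{band.name}:{ch}"] = bp.loc[band.name, ch]
        rows.append(row)
    table = pd.DataFrame(rows)
    cols = list(ID_COLUMNS) + [f"{b.name}:{ch}" for b in bands for ch in montage]
    return table[cols]


def assign_regions(
    channel_labels: Sequence[str], region_map: Mapping[str, str]
) -> List[str]:
    """Region label for each channel, erroring on any unmapped channel."""
    validate_region_map(channel_labels, region_map)
    return [region_map[c] for c in channel_labels]


def save_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ID_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"feature table missing required column {col!r}")
    return table
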