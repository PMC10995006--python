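"""Synthetic multi-channel EEG cohorts with planted dose-dependent effects.

The generator emulates the design of a 12-participant nitrous-oxide
crossover study: each participant contributes one recording per end-tidal
dose condition (0/20/30/40%), 32 BioSemi 10-10 scalp channels at 256 Hz,
segmented into clean 2-s epochs.

Signal model
------------
Each epoch is a sum over the four canonical bands of independent
band-limited Gaussian noise per channel, synthesised in the Fourier
domain with a flat one-sided spectral density inside the band. The
density level (µV²/Hz) of each band IS the planted per-frequency band
power, so the spectral pipeline can recover the targets directly. The
planted target for channel c, band b, dose d, epoch e factorises as

    baseline(b) * participant(b) * dose_multiplier(b, region(c), d) * jitter(e, b)

with log-normal participant and epoch multipliers. At dose 0 every dose
multiplier is 1 by construction. The default planted effect is the
direction reported for nitrous oxide: delta power down, beta power up,
confined to frontal and central channels, log-linearly interpolated in
dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from ._seeds import child_seed, substream
from .montage import BIOSEMI32_CHANNELS, REGIONS, default_region_map, validate_region_map
from .spectra import DEFAULT_BANDS, BandDefinition, _is_top_band

DEFAULT_CONDITIONS = (0, 20, 30, 40)


@dataclass(frozen=True)
class CohortConfig:
    """Design constants of a synthetic cohort."""

    n_participants: int = 12
    conditions: Tuple[int, ...] = DEFAULT_CONDITIONS
    channel_labels: Tuple[str, ...] = BIOSEMI32_CHANNELS
    fs: float = 256.0
    epoch_s: float = 2.0
    n_epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be distinct")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n_samp = self.fs * self.epoch_s
        if abs(n_samp - round(n_samp)) > 1e-9 or n_samp < 2:
            raise ValueError("fs * epoch_s must be an integer >= 2")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_s))

    @property
    def participant_ids(self) -> List[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_participants)]


@dataclass(frozen=True)
class EffectProfile:
    """Baseline spectra, between/within-participant variability, and the
    planted dose effect.

    baseline_band_power is the per-frequency power level of each band in
    µV²/Hz (arbitrary realistic units). dose_effects gives the multiplier
    reached at ``anchor_dose`` in the affected regions; intermediate doses
    interpolate log-linearly, so dose 0 always maps to multiplier 1.
    participant_sd_log / channel_sd_log / epoch_jitter_sd_log are standard
    deviations of log-normal multipliers drawn per (participant, band),
    per (participant, band, channel) and per (epoch, band) respectively.
    The channel-level term gives every participant an idiosyncratic scalp
    topography, as real EEG has; without it, cross-channel contrasts would
    be unrealistically noise-free.
    """

    baseline_band_power: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 40.0, "theta": 20.0, "alpha": 25.0, "beta": 10.0}
    )
    participant_sd_log: float = 0.6
    channel_sd_log: float = 0.2
    epoch_jitter_sd_log: float = 0.1
    dose_effects: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 0.6, "beta": 1.5}
    )
    affected_regions: Tuple[str, ...] = ("frontal", "central")
    anchor_dose: float = 40.0
    region_map: Mapping[str, str] = field(default_factory=default_region_map)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.baseline_band_power.values()):
            raise ValueError("baseline band powers must be strictly positive")
        if any(v <= 0 for v in self.dose_effects.values()):
            raise ValueError("dose multipliers must be strictly positive")
        bad = [r for r in self.affected_regions if r not in REGIONS]
        if bad:
            raise ValueError(f"unknown affected regions {bad}")
        if self.anchor_dose <= 0:
            raise ValueError("anchor_dose must be positive")

    def dose_multiplier(self, band: str, region: str, dose: float) -> float:
        """Multiplicative power factor for (band, region) at ``dose`` %.

        Log-linear in dose between 1 at dose 0 and dose_effects[band] at
        anchor_dose; 1 everywhere outside the affected regions/bands.
        """
        if dose == 0 or region not in self.affected_regions:
            return 1.0
        m = self.dose_effects.get(band)
        if m is None:
            return 1.0
        return math.exp(math.log(m) * dose / self.anchor_dose)

    def null(self) -> "EffectProfile":
        """A copy with no planted dose effect (all multipliers 1)."""
        return EffectProfile(
            baseline_band_power=dict(self.baseline_band_power),
            participant_sd_log=self.participant_sd_log,
            channel_sd_log=self.channel_sd_log,
            epoch_jitter_sd_log=self.epoch_jitter_sd_log,
            dose_effects={},
            affected_regions=self.affected_regions,
            anchor_dose=self.anchor_dose,
            region_map=dict(self.region_map),
        )


@dataclass
class Recording:
    """One participant-condition signal block (epoched, µV)."""

    participant_id: str
    condition: int
    channels: Tuple[str, ...]
    fs: float
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.epochs.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_s(self) -> float:
        return self.epochs.shape[2] / self.fs


def synthesize_epoch(
    target_band_powers: np.ndarray,
    fs: float,
    duration: float,
    seed: int | np.random.Generator,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> np.ndarray:
    """One epoch of per-band band-limited Gaussian noise.

    Parameters
    ----------
    target_band_powers : array (n_channels, n_bands)
        Desired per-frequency band power (one-sided PSD level, µV²/Hz) for
        each channel and band, in the order of ``bands``. Must be >= 0.
    fs, duration : float
        Sampling rate (Hz) and epoch duration (s); fs*duration must be an
        integer number of samples.
    seed : int or Generator
        Randomness source; identical seeds give identical epochs.

    Returns
    -------
    array (n_channels, n_samples)
        Real signal whose expected Hann-periodogram band powers equal the
        targets (up to taper leakage at band edges).

    Notes
    -----
    Synthesis is in the rfft domain: independent complex-Gaussian
    coefficients on the native frequency grid inside each band, scaled so
    E|X_k|^2 = target * fs * n / 2, which makes the one-sided periodogram
    density equal the target. Each band occupies the half-open bin range
    [lo, hi); the top band also fills its upper-edge bin. The lowest band's
    lower edge and the top band's upper edge are padded by one native bin,
    so Hann-taper leakage does not bias the outermost analysis frequencies
    (real EEG likewise has energy just outside the analysis range).
    """
    targets = np.atleast_2d(np.asarray(target_band_powers, dtype=float))
    if targets.shape[1] != len(bands):
        raise ValueError(f"expected {len(bands)} band targets per channel")
    if np.any(targets < 0):
        raise ValueError("band-power targets must be non-negative")
    if duration <= 0:
        raise ValueError("epoch duration must be positive")
    n = fs * duration
    if abs(n - round(n)) > 1e-9:
        raise ValueError("fs * duration must be an integer sample count")
    n = int(round(n))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_ch = targets.shape[0]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    df = fs / n
    X = np.zeros((n_ch, freqs.size), dtype=complex)
    nyquist = fs / 2.0
    lowest_lo = min(b.lo for b in bands)
    for j, band in enumerate(bands):
        lo, hi = band.lo, band.hi
        if band.lo <= lowest_lo:
            lo -= df  # outer-edge padding (see Notes)
        mask = (freqs >= lo - 1e-9) & (freqs < hi)
        if _is_top_band(band, bands):
            mask |= np.isclose(freqs, hi) | np.isclose(freqs, hi + df)
        mask &= freqs > 0  # DC is never part of a band
        mask &= freqs <= nyquist + 1e-9
        sigma2 = targets[:, j : j + 1] * fs * n / 2.0  # (n_ch, 1)
        k = int(mask.sum())
        z = rng.standard_normal((n_ch, k)) + 1j * rng.standard_normal((n_ch, k))
        X[:, mask] += np.sqrt(sigma2 / 2.0) * z
    # A real-valued Nyquist coefficient, if a band ever reaches it.
    nyq = np.isclose(freqs, nyquist)
    X[:, nyq] = X[:, nyq].real * math.sqrt(2.0)
    return np.fft.irfft(X, n=n, axis=1)


def _channel_targets(
    participant_effects: Mapping[str, float],
    condition: int,
    profile: EffectProfile,
    config: CohortConfig,
    bands: Sequence[BandDefinition],
) -> np.ndarray:
    """Per-channel per-band targets before epoch jitter: (n_ch, n_bands).

    participant_effects values may be scalars (one multiplier per band) or
    per-channel vectors in montage order.
    """
    validate_region_map(config.channel_labels, profile.region_map)
    targets = np.empty((config.n_channels, len(bands)))
    for j, band in enumerate(bands):
        mult = np.broadcast_to(
            np.asarray(participant_effects[band.name], dtype=float), (config.n_channels,)
        )
        base = profile.baseline_band_power[band.name] * mult
        for i, ch in enumerate(config.channel_labels):
            region = profile.region_map[ch]
            targets[i, j] = base[i] * profile.dose_multiplier(band.name, region, condition)
    return targets


def generate_recording(
    participant_effects: Mapping[str, float],
    participant_id: str,
    condition: int,
    profile: EffectProfile,
    config: CohortConfig,
    seed: int,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> Recording:
    """Generate one participant-condition recording of n_epochs epochs.

    Epoch-level log-normal jitter (shared across channels within an epoch,
    independent across bands) multiplies the planted targets; each epoch
    uses its own derived substream so regeneration is reproducible.
    """
    if condition not in config.conditions:
        raise ValueError(f"condition {condition} not in config conditions {config.conditions}")
    base_targets = _channel_targets(participant_effects, condition, profile, config, bands)
    jitter_rng = substream(seed, "jitter")
    epochs = np.empty((config.n_epochs, config.n_channels, config.n_samples))
    for e in range(config.n_epochs):
        jit = np.exp(jitter_rng.normal(0.0, profile.epoch_jitter_sd_log, size=len(bands)))
        epochs[e] = synthesize_epoch(
            base_targets * jit[None, :],
            config.fs,
            config.epoch_s,
            substream(seed, "epoch", e),
            bands,
        )
    return Recording(
        participant_id=participant_id,
        condition=condition,
        channels=config.channel_labels,
        fs=config.fs,
        epochs=epochs,
    )


def draw_participant_effects(
    config: CohortConfig,
    profile: EffectProfile,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Log-normal per-(participant, band, channel) baseline multipliers.

    Each participant's multiplier for a band is a shared band-level
    log-normal factor times an independent per-channel log-normal factor
    (the participant's scalp topography). Drawn once per participant from
    a participant-keyed substream of the cohort seed and shared across
    that participant's conditions.
    """
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for pid in config.participant_ids:
        rng = substream(config.seed, "participant", pid)
        effects: Dict[str, np.ndarray] = {}
        for b in bands:
            band_level = rng.normal(0.0, profile.participant_sd_log)
            channel_level = rng.normal(0.0, profile.channel_sd_log, size=config.n_channels)
            effects[b.name] = np.exp(band_level + channel_level)
        out[pid] = effects
    return out


def generate_cohort(
    config: CohortConfig,
    profile: EffectProfile | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> List[Recording]:
    """One recording per participant x condition (n_participants * k total)."""
    if profile is None:
        profile = EffectProfile()
    effects = draw_participant_effects(config, profile, bands)
    recordings = []
    for pid in config.participant_ids:
        for cond in config.conditions:
            recordings.append(
                generate_recording(
                    effects[pid],
                    pid,
                    cond,
                    profile,
                    config,
                    seed=child_seed(config.seed, "recording", pid, cond),
                    bands=bands,
                )
            )
    return recordings


def reject_artifact_epochs(
    recording: Recording, amplitude_threshold: float
) -> Tuple[Recording, int]:
    """Drop epochs whose absolute amplitude exceeds the threshold anywhere.

    A simple amplitude gate standing in for artifact screening: an epoch is
    removed iff any sample's |value| exceeds ``amplitude_threshold`` µV.
    Surviving epochs keep their order. Rejecting every epoch is an error.
    """
    if amplitude_threshold <= 0:
        raise ValueError("amplitude threshold must be positive (µV)")
    peak = np.abs(recording.epochs).max(axis=(1, 2))
    keep = peak <= amplitude_threshold
    n_rejected = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"all epochs rejected for {recording.participant_id}/"
            f"{recording.condition}% at threshold {amplitude_threshold} µV"
        )
    cleaned = Recording(
        participant_id=recording.participant_id,
        condition=recording.condition,
        channels=recording.channels,
        fs=recording.fs,
        epochs=recording.epochs[keep],
    )
    return cleaned, n_rejected
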