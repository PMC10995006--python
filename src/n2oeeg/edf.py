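"""EDF export/import of synthetic recordings.

Writes standard European Data Format (EDF) files — one per
participant-condition recording, one data record per 2-s epoch — plus a
TSV manifest mapping files to participants and conditions. Signals are
stored as 16-bit integers over a fixed physical range of ±500 µV, so the
quantization step is 1000/65535 ≈ 0.0153 µV. Reading goes through MNE's
EDF reader, which also serves as an independent check on the writer.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .synthgen import Recording

logger = logging.getLogger(__name__)

PHYS_MIN = -500.0  # µV
PHYS_MAX = 500.0
DIG_MIN = -32768
DIG_MAX = 32767

#: Physical value of one digital step (µV); round-trip error is <= this.
QUANTIZATION_STEP = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)

MANIFEST_NAME = "manifest.tsv"
MANIFEST_COLUMNS = ("participant_id", "condition_pct", "path", "n_epochs", "seed")


def _ascii_field(value: str, width: int, what: str) -> bytes:
    if len(value) > width:
        logger.warning("truncating %s %r to %d characters for EDF header", what, value, width)
        value = value[:width]
    return value.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: Path | str) -> None:
    """Write one recording as an EDF file (one data record per epoch)."""
    path = Path(path)
    n_epochs, n_ch, n_samp = recording.epochs.shape
    duration = recording.epochs.shape[2] / recording.fs
    dur_str = f"{duration:g}"
    if len(dur_str) > 8:
        raise ValueError(f"record duration {duration} does not fit the EDF header")

    header = b"".join(
        [
            _ascii_field("0", 8, "version"),
            _ascii_field(f"X X X {recording.participant_id}", 80, "patient id"),
            _ascii_field(
                f"Startdate 01-JAN-2000 X X cond-{recording.condition}pct", 80, "recording id"
            ),
            _ascii_field("01.01.00", 8, "start date"),
            _ascii_field("00.00.00", 8, "start time"),
            _ascii_field(str(256 * (1 + n_ch)), 8, "header bytes"),
            _ascii_field("", 44, "reserved"),
            _ascii_field(str(n_epochs), 8, "n records"),
            _ascii_field(dur_str, 8, "record duration"),
            _ascii_field(str(n_ch), 4, "n signals"),
        ]
    )
    fields: list[bytes] = []
    for width, values, what in [
        (16, [f"EEG {c}" for c in recording.channels], "channel label"),
        (80, ["active electrode"] * n_ch, "transducer"),
        (8, ["uV"] * n_ch, "physical dimension"),
        (8, [f"{PHYS_MIN:g}"] * n_ch, "physical min"),
        (8, [f"{PHYS_MAX:g}"] * n_ch, "physical max"),
        (8, [str(DIG_MIN)] * n_ch, "digital min"),
        (8, [str(DIG_MAX)] * n_ch, "digital max"),
        (80, [""] * n_ch, "prefiltering"),
        (8, [str(n_samp)] * n_ch, "samples per record"),
        (32, [""] * n_ch, "signal reserved"),
    ]:
        fields.extend(_ascii_field(v, width, what) for v in values)

    clipped = np.clip(recording.epochs, PHYS_MIN, PHYS_MAX)
    if np.any(clipped != recording.epochs):
        logger.warning(
            "samples outside ±%g µV clipped while writing %s", PHYS_MAX, path.name
        )
    gain = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.rint((clipped - PHYS_MIN) * gain + DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        # Record-major layout: all samples of signal 1, then signal 2, ...
        digital.reshape(n_epochs, n_ch * n_samp).tofile(fh)


def export_recordings(
    recordings: Iterable[Recording], directory: Path | str, seed: int | None = None
) -> pd.DataFrame:
    """Write one EDF per recording plus a manifest TSV; return the manifest.

    The manifest maps each file to its participant and condition and
    records epoch counts and the generating seed (if given).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"sub-{rec.participant_id}_cond-{rec.condition:02d}.edf"
        write_edf(rec, directory / fname)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "condition_pct": rec.condition,
                "path": fname,
                "n_epochs": rec.n_epochs,
                "seed": "" if seed is None else seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(directory / MANIFEST_NAME, sep="\t", index=False)
    return manifest


def load_recordings(directory: Path | str) -> List[Recording]:
    """Read a manifest + EDF directory back into Recording objects.

    Uses MNE's EDF reader; the continuous signal of each file is re-split
    into the epochs recorded in the manifest.
    """
    import mne

    directory = Path(directory)
    manifest = pd.read_csv(directory / MANIFEST_NAME, sep="\t")
    recordings = []
    for row in manifest.itertuples(index=False):
        raw = mne.io.read_raw_edf(directory / row.path, preload=True, verbose="error")
        data_uv = raw.get_data() * 1e6  # MNE returns volts
        channels = tuple(c.removeprefix("EEG ") for c in raw.ch_names)
        n_epochs = int(row.n_epochs)
        n_ch, n_times = data_uv.shape
        n_samp = n_times // n_epochs
        epochs = data_uv.reshape(n_ch, n_epochs, n_samp).transpose(1, 0, 2)
        recordings.append(
            Recording(
                participant_id=str(row.participant_id),
                condition=int(row.condition_pct),
                channels=channels,
                fs=float(raw.info["sfreq"]),
                epochs=epochs,
            )
        )
    return recordings
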