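"""BioSemi 32-channel 10-10 montage and the default scalp-region grouping."""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping

# BioSemi ActiveTwo 32-channel cap, electrode order A1..A32.
BIOSEMI32_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

REGIONS: tuple[str, ...] = ("frontal", "lateral", "central", "occipital")

# Anterior-posterior grouping of the 32 scalp sites into four regions.
_DEFAULT_REGIONS: Dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "Fz"),
    "lateral": ("F7", "F8", "FC5", "FC6", "T7", "T8", "CP5", "CP6"),
    "central": ("FC1", "FC2", "C3", "C4", "Cz", "CP1", "CP2"),
    "occipital": ("P7", "P3", "Pz", "P4", "P8", "PO3", "PO4", "O1", "Oz", "O2"),
}


def default_region_map() -> Dict[str, str]:
    """Channel label -> region for the BioSemi-32 montage.

    Regions partition the montage: 7 frontal, 8 lateral, 7 central and
    10 occipital channels.
    """
    out: Dict[str, str] = {}
    for region, labels in _DEFAULT_REGIONS.items():
        for lab in labels:
            out[lab] = region
    return out


def validate_region_map(
    channel_labels: Iterable[str], region_map: Mapping[str, str]
) -> None:
    """Check that every channel is mapped and every region is known."""
    labels: List[str] = list(channel_labels)
    missing = [c for c in labels if c not in region_map]
    if missing:
        raise KeyError(f"channels missing from region map: {missing}")
    bad = sorted({r for r in (region_map[c] for c in labels) if r not in REGIONS})
    if bad:
        raise ValueError(f"unknown regions {bad}; expected one of {REGIONS}")
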