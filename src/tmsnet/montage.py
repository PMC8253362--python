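"""The 21-channel 10-20 montage and its scalp-region grouping.

The region map drives the network summaries: significant directed edges are
reported per (source region -> target region) pair.
"""

from __future__ import annotations

MONTAGE_21: list[str] = [
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
]

#: scalp-region grouping; midline electrodes form their own group
REGION_MAP: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal", "F7": "frontal", "F3": "frontal",
    "F4": "frontal", "F8": "frontal",
    "C3": "central", "C4": "central",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "P3": "parietal", "P4": "parietal",
    "O1": "occipital", "O2": "occipital",
    "Fpz": "midline", "Fz": "midline", "Cz": "midline", "Pz": "midline",
    "Oz": "midline",
}


def region_of(channel: str) -> str:
    """Region name for a 10-20 channel label."""
    try:
        return REGION_MAP[channel]
    except KeyError:
        raise KeyError(f"channel {channel!r} has no region assignment") from None
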