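"""Standard 10-20 montage used throughout the package.

The default electrode set is the 19 scalp channels of the clinical montage,
in acquisition order, with an optional ECG channel appended.  Each scalp
channel is assigned to one of five coarse cortical regions; the region map
drives the region-similarity half of the adjacency matrix.
"""

from __future__ import annotations

#: 19 scalp electrodes in acquisition order.
SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "T3", "T5", "C3", "C4", "Fz",
    "Cz", "Pz", "F8", "T4", "T6", "P3", "P4", "O1", "O2",
)

ECG_CHANNEL = "ECG"

#: Coarse lobe assignment for each scalp electrode.
DEFAULT_REGION_MAP: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal", "F3": "frontal", "F4": "frontal",
    "F7": "frontal", "F8": "frontal", "Fz": "frontal",
    "C3": "central", "C4": "central", "Cz": "central",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "P3": "parietal", "P4": "parietal", "Pz": "parietal",
    "O1": "occipital", "O2": "occipital",
}

REGIONS: tuple[str, ...] = ("frontal", "central", "temporal", "parietal", "occipital")
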