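"""Putative cell-type classification from spike-waveform features.

Features arrive precomputed (waveforms.csv): total spike duration, defined as
the inverse of the frequency of maximal wavelet power, and the trough-to-peak
interval, both in ms. The two thresholds separate narrow-spiking putative
interneurons from broad-spiking putative pyramidal cells, with a deliberate
exclusion gap (0.9-0.95 ms duration, and exactly 0.42 ms trough-to-peak)
mapped to "unclassified".
"""
from __future__ import annotations

from dataclasses import dataclass

DURATION_INTERNEURON_MS = 0.9
DURATION_PYRAMIDAL_MS = 0.95
TROUGH_TO_PEAK_MS = 0.42


@dataclass(frozen=True)
class WaveformFeatures:
    """Waveform summary for one cell (both in ms, both > 0)."""

    duration_ms: float
    trough_to_peak_ms: float

    def __post_init__(self):
        if not (self.duration_ms > 0 and self.trough_to_peak_ms > 0):
            raise ValueError("waveform features must be positive")


def classify_cell_type(features: WaveformFeatures) -> str:
    """Return 'interneuron', 'pyramidal' or 'unclassified'.

    Interneuron: duration < 0.9 ms and trough-to-peak < 0.42 ms.
    Pyramidal: duration > 0.95 ms and trough-to-peak > 0.42 ms.
    Everything else (including the boundary values) is unclassified.
    """
    d = features.duration_ms
    t = features.trough_to_peak_ms
    if d < DURATION_INTERNEURON_MS and t < TROUGH_TO_PEAK_MS:
        return "interneuron"
    if d > DURATION_PYRAMIDAL_MS and t > TROUGH_TO_PEAK_MS:
        return "pyramidal"
    return "unclassified"
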