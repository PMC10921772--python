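"""Acquisition-timing arithmetic for segmented real-time phase contrast.

Real-time phase contrast (RT-PC) fills k-space shot by shot without cardiac
gating; its temporal resolution is set by the number of k-space segments and
the repetition time, which in turn bounds how many samples land in each
cardiac cycle. These helpers make that bookkeeping explicit.
"""

from __future__ import annotations

import math


def kspace_segments(matrix_lines: float, sense_factor: float, epi_factor: float) -> float:
    """Number of k-space segments (shots) per velocity map.

    segments = acquisition matrix lines / parallel-imaging (SENSE) factor /
    EPI factor. E.g. 70 lines with SENSE 2.5 and EPI factor 7 gives a
    4-shot acquisition.
    """
    if min(matrix_lines, sense_factor, epi_factor) <= 0:
        raise ValueError("all factors must be positive")
    return matrix_lines / sense_factor / epi_factor


def temporal_resolution(n_segments: float, tr_s: float) -> float:
    """Frame interval (s) of a flow-encoded pair: 2 * segments * TR."""
    return 2.0 * n_segments * tr_s


def points_per_cycle(bpm: float, frame_interval_s: float) -> int:
    """Whole velocity maps acquired within one cardiac cycle.

    At 60 BPM and 96 ms per image this is floor(1.0 / 0.096) = 10 points,
    which is why beat-to-beat curves need interpolation up to the 32-point
    gated (CINE) format before parameters are compared.
    """
    if bpm <= 0 or frame_interval_s <= 0:
        raise ValueError("bpm and frame_interval must be positive")
    return math.floor((60.0 / bpm) / frame_interval_s)
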