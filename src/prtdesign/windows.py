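"""Split a target region into overlapping design windows.

Primer candidates concentrate where the sequence is closest to the optimal
design parameters; running the designer separately in overlapping windows
(default 2 kb windows overlapping by 300 bp) spreads assays evenly across
the target interval.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_WINDOW = 2000
DEFAULT_OVERLAP = 300


@dataclass(frozen=True)
class WindowPlan:
    window_length: int
    overlap: int
    windows: list[tuple[int, int]]


def plan_windows(
    region_length: int,
    window_length: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
) -> WindowPlan:
    """Tile ``[0, region_length)`` with overlapping windows.

    Windows start at multiples of ``window_length - overlap``; if the final
    window would overrun the region it is re-anchored to end exactly at
    ``region_length`` (so it overlaps its predecessor by more than
    ``overlap`` rather than being short). A region shorter than one window
    yields a single window equal to the region.
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    if not 0 <= overlap < window_length:
        raise ValueError("overlap must satisfy 0 <= overlap < window_length")
    if region_length <= window_length:
        return WindowPlan(window_length, overlap, [(0, region_length)])
    step = window_length - overlap
    windows: list[tuple[int, int]] = []
    start = 0
    while True:
        end = start + window_length
        if end >= region_length:
            windows.append((region_length - window_length, region_length))
            break
        windows.append((start, end))
        start += step
    return WindowPlan(window_length, overlap, windows)
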