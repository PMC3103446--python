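"""Summit detection inside enriched regions.

The summit-valley-alternator scans a region's (optionally smoothed)
coverage left to right, alternating between two states.  While seeking a
summit it tracks the running maximum M; when coverage drops below
delta * M the leftmost position attaining M is emitted as a summit and
the scan starts seeking a valley.  While seeking a valley it tracks the
running minimum m; when coverage rises strictly above m / delta the scan
re-arms for the next summit.  delta in (0, 1) tunes the sensitivity:
larger delta splits shallower valleys, so punctate transcription-factor
data is called with a high delta and broad histone data with a low one.

The valley re-arming criterion (rise above m / delta) is this package's
symmetric completion of the summit rule; it prevents cascades of spurious
summits on monotone decays.  Two extra filters follow: summits separated
only by zero-coverage gaps are collapsed to the higher one (a guard
against undersequenced regions), and summits far below the region's top
summit can be dropped to keep only comparable-height summits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .region_caller import CandidateRegion, Summit


@dataclass
class SummitConfig:
    """Tunables for summit calling within one region."""

    delta: float = 0.8
    smooth_window: int = 5
    min_rel_height: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must be in the open interval (0,1), got {self.delta}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError(f"smooth_window must be odd and >= 1, got {self.smooth_window}")
        if not 0.0 <= self.min_rel_height <= 1.0:
            raise ValueError(f"min_rel_height must be in [0,1], got {self.min_rel_height}")


def smooth_profile(segment: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the boundaries.

    The divisor is always the number of positions actually inside the
    window (no zero padding), so a constant segment is a fixed point and
    window=1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    seg = np.asarray(segment, dtype=float)
    if window == 1 or seg.size == 0:
        return seg.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(seg)))
    idx = np.arange(seg.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, seg.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def summit_valley_alternator(segment: np.ndarray, delta: float) -> list[int]:
    """Emit segment-relative summit indices via the two-state scan.

    Plateau ties break to the leftmost index (the running maximum is
    only replaced on a strict increase).  A scan ending in summit-seek
    emits its pending maximum; one ending in valley-seek emits nothing.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in the open interval (0,1), got {delta}")
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        return []
    summits: list[int] = []
    seeking_summit = True
    best = seg[0]
    best_i = 0
    valley = np.inf
    for i in range(1, seg.size):
        v = seg[i]
        if seeking_summit:
            if v > best:
                best, best_i = v, i
            elif v < delta * best:
                summits.append(best_i)
                seeking_summit = False
                valley = v
        else:
            if v < valley:
                valley = v
            elif v * delta > valley:
                seeking_summit = True
                best, best_i = v, i
    if seeking_summit:
        summits.append(best_i)
    return summits


def suppress_zero_gap_summits(
    summits: list[Summit], segment: np.ndarray, segment_offset: int = 0
) -> list[Summit]:
    """Collapse summit pairs separated by zero-coverage stretches.

    For each consecutive pair with at least one zero-depth position
    between them (tested on the raw, unsmoothed track), the lower summit
    is dropped (ties drop the right one); repeated until stable.
    ``segment_offset`` maps absolute summit positions into the segment.
    """
    seg = np.asarray(segment)
    out = list(summits)
    changed = True
    while changed and len(out) > 1:
        changed = False
        for i in range(len(out) - 1):
            a, b = out[i], out[i + 1]
            lo = a.pos - segment_offset + 1
            hi = b.pos - segment_offset
            if lo < hi and np.any(seg[lo:hi] == 0):
                out.pop(i + 1 if b.height <= a.height else i)
                changed = True
                break
    return out


def filter_relative_height(summits: list[Summit], min_rel_height: float) -> list[Summit]:
    """Drop summits below ``min_rel_height`` x the region's top summit; 0 disables."""
    if not 0.0 <= min_rel_height <= 1.0:
        raise ValueError(f"min_rel_height must be in [0,1], got {min_rel_height}")
    if not summits or min_rel_height == 0.0:
        return list(summits)
    cutoff = min_rel_height * max(s.height for s in summits)
    return [s for s in summits if s.height >= cutoff]


def call_summits(
    region: CandidateRegion, depth: np.ndarray, config: SummitConfig
) -> CandidateRegion:
    """Fill ``region.summits`` from the chromosome's raw coverage track.

    Pipeline: slice -> smooth -> alternator -> zero-gap suppression
    (zero test on the raw track) -> relative-height filter.  Every
    surviving region keeps at least one summit: if all are filtered
    away, the global maximum of the smoothed segment is reinstated.
    """
    raw = np.asarray(depth[region.start : region.end])
    smoothed = smooth_profile(raw, config.smooth_window)
    idx = summit_valley_alternator(smoothed, config.delta)
    summits = [
        Summit(pos=region.start + i, height=float(smoothed[i])) for i in idx
    ]
    summits = suppress_zero_gap_summits(summits, raw, segment_offset=region.start)
    summits = filter_relative_height(summits, config.min_rel_height)
    summits = [s for s in summits if s.height > 0]
    if not summits and raw.size:
        top = int(np.argmax(smoothed))
        summits = [Summit(pos=region.start + top, height=float(smoothed[top]))]
    region.summits = summits
    return region
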