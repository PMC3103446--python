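"""Enriched-region detection and significance.

Broad candidate regions are maximal runs of coverage at or above a
Poisson-tail depth threshold, with nearby runs merged across short gaps.
Each candidate is then scored against the control library (binomial
two-sample test after regression-based scaling) or, without a control,
against the genome-wide Poisson background, and the whole candidate set
is filtered by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .coverage import CoverageProfile, genome_background_rate


@dataclass
class Summit:
    """A single-bp summit: absolute chromosome position and (smoothed) height."""

    pos: int
    height: float


@dataclass
class CandidateRegion:
    """A contiguous above-threshold interval and its significance."""

    chrom: str
    start: int
    end: int
    max_height: int
    treat_count: int = 0
    ctrl_count_scaled: float = 0.0
    p_value: float = 1.0
    q_value: float = 1.0
    summits: list[Summit] = field(default_factory=list)
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ScalingFit:
    """Multiplier placing control counts on the treatment scale."""

    r: float
    method: str  # "regression" | "library_ratio"
    n_bins_used: int = 0


def poisson_region_threshold(lam: float, p0: float = 1e-4) -> int:
    """Smallest integer depth h >= 1 with P(Poisson(lam) >= h) < p0."""
    if lam < 0:
        raise ValueError(f"background rate must be >= 0, got {lam}")
    if not 0 < p0 < 1:
        raise ValueError(f"tail probability must be in (0,1), got {p0}")
    h = 1
    # sf(h-1) = P(X >= h); the tail shrinks geometrically so this terminates.
    while stats.poisson.sf(h - 1, lam) >= p0:
        h += 1
    return h


def detect_candidate_regions(
    depth: np.ndarray, h: int, max_gap: int = 0
) -> list[tuple[int, int, int]]:
    """Maximal runs of positions with depth >= h, merging sub-``max_gap`` gaps.

    Runs separated by strictly fewer than ``max_gap`` below-threshold
    positions are merged, gap positions included.  Returns sorted,
    disjoint ``(start, end, max_height)`` triples.
    """
    if h < 1:
        raise ValueError(f"threshold must be >= 1, got {h}")
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    above = depth >= h
    if not above.any():
        return []
    # Run boundaries from the 0/1 transition points.
    padded = np.concatenate(([False], above, [False]))
    flips = np.flatnonzero(np.diff(padded.astype(np.int8)))
    bounds = list(zip(flips[0::2].tolist(), flips[1::2].tolist()))
    merged: list[list[int]] = []
    for s, e in bounds:
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e, int(depth[s:e].max())) for s, e in merged]


def fit_control_scaling(
    treat_bin_counts: np.ndarray,
    ctrl_bin_counts: np.ndarray,
    excluded_bins: Sequence[int] = (),
    total_treat: Optional[int] = None,
    total_ctrl: Optional[int] = None,
) -> ScalingFit:
    """Fit the control-to-treatment scaling factor r over background bins.

    Zero-intercept least squares of treatment counts on control counts
    over bins not overlapping any candidate region; falls back to the
    library-size ratio when the regression is degenerate (all remaining
    control counts zero, or fewer than two usable bins).
    """
    t = np.asarray(treat_bin_counts, dtype=float)
    c = np.asarray(ctrl_bin_counts, dtype=float)
    if t.shape != c.shape:
        raise ValueError("treatment and control bin vectors differ in length")
    keep = np.ones(t.size, dtype=bool)
    excl = np.asarray(list(excluded_bins), dtype=int)
    if excl.size:
        keep[excl] = False
    t, c = t[keep], c[keep]

    def _ratio() -> ScalingFit:
        tt = total_treat if total_treat is not None else float(t.sum())
        cc = total_ctrl if total_ctrl is not None else float(c.sum())
        r = tt / cc if cc > 0 else 1.0
        return ScalingFit(r=max(r, np.finfo(float).tiny), method="library_ratio",
                          n_bins_used=int(t.size))

    if t.size < 2 or not np.any(c > 0):
        return _ratio()
    denom = float(np.dot(c, c))
    slope = float(np.dot(t, c)) / denom
    if slope <= 0:
        return _ratio()
    return ScalingFit(r=slope, method="regression", n_bins_used=int(t.size))


def region_pvalue_binomial(treat_count: int, ctrl_count_scaled: float) -> float:
    """One-sided two-sample binomial p-value for treatment enrichment.

    Under the null the ``k_t + k_c`` fragments split evenly between the
    two libraries: p = P(X >= k_t) for X ~ Binomial(k_t + k_c, 1/2).
    """
    k_t = int(treat_count)
    if k_t < 0:
        raise ValueError("treatment count must be >= 0")
    if k_t == 0:
        return 1.0
    k_c = max(int(round(ctrl_count_scaled)), 0)
    n = k_t + k_c
    return float(stats.binom.sf(k_t - 1, n, 0.5))


def region_pvalue_poisson(
    treat_count: int, lam: float, region_len: int, ext_len: int
) -> float:
    """No-control p-value: Poisson tail on the expected fragment count.

    mu = lam * region_len / ext_len is the background expectation of
    fragments overlapping a region of that length.
    """
    if lam < 0:
        raise ValueError("background rate must be >= 0")
    if treat_count <= 0:
        return 1.0
    mu = lam * region_len / ext_len
    return float(stats.poisson.sf(treat_count - 1, mu))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.clip(stats.false_discovery_control(p, method="bh"), 0.0, 1.0)


def rank_regions(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    """Significance ranking: ascending p, ties by descending height, then coordinate."""
    return sorted(
        regions, key=lambda r: (r.p_value, -r.max_height, r.chrom, r.start)
    )


def _count_overlapping(
    starts: np.ndarray, ends: np.ndarray, lo: int, hi: int
) -> int:
    """Fragments with interval overlapping [lo, hi); arrays sorted independently."""
    if starts.size == 0:
        return 0
    return int(
        np.searchsorted(starts, hi, side="left")
        - np.searchsorted(ends, lo, side="right")
    )


def _chrom_candidate_stage(args) -> tuple[str, list, np.ndarray, np.ndarray, list[int]]:
    """Per-chromosome detection + counting; picklable for worker processes.

    Returns (chrom, [(start, end, max_height, k_t, k_c_raw)], treatment
    bin counts, control bin counts, bin indices overlapping candidates).
    """
    (chrom, depth, t_starts, t_ends, c_starts, c_ends, h, max_gap, bin_size) = args
    cands = []
    excluded: list[int] = []
    n_bins = (depth.size + bin_size - 1) // bin_size
    for s, e, mh in detect_candidate_regions(depth, h, max_gap):
        k_t = _count_overlapping(t_starts, t_ends, s, e)
        k_c = (
            _count_overlapping(c_starts, c_ends, s, e) if c_starts is not None else 0
        )
        cands.append((s, e, mh, k_t, k_c))
        excluded.extend(range(s // bin_size, min((e - 1) // bin_size, n_bins - 1) + 1))
    t_bins = (
        np.bincount(t_starts // bin_size, minlength=n_bins)
        if t_starts.size
        else np.zeros(n_bins, dtype=np.int64)
    )
    if c_starts is not None and c_starts.size:
        c_bins = np.bincount(c_starts // bin_size, minlength=n_bins)
    else:
        c_bins = np.zeros(n_bins, dtype=np.int64)
    return chrom, cands, t_bins, c_bins, sorted(set(excluded))


def call_regions(
    treat_profile: CoverageProfile,
    ctrl_profile: Optional[CoverageProfile],
    fdr_cutoff: float = 0.01,
    thr_p: float = 1e-4,
    max_gap: int = 100,
    bin_size: int = 10_000,
    pool_map=map,
) -> tuple[list[CandidateRegion], Optional[ScalingFit], dict]:
    """Detect, score and FDR-filter enriched regions genome-wide.

    Per-chromosome detection runs through ``pool_map`` (any order-
    preserving map; pass an executor's map for parallel execution),
    while scaling, p-values and the BH step are gathered centrally so
    the FDR is controlled over the whole genome.  Returns the surviving
    regions sorted by coordinate, the control scaling fit (None in
    no-control mode), and an info dict.
    """
    lam = genome_background_rate(treat_profile)
    h = poisson_region_threshold(lam, thr_p)
    ext_len = treat_profile.ext_len
    has_ctrl = ctrl_profile is not None

    tasks = []
    for chrom in treat_profile.chroms():
        empty = np.zeros(0, dtype=np.int64)
        if has_ctrl:
            c_starts = ctrl_profile.frag_starts.get(chrom, empty)
            c_ends = ctrl_profile.frag_ends.get(chrom, empty)
        else:
            c_starts = c_ends = None
        tasks.append(
            (
                chrom,
                treat_profile[chrom],
                treat_profile.frag_starts.get(chrom, empty),
                treat_profile.frag_ends.get(chrom, empty),
                c_starts,
                c_ends,
                h,
                max_gap,
                bin_size,
            )
        )

    candidates: list[CandidateRegion] = []
    t_bins_all, c_bins_all, excluded_all = [], [], []
    offset = 0
    for chrom, cands, t_bins, c_bins, excluded in pool_map(
        _chrom_candidate_stage, tasks
    ):
        for s, e, mh, k_t, k_c in cands:
            candidates.append(
                CandidateRegion(
                    chrom, s, e, mh, treat_count=k_t, ctrl_count_scaled=float(k_c)
                )
            )
        t_bins_all.append(t_bins)
        c_bins_all.append(c_bins)
        excluded_all.extend(offset + i for i in excluded)
        offset += t_bins.size

    fit: Optional[ScalingFit] = None
    if has_ctrl:
        fit = fit_control_scaling(
            np.concatenate(t_bins_all) if t_bins_all else np.zeros(0),
            np.concatenate(c_bins_all) if c_bins_all else np.zeros(0),
            excluded_bins=excluded_all,
            total_treat=treat_profile.n_fragments,
            total_ctrl=ctrl_profile.n_fragments,
        )
        for reg in candidates:
            reg.ctrl_count_scaled *= fit.r  # raw control count was stashed here
            reg.p_value = region_pvalue_binomial(reg.treat_count, reg.ctrl_count_scaled)
    else:
        for reg in candidates:
            reg.p_value = region_pvalue_poisson(
                reg.treat_count, lam, reg.length, ext_len
            )

    if candidates:
        q = bh_fdr([r.p_value for r in candidates])
        for reg, qv in zip(candidates, q):
            reg.q_value = float(qv)
    surviving = [r for r in candidates if r.q_value <= fdr_cutoff]
    for rank, reg in enumerate(rank_regions(surviving), start=1):
        reg.name = f"region_{rank}"
    surviving.sort(key=lambda r: (r.chrom, r.start))
    info = {
        "background_rate": lam,
        "depth_threshold": h,
        "n_candidates": len(candidates),
        "n_surviving": len(surviving),
    }
    return surviving, fit, info
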