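"""Semi-synthetic ChIP-seq benchmarks with known truth.

Real gold standards for summit accuracy and inter-peak resolution do not
exist, so these generators emulate the classic spike-in design: a
uniform sequencing background on one chromosome, point-source binding
peaks spiked in at known positions, and — for the resolution benchmark —
a series of datasets with peak *pairs* at increasing separations
(200-500 bp in 25 bp steps, 13 datasets), each with a control holding
the same total number of reads.

Spiked fragments are drawn so that every fragment covers the true
binding position; the raw fragment coverage at a truth position
therefore equals the number of spiked fragments exactly, and the
expected coverage decays linearly to zero ``ext_len`` bp away.

The generators emulate the benchmark *design*, not any particular real
control library: the background here is uniform, with none of the
mappability structure, duplicate towers or copy-number waves of real
input data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .alignment_io import AlignedRead, ChromTable
from .coverage import build_coverage
from .pipeline import CallerConfig, apply_preset, call_peaks
from .region_caller import CandidateRegion

DEFAULT_CHROM = "chr1"
DEFAULT_CHROM_LEN = 10_000_000
DEFAULT_N_BG_READS = 20_000
DEFAULT_FRAGS_PER_PEAK = 100
DEFAULT_READ_LEN = 36
DEFAULT_EXT_LEN = 200
DEFAULT_SEPARATIONS = tuple(range(200, 501, 25))  # 13 datasets
MIN_ANCHOR_SPACING = 5_000


@dataclass(frozen=True)
class TruthRecord:
    """One spiked binding event: a single summit or a close pair."""

    chrom: str
    positions: tuple[int, ...]
    n_fragments: int
    separation: Optional[int] = None
    pair_id: str = ""


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated dataset."""

    records: list[TruthRecord]
    background_rate: float  # background reads per bp
    ext_len: int
    seed: int
    chrom: str = DEFAULT_CHROM
    chrom_len: int = DEFAULT_CHROM_LEN

    def all_positions(self) -> list[tuple[str, int]]:
        return [(r.chrom, p) for r in self.records for p in r.positions]

    def to_bed(self, path: str) -> None:
        """Truth as BED: one row per summit, pair id in the name column."""
        with open(path, "wt") as fh:
            for i, r in enumerate(self.records):
                name = r.pair_id or f"peak_{i}"
                for j, p in enumerate(r.positions):
                    sep = r.separation if r.separation is not None else -1
                    fh.write(
                        f"{r.chrom}\t{p}\t{p + 1}\t{name}/{j}\t{r.n_fragments}\t.\t{sep}\n"
                    )

    @classmethod
    def from_bed(
        cls, path: str, background_rate: float = 0.0,
        ext_len: int = DEFAULT_EXT_LEN, seed: int = 0,
        chrom_len: int = DEFAULT_CHROM_LEN,
    ) -> "SyntheticTruth":
        groups: dict[str, dict] = {}
        with open(path, "rt") as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                name = f[3].rsplit("/", 1)[0]
                g = groups.setdefault(
                    name,
                    {"chrom": f[0], "positions": [], "n": int(f[4]),
                     "sep": int(f[6]) if len(f) > 6 else -1},
                )
                g["positions"].append(int(f[1]))
        records = [
            TruthRecord(
                chrom=g["chrom"],
                positions=tuple(g["positions"]),
                n_fragments=g["n"],
                separation=g["sep"] if g["sep"] >= 0 else None,
                pair_id=name,
            )
            for name, g in groups.items()
        ]
        chrom = records[0].chrom if records else DEFAULT_CHROM
        return cls(records, background_rate, ext_len, seed, chrom, chrom_len)


@dataclass
class SyntheticDataset:
    """Treatment + control reads with their truth."""

    treatment: list[AlignedRead]
    control: list[AlignedRead]
    truth: SyntheticTruth
    separation: Optional[int] = None


@dataclass
class EvalReport:
    """Benchmark metrics for one dataset."""

    recall: float
    fpr: float
    spatial_errors: list[int] = field(default_factory=list)
    resolved_fraction: float = 0.0
    n_truth: int = 0
    n_calls: int = 0
    n_matched: int = 0


def _reads_from_fragment_starts(
    starts: np.ndarray,
    strands: np.ndarray,
    ext_len: int,
    read_len: int,
    chrom: str,
) -> list[AlignedRead]:
    """Emit the 5'-most ``read_len`` bases of each fragment as the read."""
    pos5 = np.where(strands, starts, starts + ext_len - 1)
    out = []
    for p, plus in zip(pos5.tolist(), strands.tolist()):
        out.append(AlignedRead(chrom, p, "+" if plus else "-", read_len))
    return out


def generate_background(
    chrom_len: int,
    n_reads: int,
    read_len: int = DEFAULT_READ_LEN,
    ext_len: int = DEFAULT_EXT_LEN,
    seed: int | np.random.Generator = 0,
    chrom: str = DEFAULT_CHROM,
) -> tuple[list[AlignedRead], SyntheticTruth]:
    """Uniform background reads; fragments never hang off the chromosome.

    Fragment starts are uniform over the positions where the full
    ``ext_len`` fragment fits (equivalent to redrawing clipped
    fragments); strands are a fair coin.
    """
    if chrom_len < ext_len:
        raise ValueError(
            f"chromosome length {chrom_len} is shorter than ext_len {ext_len}"
        )
    if n_reads < 0:
        raise ValueError(f"n_reads must be >= 0, got {n_reads}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = rng.integers(0, chrom_len - ext_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads).astype(bool)
    reads = _reads_from_fragment_starts(starts, strands, ext_len, read_len, chrom)
    seed_val = seed if isinstance(seed, int) else -1
    truth = SyntheticTruth(
        records=[],
        background_rate=n_reads / chrom_len,
        ext_len=ext_len,
        seed=seed_val,
        chrom=chrom,
        chrom_len=chrom_len,
    )
    return reads, truth


def spike_peak(
    center: int,
    n_fragments: int,
    ext_len: int = DEFAULT_EXT_LEN,
    read_len: int = DEFAULT_READ_LEN,
    seed: int | np.random.Generator = 0,
    chrom: str = DEFAULT_CHROM,
    chrom_len: int = DEFAULT_CHROM_LEN,
) -> list[AlignedRead]:
    """Reads of a point-source binding peak centred at ``center``.

    Every fragment covers ``center`` (starts uniform over
    ``(center - ext_len, center]``), so raw fragment coverage at the
    center equals ``n_fragments`` exactly.
    """
    if not (ext_len <= center <= chrom_len - ext_len):
        raise ValueError(
            f"peak center {center} must lie in [{ext_len}, {chrom_len - ext_len}]"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = rng.integers(center - ext_len + 1, center + 1, size=n_fragments)
    strands = rng.integers(0, 2, size=n_fragments).astype(bool)
    return _reads_from_fragment_starts(starts, strands, ext_len, read_len, chrom)


def _spaced_anchors(
    n: int, chrom_len: int, ext_len: int, extra_span: int
) -> list[int]:
    """Evenly spaced anchors, >= MIN_ANCHOR_SPACING apart, clear of both ends."""
    margin = 2 * ext_len + MIN_ANCHOR_SPACING // 2
    usable = chrom_len - 2 * margin - extra_span
    if n < 1:
        raise ValueError("need at least one anchor")
    spacing = usable / max(n - 1, 1) if n > 1 else 0
    if n > 1 and spacing < MIN_ANCHOR_SPACING + extra_span:
        raise ValueError(
            f"{n} anchors on a {chrom_len} bp chromosome would collide "
            f"(spacing {spacing:.0f} < {MIN_ANCHOR_SPACING + extra_span} bp)"
        )
    return [margin + round(i * spacing) for i in range(n)]


def generate_spiked_dataset(
    n_peaks: int = 100,
    frags_per_peak: int = DEFAULT_FRAGS_PER_PEAK,
    chrom_len: int = DEFAULT_CHROM_LEN,
    n_bg_reads: int = DEFAULT_N_BG_READS,
    read_len: int = DEFAULT_READ_LEN,
    ext_len: int = DEFAULT_EXT_LEN,
    seed: int = 0,
    chrom: str = DEFAULT_CHROM,
) -> SyntheticDataset:
    """Single-summit specificity benchmark: spiked peaks on uniform background.

    The control is an independent background with the same total read
    count as the treatment.
    """
    rng = np.random.default_rng([seed, 1])
    bg_reads, truth = generate_background(
        chrom_len, n_bg_reads, read_len, ext_len, rng, chrom
    )
    centers = _spaced_anchors(n_peaks, chrom_len, ext_len, extra_span=0)
    records = []
    treatment = list(bg_reads)
    for i, c in enumerate(centers):
        treatment.extend(
            spike_peak(c, frags_per_peak, ext_len, read_len, rng, chrom, chrom_len)
        )
        records.append(
            TruthRecord(chrom, (c,), frags_per_peak, pair_id=f"peak_{i}")
        )
    truth.records = records
    truth.seed = seed
    control, _ = generate_background(
        chrom_len, len(treatment), read_len, ext_len,
        np.random.default_rng([seed, 2]), chrom,
    )
    return SyntheticDataset(treatment, control, truth)


def generate_paired_series(
    separations: Sequence[int] = DEFAULT_SEPARATIONS,
    pairs_per_dataset: int = 1000,
    n_fragments_per_peak: int = DEFAULT_FRAGS_PER_PEAK,
    chrom_len: int = DEFAULT_CHROM_LEN,
    n_bg_reads: int = DEFAULT_N_BG_READS,
    read_len: int = DEFAULT_READ_LEN,
    ext_len: int = DEFAULT_EXT_LEN,
    seed: int = 0,
    chrom: str = DEFAULT_CHROM,
) -> list[SyntheticDataset]:
    """Inter-peak resolution series: one dataset per pair separation.

    Each dataset is a uniform background plus ``pairs_per_dataset``
    peak pairs at the given separation (anchors >= 5 kb apart); its
    control is an independent background with the same total read count
    as the treatment.
    """
    datasets = []
    for d_idx, sep in enumerate(separations):
        if sep <= 0:
            raise ValueError(f"pair separation must be > 0, got {sep}")
        rng = np.random.default_rng([seed, 10 + d_idx])
        bg_reads, truth = generate_background(
            chrom_len, n_bg_reads, read_len, ext_len, rng, chrom
        )
        anchors = _spaced_anchors(pairs_per_dataset, chrom_len, ext_len, sep)
        treatment = list(bg_reads)
        records = []
        for i, a in enumerate(anchors):
            for p in (a, a + sep):
                treatment.extend(
                    spike_peak(
                        p, n_fragments_per_peak, ext_len, read_len, rng, chrom,
                        chrom_len,
                    )
                )
            records.append(
                TruthRecord(
                    chrom, (a, a + sep), n_fragments_per_peak,
                    separation=sep, pair_id=f"pair_{i}",
                )
            )
        truth.records = records
        truth.seed = seed
        control, _ = generate_background(
            chrom_len, len(treatment), read_len, ext_len,
            np.random.default_rng([seed, 1000 + d_idx]), chrom,
        )
        datasets.append(SyntheticDataset(treatment, control, truth, separation=sep))
    return datasets


def summit_positions(regions: Iterable[CandidateRegion]) -> list[tuple[str, int]]:
    """Flatten called regions into (chrom, summit position) tuples."""
    return [(r.chrom, s.pos) for r in regions for s in r.summits]


def evaluate_calls(
    calls: Sequence[tuple[str, int]],
    truth: SyntheticTruth,
    match_dist: int = 100,
) -> EvalReport:
    """Greedy one-to-one matching of called summits to truth positions.

    Candidate (call, truth) pairs within ``match_dist`` are assigned in
    order of increasing distance; each call and each truth position is
    used at most once.  Recall counts matched truth positions, fpr
    counts calls matching nothing, and a pair is resolved iff both of
    its truth summits are matched (necessarily by distinct calls).
    """
    truth_items = [
        (r_idx, p_idx, r.chrom, p)
        for r_idx, r in enumerate(truth.records)
        for p_idx, p in enumerate(r.positions)
    ]
    n_truth = len(truth_items)
    n_calls = len(calls)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c_idx, (chrom, pos) in enumerate(calls):
        by_chrom.setdefault(chrom, []).append((pos, c_idx))
    for lst in by_chrom.values():
        lst.sort()

    pairs: list[tuple[int, int, int]] = []  # (distance, call_idx, truth_item_idx)
    for t_idx, (_, _, chrom, pos) in enumerate(truth_items):
        lst = by_chrom.get(chrom)
        if not lst:
            continue
        positions = [p for p, _ in lst]
        lo = np.searchsorted(positions, pos - match_dist, side="left")
        hi = np.searchsorted(positions, pos + match_dist, side="right")
        for p, c_idx in lst[lo:hi]:
            pairs.append((abs(p - pos), c_idx, t_idx))
    pairs.sort()

    call_used = [False] * n_calls
    truth_used = [False] * n_truth
    matched: list[tuple[int, int, int]] = []
    for dist, c_idx, t_idx in pairs:
        if call_used[c_idx] or truth_used[t_idx]:
            continue
        call_used[c_idx] = True
        truth_used[t_idx] = True
        matched.append((dist, c_idx, t_idx))

    n_matched = len(matched)
    matched_per_record: dict[int, set[int]] = {}
    for _, _, t_idx in matched:
        r_idx, p_idx = truth_items[t_idx][0], truth_items[t_idx][1]
        matched_per_record.setdefault(r_idx, set()).add(p_idx)
    pair_records = [
        i for i, r in enumerate(truth.records) if len(r.positions) == 2
    ]
    resolved = sum(
        1 for i in pair_records if len(matched_per_record.get(i, ())) == 2
    )
    return EvalReport(
        recall=n_matched / n_truth if n_truth else 0.0,
        fpr=(n_calls - n_matched) / n_calls if n_calls else 0.0,
        spatial_errors=sorted(d for d, _, _ in matched),
        resolved_fraction=resolved / len(pair_records) if pair_records else 0.0,
        n_truth=n_truth,
        n_calls=n_calls,
        n_matched=n_matched,
    )


def run_caller_on_dataset(
    dataset: SyntheticDataset,
    config: Optional[CallerConfig] = None,
    use_control: bool = True,
) -> list[CandidateRegion]:
    """Run the peak caller in memory on a generated dataset."""
    if config is None:
        config = apply_preset("resolution")
    table = ChromTable(
        {dataset.truth.chrom: dataset.truth.chrom_len}, provenance="precomputed"
    )
    treat_profile = build_coverage(dataset.treatment, config.ext_len, table)
    ctrl_profile = (
        build_coverage(dataset.control, config.ext_len, table)
        if use_control and dataset.control
        else None
    )
    regions, _ = call_peaks(treat_profile, ctrl_profile, config)
    return regions


def resolution_curve(
    series: list[SyntheticDataset],
    caller_runner: Optional[
        Callable[[SyntheticDataset], list[CandidateRegion]]
    ] = None,
    match_dist: int = 100,
) -> list[tuple[int, float, float]]:
    """(separation, resolved_fraction, fpr) per dataset, ordered by separation.

    The default runner calls peaks in resolution mode with the control.
    """
    if caller_runner is None:
        caller_runner = run_caller_on_dataset
    rows = []
    for ds in sorted(series, key=lambda d: d.separation or 0):
        regions = caller_runner(ds)
        report = evaluate_calls(summit_positions(regions), ds.truth, match_dist)
        rows.append((ds.separation, report.resolved_fraction, report.fpr))
    return rows
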