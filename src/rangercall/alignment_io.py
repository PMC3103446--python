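"""Aligned-read input, chromosome tables, and wiggle/peak output.

All internal coordinates are 0-based half-open.  SAM/BAM's 1-based input
and the wiggle format's 1-based output are converted at the boundary, so
no other module ever sees a 1-based coordinate.

Supported alignment formats: BED6, SAM, BAM (via pysam), plus thin
column-mapped readers for the legacy Bowtie and Eland text dialects.
"""

from __future__ import annotations

import gzip
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO

import numpy as np
import pysam

FORMATS = ("bed", "sam", "bam", "bowtie", "eland")

_EXT_MAP = {
    ".bed": "bed",
    ".sam": "sam",
    ".bam": "bam",
    ".bowtie": "bowtie",
    ".bwt": "bowtie",
    ".eland": "eland",
}


class FormatError(ValueError):
    """Unresolvable or malformed input format."""


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One mapped read reduced to what peak calling needs.

    ``pos5`` is the 0-based coordinate of the read's 5'-most aligned
    base: the leftmost base for + reads, the rightmost for - reads.
    """

    chrom: str
    pos5: int
    strand: str  # "+" or "-"
    read_len: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.read_len < 1:
            raise ValueError(f"read_len must be >= 1, got {self.read_len}")


@dataclass
class ParseStats:
    """Bookkeeping for one parsing pass."""

    n_parsed: int = 0
    n_skipped: int = 0  # unmapped or (lenient mode) malformed
    chroms: set[str] = field(default_factory=set)


@dataclass
class ChromTable:
    """Ordered map of chromosome name -> length, sorted lexicographically."""

    lengths: dict[str, int]
    provenance: str  # "derived_from_reads" | "precomputed"

    def __post_init__(self) -> None:
        items = sorted(self.lengths.items())
        for name, length in items:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has length {length} < 1")
        self.lengths = dict(items)

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    def items(self):
        return self.lengths.items()

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


def resolve_format(path: str, fmt: str = "auto") -> str:
    """Resolve an alignment format; an explicit ``fmt`` wins over the extension."""
    if fmt != "auto":
        if fmt not in FORMATS:
            raise FormatError(
                f"unknown format {fmt!r}; accepted formats: {', '.join(FORMATS)}"
            )
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext == ".gz":
        ext = os.path.splitext(path[: -len(".gz")])[1].lower()
    if ext not in _EXT_MAP:
        raise FormatError(
            f"cannot infer alignment format of {path!r} from its extension; "
            f"accepted formats: {', '.join(FORMATS)}"
        )
    return _EXT_MAP[ext]


def _open_text(path: str) -> TextIO:
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_bed(path: str, stats: ParseStats, lenient: bool) -> Iterator[AlignedRead]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                strand = fields[5] if len(fields) >= 6 else "+"
                if strand not in ("+", "-"):
                    raise ValueError(f"bad strand {strand!r}")
                if end <= start:
                    raise ValueError(f"empty interval [{start},{end})")
                pos5 = start if strand == "+" else end - 1
                read = AlignedRead(chrom, pos5, strand, end - start)
            except (IndexError, ValueError) as exc:
                if lenient:
                    stats.n_skipped += 1
                    continue
                raise FormatError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            stats.n_parsed += 1
            stats.chroms.add(chrom)
            yield read


def _parse_sam_bam(path: str, mode: str, stats: ParseStats) -> Iterator[AlignedRead]:
    open_mode = "rb" if mode == "bam" else "r"
    with pysam.AlignmentFile(path, open_mode, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.reference_id < 0:
                stats.n_skipped += 1
                continue
            rlen = rec.reference_length
            if not rlen:
                stats.n_skipped += 1
                continue
            chrom = rec.reference_name
            if rec.is_reverse:
                read = AlignedRead(chrom, rec.reference_end - 1, "-", rlen)
            else:
                read = AlignedRead(chrom, rec.reference_start, "+", rlen)
            stats.n_parsed += 1
            stats.chroms.add(chrom)
            yield read


def _parse_bowtie(path: str, stats: ParseStats, lenient: bool) -> Iterator[AlignedRead]:
    # Bowtie default output: name, strand, chrom, 0-based leftmost offset,
    # sequence, qualities, ... (tab-separated).
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                strand = fields[1]
                if strand not in ("+", "-"):
                    raise ValueError(f"bad strand {strand!r}")
                chrom = fields[2]
                left = int(fields[3])
                rlen = len(fields[4])
                if rlen < 1:
                    raise ValueError("empty sequence")
                pos5 = left if strand == "+" else left + rlen - 1
                read = AlignedRead(chrom, pos5, strand, rlen)
            except (IndexError, ValueError) as exc:
                if lenient:
                    stats.n_skipped += 1
                    continue
                raise FormatError(
                    f"{path}:{lineno}: malformed Bowtie line: {exc}"
                ) from exc
            stats.n_parsed += 1
            stats.chroms.add(chrom)
            yield read


def _parse_eland(path: str, stats: ParseStats, lenient: bool) -> Iterator[AlignedRead]:
    # Eland "sorted"-style columns: name, sequence, match type, ...,
    # chrom, 1-based position, strand (F/R).  Only unique matches (U0/U1/U2)
    # carry coordinates; everything else is skipped as unmapped.
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                match_type = fields[2]
                if not match_type.startswith("U"):
                    stats.n_skipped += 1
                    continue
                seq = fields[1]
                chrom = fields[6]
                left = int(fields[7]) - 1  # Eland positions are 1-based
                sense = fields[8]
                if sense not in ("F", "R"):
                    raise ValueError(f"bad strand {sense!r}")
                rlen = len(seq)
                if rlen < 1:
                    raise ValueError("empty sequence")
                if sense == "F":
                    read = AlignedRead(chrom, left, "+", rlen)
                else:
                    read = AlignedRead(chrom, left + rlen - 1, "-", rlen)
            except (IndexError, ValueError) as exc:
                if lenient:
                    stats.n_skipped += 1
                    continue
                raise FormatError(
                    f"{path}:{lineno}: malformed Eland line: {exc}"
                ) from exc
            stats.n_parsed += 1
            stats.chroms.add(chrom)
            yield read


def parse_alignments(
    path: str,
    fmt: str = "auto",
    lenient: bool = False,
    stats: Optional[ParseStats] = None,
) -> Iterator[AlignedRead]:
    """Stream :class:`AlignedRead` records from an alignment file.

    Unmapped records are skipped and counted.  Malformed lines are a
    fatal :class:`FormatError` naming the line number, unless
    ``lenient`` is set, in which case they are skipped and counted.
    Pass a :class:`ParseStats` to receive parsed/skipped counts and the
    observed chromosome name set.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"alignment file not found: {path}")
    fmt = resolve_format(path, fmt)
    if stats is None:
        stats = ParseStats()
    if fmt == "bed":
        return _parse_bed(path, stats, lenient)
    if fmt in ("sam", "bam"):
        return _parse_sam_bam(path, fmt, stats)
    if fmt == "bowtie":
        return _parse_bowtie(path, stats, lenient)
    return _parse_eland(path, stats, lenient)


def read_end(read: AlignedRead) -> int:
    """0-based exclusive right end of the aligned bases."""
    return read.pos5 + read.read_len if read.strand == "+" else read.pos5 + 1


def derive_chrom_table(reads: Iterable[AlignedRead], slack: int = 0) -> ChromTable:
    """Derive a chromosome table from the reads themselves.

    Each length is the maximum observed read end plus ``slack``.
    """
    lengths: dict[str, int] = {}
    for r in reads:
        end = read_end(r)
        if end > lengths.get(r.chrom, 0):
            lengths[r.chrom] = end
    if not lengths:
        raise ValueError("cannot derive a chromosome table from zero reads")
    return ChromTable(
        {c: length + slack for c, length in lengths.items()},
        provenance="derived_from_reads",
    )


def load_chrom_table(path: str) -> ChromTable:
    """Load a UCSC chrom.sizes-style two-column table (name<TAB>length)."""
    lengths: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two fields, got {len(fields)}"
                )
            name, raw_len = fields
            if name in lengths:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            try:
                length = int(raw_len)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {raw_len!r}"
                ) from exc
            if length < 1:
                raise FormatError(f"{path}:{lineno}: length must be >= 1, got {length}")
            lengths[name] = length
    if not lengths:
        raise FormatError(f"{path}: empty chromosome table")
    return ChromTable(lengths, provenance="precomputed")


def write_wiggle(profile, path: str, compress: bool = False, span: int = 1) -> None:
    """Write a coverage profile as UCSC variableStep wiggle.

    Positions are 1-based; zero-coverage positions are omitted.  With
    ``compress`` the identical text is gzip-compressed.
    """
    lines: list[str] = []
    for chrom in sorted(profile.chroms()):
        arr = profile[chrom]
        lines.append(f"variableStep chrom={chrom} span={span}")
        nz = np.flatnonzero(arr)
        for i in nz:
            lines.append(f"{i + 1} {arr[i]}")
    text = "\n".join(lines) + "\n"
    if compress:
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        with open(path, "wt") as fh:
            fh.write(text)


PEAK_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tp_value\tq_value\t"
    "max_height\tsummit_pos\tsummit_height"
)

_SCORE_CAP = 330.0


def qvalue_score(q: float) -> float:
    """-log10(q), capped at 330 (q == 0 maps to the cap)."""
    if q <= 0:
        return _SCORE_CAP
    return min(_SCORE_CAP, -math.log10(q))


def write_peaks(calls, path: str, mode: str = "region") -> None:
    """Write called regions as a tab-delimited, BED6-prefixed peak table.

    One row per region in ``region`` mode (the highest summit is
    reported); one row per summit in ``resolution`` mode.  Callers must
    pass regions sorted by (chrom, start).
    """
    with open(path, "wt") as fh:
        fh.write(PEAK_HEADER + "\n")
        for region in calls:
            score = qvalue_score(region.q_value)
            base = (
                f"{region.chrom}\t{region.start}\t{region.end}\t{region.name}\t"
                f"{score:.5g}\t.\t{region.p_value:.6g}\t{region.q_value:.6g}\t"
                f"{region.max_height:.6g}"
            )
            summits = region.summits or []
            if mode == "resolution" and summits:
                for s in summits:
                    fh.write(f"{base}\t{s.pos}\t{s.height:.6g}\n")
            elif summits:
                top = max(summits, key=lambda s: (s.height, -s.pos))
                fh.write(f"{base}\t{top.pos}\t{top.height:.6g}\n")
            else:
                fh.write(f"{base}\t-1\t0\n")


def write_reads_bed(reads: Iterable[AlignedRead], path: str) -> None:
    """Serialize reads as BED6 (round-trips exactly through the BED parser)."""
    with open(path, "wt") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                start, end = r.pos5, r.pos5 + r.read_len
            else:
                start, end = r.pos5 - r.read_len + 1, r.pos5 + 1
            fh.write(f"{r.chrom}\t{start}\t{end}\tr{i}\t0\t{r.strand}\n")
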