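import numpy as np
import pysam
import pytest

from rangercall.alignment_io import AlignedRead, ChromTable


@pytest.fixture
def chrom_table():
    return ChromTable({"chr1": 1000, "chr2": 500}, provenance="precomputed")


@pytest.fixture
def bed_file(tmp_path):
    """Write reads as BED6 and return the path factory."""

    def _write(reads, name="reads.bed"):
        path = tmp_path / name
        with open(path, "wt") as fh:
            for i, r in enumerate(reads):
                if r.strand == "+":
                    s, e = r.pos5, r.pos5 + r.read_len
                else:
                    s, e = r.pos5 - r.read_len + 1, r.pos5 + 1
                fh.write(f"{r.chrom}\t{s}\t{e}\tr{i}\t0\t{r.strand}\n")
        return str(path)

    return _write


@pytest.fixture
def sam_file(tmp_path):
    """Write reads as SAM (with matching @SQ header) and return the path."""

    def _write(reads, chrom_lengths, name="reads.sam"):
        path = tmp_path / name
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chrom_lengths.items())],
        }
        tid = {c: i for i, (c, _) in enumerate(sorted(chrom_lengths.items()))}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i, r in enumerate(reads):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"r{i}"
                a.reference_id = tid[r.chrom]
                a.query_sequence = "A" * r.read_len
                a.cigarstring = f"{r.read_len}M"
                a.mapping_quality = 30
                if r.strand == "+":
                    a.reference_start = r.pos5
                else:
                    a.reference_start = r.pos5 - r.read_len + 1
                    a.flag = 16
                out.write(a)
        return str(path)

    return _write


def random_reads(rng, n, chroms=("chr1", "chr2"), chrom_len=1000, read_len=36):
    reads = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        strand = "+" if rng.integers(0, 2) else "-"
        if strand == "+":
            pos5 = int(rng.integers(0, chrom_len - read_len))
        else:
            pos5 = int(rng.integers(read_len - 1, chrom_len - 1))
        reads.append(AlignedRead(chrom, pos5, strand, read_len))
    return reads
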