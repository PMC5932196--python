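"""Shared fixtures: in-memory read views, handmade BAM/VCF builders, and
session-scoped simulated datasets."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pysam
import pytest
from hypothesis import settings

from haplosweep import SimConfig, simulate

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


class FakeReadView:
    """Duck-typed stand-in for AlignedReadView: bases given explicitly."""

    def __init__(self, accession_id, bases, name="r", is_proper_pair=False):
        self.accession_id = accession_id
        self.read_name = name
        self.is_read1 = True
        self.is_read2 = False
        self.mapq = 60
        self.is_proper_pair = is_proper_pair
        self._bases = dict(bases)
        positions = sorted(self._bases) or [1]
        self.reference_start = positions[0]
        self.reference_end = positions[-1]

    def base_at(self, pos):
        return self._bases.get(pos)


def write_vcf(path: Path, records, contigs=("chr1",)) -> Path:
    """records: iterable of (chrom, pos, ref, alt_string)."""
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length=1000000>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, ref, alt in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_bam(path: Path, reads, ref_name="chr1", ref_length=100_000) -> Path:
    """reads: iterable of dicts with keys name, start (0-based), seq and
    optional cigar, flag, mapq, qual, next_start, tlen."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": ref_length}],
    }
    reads = sorted(reads, key=lambda r: r["start"])
    with pysam.AlignmentFile(str(path), "wb", header=header) as af:
        for r in reads:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = r["name"]
            seg.flag = r.get("flag", 0)
            seg.reference_id = 0
            seg.reference_start = r["start"]
            seg.mapping_quality = r.get("mapq", 60)
            seg.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
            seg.query_sequence = r["seq"]
            seg.query_qualities = r.get("qual", [40] * len(r["seq"]))
            if seg.flag & 0x1:
                seg.next_reference_id = 0
                seg.next_reference_start = r.get("next_start", r["start"])
                seg.template_length = r.get("tlen", 0)
            af.write(seg)
    pysam.index(str(path))
    return path


@pytest.fixture(scope="session")
def sim_default(tmp_path_factory):
    """One simulation at the default study conditions (seed 11)."""
    out = tmp_path_factory.mktemp("sim_default")
    return simulate(SimConfig(seed=11), out)


@pytest.fixture(scope="session")
def sim_clean(tmp_path_factory):
    """Error-free simulation (seed 7): every observation reflects the truth."""
    out = tmp_path_factory.mktemp("sim_clean")
    config = dataclasses.replace(SimConfig(seed=7), error_rate=0.0)
    return simulate(config, out)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """Small, fast simulation for oracle comparisons (seed 3)."""
    out = tmp_path_factory.mktemp("sim_small")
    config = dataclasses.replace(
        SimConfig(seed=3), ancestor_length=4000, n_snps=8, coverage=10.0
    )
    return simulate(config, out)
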