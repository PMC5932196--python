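"""Truth-tabled allotetraploid read simulation and evaluation utilities.

The simulator emulates the collapsed-mapping situation that confounds SNP
calling in allopolyploids: an allotetraploid carries two diverged copies
(subgenomes A and B) of a common ancestral sequence, and short reads from
both subgenomes align to the same coordinates of a single reference.
Positions where the subgenomes differ (homeolog sites) then masquerade as
SNPs in every accession, while true inter-accession polymorphisms sit on
one subgenome of some accessions only.

Generation is substitution-only, so the collapsed alignment is positional
and exact: reads are written with all-match CIGARs at their true origin
(MAPQ 60), which makes every downstream observation attributable to the
truth table rather than to mapping noise.  A candidate-site caller (any
position where at least two bases are each seen at least twice across all
accessions) stands in for samtools mpileup, producing the guide VCF the
discovery pipeline consumes.

Default parameters describe a desk-scale experiment: a 20 kb ancestor,
1% homeolog divergence, three accessions, forty accession-specific
subgenome-A SNPs spiked within 140 bp of an anchor, paired 2x150 bp reads
at 20-fold coverage per subgenome with a 0.2% base error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .filters import MarkerCall
from .io import CandidateSite

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

REF_NAME = "chr1"
SIM_MAPQ = 60
SIM_BASEQ = 40


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated allotetraploid sequencing experiment.

    ``seed`` is mandatory: every draw flows from one generator so identical
    configurations produce byte-identical outputs.  ``coverage`` is the
    fold coverage *per subgenome* (an accession's total depth is twice it).
    ``n_snps`` spikes that many accession-specific subgenome-A SNPs, each
    placed within ``snp_anchor_dist`` bases of a homeolog site; set it to
    None to draw SNPs per base at ``snp_rate`` instead.
    """

    seed: int
    ancestor_length: int = 20_000
    homeolog_divergence: float = 0.01
    n_accessions: int = 3
    n_snps: int | None = 40
    snp_anchor_dist: int = 140
    snp_rate: float = 0.0
    read_length: int = 150
    coverage: float = 20.0
    error_rate: float = 0.002
    paired: bool = True
    insert_mean: int = 500
    insert_sd: int = 50

    def validate(self) -> None:
        for name in ("homeolog_divergence", "snp_rate", "error_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if self.ancestor_length < self.read_length:
            raise ConfigError("ancestor_length must be >= read_length")
        if self.n_accessions < 1:
            raise ConfigError("n_accessions must be >= 1")
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")
        if self.n_snps is not None and self.n_snps < 0:
            raise ConfigError("n_snps must be >= 0")
        if self.snp_anchor_dist < 1:
            raise ConfigError("snp_anchor_dist must be >= 1")
        if self.paired:
            if self.insert_mean < 2 * self.read_length:
                raise ConfigError("insert_mean must be >= 2 * read_length")
            if self.ancestor_length < 2 * self.read_length:
                raise ConfigError("ancestor_length too short for paired reads")


@dataclass(frozen=True)
class AccessionSnp:
    """One spiked accession-specific SNP on a subgenome."""

    accession: str
    pos: int  # 1-based
    subgenome: str
    ref_base: str
    alt_base: str


@dataclass
class TruthTable:
    """Ground truth of one simulation.

    ``homeolog_sites`` maps 1-based position to (subgenome A base,
    subgenome B base) — the anchors.  ``accession_snps`` lists the spiked
    inter-accession polymorphisms.  The two sets are positionally disjoint.
    """

    homeolog_sites: dict[int, tuple[str, str]]
    accession_snps: list[AccessionSnp]

    @property
    def anchor_positions(self) -> set[int]:
        return set(self.homeolog_sites)

    @property
    def snp_positions(self) -> set[int]:
        return {s.pos for s in self.accession_snps}

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        anchors = out / "truth_homeolog_sites.tsv"
        lines = ["pos\tsubgenome_a\tsubgenome_b"]
        lines += [
            f"{pos}\t{a}\t{b}"
            for pos, (a, b) in sorted(self.homeolog_sites.items())
        ]
        anchors.write_text("\n".join(lines) + "\n")
        snps = out / "truth_accession_snps.tsv"
        lines = ["accession\tpos\tsubgenome\tref_base\talt_base"]
        lines += [
            f"{s.accession}\t{s.pos}\t{s.subgenome}\t{s.ref_base}\t{s.alt_base}"
            for s in sorted(self.accession_snps, key=lambda s: (s.pos, s.accession))
        ]
        snps.write_text("\n".join(lines) + "\n")
        return anchors, snps

    @classmethod
    def read(cls, truth_dir: str | Path) -> "TruthTable":
        out = Path(truth_dir)
        homeolog: dict[int, tuple[str, str]] = {}
        with open(out / "truth_homeolog_sites.tsv") as fh:
            fh.readline()
            for line in fh:
                pos, a, b = line.rstrip("\n").split("\t")
                homeolog[int(pos)] = (a, b)
        snps: list[AccessionSnp] = []
        with open(out / "truth_accession_snps.tsv") as fh:
            fh.readline()
            for line in fh:
                acc, pos, sub, ref, alt = line.rstrip("\n").split("\t")
                snps.append(AccessionSnp(acc, int(pos), sub, ref, alt))
        return cls(homeolog, snps)


@dataclass
class SimResult:
    """Paths and truth emitted by :func:`simulate`."""

    out_dir: Path
    config: SimConfig
    bam_paths: dict[str, Path]
    vcf_path: Path
    reference_path: Path
    truth: TruthTable


def make_genomes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], TruthTable]:
    """Draw the ancestor, subgenome B, per-accession subgenome A, and truth.

    Returned genomes are base-index arrays (0..3 for A/C/G/T).
    """
    L = config.ancestor_length
    ancestor = rng.integers(0, 4, L, dtype=np.int8)

    div_mask = rng.random(L) < config.homeolog_divergence
    sub_b = ancestor.copy()
    n_div = int(div_mask.sum())
    if n_div:
        sub_b[div_mask] = (
            ancestor[div_mask] + rng.integers(1, 4, n_div, dtype=np.int8)
        ) % 4
    anchors0 = np.flatnonzero(sub_b != ancestor)

    snps: list[AccessionSnp] = []
    taken: set[int] = set(anchors0.tolist())
    acc_ids = [f"acc{i + 1}" for i in range(config.n_accessions)]
    sub_a = [ancestor.copy() for _ in acc_ids]

    if config.n_snps:
        if anchors0.size == 0:
            raise ConfigError(
                "cannot place anchor-adjacent SNPs with zero homeolog divergence"
            )
        placed = 0
        attempts = 0
        while placed < config.n_snps:
            attempts += 1
            if attempts > 200 * config.n_snps:
                raise ConfigError(
                    "could not place the requested number of SNPs; "
                    "increase ancestor_length or homeolog_divergence"
                )
            anchor = int(anchors0[rng.integers(anchors0.size)])
            offset = int(rng.integers(1, config.snp_anchor_dist + 1))
            if rng.random() < 0.5:
                offset = -offset
            pos = anchor + offset
            if not 0 <= pos < L or pos in taken:
                continue
            acc_i = int(rng.integers(config.n_accessions))
            alt = int((ancestor[pos] + rng.integers(1, 4)) % 4)
            sub_a[acc_i][pos] = alt
            taken.add(pos)
            snps.append(
                AccessionSnp(
                    accession=acc_ids[acc_i],
                    pos=pos + 1,
                    subgenome="A",
                    ref_base=_BASES[ancestor[pos]],
                    alt_base=_BASES[alt],
                )
            )
            placed += 1
    elif config.snp_rate > 0:
        for acc_i, acc in enumerate(acc_ids):
            snp_mask = rng.random(L) < config.snp_rate
            for pos in np.flatnonzero(snp_mask):
                pos = int(pos)
                if pos in taken:
                    continue
                alt = int((ancestor[pos] + rng.integers(1, 4)) % 4)
                sub_a[acc_i][pos] = alt
                taken.add(pos)
                snps.append(
                    AccessionSnp(
                        accession=acc,
                        pos=pos + 1,
                        subgenome="A",
                        ref_base=_BASES[ancestor[pos]],
                        alt_base=_BASES[alt],
                    )
                )

    snps.sort(key=lambda s: (s.pos, s.accession))
    truth = TruthTable(
        homeolog_sites={
            int(p) + 1: (_BASES[ancestor[p]], _BASES[sub_b[p]])
            for p in anchors0
        },
        accession_snps=snps,
    )
    return ancestor, sub_b, sub_a, truth


@dataclass
class _SimRead:
    name: str
    start: int  # 0-based
    seq: np.ndarray
    flag: int
    mate_start: int
    tlen: int


def _reads_from_genome(
    genome: np.ndarray,
    label: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[_SimRead]:
    L = config.ancestor_length
    rl = config.read_length
    reads: list[_SimRead] = []

    def _seq(start: int) -> np.ndarray:
        seq = genome[start : start + rl].copy()
        if config.error_rate > 0:
            err = rng.random(rl) < config.error_rate
            n_err = int(err.sum())
            if n_err:
                seq[err] = (seq[err] + rng.integers(1, 4, n_err, dtype=np.int8)) % 4
        return seq

    if config.paired:
        n_frag = max(1, round(config.coverage * L / (2 * rl)))
        for k in range(n_frag):
            insert = int(
                np.clip(
                    round(rng.normal(config.insert_mean, config.insert_sd)),
                    2 * rl,
                    L,
                )
            )
            start = int(rng.integers(0, L - insert + 1))
            mate_start = start + insert - rl
            name = f"{label}_{k}"
            # paired, proper, mate-reverse, first in pair
            reads.append(_SimRead(name, start, _seq(start), 0x63, mate_start, insert))
            # paired, proper, reverse, second in pair
            reads.append(
                _SimRead(name, mate_start, _seq(mate_start), 0x93, start, -insert)
            )
    else:
        n_reads = max(1, round(config.coverage * L / rl))
        for k in range(n_reads):
            start = int(rng.integers(0, L - rl + 1))
            reads.append(_SimRead(f"{label}_{k}", start, _seq(start), 0, -1, 0))
    return reads


def _write_bam(path: Path, reads: list[_SimRead], ref_length: int, rl: int) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": REF_NAME, "LN": ref_length}],
    }
    reads = sorted(reads, key=lambda r: (r.start, r.name, r.flag))
    quals = [SIM_BASEQ] * rl
    with pysam.AlignmentFile(str(path), "wb", header=header) as af:
        for r in reads:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = r.name
            seg.flag = r.flag
            seg.reference_id = 0
            seg.reference_start = r.start
            seg.mapping_quality = SIM_MAPQ
            seg.cigartuples = [(0, len(r.seq))]
            seg.query_sequence = "".join(_BASES[i] for i in r.seq)
            seg.query_qualities = quals
            if r.flag & 0x1:
                seg.next_reference_id = 0
                seg.next_reference_start = r.mate_start
                seg.template_length = r.tlen
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            af.write(seg)
    pysam.index(str(path))


def _write_vcf(
    path: Path, ancestor: np.ndarray, counts: np.ndarray, min_count: int = 2
) -> int:
    """Candidate-site stand-in for mpileup.

    A position is a candidate when at least two distinct bases each have
    ``min_count`` or more supporting reads summed over all accessions.
    REF is the reference (ancestor) base; ALT lists the other qualifying
    bases.  Returns the number of records written.
    """
    qualifying = counts >= min_count
    cand = np.flatnonzero(qualifying.sum(axis=0) >= 2)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={REF_NAME},length={ancestor.size}>",
        "##INFO=<ID=DP,Number=1,Type=Integer,Description=\"Total read depth\">",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    n = 0
    for p in cand:
        ref_i = int(ancestor[p])
        alts = [_BASES[b] for b in range(4) if qualifying[b, p] and b != ref_i]
        if not alts:
            continue
        depth = int(counts[:, p].sum())
        lines.append(
            f"{REF_NAME}\t{int(p) + 1}\t.\t{_BASES[ref_i]}\t{','.join(alts)}"
            f"\t.\t.\tDP={depth}"
        )
        n += 1
    path.write_text("\n".join(lines) + "\n")
    return n


def simulate(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Run one simulation and write BAMs, candidate VCF, truth and reference.

    Reads are sampled from both subgenomes of every accession at
    ``config.coverage`` fold each and written as coordinate-sorted, indexed
    BAM alignments against the ancestor coordinate system.  All outputs
    are reproducible byte-for-byte from ``config.seed``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    ancestor, sub_b, sub_a, truth = make_genomes(config, rng)
    L = config.ancestor_length

    counts = np.zeros((4, L), dtype=np.int32)
    bam_paths: dict[str, Path] = {}
    acc_ids = [f"acc{i + 1}" for i in range(config.n_accessions)]
    for acc_i, acc in enumerate(acc_ids):
        acc_reads: list[_SimRead] = []
        for sub_label, genome in (("A", sub_a[acc_i]), ("B", sub_b)):
            acc_reads.extend(
                _reads_from_genome(genome, f"{acc}_{sub_label}", config, rng)
            )
        cols = np.arange(config.read_length)
        for r in acc_reads:
            counts[r.seq, r.start + cols[: len(r.seq)]] += 1
        bam = out / f"{acc}.bam"
        _write_bam(bam, acc_reads, L, config.read_length)
        bam_paths[acc] = bam

    vcf_path = out / "candidates.vcf"
    n_cand = _write_vcf(vcf_path, ancestor, counts)
    log.info(
        "simulated %d accessions, %d anchors, %d SNPs, %d candidate sites",
        config.n_accessions, len(truth.homeolog_sites),
        len(truth.accession_snps), n_cand,
    )

    ref_path = out / "reference.fa"
    seq = "".join(_BASES[i] for i in ancestor)
    ref_path.write_text(
        f">{REF_NAME}\n"
        + "\n".join(seq[i : i + 80] for i in range(0, len(seq), 80))
        + "\n"
    )
    truth.write(out)

    return SimResult(
        out_dir=out,
        config=config,
        bam_paths=bam_paths,
        vcf_path=vcf_path,
        reference_path=ref_path,
        truth=truth,
    )


def naive_coverage_filter_snps(
    bam_paths: Mapping[str, str | Path],
    reference: str | np.ndarray,
    expected_coverage: float,
    low_x: float = 0.4,
    high_x: float = 1.5,
    min_alt: int = 2,
) -> dict[str, set[int]]:
    """The straw-man coverage-based SNP caller.

    Per accession, a site is called when at least ``min_alt`` reads show a
    non-reference base and the total depth lies within
    ``[low_x, high_x] * expected_coverage`` (inclusive).  With the default
    multipliers and 10-fold expected coverage this reproduces the common
    "ignore sites above 15 or below 4 reads" rule.  Returns 1-based called
    positions per accession; compare against a truth table to expose the
    homeolog false positives this strategy lets through.
    """
    if isinstance(reference, str):
        ref_idx = np.array([_BASE_INDEX[b] for b in reference], dtype=np.int64)
    else:
        ref_idx = np.asarray(reference, dtype=np.int64)
    lo = low_x * expected_coverage
    hi = high_x * expected_coverage
    calls: dict[str, set[int]] = {}
    for acc in sorted(bam_paths):
        with pysam.AlignmentFile(str(bam_paths[acc]), "rb") as af:
            cov = np.array(
                af.count_coverage(REF_NAME, quality_threshold=0), dtype=np.int64
            )
        depth = cov.sum(axis=0)
        ref_count = cov[ref_idx, np.arange(cov.shape[1])]
        alt = depth - ref_count
        called = np.flatnonzero((alt >= min_alt) & (depth >= lo) & (depth <= hi))
        calls[acc] = {int(p) + 1 for p in called}
    return calls


@dataclass
class EvalResult:
    """Sensitivity/specificity of a call set against a truth table."""

    tpr: float
    fpr: float
    n_discoverable: int
    n_recovered: int
    n_negative: int
    n_false_positive: int


def _candidate_positions(
    candidate_sites: Iterable[CandidateSite | int] | None,
) -> set[int] | None:
    if candidate_sites is None:
        return None
    return {
        s.pos if isinstance(s, CandidateSite) else int(s)
        for s in candidate_sites
    }


def evaluate(
    calls: Sequence[MarkerCall] | Mapping[str, set[int]],
    truth: TruthTable,
    candidate_sites: Iterable[CandidateSite | int] | None = None,
    window: int = 150,
) -> EvalResult:
    """Score marker calls (or naive per-site calls) against the truth table.

    For haplotype markers, a true SNP is *discoverable* when it appears in
    the candidate set and has at least one candidate homeolog anchor
    within ``window`` bases; it is *recovered* when some called marker
    pairs its position with an anchor.  TPR is recovered / discoverable
    (1.0 vacuously when nothing is discoverable).  FPR is the fraction of
    pure-homeolog candidate pairs (both sites anchors, neither a SNP,
    within the window) that were called.

    For naive per-accession site calls (a mapping), TPR is the fraction of
    spiked SNP records called in their carrier accession, and FPR the
    fraction of anchors called as a SNP in at least one accession.
    """
    anchors = truth.anchor_positions
    snp_positions = truth.snp_positions

    if isinstance(calls, Mapping):
        n_true = len(truth.accession_snps)
        recovered = sum(
            1
            for s in truth.accession_snps
            if s.pos in calls.get(s.accession, set())
        )
        called_anywhere = set().union(*calls.values()) if calls else set()
        fp = len(anchors & called_anywhere)
        return EvalResult(
            tpr=recovered / n_true if n_true else 1.0,
            fpr=fp / len(anchors) if anchors else 0.0,
            n_discoverable=n_true,
            n_recovered=recovered,
            n_negative=len(anchors),
            n_false_positive=fp,
        )

    cand = _candidate_positions(candidate_sites)
    if cand is None:
        cand = anchors | snp_positions
    cand_anchors = sorted(anchors & cand)

    discoverable = {
        p
        for p in snp_positions & cand
        if any(0 < abs(p - a) <= window for a in cand_anchors)
    }

    recovered: set[int] = set()
    called_homeolog_pairs: set[tuple[int, int]] = set()
    for m in calls:
        p1, p2 = m.pair.positions
        for snp, other in ((p1, p2), (p2, p1)):
            if snp in discoverable and other in anchors:
                recovered.add(snp)
        if (
            p1 in anchors
            and p2 in anchors
            and p1 not in snp_positions
            and p2 not in snp_positions
        ):
            called_homeolog_pairs.add((p1, p2))

    n_homeolog_pairs = 0
    for i, a in enumerate(cand_anchors):
        for b in cand_anchors[i + 1 :]:
            if b - a > window:
                break
            n_homeolog_pairs += 1

    return EvalResult(
        tpr=len(recovered) / len(discoverable) if discoverable else 1.0,
        fpr=(
            len(called_homeolog_pairs) / n_homeolog_pairs
            if n_homeolog_pairs
            else 0.0
        ),
        n_discoverable=len(discoverable),
        n_recovered=len(recovered),
        n_negative=n_homeolog_pairs,
        n_false_positive=len(called_homeolog_pairs),
    )


def anchor_reach(n_anchors: int, read_length: int) -> int:
    """Bases within one read length of ``n_anchors`` anchor sites.

    Counts ``2 * read_length`` bases per anchor (either side), without
    overlap correction — the non-overlapping-window upper bound on the
    genome fraction assayable by anchored two-site haplotypes.
    """
    if n_anchors < 0:
        raise ValueError("n_anchors must be >= 0")
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    return n_anchors * 2 * read_length
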