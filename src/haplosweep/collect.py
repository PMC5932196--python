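"""Two-site haplotype collection from single contiguous reads.

In a collapsed allopolyploid alignment every locus carries reads from two
(or more) subgenomes.  A two-base haplotype — the ordered pair of bases a
single read shows at two nearby candidate polymorphic sites — separates
those read populations: a homeologous difference at one site "anchors" the
subgenome origin of the read, so variation at the other site can be
attributed to a true allelic difference rather than to subgenome mixing.

This module enumerates the candidate site pairs inside a base-pair window
and counts, per accession, every haplotype observed within a single read.
Collection is allele-agnostic: whatever base a read shows at a candidate
site is recorded literally, and the downstream filters decide relevance.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .io import (
    DEFAULT_MIN_BASEQ,
    DEFAULT_MIN_MAPQ,
    AlignedReadView,
    CandidateSite,
    _keep_alignment,
)


@dataclass(frozen=True, order=True)
class SitePair:
    """An ordered pair of candidate sites; the unit of marker discovery."""

    chrom: str
    site1: CandidateSite
    site2: CandidateSite

    def __post_init__(self) -> None:
        if self.site1.chrom != self.chrom or self.site2.chrom != self.chrom:
            raise ValueError("site pair mixes reference sequences")
        if not self.site1.pos < self.site2.pos:
            raise ValueError(
                f"site1.pos must precede site2.pos "
                f"({self.site1.pos} !< {self.site2.pos})"
            )

    @property
    def positions(self) -> tuple[int, int]:
        return (self.site1.pos, self.site2.pos)

    @property
    def span(self) -> int:
        return self.site2.pos - self.site1.pos


@dataclass
class HaplotypeTable:
    """Per site-pair, per accession counts of each observed haplotype string."""

    entries: dict[SitePair, dict[str, dict[str, int]]] = field(default_factory=dict)

    def add(self, pair: SitePair, accession: str, haplotype: str, n: int = 1) -> None:
        acc_counts = self.entries.setdefault(pair, {}).setdefault(accession, {})
        acc_counts[haplotype] = acc_counts.get(haplotype, 0) + n

    def counts(self, pair: SitePair, accession: str) -> dict[str, int]:
        return dict(self.entries.get(pair, {}).get(accession, {}))

    def site_pairs(self) -> list[SitePair]:
        return sorted(self.entries)

    def total_observations(self) -> int:
        return sum(
            c
            for entry in self.entries.values()
            for counts in entry.values()
            for c in counts.values()
        )

    def __len__(self) -> int:
        return len(self.entries)


def enumerate_site_pairs(
    sites: Sequence[CandidateSite], window: int
) -> list[SitePair]:
    """All pairs of same-chromosome sites at most ``window`` bases apart.

    ``sites`` must be sorted by (chrom, pos); the output is lexicographic by
    (chrom, pos1, pos2).
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    pairs: list[SitePair] = []
    for i, s1 in enumerate(sites):
        for s2 in sites[i + 1 :]:
            if s2.chrom != s1.chrom:
                break
            if s2.pos - s1.pos > window:
                break
            pairs.append(SitePair(s1.chrom, s1, s2))
    return pairs


def collect_within_read(
    pair: SitePair, reads: Iterable[AlignedReadView]
) -> dict[str, dict[str, int]]:
    """Count two-base haplotypes observed within single contiguous reads.

    Only reads resolving valid bases at both sites contribute; a read
    covering one site only adds nothing.  Mates of a read pair are treated
    as independent reads here (the long-range collector is pair-scoped).
    """
    counts: dict[str, dict[str, int]] = {}
    p1, p2 = pair.positions
    for view in reads:
        b1 = view.base_at(p1)
        if b1 is None:
            continue
        b2 = view.base_at(p2)
        if b2 is None:
            continue
        acc_counts = counts.setdefault(view.accession_id, {})
        hap = b1 + b2
        acc_counts[hap] = acc_counts.get(hap, 0) + 1
    return counts


def _group_pairs_by_chrom(
    pairs: Iterable[SitePair],
) -> dict[str, list[SitePair]]:
    grouped: dict[str, list[SitePair]] = {}
    for pair in pairs:
        grouped.setdefault(pair.chrom, []).append(pair)
    return grouped


def build_table(
    pairs: Sequence[SitePair],
    bams: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> HaplotypeTable:
    """Collect within-read haplotypes for every site pair over all accessions.

    Each BAM is scanned once per chromosome; every retained read contributes
    one observation to each enumerated pair whose two sites it resolves.
    Raises ``ValueError`` if a chromosome named by the candidate sites is
    absent from a BAM header (reference mismatch).
    """
    table = HaplotypeTable()
    for chrom, group in sorted(_group_pairs_by_chrom(pairs).items()):
        positions = sorted({p for pair in group for p in pair.positions})
        lookup = {pair.positions: pair for pair in group}
        lo, hi = positions[0], positions[-1]
        for acc in sorted(bams):
            with pysam.AlignmentFile(str(bams[acc]), "rb") as af:
                if chrom not in af.references:
                    raise ValueError(
                        f"reference sequence '{chrom}' from the candidate sites "
                        f"is absent from BAM '{bams[acc]}'"
                    )
                for read in af.fetch(chrom, lo - 1, hi):
                    if not _keep_alignment(read, min_mapq):
                        continue
                    view = AlignedReadView(read, acc, min_baseq)
                    i = bisect_left(positions, view.reference_start)
                    j = bisect_right(positions, view.reference_end)
                    covered = [
                        (p, b)
                        for p in positions[i:j]
                        if (b := view.base_at(p)) is not None
                    ]
                    for a in range(len(covered)):
                        pa, ba = covered[a]
                        for b_ in range(a + 1, len(covered)):
                            pb, bb = covered[b_]
                            pair = lookup.get((pa, pb))
                            if pair is not None:
                                table.add(pair, acc, ba + bb)
    return table
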