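"""Fragment-scoped haplotype collection spanning paired mates.

With paired-end libraries a haplotype can span up to the fragment length:
one mate resolves the first site, the other mate the second.  This mode
collects both within-read and cross-mate haplotypes, so site pairs out of
reach of a single read (but within the insert size) become assayable.
Each fragment contributes at most one observation per site pair.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Iterable, Mapping, Sequence

import pysam

from .collect import HaplotypeTable, SitePair, _group_pairs_by_chrom
from .io import (
    DEFAULT_MIN_BASEQ,
    DEFAULT_MIN_MAPQ,
    MISSING,
    AlignedReadView,
    _keep_alignment,
)


class FragmentView:
    """Base access resolved across the mates of one sequenced fragment.

    ``base_at`` returns the base whichever mate resolves; when both mates
    cover a position with valid bases that disagree, the position resolves
    to :data:`MISSING` so the conflicting observation is discarded (a mate
    whose base fails the quality floor simply defers to the other mate).
    """

    __slots__ = ("fragment_name", "accession_id", "mates")

    def __init__(self, mates: Sequence[AlignedReadView]) -> None:
        if not mates:
            raise ValueError("a fragment needs at least one mate")
        self.mates = tuple(mates)
        self.fragment_name = self.mates[0].read_name
        self.accession_id = self.mates[0].accession_id

    def base_at(self, pos: int) -> str | None:
        bases = {b for m in self.mates if (b := m.base_at(pos)) is not None}
        if len(bases) == 1:
            return next(iter(bases))
        return MISSING

    def covered_positions(self, positions: Sequence[int]) -> list[int]:
        """Subset of sorted ``positions`` lying within any mate's aligned span."""
        hit: set[int] = set()
        for m in self.mates:
            i = bisect_left(positions, m.reference_start)
            j = bisect_right(positions, m.reference_end)
            hit.update(positions[i:j])
        return sorted(hit)


def build_fragment_views(
    views: Iterable[AlignedReadView],
) -> list[FragmentView]:
    """Group read views into fragments.

    Two same-name, properly paired mates form one joint fragment; any other
    read stands alone as a single-mate fragment, so every read counted by
    the within-read collector is also represented here.
    """
    by_name: dict[str, list[AlignedReadView]] = {}
    order: list[str] = []
    for view in views:
        if view.read_name not in by_name:
            order.append(view.read_name)
        by_name.setdefault(view.read_name, []).append(view)
    fragments: list[FragmentView] = []
    for name in order:
        group = by_name[name]
        if len(group) == 2 and all(m.is_proper_pair for m in group):
            fragments.append(FragmentView(group))
        else:
            fragments.extend(FragmentView([m]) for m in group)
    return fragments


def collect_longrange(
    pair: SitePair, fragments: Iterable[FragmentView]
) -> dict[str, dict[str, int]]:
    """Count haplotypes per fragment: within-read plus cross-mate observations."""
    counts: dict[str, dict[str, int]] = {}
    p1, p2 = pair.positions
    for frag in fragments:
        b1 = frag.base_at(p1)
        if b1 is None:
            continue
        b2 = frag.base_at(p2)
        if b2 is None:
            continue
        acc_counts = counts.setdefault(frag.accession_id, {})
        hap = b1 + b2
        acc_counts[hap] = acc_counts.get(hap, 0) + 1
    return counts


def build_table_longrange(
    pairs: Sequence[SitePair],
    bams: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> HaplotypeTable:
    """Fragment-scoped analogue of :func:`haplosweep.collect.build_table`.

    The set of site pairs with at least one observation here is a superset
    of the within-read mode's on the same BAMs and window, because every
    single read is also a (single-mate) fragment.
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
                views = [
                    AlignedReadView(read, acc, min_baseq)
                    for read in af.fetch(chrom, lo - 1, hi)
                    if _keep_alignment(read, min_mapq)
                ]
            for frag in build_fragment_views(views):
                covered = [
                    (p, b)
                    for p in frag.covered_positions(positions)
                    if (b := frag.base_at(p)) is not None
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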