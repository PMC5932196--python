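"""Filtering of collected haplotypes into polymorphic marker calls.

Four counting rules separate true inter-accession polymorphisms from
homeologous subgenome differences:

1. at least two accessions must show more than one haplotype at the pair;
2. every haplotype an accession contributes must be observed at least
   ``min_obs`` times (default 2);
3. the least observed haplotype in an accession must be at least
   ``minor_ratio`` (default 25%, inclusive) as frequent as its most
   observed one, excluding rare haplotypes arising from sequencing error;
4. in at least one, but not all, of the multi-haplotype accessions the
   haplotypes must agree at one site and differ from each other at the
   other site.

Rule 4 is the discriminating step.  An accession whose two haplotypes
differ at both sites carries a subgenome difference at one site *and* an
allelic difference at the other; an accession whose haplotypes agree at
one site shows the pure subgenome contrast.  The site that is invariant
within the pattern-showing accessions is the inter-accession polymorphic
marker site, and the site at which their haplotypes differ is the
homeolog anchor.  When every multi-haplotype accession shows the pattern
the pair is a pure homeolog difference and is rejected.

Rules 2 and 3 are applied as a per-accession retention step before rules
1 and 4 are evaluated, so each rule is independently testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Mapping

from .collect import HaplotypeTable, SitePair

DEFAULT_MIN_OBS = 2
DEFAULT_MINOR_RATIO = 0.25


@dataclass
class MarkerCall:
    """A site pair that survived all filters.

    ``anchor_index``/``polymorphic_index`` are 1 or 2 and designate which
    site of the pair is the homeolog anchor and which carries the
    inter-accession polymorphism.  ``pattern_accessions`` is the subset of
    multi-haplotype accessions whose haplotypes are invariant at the
    polymorphic site (rule 4).
    """

    pair: SitePair
    anchor_index: int
    polymorphic_index: int
    per_accession_haplotypes: Mapping[str, frozenset[str]]
    pattern_accessions: frozenset[str]

    @property
    def marker_id(self) -> str:
        return f"{self.pair.chrom}_{self.pair.site1.pos}_{self.pair.site2.pos}"


def retain_haplotypes(
    counts: Mapping[str, int],
    min_obs: int = DEFAULT_MIN_OBS,
    minor_ratio: float = DEFAULT_MINOR_RATIO,
) -> set[str]:
    """Haplotypes passing the per-accession observation thresholds.

    A haplotype is retained iff its count is at least ``min_obs`` and at
    least ``minor_ratio`` times the count of the most observed haplotype
    (inclusive comparison on both thresholds).
    """
    if not counts:
        return set()
    top = max(counts.values())
    return {
        hap
        for hap, count in counts.items()
        if count >= min_obs and count >= minor_ratio * top
    }


def criterion_two_multihap_accessions(
    retained: Mapping[str, AbstractSet[str]],
) -> bool:
    """Rule 1: at least two accessions retain more than one haplotype."""
    return sum(1 for haps in retained.values() if len(haps) >= 2) >= 2


def _shows_pattern(haps: AbstractSet[str], invariant_index: int) -> bool:
    """All haplotypes agree at ``invariant_index`` and differ pairwise at the other."""
    other = 1 - invariant_index
    if len({h[invariant_index] for h in haps}) != 1:
        return False
    return len({h[other] for h in haps}) == len(haps)


def criterion_anchor_pattern(
    retained: Mapping[str, AbstractSet[str]],
) -> tuple[bool, int | None, int | None, frozenset[str]]:
    """Rule 4: some, but not all, accessions show the anchor pattern.

    Returns ``(passed, anchor_index, polymorphic_index, pattern_accessions)``
    with 1-based site indices.  Accessions with three or more retained
    haplotypes participate through pairwise agreement over all of them; if
    no site is invariant across all, the accession shows no pattern.  When
    both site indices would qualify, the designation with the polymorphic
    site at index 1 is preferred deterministically.
    """
    multi = {acc: haps for acc, haps in retained.items() if len(haps) >= 2}
    if not multi:
        return False, None, None, frozenset()
    all_multi = frozenset(multi)
    for invariant in (0, 1):
        pattern = frozenset(
            acc for acc, haps in multi.items() if _shows_pattern(haps, invariant)
        )
        if pattern and pattern != all_multi:
            return True, 2 - invariant, invariant + 1, pattern
    return False, None, None, frozenset()


def call_markers(
    table: HaplotypeTable,
    min_obs: int = DEFAULT_MIN_OBS,
    minor_ratio: float = DEFAULT_MINOR_RATIO,
) -> list[MarkerCall]:
    """Apply retention plus rules 1 and 4 to every table entry.

    Returns the surviving markers sorted by coordinates.
    """
    markers: list[MarkerCall] = []
    for pair in table.site_pairs():
        entry = table.entries[pair]
        retained = {
            acc: frozenset(kept)
            for acc, counts in entry.items()
            if (kept := retain_haplotypes(counts, min_obs, minor_ratio))
        }
        if not criterion_two_multihap_accessions(retained):
            continue
        passed, anchor_index, polymorphic_index, pattern = criterion_anchor_pattern(
            retained
        )
        if not passed:
            continue
        markers.append(
            MarkerCall(
                pair=pair,
                anchor_index=anchor_index,
                polymorphic_index=polymorphic_index,
                per_accession_haplotypes=retained,
                pattern_accessions=pattern,
            )
        )
    return markers
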