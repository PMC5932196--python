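"""N-base haplotype collection for long reads and diploid genomes.

Instead of fixed two-site haplotypes, this mode collects haplotypes of
length 2..N over runs of candidate sites a read resolves, up to the base
window.  With long reads the extra sites sharpen the resolution of each
haplotype; in a diploid there is no homeolog anchor to exploit, but the
same contrast-between-accessions filtering still separates genuine
polymorphisms from noise.

``max_len == 2`` is by definition the two-site collector, producing counts
identical to the default polyploid mode on the same input.  For longer
haplotypes each read contributes its maximal runs only: a run of covered
sites is emitted when it extends past the previous emitted run, so
sub-haplotypes of an emitted haplotype are not additionally counted.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Sequence

import pysam

from .collect import CandidateSite
from .filters import DEFAULT_MIN_OBS, DEFAULT_MINOR_RATIO, retain_haplotypes
from .io import (
    DEFAULT_MIN_BASEQ,
    DEFAULT_MIN_MAPQ,
    AlignedReadView,
    _keep_alignment,
)

#: Table key: (chrom, positions tuple); value: accession -> haplotype -> count.
NBaseEntries = dict[tuple[str, tuple[int, ...]], dict[str, dict[str, int]]]


@dataclass
class NBaseMarkerCall:
    """A site tuple surviving the generalized filters in N-base mode."""

    chrom: str
    positions: tuple[int, ...]
    per_accession_haplotypes: Mapping[str, frozenset[str]]
    pattern_accessions: frozenset[str]
    invariant_positions: tuple[int, ...]

    @property
    def marker_id(self) -> str:
        return "_".join([self.chrom, *map(str, self.positions)])


def _covered_sites(
    view: AlignedReadView, positions: Sequence[int]
) -> list[tuple[int, str]]:
    i = bisect_left(positions, view.reference_start)
    j = bisect_right(positions, view.reference_end)
    return [
        (p, b) for p in positions[i:j] if (b := view.base_at(p)) is not None
    ]


def _read_runs(
    covered: Sequence[tuple[int, str]], max_len: int, window: int
) -> list[tuple[tuple[int, ...], str]]:
    """Maximal runs of consecutively covered sites, length 2..max_len."""
    runs: list[tuple[tuple[int, ...], str]] = []
    prev_end = -1
    for i in range(len(covered)):
        j = i
        while (
            j + 1 < len(covered)
            and j + 1 - i < max_len
            and covered[j + 1][0] - covered[i][0] <= window
        ):
            j += 1
        if j > i and j > prev_end:
            runs.append(
                (
                    tuple(p for p, _ in covered[i : j + 1]),
                    "".join(b for _, b in covered[i : j + 1]),
                )
            )
            prev_end = j
    return runs


def collect_nbase(
    sites: Sequence[CandidateSite],
    reads: Iterable[AlignedReadView],
    max_len: int,
    window: int,
) -> NBaseEntries:
    """Collect per-accession haplotypes of length 2..``max_len``.

    With ``max_len == 2`` every pair of resolved sites within ``window`` is
    counted — exactly the default two-site collection.  With larger
    ``max_len`` each read contributes its maximal runs only, and shorter
    haplotypes appear where the window or read end truncates a run.
    """
    if max_len < 2:
        raise ValueError(f"max_len must be >= 2, got {max_len}")
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    for positions in by_chrom.values():
        positions.sort()

    entries: NBaseEntries = {}
    default_chrom = next(iter(by_chrom)) if len(by_chrom) == 1 else None

    def _add(chrom: str, pos_tuple: tuple[int, ...], acc: str, hap: str) -> None:
        acc_counts = entries.setdefault((chrom, pos_tuple), {}).setdefault(acc, {})
        acc_counts[hap] = acc_counts.get(hap, 0) + 1

    for view, chrom in _with_chrom(reads, default_chrom):
        positions = by_chrom.get(chrom)
        if not positions:
            continue
        covered = _covered_sites(view, positions)
        if max_len == 2:
            for a in range(len(covered)):
                pa, ba = covered[a]
                for b_ in range(a + 1, len(covered)):
                    pb, bb = covered[b_]
                    if pb - pa > window:
                        break
                    _add(chrom, (pa, pb), view.accession_id, ba + bb)
        else:
            for pos_tuple, hap in _read_runs(covered, max_len, window):
                _add(chrom, pos_tuple, view.accession_id, hap)
    return entries


def _with_chrom(
    reads: Iterable, default_chrom: str | None
) -> Iterable[tuple[AlignedReadView, str]]:
    """Pair each view with its reference name (supplied or single-chrom default)."""
    for item in reads:
        if isinstance(item, tuple):
            yield item
        else:
            yield item, getattr(item, "chrom", default_chrom or "")


def build_table_nbase(
    sites: Sequence[CandidateSite],
    bams: Mapping[str, str],
    max_len: int,
    window: int,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> NBaseEntries:
    """Scan each BAM once per chromosome and collect N-base haplotypes."""
    if max_len < 2:
        raise ValueError(f"max_len must be >= 2, got {max_len}")
    by_chrom: dict[str, list[CandidateSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    merged: NBaseEntries = {}
    for chrom, chrom_sites in sorted(by_chrom.items()):
        positions = sorted(s.pos for s in chrom_sites)
        lo, hi = positions[0], positions[-1]
        for acc in sorted(bams):
            with pysam.AlignmentFile(str(bams[acc]), "rb") as af:
                if chrom not in af.references:
                    raise ValueError(
                        f"reference sequence '{chrom}' from the candidate sites "
                        f"is absent from BAM '{bams[acc]}'"
                    )
                views = [
                    (AlignedReadView(read, acc, min_baseq), chrom)
                    for read in af.fetch(chrom, lo - 1, hi)
                    if _keep_alignment(read, min_mapq)
                ]
            part = collect_nbase(chrom_sites, views, max_len, window)
            for key, entry in part.items():
                for acc_id, counts in entry.items():
                    tgt = merged.setdefault(key, {}).setdefault(acc_id, {})
                    for hap, n in counts.items():
                        tgt[hap] = tgt.get(hap, 0) + n
    return merged


def _pattern_positions(haps: AbstractSet[str]) -> tuple[set[int], set[int]]:
    """Indices where all haplotypes agree vs where they vary."""
    length = len(next(iter(haps)))
    invariant = {
        i for i in range(length) if len({h[i] for h in haps}) == 1
    }
    return invariant, set(range(length)) - invariant


def call_markers_nbase(
    entries: NBaseEntries,
    min_obs: int = DEFAULT_MIN_OBS,
    minor_ratio: float = DEFAULT_MINOR_RATIO,
) -> list[NBaseMarkerCall]:
    """Generalized filtering for N-base haplotypes.

    Retention (rules 2 and 3) is unchanged.  Rule 1 still requires two
    multi-haplotype accessions.  Rule 4 generalizes position-wise: an
    accession shows the pattern when its retained haplotypes share at
    least one invariant position (and, being distinct, vary at least at
    one other); the pattern-showing accessions must be a non-empty proper
    subset of the multi-haplotype accessions.
    """
    markers: list[NBaseMarkerCall] = []
    for (chrom, positions), entry in sorted(entries.items()):
        retained = {
            acc: frozenset(kept)
            for acc, counts in entry.items()
            if (kept := retain_haplotypes(counts, min_obs, minor_ratio))
        }
        multi = {acc: haps for acc, haps in retained.items() if len(haps) >= 2}
        if len(multi) < 2:
            continue
        pattern: dict[str, set[int]] = {}
        for acc, haps in multi.items():
            if len({len(h) for h in haps}) != 1:
                continue
            invariant, varying = _pattern_positions(haps)
            if invariant and varying:
                pattern[acc] = invariant
        if not pattern or set(pattern) == set(multi):
            continue
        shared_invariant = set.intersection(*pattern.values())
        markers.append(
            NBaseMarkerCall(
                chrom=chrom,
                positions=positions,
                per_accession_haplotypes=retained,
                pattern_accessions=frozenset(pattern),
                invariant_positions=tuple(
                    positions[i] for i in sorted(shared_invariant)
                ),
            )
        )
    return markers


def write_nbase_outputs(markers, entries, out_prefix):
    """Write N-base analogues of the two discovery files."""
    from pathlib import Path

    prefix = Path(str(out_prefix))
    if prefix.parent and not prefix.parent.exists():
        prefix.parent.mkdir(parents=True, exist_ok=True)
    obs_path = Path(str(prefix) + ".nbase_observations.tsv")
    marker_path = Path(str(prefix) + ".nbase_polymorphic_haplotypes.tsv")

    lines = ["chrom\tpositions\taccession\thaplotype\tcount"]
    for (chrom, positions), entry in sorted(entries.items()):
        pos_str = ",".join(map(str, positions))
        for acc in sorted(entry):
            for hap, count in sorted(
                entry[acc].items(), key=lambda kv: (-kv[1], kv[0])
            ):
                lines.append(f"{chrom}\t{pos_str}\t{acc}\t{hap}\t{count}")
    obs_path.write_text("\n".join(lines) + "\n")

    lines = [
        "chrom\tpositions\tinvariant_positions\tpattern_accessions\thaplotypes"
    ]
    for m in sorted(markers, key=lambda m: (m.chrom, m.positions)):
        haps = ";".join(
            f"{acc}={'|'.join(sorted(m.per_accession_haplotypes[acc]))}"
            for acc in sorted(m.per_accession_haplotypes)
        )
        lines.append(
            f"{m.chrom}\t{','.join(map(str, m.positions))}"
            f"\t{','.join(map(str, m.invariant_positions))}"
            f"\t{','.join(sorted(m.pattern_accessions))}\t{haps}"
        )
    marker_path.write_text("\n".join(lines) + "\n")
    return obs_path, marker_path
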