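"""Population genotyping at discovered haplotype markers.

Given a set of marker calls and a population's BAM alignments, each
individual is genotyped at each marker by re-collecting its haplotypes at
the marker's site pair and matching the retained set against the founder
(discovery accession) haplotype sets recorded on the marker.

Haplotypes present in *every* founder are homeolog-shared and carry no
allelic information, so they are ignored during calling.  The remaining
founder-specific (diagnostic) haplotypes partition the founders into
allele classes; with two classes the calls are encoded "A" (class of the
lexicographically first founder) and "B", plus "H" for individuals whose
retained haplotypes hit both classes and "." for missing / uninformative.
Markers contrasting more than two founder classes are encoded by the
class index ("0", "1", ...).  Retained haplotypes matching no founder
class (e.g. from sequencing error) are ignored as non-diagnostic noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .collect import collect_within_read
from .filters import DEFAULT_MINOR_RATIO, MarkerCall
from .io import DEFAULT_MIN_BASEQ, DEFAULT_MIN_MAPQ, fetch_read_views
from .longrange import build_fragment_views, collect_longrange

log = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 2

MISSING_CALL = "."
HET_CALL = "H"


@dataclass(frozen=True)
class AlleleClass:
    code: str
    haplotypes: frozenset[str]
    founders: frozenset[str]


def marker_allele_classes(marker: MarkerCall) -> tuple[frozenset[str], list[AlleleClass]]:
    """Non-diagnostic haplotypes and the founder allele classes of a marker.

    Founders with identical retained haplotype sets form one group.  A
    haplotype observed in more than one group is non-diagnostic: for the
    homeolog-shared haplotype this is the "present in all founders" case,
    and under partial sampling it also covers haplotypes that happen to be
    retained by some but not all founders and therefore cannot separate
    them.  Each group's remaining (group-unique) haplotypes define its
    allele class; groups left without a diagnostic haplotype define no
    class and their founders can only be genotyped as missing.  Classes
    are ordered by their lexicographically smallest founder and coded
    "A"/"B" for the biallelic case, by index otherwise.
    """
    sets = {
        acc: frozenset(haps)
        for acc, haps in marker.per_accession_haplotypes.items()
    }
    groups: dict[frozenset[str], set[str]] = {}
    for acc, haps in sets.items():
        groups.setdefault(haps, set()).add(acc)
    hap_groups: dict[str, int] = {}
    for haps in groups:
        for hap in haps:
            hap_groups[hap] = hap_groups.get(hap, 0) + 1
    shared = frozenset(h for h, n in hap_groups.items() if n > 1)
    diag_groups: dict[frozenset[str], set[str]] = {}
    for haps, accs in groups.items():
        diag = frozenset(haps - shared)
        if diag:
            diag_groups[diag] = diag_groups.get(diag, set()) | accs
    ordered = sorted(diag_groups.items(), key=lambda kv: min(kv[1]))
    if len(ordered) == 2:
        codes = ["A", "B"]
    else:
        codes = [str(i) for i in range(len(ordered))]
    classes = [
        AlleleClass(code=c, haplotypes=haps, founders=frozenset(accs))
        for c, (haps, accs) in zip(codes, ordered)
    ]
    return shared, classes


def _retain_with_counts(
    counts: Mapping[str, int], min_depth: int, minor_ratio: float
) -> dict[str, int]:
    if not counts:
        return {}
    top = max(counts.values())
    return {
        hap: n
        for hap, n in counts.items()
        if n >= min_depth and n >= minor_ratio * top
    }


def genotype_individual(
    bam_path: str | Path,
    marker: MarkerCall,
    accession_id: str = "individual",
    min_depth: int = DEFAULT_MIN_DEPTH,
    minor_ratio: float = DEFAULT_MINOR_RATIO,
    mode: str = "default",
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> tuple[str, int]:
    """Call one individual at one marker; returns ``(call, depth)``.

    ``depth`` is the number of retained observations supporting diagnostic
    haplotypes, so every non-missing call is backed by at least
    ``min_depth`` observations.
    """
    pair = marker.pair
    views = fetch_read_views(
        bam_path,
        accession_id,
        pair.chrom,
        pair.site1.pos,
        pair.site2.pos,
        min_mapq=min_mapq,
        min_baseq=min_baseq,
    )
    if mode == "longrange":
        counts = collect_longrange(pair, build_fragment_views(views)).get(
            accession_id, {}
        )
    else:
        counts = collect_within_read(pair, views).get(accession_id, {})

    retained = _retain_with_counts(counts, min_depth, minor_ratio)
    shared, classes = marker_allele_classes(marker)
    diagnostic = {
        hap: n for hap, n in retained.items() if hap not in shared
    }
    hits = [
        cls for cls in classes if any(h in cls.haplotypes for h in diagnostic)
    ]
    depth = sum(
        n
        for hap, n in diagnostic.items()
        if any(hap in cls.haplotypes for cls in hits)
    )
    if not hits:
        return MISSING_CALL, 0
    if len(hits) == 1:
        return hits[0].code, depth
    return HET_CALL, depth


@dataclass
class GenotypeMatrix:
    """Individuals x markers categorical calls with a sidecar depth matrix."""

    calls: pd.DataFrame
    depth: pd.DataFrame

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    def to_tsv(self, path: str | Path, depth_path: str | Path | None = None) -> None:
        out = self.calls.copy()
        out.index.name = "individual"
        out.to_csv(path, sep="\t")
        if depth_path is not None:
            dep = self.depth.copy()
            dep.index.name = "individual"
            dep.to_csv(depth_path, sep="\t")


def genotype_population(
    bams: Mapping[str, str] | Sequence[tuple[str, str]],
    markers: Sequence[MarkerCall],
    min_depth: int = DEFAULT_MIN_DEPTH,
    minor_ratio: float = DEFAULT_MINOR_RATIO,
    mode: str = "default",
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> GenotypeMatrix:
    """Genotype every individual at every marker.

    ``bams`` maps individual ids to BAM paths (a sequence of pairs is
    accepted to preserve an explicit ordering).  Duplicate ids and missing
    BAM files are fatal.
    """
    if isinstance(bams, Mapping):
        items = list(bams.items())
    else:
        items = list(bams)
        ids = [i for i, _ in items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {', '.join(dup)}")
    for ind, path in items:
        if not Path(path).exists():
            raise FileNotFoundError(
                f"BAM for individual '{ind}' not found: {path}"
            )

    marker_ids = [m.marker_id for m in markers]
    calls: dict[str, list[str]] = {}
    depths: dict[str, list[int]] = {}
    for ind, path in items:
        row_calls: list[str] = []
        row_depth: list[int] = []
        for marker in markers:
            call, depth = genotype_individual(
                path,
                marker,
                accession_id=ind,
                min_depth=min_depth,
                minor_ratio=minor_ratio,
                mode=mode,
                min_mapq=min_mapq,
                min_baseq=min_baseq,
            )
            row_calls.append(call)
            row_depth.append(depth)
        calls[ind] = row_calls
        depths[ind] = row_depth

    index = [ind for ind, _ in items]
    return GenotypeMatrix(
        calls=pd.DataFrame.from_dict(
            calls, orient="index", columns=marker_ids
        ).loc[index],
        depth=pd.DataFrame.from_dict(
            depths, orient="index", columns=marker_ids
        ).loc[index],
    )
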