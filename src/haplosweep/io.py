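"""Alignment and variant I/O for haplotype-based marker discovery.

Candidate polymorphic sites come from an unfiltered VCF (typically a
samtools-mpileup style call set over every accession); aligned bases are
pulled from coordinate-sorted, indexed BAM files through a CIGAR-aware
read view; discovery results are written as two tab-separated files — one
listing every observed haplotype with its per-accession observation count,
and one listing the surviving polymorphic haplotype markers.

All user-facing coordinates are 1-based, matching the VCF convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pysam

if TYPE_CHECKING:  # pragma: no cover - import cycle avoidance, typing only
    from .collect import HaplotypeTable
    from .filters import MarkerCall

log = logging.getLogger(__name__)

#: Sentinel returned by ``base_at`` when a position is not resolvable in a read.
MISSING = None

VALID_BASES = frozenset("ACGT")

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_BASEQ = 13

OBSERVATIONS_SUFFIX = ".haplotype_observations.tsv"
MARKERS_SUFFIX = ".polymorphic_haplotypes.tsv"

_OBS_HEADER = "chrom\tpos1\tpos2\taccession\thaplotype\tcount"
_MARKER_HEADER = (
    "chrom\tpos1\tpos2\tref1\talt1\tref2\talt2\tanchor_site"
    "\tpolymorphic_site\tpattern_accessions\thaplotypes"
)


@dataclass(frozen=True, order=True)
class CandidateSite:
    """One putative polymorphic reference position with its observed alleles.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    pos : int
        1-based reference position, as printed in a VCF.
    ref_allele : str
        Reference base, one of A/C/G/T.
    alt_alleles : tuple of str
        Alternate single bases, non-empty and disjoint from ``ref_allele``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alt_alleles", tuple(self.alt_alleles))
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")
        if self.ref_allele not in VALID_BASES:
            raise ValueError(f"invalid reference allele {self.ref_allele!r}")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        for alt in self.alt_alleles:
            if alt not in VALID_BASES or alt == self.ref_allele:
                raise ValueError(f"invalid alternate allele {alt!r}")


class AlignedReadView:
    """CIGAR-aware view of one aligned read.

    ``base_at(pos)`` resolves a 1-based reference position to the read base
    aligned there, or :data:`MISSING` when the position lies outside the
    aligned span, falls in a deletion or reference skip, the base is not a
    plain A/C/G/T, or its base quality is below the configured floor.
    """

    __slots__ = (
        "read_name",
        "accession_id",
        "is_read1",
        "is_read2",
        "mapq",
        "is_proper_pair",
        "reference_start",
        "reference_end",
        "_read",
        "_min_baseq",
        "_bases",
    )

    def __init__(
        self,
        read: pysam.AlignedSegment,
        accession_id: str,
        min_baseq: int = DEFAULT_MIN_BASEQ,
    ) -> None:
        self.read_name: str = read.query_name or ""
        self.accession_id = accession_id
        self.is_read1 = read.is_read1
        self.is_read2 = read.is_read2
        self.mapq = read.mapping_quality
        self.is_proper_pair = read.is_paired and read.is_proper_pair
        # 1-based inclusive aligned span
        self.reference_start = read.reference_start + 1
        self.reference_end = int(read.reference_end or read.reference_start + 1)
        self._read = read
        self._min_baseq = min_baseq
        self._bases: dict[int, str] | None = None

    def _resolve(self) -> dict[int, str]:
        bases: dict[int, str] = {}
        seq = self._read.query_sequence
        if seq:
            quals = self._read.query_qualities
            for qpos, rpos in self._read.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in VALID_BASES:
                    continue
                if quals is not None and quals[qpos] < self._min_baseq:
                    continue
                bases[rpos + 1] = base
        self._bases = bases
        return bases

    def base_at(self, pos: int) -> str | None:
        """Base aligned at 1-based reference ``pos``, or :data:`MISSING`."""
        bases = self._bases
        if bases is None:
            bases = self._resolve()
        return bases.get(pos, MISSING)


def read_candidate_sites(
    vcf_path: str | Path,
    region: str | tuple[str, int, int] | None = None,
) -> list[CandidateSite]:
    """Parse candidate polymorphic SNP sites from a VCF.

    One :class:`CandidateSite` is produced per SNP record; records whose REF
    is not a single base, or with no single-base alternate allele (indels,
    symbolic alleles), are skipped.  Duplicate (chrom, pos) records are
    collapsed with an allele union.  Genotype columns of multi-sample VCFs
    are ignored — only the site and its alleles matter.

    Parameters
    ----------
    vcf_path : path
        Plain or bgzipped VCF v4.x.
    region : str or (chrom, start, end), optional
        Restrict to one reference sequence, optionally to a 1-based
        inclusive interval.

    Returns
    -------
    list of CandidateSite, sorted by (chrom, pos).
    """
    chrom_filter: str | None = None
    start = end = None
    if region is not None:
        if isinstance(region, str):
            chrom_filter = region
        else:
            chrom_filter, start, end = region

    collapsed: dict[tuple[str, int], tuple[str, set[str]]] = {}
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except Exception as exc:  # htslib raises several types on garbled input
        raise ValueError(f"failed to parse VCF '{vcf_path}': {exc}") from exc
    try:
        with vf:
            for rec in vf:
                chrom = rec.chrom
                pos = rec.pos
                if chrom_filter is not None and chrom != chrom_filter:
                    continue
                if start is not None and not (start <= pos <= end):
                    continue
                ref = (rec.ref or "").upper()
                if len(ref) != 1 or ref not in VALID_BASES:
                    continue
                alts = {
                    a.upper()
                    for a in (rec.alts or ())
                    if a and len(a) == 1 and a.upper() in VALID_BASES
                }
                alts.discard(ref)
                if not alts:
                    continue
                key = (chrom, pos)
                if key in collapsed:
                    prev_ref, prev_alts = collapsed[key]
                    if prev_ref != ref:
                        log.warning(
                            "conflicting REF alleles at %s:%d (%s vs %s); keeping %s",
                            chrom, pos, prev_ref, ref, prev_ref,
                        )
                        alts.discard(prev_ref)
                    prev_alts |= alts
                else:
                    collapsed[key] = (ref, alts)
    except ValueError as exc:
        raise ValueError(f"failed to parse VCF '{vcf_path}': {exc}") from exc

    return [
        CandidateSite(chrom, pos, ref, tuple(sorted(alts)))
        for (chrom, pos), (ref, alts) in sorted(collapsed.items())
    ]


def _keep_alignment(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    """Standard variant-calling hygiene: primary, unique-placement reads only."""
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
    ) and read.mapping_quality >= min_mapq


def _require_index(af: pysam.AlignmentFile, bam_path: str | Path) -> None:
    try:
        ok = af.check_index()
    except (ValueError, OSError, AttributeError) as exc:
        raise FileNotFoundError(
            f"BAM index missing for '{bam_path}'; create it with 'samtools index'"
        ) from exc
    if not ok:  # pragma: no cover - pysam raises rather than returning False
        raise FileNotFoundError(
            f"BAM index missing for '{bam_path}'; create it with 'samtools index'"
        )


def fetch_read_views(
    bam_path: str | Path,
    accession_id: str,
    chrom: str,
    start: int,
    end: int,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> list[AlignedReadView]:
    """Retrieve read views overlapping the 1-based inclusive span [start, end].

    Secondary, supplementary, duplicate and QC-fail alignments are excluded,
    as are reads below the mapping-quality floor.
    """
    with pysam.AlignmentFile(str(bam_path), "rb") as af:
        _require_index(af, bam_path)
        if chrom not in af.references:
            log.warning(
                "reference sequence '%s' absent from BAM '%s'; returning no reads",
                chrom, bam_path,
            )
            return []
        return [
            AlignedReadView(read, accession_id, min_baseq)
            for read in af.fetch(chrom, start - 1, end)
            if _keep_alignment(read, min_mapq)
        ]


def read_bam_list(path: str | Path) -> dict[str, str]:
    """Parse a two-column TSV of ``accession_id<TAB>bam_path``."""
    bams: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id<TAB>path', got {line!r}"
                )
            acc, bam = parts
            if acc in bams:
                raise ValueError(f"{path}:{lineno}: duplicate accession id {acc!r}")
            bams[acc] = bam
    return bams


def write_outputs(
    markers: Sequence["MarkerCall"],
    table: "HaplotypeTable",
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the two discovery output files.

    File 1 (``*.haplotype_observations.tsv``) lists every observed haplotype
    with its number of observations in each accession.  File 2
    (``*.polymorphic_haplotypes.tsv``) lists the polymorphic haplotype
    markers that survived filtering, with the anchor / polymorphic site
    designation and the per-accession haplotype sets.  Both files are
    byte-for-byte deterministic given identical inputs.
    """
    prefix = Path(out_prefix)
    if prefix.parent and not prefix.parent.exists():
        prefix.parent.mkdir(parents=True, exist_ok=True)
    obs_path = Path(str(prefix) + OBSERVATIONS_SUFFIX)
    marker_path = Path(str(prefix) + MARKERS_SUFFIX)

    obs_lines = [_OBS_HEADER]
    for pair in sorted(table.entries):
        entry = table.entries[pair]
        for acc in sorted(entry):
            by_count = sorted(entry[acc].items(), key=lambda kv: (-kv[1], kv[0]))
            for hap, count in by_count:
                obs_lines.append(
                    f"{pair.chrom}\t{pair.site1.pos}\t{pair.site2.pos}"
                    f"\t{acc}\t{hap}\t{count}"
                )
    obs_path.write_text("\n".join(obs_lines) + "\n")

    marker_lines = [_MARKER_HEADER]
    for m in sorted(markers, key=lambda m: m.pair):
        haps = ";".join(
            f"{acc}={'|'.join(sorted(m.per_accession_haplotypes[acc]))}"
            for acc in sorted(m.per_accession_haplotypes)
        )
        s1, s2 = m.pair.site1, m.pair.site2
        marker_lines.append(
            f"{m.pair.chrom}\t{s1.pos}\t{s2.pos}"
            f"\t{s1.ref_allele}\t{','.join(s1.alt_alleles)}"
            f"\t{s2.ref_allele}\t{','.join(s2.alt_alleles)}"
            f"\t{m.anchor_index}\t{m.polymorphic_index}"
            f"\t{','.join(sorted(m.pattern_accessions))}\t{haps}"
        )
    marker_path.write_text("\n".join(marker_lines) + "\n")
    return obs_path, marker_path


def read_observations(
    path: str | Path,
) -> dict[tuple[str, int, int], dict[str, dict[str, int]]]:
    """Parse file 1 back into nested (chrom, pos1, pos2) -> accession -> counts."""
    out: dict[tuple[str, int, int], dict[str, dict[str, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _OBS_HEADER:
            raise ValueError(f"unexpected header in '{path}': {header!r}")
        for line in fh:
            chrom, pos1, pos2, acc, hap, count = line.rstrip("\n").split("\t")
            key = (chrom, int(pos1), int(pos2))
            out.setdefault(key, {}).setdefault(acc, {})[hap] = int(count)
    return out


def read_markers(path: str | Path) -> list["MarkerCall"]:
    """Parse file 2 back into :class:`~haplosweep.filters.MarkerCall` objects."""
    from .collect import SitePair
    from .filters import MarkerCall

    markers: list[MarkerCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _MARKER_HEADER:
            raise ValueError(f"unexpected header in '{path}': {header!r}")
        for line in fh:
            (
                chrom, pos1, pos2, ref1, alt1, ref2, alt2,
                anchor, polymorphic, pattern, haps,
            ) = line.rstrip("\n").split("\t")
            site1 = CandidateSite(chrom, int(pos1), ref1, tuple(alt1.split(",")))
            site2 = CandidateSite(chrom, int(pos2), ref2, tuple(alt2.split(",")))
            per_acc: dict[str, frozenset[str]] = {}
            for field in haps.split(";"):
                acc, hapset = field.split("=")
                per_acc[acc] = frozenset(hapset.split("|"))
            markers.append(
                MarkerCall(
                    pair=SitePair(chrom, site1, site2),
                    anchor_index=int(anchor),
                    polymorphic_index=int(polymorphic),
                    per_accession_haplotypes=per_acc,
                    pattern_accessions=frozenset(pattern.split(",")),
                )
            )
    return markers
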