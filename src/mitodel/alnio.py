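"""SAM/BAM ingestion restricted to the mitochondrial contig, plus coverage.

Reads are filtered to primary and supplementary alignments on the
mitochondrial contig with a minimum mapping quality (default 10); secondary
and unmapped records are dropped.  Restricting to the mito contig plus the
mapq filter is also the guard against NUMT (nuclear-embedded mtDNA)
contamination: reads whose best placement is a nuclear NUMT locus never
enter the analysis.

Depth counts only reference-consuming match operations (M, =, X); deletion
(D) and skip (N) operations contribute zero depth, so a single large-scale
deletion produces the characteristic sharp coverage dip between its
breakpoints and the MT-RNR2 denominator counts only molecules physically
covering MT-RNR2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .refmodel import Region

logger = logging.getLogger(__name__)

#: CIGAR operations that consume the reference.
_REF_OPS = frozenset("M=XDN")
#: CIGAR operations that consume the query.
_QUERY_OPS = frozenset("M=XIS")

_PYSAM_OPS = "MIDNSHP=X"


@dataclass(frozen=True)
class AlignedRead:
    """A single alignment record on the mitochondrial contig."""

    read_id: str
    ref_start: int  # 1-based leftmost aligned reference position
    cigar: tuple[tuple[str, int], ...]
    mapq: int = 60
    is_supplementary: bool = False
    is_reverse: bool = False

    @property
    def ref_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def ref_end(self) -> int:
        """1-based rightmost aligned reference position (inclusive)."""
        return self.ref_start + self.ref_span - 1

    def query_span(self) -> tuple[int, int]:
        """Aligned query interval ``[qstart, qend)`` in read orientation.

        Clipped prefixes/suffixes (S or H) are excluded; for reverse-strand
        alignments the clip lengths are taken from the opposite CIGAR end so
        coordinates refer to the original read orientation.
        """
        lead = 0
        for op, n in self.cigar:
            if op in "SH":
                lead += n
            else:
                break
        trail = 0
        for op, n in reversed(self.cigar):
            if op in "SH":
                trail += n
            else:
                break
        aligned = sum(n for op, n in self.cigar if op in "MI=X")
        if self.is_reverse:
            lead, trail = trail, lead
        return lead, lead + aligned


def cigar_from_string(cigar: str) -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string into (op, length) pairs."""
    out: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in _PYSAM_OPS:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return tuple(out)


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = tuple(
        (_PYSAM_OPS[op], length) for op, length in (rec.cigartuples or ())
    )
    return AlignedRead(
        read_id=rec.query_name,
        ref_start=rec.reference_start + 1,
        cigar=cigar,
        mapq=rec.mapping_quality,
        is_supplementary=rec.is_supplementary,
        is_reverse=rec.is_reverse,
    )


def read_mito_alignments(
    path: str | Path,
    contig: str = "chrM",
    min_mapq: int = 10,
) -> Iterator[AlignedRead]:
    """Stream filtered alignments to the mitochondrial contig.

    Yields primary and supplementary alignments with ``mapq >= min_mapq``;
    secondary and unmapped records are dropped.  A single alignment record
    that would extend past the contig end (an origin-wrapping CIGAR) is
    rejected: wrap-around alignments must be represented as supplementary
    segment pairs.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if contig not in (af.references or ()):
            raise ValueError(f"contig {contig!r} not present in {path} header")
        length = af.get_reference_length(contig)
        if af.has_index():
            it: Iterable[pysam.AlignedSegment] = af.fetch(contig)
        else:
            it = (
                rec
                for rec in af.fetch(until_eof=True)
                if rec.reference_name == contig
            )
        n = 0
        for rec in it:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            read = _from_pysam(rec)
            if read.ref_end > length:
                raise ValueError(
                    f"alignment of {read.read_id} extends past contig end "
                    f"({read.ref_end} > {length}); origin-wrapping alignments "
                    "must be split into supplementary segments"
                )
            n += 1
            yield read
        logger.debug("read %d accepted alignments from %s", n, path)


@dataclass
class CoverageProfile:
    """Per-base depth over the full circular reference."""

    depth: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return int(self.depth.size)

    @property
    def mean(self) -> float:
        return float(self.depth.mean())


def depth_profile(reads: Iterable[AlignedRead], length: int) -> CoverageProfile:
    """Per-position depth counting M/=/X operations only.

    Deletion (D) and skip (N) gaps consume reference but add no depth, so
    deletion-bearing molecules leave a visible coverage dip.
    """
    depth = np.zeros(length, dtype=np.int64)
    for read in reads:
        pos = read.ref_start  # 1-based
        for op, n in read.cigar:
            if op in "M=X":
                depth[pos - 1 : pos - 1 + n] += 1
                pos += n
            elif op in "DN":
                pos += n
            # I, S, H, P consume no reference
    return CoverageProfile(depth=depth)


def mean_region_coverage(profile: CoverageProfile, region: Region) -> float:
    """Arithmetic mean depth over a (possibly origin-wrapping) region."""
    if region.length(profile.length) <= 0:
        raise ValueError(f"region {region.name} has zero length")
    region.validate(profile.length)
    if region.wraps:
        values = np.concatenate(
            [profile.depth[region.start - 1 :], profile.depth[: region.end]]
        )
    else:
        values = profile.depth[region.start - 1 : region.end]
    return float(values.mean())


def estimate_mtdna_content(mean_mt_cov: float, mean_n_cov: float) -> float:
    """Estimated mtDNA copies per diploid cell: ``2 * mt_cov / n_cov``.

    The nuclear genome is present at two copies per cell, so the ratio of
    mean mitochondrial to mean nuclear coverage, doubled, estimates mtDNA
    copy number.
    """
    if mean_n_cov <= 0:
        raise ValueError("mean nuclear coverage must be positive")
    if mean_mt_cov < 0:
        raise ValueError("mean mtDNA coverage must be non-negative")
    return 2.0 * mean_mt_cov / mean_n_cov


def write_bedgraph(
    profile: CoverageProfile, path: str | Path, contig: str = "chrM"
) -> None:
    """Export depth as bedGraph-style TSV (contig, start0, end0, depth)."""
    depth = profile.depth
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[start]:
                fh.write(f"{contig}\t{start}\t{i}\t{int(depth[start])}\n")
                start = i


def group_by_read(reads: Iterable[AlignedRead]) -> dict[str, list[AlignedRead]]:
    """Group alignment records (primary + supplementary) by read id."""
    groups: dict[str, list[AlignedRead]] = {}
    for read in reads:
        groups.setdefault(read.read_id, []).append(read)
    return groups
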