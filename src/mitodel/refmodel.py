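"""Circular mitochondrial reference model.

The human mitochondrial genome (rCRS, NC_012920.1) is a 16,569 bp circle.
All coordinates in this package are 1-based positions on that circle, with
position ``L + 1`` identified with position 1.  A deletion is represented as
the half-open circular segment ``[b5, b3)``: ``b5`` is the first deleted
base and ``b3`` the first retained base after the deleted segment, so the
deleted length is ``b3 - b5`` modulo ``L``.  Under this convention the
common deletion at chrM:8470-13447 has length 4,977 bp.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

RCRS_LENGTH = 16569
"""Length of the revised Cambridge Reference Sequence in bp."""

DLOOP = "D-loop"
RNR2 = "MT-RNR2"
ND4 = "MT-ND4"

#: Default region annotations on the rCRS.  The D-loop control region spans
#: the replication origin and therefore wraps.
DEFAULT_REGIONS: dict[str, dict] = {
    RNR2: {"start": 1671, "end": 3229, "wraps": False},
    ND4: {"start": 10760, "end": 12137, "wraps": False},
    DLOOP: {"start": 16024, "end": 576, "wraps": True},
}

_VALID_BASES = frozenset("ACGTN")


def circular_gap(b5: int, b3: int, length: int) -> int:
    """Number of deleted bases for the half-open circular segment [b5, b3).

    Returns ``b3 - b5`` when ``b3 > b5`` and ``b3 - b5 + length`` for
    origin-spanning deletions.  ``b5 == b3`` would denote a zero-length
    deletion and raises ``ValueError``.
    """
    if not (1 <= b5 <= length and 1 <= b3 <= length):
        raise ValueError(f"breakpoints ({b5}, {b3}) outside [1, {length}]")
    if b5 == b3:
        raise ValueError("zero-length deletion: b5 == b3")
    gap = b3 - b5
    return gap if gap > 0 else gap + length


@dataclass(frozen=True)
class Region:
    """A named annotated region, possibly wrapping the origin."""

    name: str
    start: int
    end: int
    wraps: bool = False

    def validate(self, length: int) -> None:
        if not (1 <= self.start <= length and 1 <= self.end <= length):
            raise ValueError(
                f"region {self.name}: ({self.start}, {self.end}) outside [1, {length}]"
            )
        if not self.wraps and self.end < self.start:
            raise ValueError(
                f"region {self.name}: end {self.end} < start {self.start} "
                "but wraps is false"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def positions(self, genome_length: int) -> Iterator[int]:
        """1-based positions of the region, in circular order."""
        if self.wraps:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)


@dataclass(frozen=True)
class MitoReference:
    """Circular mitochondrial reference sequence with region annotations."""

    name: str
    sequence: str
    regions: Mapping[str, Region] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        for region in self.regions.values():
            region.validate(len(seq))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at a 1-based circular position."""
        return self.sequence[(pos - 1) % self.length]

    def fetch(self, start: int, length: int) -> str:
        """``length`` bases starting at 1-based circular position ``start``."""
        if length < 0:
            raise ValueError("negative slice length")
        start0 = (start - 1) % self.length
        doubled = self.sequence + self.sequence
        if length > self.length:
            raise ValueError("slice longer than genome")
        return doubled[start0 : start0 + length]

    def region(self, name: str) -> Region:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(f"reference has no region named {name!r}") from None

    def with_sequence(self, sequence: str) -> "MitoReference":
        return replace(self, sequence=sequence)


@dataclass(frozen=True)
class DeletionEvent:
    """One read-supported large-scale deletion.

    ``b5`` is the first deleted base, ``b3`` the first retained base after
    the deleted segment (both 1-based); ``evidence`` records whether the
    deletion surfaced as a CIGAR ``D`` operation or from paired split
    (supplementary) alignments.
    """

    read_id: str
    b5: int
    b3: int
    del_len: int
    evidence: str = "cigar"

    def __post_init__(self) -> None:
        if self.b5 == self.b3:
            raise ValueError("b5 == b3 is a zero-length deletion")
        if self.del_len < 1:
            raise ValueError("del_len must be >= 1")
        if self.evidence not in ("cigar", "split"):
            raise ValueError(f"unknown evidence type {self.evidence!r}")

    @property
    def junction(self) -> tuple[int, int]:
        return (self.b5, self.b3)


def make_event(
    read_id: str, b5: int, b3: int, length: int, evidence: str = "cigar"
) -> DeletionEvent:
    """Build a DeletionEvent, deriving del_len from the circular gap."""
    return DeletionEvent(
        read_id=read_id,
        b5=b5,
        b3=b3,
        del_len=circular_gap(b5, b3, length),
        evidence=evidence,
    )


def in_dloop(event: DeletionEvent, ref: MitoReference) -> bool:
    """True iff either breakend of the event falls inside the D-loop."""
    dloop = ref.region(DLOOP)
    return dloop.contains(event.b5) or dloop.contains(event.b3)


def format_deletion_name(event: DeletionEvent, length: int = RCRS_LENGTH) -> str:
    """HGVS-like name ``m.{b5}_{last_deleted}del{del_len}``.

    The last deleted base is ``b3 - 1`` (wrapping to ``L`` when ``b3`` is 1),
    i.e. names use inclusive deleted-segment bounds while the internal
    representation stays half-open.
    """
    last = event.b3 - 1
    if last == 0:
        last = length
    return f"m.{event.b5}_{last}del{event.del_len}"


_NAME_RE = re.compile(r"^m\.(\d+)_(\d+)del(\d+)$")


def parse_deletion_name(name: str, length: int = RCRS_LENGTH) -> tuple[int, int, int]:
    """Inverse of :func:`format_deletion_name`; returns ``(b5, b3, del_len)``."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable deletion name {name!r}")
    b5, last, del_len = (int(g) for g in m.groups())
    b3 = last % length + 1
    if circular_gap(b5, b3, length) != del_len:
        raise ValueError(f"inconsistent deletion name {name!r}")
    return b5, b3, del_len


def load_reference(
    fasta: str | Path,
    contig: str | None = None,
    region_config: Mapping[str, Mapping] | None = None,
) -> MitoReference:
    """Load a mitochondrial reference from FASTA with region annotations.

    ``region_config`` maps region name to ``{"start", "end", "wraps"}``;
    it defaults to the rCRS annotations for MT-RNR2, MT-ND4 and the D-loop
    and may be overridden e.g. for toy genomes.
    """
    records = {rec.id: rec for rec in SeqIO.parse(str(fasta), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {fasta}")
    if contig is None:
        record = next(iter(records.values()))
    elif contig in records:
        record = records[contig]
    else:
        raise ValueError(f"contig {contig!r} not found in {fasta}")
    config = region_config if region_config is not None else DEFAULT_REGIONS
    regions = {
        name: Region(
            name=name,
            start=int(cfg["start"]),
            end=int(cfg["end"]),
            wraps=bool(cfg.get("wraps", False)),
        )
        for name, cfg in config.items()
    }
    return MitoReference(name=record.id, sequence=str(record.seq), regions=regions)


def scaled_regions(genome_length: int) -> dict[str, Region]:
    """rCRS region annotations scaled proportionally to ``genome_length``."""

    def scale(pos: int) -> int:
        return max(1, min(genome_length, round(pos / RCRS_LENGTH * genome_length)))

    regions = {}
    for name, cfg in DEFAULT_REGIONS.items():
        start, end = scale(cfg["start"]), scale(cfg["end"])
        if not cfg["wraps"] and end < start:
            end = start
        regions[name] = Region(name=name, start=start, end=end, wraps=cfg["wraps"])
    return regions
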