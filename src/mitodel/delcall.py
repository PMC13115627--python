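"""Large-scale deletion calling from CIGAR and split alignments.

Deletions between 500 bp and 15,000 bp (inclusive, configurable) are
extracted from two evidence classes:

* ``cigar`` — a deletion (D) operation inside a single alignment record;
  with a long-read aligner tuned for low gap-extension penalties most
  large deletions surface this way.
* ``split`` — two supplementary segments of one read adjacent in query
  coordinates whose reference footprints leave a gap in the size window.

A read contributing both a CIGAR and a split view of the same junction
counts once.  The heteroplasmy numerator downstream counts deletion-bearing
reads (molecules), not events, since heteroplasmy is a molecule fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alnio import AlignedRead, group_by_read
from .refmodel import DeletionEvent, circular_gap

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 500
DEFAULT_MAX_LEN = 15000
DEFAULT_MAX_READ_GAP = 50


@dataclass
class DeletionSet:
    """All qualifying deletion events for one sample."""

    sample_id: str
    events: list[DeletionEvent] = field(default_factory=list)
    size_window: tuple[int, int] = (DEFAULT_MIN_LEN, DEFAULT_MAX_LEN)

    @property
    def n_deletion_reads(self) -> int:
        """Distinct reads bearing at least one qualifying deletion."""
        return len({e.read_id for e in self.events})

    @property
    def junctions(self) -> list[tuple[int, int]]:
        return [e.junction for e in self.events]


def deletions_from_cigar(
    read: AlignedRead,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    merge_gap: int = 0,
) -> list[DeletionEvent]:
    """Deletion events from D operations within the size window.

    With ``merge_gap > 0``, consecutive D operations separated by at most
    ``merge_gap`` matched bases (alignment wobble) are merged into a single
    deletion spanning first-D start to last-D end before the size filter is
    applied; merging is off by default.
    """
    raw: list[tuple[int, int]] = []  # (b5, b3) of each D op
    pos = read.ref_start
    for op, n in read.cigar:
        if op == "D":
            raw.append((pos, pos + n))
            pos += n
        elif op in "M=XN":
            pos += n
    if merge_gap > 0 and len(raw) > 1:
        merged: list[tuple[int, int]] = [raw[0]]
        for b5, b3 in raw[1:]:
            if b5 - merged[-1][1] <= merge_gap:
                merged[-1] = (merged[-1][0], b3)
            else:
                merged.append((b5, b3))
        raw = merged
    events = []
    for b5, b3 in raw:
        del_len = b3 - b5
        if min_len <= del_len <= max_len:
            events.append(
                DeletionEvent(
                    read_id=read.read_id,
                    b5=b5,
                    b3=b3,
                    del_len=del_len,
                    evidence="cigar",
                )
            )
    return events


def deletions_from_split(
    segments: Sequence[AlignedRead],
    length: int,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_read_gap: int = DEFAULT_MAX_READ_GAP,
) -> list[DeletionEvent]:
    """Deletion events from supplementary segment pairs of one read.

    Segments are ordered by their aligned interval on the read; each pair
    adjacent in query coordinates (|gap| <= ``max_read_gap``) whose
    reference footprints leave a circular gap in the size window yields an
    event.  A pair that is contiguous on the circle (split only because the
    alignment crossed the origin) yields nothing.  Mixed-strand segment
    sets are skipped: a deletion junction keeps both segments on one strand.
    """
    if len(segments) < 2:
        return []
    strands = {seg.is_reverse for seg in segments}
    if len(strands) > 1:
        logger.warning(
            "read %s has segments on both strands; skipped for split calling",
            segments[0].read_id,
        )
        return []
    ordered = sorted(segments, key=lambda s: s.query_span()[0])
    events = []
    for left, right in zip(ordered, ordered[1:]):
        q_gap = right.query_span()[0] - left.query_span()[1]
        if abs(q_gap) > max_read_gap:
            continue
        b5 = left.ref_end % length + 1
        b3 = right.ref_start
        if b5 == b3:  # contiguous around the origin, no deleted bases
            continue
        gap = circular_gap(b5, b3, length)
        if min_len <= gap <= max_len:
            events.append(
                DeletionEvent(
                    read_id=left.read_id,
                    b5=b5,
                    b3=b3,
                    del_len=gap,
                    evidence="split",
                )
            )
    return events


def collect_sample_deletions(
    reads: Iterable[AlignedRead],
    length: int,
    sample_id: str = "sample",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_read_gap: int = DEFAULT_MAX_READ_GAP,
    merge_gap: int = 0,
) -> DeletionSet:
    """Union of CIGAR and split deletion evidence, deduplicated per read.

    Within one read, identical junctions ``(b5, b3)`` seen through both
    evidence classes count once (CIGAR evidence preferred).  Output order
    is independent of read order.
    """
    groups = group_by_read(reads)
    events: list[DeletionEvent] = []
    for read_id in sorted(groups):
        segs = groups[read_id]
        seen: dict[tuple[int, int], DeletionEvent] = {}
        for seg in segs:
            for ev in deletions_from_cigar(seg, min_len, max_len, merge_gap):
                seen.setdefault(ev.junction, ev)
        for ev in deletions_from_split(segs, length, min_len, max_len, max_read_gap):
            seen.setdefault(ev.junction, ev)
        events.extend(seen[j] for j in sorted(seen))
    events.sort(key=lambda e: (e.b5, e.b3, e.read_id))
    return DeletionSet(
        sample_id=sample_id, events=events, size_window=(min_len, max_len)
    )
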