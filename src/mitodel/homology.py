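"""Breakpoint microhomology measurement and catalogue comparison.

For each deletion, 20 bp on either side of the 5' and of the 3' breakpoint
are extracted (40 bp per breakpoint, circular wrap allowed).  The
microhomology length is the run of position-wise identical bases through
the junction offset: the forward run starting at the junction plus the
backward run immediately before it, capped at the window size.  This is
the junction-anchored repeat conventionally reported for deletion
breakpoints; an unanchored longest-common-substring variant is available
behind ``mode="substring"`` but inflates lengths on short windows.

Deletions with either breakend in the D-loop are excluded from summaries,
since NUMT breakpoints concentrate there and clinical interpretation
focuses on coding regions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cluster import DeletionCluster
from .refmodel import (
    DeletionEvent,
    MitoReference,
    RCRS_LENGTH,
    in_dloop,
    make_event,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20

CATALOGUE_SOURCES = ("MITOMAP", "MitoBreak", "custom")

#: Per-source TSV dialect: breakpoint column names and coordinate basing.
CATALOGUE_DIALECTS: dict[str, dict] = {
    "MITOMAP": {"b5_col": "start", "b3_col": "end", "one_based": True},
    "MitoBreak": {"b5_col": "5' breakpoint", "b3_col": "3' breakpoint", "one_based": True},
    "custom": {"b5_col": "b5", "b3_col": "b3", "one_based": True},
}


@dataclass(frozen=True)
class MicrohomologyResult:
    event: DeletionEvent
    flank5: str
    flank3: str
    mh_len: int


@dataclass(frozen=True)
class BreakpointCatalogue:
    source: str
    records: tuple[tuple[int, int], ...]


def extract_flanks(
    ref: MitoReference, event: DeletionEvent, w: int = DEFAULT_WINDOW
) -> tuple[str, str]:
    """2w-base windows centered on each breakpoint, with circular wrap.

    ``flank5`` covers positions ``[b5-w, b5+w-1]`` and ``flank3`` covers
    ``[b3-w, b3+w-1]``, so index ``w`` of each window is the breakpoint
    itself (first deleted base / first retained base).
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    return ref.fetch(event.b5 - w, 2 * w), ref.fetch(event.b3 - w, 2 * w)


def microhomology_length(flank5: str, flank3: str, w: int = DEFAULT_WINDOW) -> int:
    """Junction-anchored run of position-wise matches between the flanks.

    Forward run from offset ``w`` plus backward run ending at ``w - 1``,
    capped at ``2w``.
    """
    if len(flank5) != len(flank3):
        raise ValueError("flanks must have equal length")
    if len(flank5) != 2 * w:
        raise ValueError(f"flanks must be {2 * w} bases for window {w}")
    forward = 0
    while forward < w and flank5[w + forward] == flank3[w + forward]:
        forward += 1
    backward = 0
    while backward < w and flank5[w - 1 - backward] == flank3[w - 1 - backward]:
        backward += 1
    return min(forward + backward, 2 * w)


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring (unanchored match rule)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def measure_event(
    ref: MitoReference,
    event: DeletionEvent,
    w: int = DEFAULT_WINDOW,
    mode: str = "junction",
) -> MicrohomologyResult:
    flank5, flank3 = extract_flanks(ref, event, w)
    if mode == "junction":
        mh = microhomology_length(flank5, flank3, w)
    elif mode == "substring":
        mh = longest_common_substring(flank5, flank3)
    else:
        raise ValueError(f"unknown microhomology mode {mode!r}")
    return MicrohomologyResult(event=event, flank5=flank5, flank3=flank3, mh_len=mh)


def exclude_dloop(
    events: Iterable[DeletionEvent], ref: MitoReference
) -> list[DeletionEvent]:
    """Drop events with either breakend inside the D-loop."""
    return [e for e in events if not in_dloop(e, ref)]


def analyze_events(
    ref: MitoReference,
    events: Sequence[DeletionEvent],
    w: int = DEFAULT_WINDOW,
    mode: str = "junction",
) -> list[MicrohomologyResult]:
    return [measure_event(ref, e, w, mode) for e in events]


def events_from_clusters(
    clusters: Sequence[DeletionCluster], length: int = RCRS_LENGTH
) -> list[DeletionEvent]:
    """Unique deletions for homology summaries: one event per cluster
    representative breakpoint pair."""
    return [
        make_event(f"cluster_{c.cluster_id}", c.rep_b5, c.rep_b3, length)
        for c in clusters
    ]


def homology_summary(results: Sequence[MicrohomologyResult]) -> dict:
    """Fraction of deletions with >=1 bp microhomology plus the mh_len
    frequency histogram."""
    if not results:
        return {"n": 0, "pct_ge1": None, "histogram": {}}
    lengths = [r.mh_len for r in results]
    ge1 = sum(1 for k in lengths if k >= 1)
    return {
        "n": len(lengths),
        "pct_ge1": 100.0 * ge1 / len(lengths),
        "histogram": dict(sorted(Counter(lengths).items())),
    }


def load_catalogue(
    path: str | Path,
    source: str = "custom",
    length: int = RCRS_LENGTH,
    b5_col: str | None = None,
    b3_col: str | None = None,
) -> BreakpointCatalogue:
    """Load a deletion breakpoint catalogue from TSV.

    Column names and coordinate basing default to the per-source dialect;
    out-of-range or unparseable rows are skipped with a logged count, and a
    file with no usable rows is an error.
    """
    if source not in CATALOGUE_SOURCES:
        raise ValueError(f"unknown catalogue source {source!r}")
    dialect = CATALOGUE_DIALECTS[source]
    b5_col = b5_col or dialect["b5_col"]
    b3_col = b3_col or dialect["b3_col"]
    table = pd.read_csv(path, sep="\t")
    if table.empty:
        raise ValueError(f"catalogue {path} has no rows")
    if b5_col not in table.columns or b3_col not in table.columns:
        raise ValueError(
            f"catalogue {path} lacks columns {b5_col!r}/{b3_col!r}"
        )
    records = []
    n_bad = 0
    for _, row in table.iterrows():
        try:
            b5, b3 = int(row[b5_col]), int(row[b3_col])
        except (TypeError, ValueError):
            n_bad += 1
            continue
        if not (1 <= b5 <= length and 1 <= b3 <= length) or b5 == b3:
            n_bad += 1
            continue
        records.append((b5, b3))
    if n_bad:
        logger.warning("catalogue %s: skipped %d invalid rows", path, n_bad)
    if not records:
        raise ValueError(f"catalogue {path} has no valid breakpoint rows")
    return BreakpointCatalogue(source=source, records=tuple(records))


def catalogue_events(
    cat: BreakpointCatalogue, length: int = RCRS_LENGTH
) -> list[DeletionEvent]:
    return [
        make_event(f"{cat.source}_{i}", b5, b3, length)
        for i, (b5, b3) in enumerate(cat.records)
    ]
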