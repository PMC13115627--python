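"""End-to-end sample workflow: alignments -> deletions -> clusters -> call.

Mirrors the per-sample reporting of a deletion analysis: mean mitogenome
coverage, qualifying deletion count, MT-RNR2 coverage, LRS heteroplasmy and
the SLSMD/MMD/Negative classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import alnio, delcall, quant
from .cluster import (
    Classification,
    ClusterParams,
    DeletionCluster,
    SampleCall,
    classify_sample,
    cluster_deletions,
)
from .delcall import DeletionSet
from .refmodel import RNR2, MitoReference, format_deletion_name, make_event

logger = logging.getLogger(__name__)


@dataclass
class DetectionReport:
    sample_id: str
    call: SampleCall
    deletions: DeletionSet
    clusters: list[DeletionCluster]
    mean_coverage: float
    rnr2_coverage: float
    heteroplasmy_pct: float

    def summary_row(self) -> dict:
        """One report row mirroring the cohort-table columns."""
        return {
            "sample_id": self.sample_id,
            "mean_mtdna_coverage": round(self.mean_coverage, 1),
            "n_deletions_in_window": self.deletions.n_deletion_reads,
            "mean_rnr2_coverage": quant.round2(self.rnr2_coverage),
            "heteroplasmy_pct": quant.round2(self.heteroplasmy_pct),
            "classification": self.call.classification.value,
        }


def detect_sample(
    alignments: str | Path,
    ref: MitoReference,
    sample_id: str = "sample",
    contig: str = "chrM",
    min_mapq: int = 10,
    min_len: int = delcall.DEFAULT_MIN_LEN,
    max_len: int = delcall.DEFAULT_MAX_LEN,
    cluster_params: ClusterParams | None = None,
) -> DetectionReport:
    """Run the full deletion-detection workflow on one alignment file."""
    reads = list(alnio.read_mito_alignments(alignments, contig, min_mapq))
    if not reads:
        logger.warning("no mitochondrial alignments in %s; calling Negative", alignments)
        empty = DeletionSet(sample_id=sample_id, size_window=(min_len, max_len))
        return DetectionReport(
            sample_id=sample_id,
            call=SampleCall(sample_id, Classification.NEGATIVE, []),
            deletions=empty,
            clusters=[],
            mean_coverage=0.0,
            rnr2_coverage=0.0,
            heteroplasmy_pct=0.0,
        )
    profile = alnio.depth_profile(reads, ref.length)
    rnr2_cov = alnio.mean_region_coverage(profile, ref.region(RNR2))
    dels = delcall.collect_sample_deletions(
        reads, ref.length, sample_id, min_len=min_len, max_len=max_len
    )
    clusters = cluster_deletions(dels, cluster_params, ref.length)
    call = classify_sample(clusters, dels)
    het = (
        quant.lrs_heteroplasmy(dels.n_deletion_reads, rnr2_cov)
        if rnr2_cov > 0
        else 0.0
    )
    call.heteroplasmy_pct = het
    return DetectionReport(
        sample_id=sample_id,
        call=call,
        deletions=dels,
        clusters=clusters,
        mean_coverage=profile.mean,
        rnr2_coverage=rnr2_cov,
        heteroplasmy_pct=het,
    )


def deletion_table(report: DetectionReport) -> pd.DataFrame:
    rows = [
        {
            "sample_id": report.sample_id,
            "read_id": e.read_id,
            "b5": e.b5,
            "b3": e.b3,
            "del_len": e.del_len,
            "evidence": e.evidence,
        }
        for e in report.deletions.events
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "read_id", "b5", "b3", "del_len", "evidence"]
    )


def cluster_table(report: DetectionReport, genome_len: int) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "rep_b5": c.rep_b5,
            "rep_b3": c.rep_b3,
            "support": c.support,
            "recurrent": c.recurrent,
            "name": format_deletion_name(
                make_event("rep", c.rep_b5, c.rep_b3, genome_len), genome_len
            ),
        }
        for c in report.clusters
    ]
    return pd.DataFrame(
        rows, columns=["cluster_id", "rep_b5", "rep_b3", "support", "recurrent", "name"]
    )


def arc_table(report: DetectionReport) -> pd.DataFrame:
    """Circos-style arc export: one arc per cluster, weighted by support."""
    rows = [
        {"start": c.rep_b5, "end": c.rep_b3, "weight": c.support}
        for c in report.clusters
    ]
    return pd.DataFrame(rows, columns=["start", "end", "weight"])


def write_report(
    report: DetectionReport, outdir: str | Path, genome_len: int
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "deletions": outdir / f"{report.sample_id}.deletions.tsv",
        "clusters": outdir / f"{report.sample_id}.clusters.tsv",
        "arcs": outdir / f"{report.sample_id}.arcs.tsv",
        "summary": outdir / f"{report.sample_id}.summary.json",
    }
    deletion_table(report).to_csv(paths["deletions"], sep="\t", index=False)
    cluster_table(report, genome_len).to_csv(paths["clusters"], sep="\t", index=False)
    arc_table(report).to_csv(paths["arcs"], sep="\t", index=False)
    paths["summary"].write_text(json.dumps(report.summary_row(), indent=2) + "\n")
    return paths
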