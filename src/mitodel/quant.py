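"""Heteroplasmy quantification, concordance statistics and benchmarks.

Deletion heteroplasmy from long reads is the percentage of sequenced mtDNA
molecules carrying a large-scale deletion.  The denominator is the mean
coverage over the MT-RNR2 gene — the locus the clinical ddPCR assay uses to
count total mtDNA molecules, chosen because it is almost never deleted —
and the numerator is the number of deletion-bearing reads:

    h = 100 * n_del / cov(MT-RNR2)

The companion ddPCR estimate uses the two-probe ratio
``[1 - (ND4 / RNR2)] * 100`` (MT-ND4 sits inside the commonly deleted arc).
Method agreement is assessed with Pearson correlation and Bland–Altman
analysis (bias and 1.96-SD limits of agreement, sample SD with n-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import alnio, delcall
from .alnio import AlignedRead, depth_profile, mean_region_coverage
from .refmodel import RCRS_LENGTH, RNR2, MitoReference

logger = logging.getLogger(__name__)


def round2(x: float) -> float:
    """Half-away-from-zero rounding to 2 decimals, as printed in reports."""
    return float(np.format_float_positional(x, 2, unique=False, fractional=True))


@dataclass(frozen=True)
class HeteroplasmyEstimate:
    sample_id: str
    n_del: int
    rnr2_cov: float

    @property
    def pct(self) -> float:
        return lrs_heteroplasmy(self.n_del, self.rnr2_cov)


def lrs_heteroplasmy(n_del: int, rnr2_cov: float) -> float:
    """Deletion heteroplasmy (%) = 100 * deletion reads / mean RNR2 coverage."""
    if rnr2_cov <= 0:
        raise ValueError("RNR2 coverage must be positive")
    if n_del < 0:
        raise ValueError("deletion read count must be non-negative")
    pct = 100.0 * n_del / rnr2_cov
    if pct > 100.0:
        logger.warning(
            "heteroplasmy %.2f%% exceeds 100%%: more deletion reads than "
            "RNR2-covering molecules (pathological input?)",
            pct,
        )
    return pct


def ddpcr_heteroplasmy(nd4_count: float, rnr2_count: float) -> float:
    """Two-probe ddPCR heteroplasmy (%): ``[1 - ND4/RNR2] * 100``."""
    if rnr2_count <= 0:
        raise ValueError("RNR2 droplet count must be positive")
    if nd4_count < 0:
        raise ValueError("ND4 droplet count must be non-negative")
    pct = (1.0 - nd4_count / rnr2_count) * 100.0
    if pct < 0:
        logger.warning("negative ddPCR heteroplasmy %.2f%% clamped to 0 (probe noise)", pct)
        pct = 0.0
    return pct


@dataclass(frozen=True)
class ConcordancePair:
    sample_id: str
    lrs_pct: float
    ddpcr_pct: float


def pearson_r(pairs: Sequence[ConcordancePair]) -> float:
    """Product-moment correlation between LRS and ddPCR heteroplasmy."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    x = np.array([p.lrs_pct for p in pairs])
    y = np.array([p.ddpcr_pct for p in pairs])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in one coordinate")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(pairs: Sequence[ConcordancePair]) -> BlandAltmanResult:
    """Bland–Altman agreement of LRS vs ddPCR heteroplasmy.

    Differences are ``lrs - ddpcr``; bias is their mean and the limits of
    agreement are ``bias ± 1.96 * SD`` with the sample SD (n-1 divisor).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    d = np.array([p.lrs_pct - p.ddpcr_pct for p in pairs])
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(pairs),
    )


@dataclass(frozen=True)
class BenchmarkCounts:
    """TP/FP/FN counts for one caller on one sample.

    ``total_called`` is the size of the truth call set; true negatives are
    the remaining genome positions, ``TN = L - total_called``.
    """

    tp: int
    fp: int
    fn: int
    total_called: int
    genome_len: int = RCRS_LENGTH

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.total_called) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def tn(self) -> int:
        return self.genome_len - self.total_called


@dataclass(frozen=True)
class BenchmarkMetrics:
    sensitivity: float
    specificity: float
    precision: float
    recall: float


def _ratio_pct(num: int, den: int) -> float:
    """100*num/den with the 0/0 -> 0.00 reporting convention."""
    if den == 0:
        return 0.0
    return round2(100.0 * num / den)


def benchmark_metrics(c: BenchmarkCounts) -> BenchmarkMetrics:
    """Sensitivity/specificity/precision/recall (%, 2 decimals)."""
    sens = _ratio_pct(c.tp, c.tp + c.fn)
    spec = _ratio_pct(c.tn, c.tn + c.fp)
    prec = _ratio_pct(c.tp, c.tp + c.fp)
    return BenchmarkMetrics(
        sensitivity=sens, specificity=spec, precision=prec, recall=sens
    )


def estimate_from_reads(
    reads: Sequence[AlignedRead],
    ref: MitoReference,
    sample_id: str = "sample",
    min_len: int = delcall.DEFAULT_MIN_LEN,
    max_len: int = delcall.DEFAULT_MAX_LEN,
) -> tuple[HeteroplasmyEstimate, float]:
    """Heteroplasmy estimate plus mean genome coverage for a read set."""
    profile = depth_profile(reads, ref.length)
    rnr2_cov = mean_region_coverage(profile, ref.region(RNR2))
    dels = delcall.collect_sample_deletions(
        reads, ref.length, sample_id, min_len=min_len, max_len=max_len
    )
    est = HeteroplasmyEstimate(
        sample_id=sample_id, n_del=dels.n_deletion_reads, rnr2_cov=rnr2_cov
    )
    return est, profile.mean


DEFAULT_FRACTIONS: tuple[float, ...] = tuple(
    round(f, 2) for f in np.arange(0.05, 1.0001, 0.05)
)


def downsample_series(
    reads: Sequence[AlignedRead],
    ref: MitoReference,
    fractions: Sequence[float] | None = None,
    n_reps: int = 5,
    seed: int = 0,
    min_len: int = delcall.DEFAULT_MIN_LEN,
    max_len: int = delcall.DEFAULT_MAX_LEN,
) -> pd.DataFrame:
    """Heteroplasmy precision under random read subsampling.

    For each (fraction, replicate) a fraction of reads is drawn without
    replacement (supplementary segments travel with their read) and the
    deletion-calling + quantification pipeline reruns on the subset.
    Defaults mirror the coverage-titration design: 5% to 100% of total
    coverage in 5% increments, 5 sub-replicates each.  Deterministic for a
    given seed.
    """
    fractions = tuple(fractions) if fractions is not None else DEFAULT_FRACTIONS
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    groups = alnio.group_by_read(reads)
    read_ids = np.array(sorted(groups))
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        for rep in range(n_reps):
            k = int(round(frac * len(read_ids)))
            if k == 0:
                rows.append(
                    dict(fraction=frac, rep=rep, n_reads=0, mean_cov=0.0,
                         rnr2_cov=0.0, n_del=0, heteroplasmy=np.nan)
                )
                continue
            chosen = rng.choice(read_ids, size=k, replace=False)
            subset = [seg for rid in chosen for seg in groups[rid]]
            est, mean_cov = estimate_from_reads(
                subset, ref, min_len=min_len, max_len=max_len
            )
            het = est.pct if est.rnr2_cov > 0 else np.nan
            rows.append(
                dict(fraction=frac, rep=rep, n_reads=k, mean_cov=mean_cov,
                     rnr2_cov=est.rnr2_cov, n_del=est.n_del, heteroplasmy=het)
            )
    return pd.DataFrame(rows)


def downsample_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction mean coverage and heteroplasmy SD across replicates."""
    return (
        table.groupby("fraction")
        .agg(
            mean_cov=("mean_cov", "mean"),
            het_mean=("heteroplasmy", "mean"),
            het_sd=("heteroplasmy", "std"),
            n_reps=("rep", "count"),
        )
        .reset_index()
    )
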