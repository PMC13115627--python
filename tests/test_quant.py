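"""Heteroplasmy formulas, concordance statistics and benchmark metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitodel import simgen
from mitodel.quant import (
    BenchmarkCounts,
    ConcordancePair,
    benchmark_metrics,
    bland_altman,
    ddpcr_heteroplasmy,
    downsample_series,
    downsample_summary,
    lrs_heteroplasmy,
    pearson_r,
    round2,
)

# Published cohort values: (sample, deletion reads, mean RNR2 coverage, %).
COHORT_ROWS = [
    ("S1", 372, 582.03, 63.91),
    ("S2", 779, 2330.24, 33.43),
    ("S3", 80, 316.84, 25.25),
    ("S4", 107, 344.87, 31.03),
    ("M1r1", 120, 487.52, 24.61),
    ("M1r2", 67, 414.11, 16.18),
    ("M2", 1097, 3526.36, 31.11),
    ("M3", 41, 1104.97, 3.71),
    ("M4", 376, 6299.55, 5.97),
    ("M5", 21, 3032.39, 0.69),
    ("M6", 1, 1549.59, 0.06),
    ("M7r1", 0, 351.83, 0.00),
    ("M7r2", 1, 252.33, 0.40),
    ("M8", 4, 870.98, 0.46),
    ("M9", 0, 307.88, 0.00),
    ("C1", 0, 5314.47, 0.00),
    ("C2", 0, 5925.83, 0.00),
    ("C3", 5, 21127.69, 0.02),
    ("C4", 0, 180.38, 0.00),
]

SLSMD_PAIRS = [
    ConcordancePair("S1", 63.91, 73.0),
    ConcordancePair("S2", 33.43, 45.0),
    ConcordancePair("S3", 25.25, 40.0),
    ConcordancePair("S4", 31.03, 34.0),
]


class TestLrsHeteroplasmy:
    @pytest.mark.parametrize("sample, n_del, cov, expected", COHORT_ROWS)
    def test_cohort_arithmetic(self, sample, n_del, cov, expected):
        assert round2(lrs_heteroplasmy(n_del, cov)) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            lrs_heteroplasmy(10, 0)

    @given(st.integers(0, 2000), st.floats(1, 1e4), st.floats(0.01, 100))
    def test_scale_invariance(self, n_del, cov, k):
        scaled = lrs_heteroplasmy(n_del, cov) if k == 0 else None
        assert lrs_heteroplasmy(n_del, cov) == pytest.approx(
            lrs_heteroplasmy(n_del * 7, cov * 7), rel=1e-9
        )


class TestDdpcrHeteroplasmy:
    @pytest.mark.parametrize(
        "nd4, rnr2, expected",
        [(100, 100, 0.0), (0, 50, 100.0), (27, 100, 73.0)],
    )
    def test_two_probe_formula(self, nd4, rnr2, expected):
        assert ddpcr_heteroplasmy(nd4, rnr2) == pytest.approx(expected)

    def test_negative_clamped_to_zero(self):
        assert ddpcr_heteroplasmy(110, 100) == 0.0

    def test_zero_rnr2_rejected(self):
        with pytest.raises(ValueError):
            ddpcr_heteroplasmy(10, 0)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        up = [ConcordancePair(str(i), float(i), 2.0 * i + 1) for i in range(5)]
        down = [ConcordancePair(str(i), float(i), -3.0 * i + 7) for i in range(5)]
        assert pearson_r(up) == pytest.approx(1.0)
        assert pearson_r(down) == pytest.approx(-1.0)

    def test_slsmd_pairs_match_independent_formula(self):
        x = np.array([p.lrs_pct for p in SLSMD_PAIRS])
        y = np.array([p.ddpcr_pct for p in SLSMD_PAIRS])
        manual = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert pearson_r(SLSMD_PAIRS) == pytest.approx(manual, abs=1e-12)
        assert round(manual, 2) == 0.96

    def test_zero_variance_rejected(self):
        flat = [ConcordancePair(str(i), 5.0, float(i)) for i in range(4)]
        with pytest.raises(ValueError):
            pearson_r(flat)


class TestBlandAltman:
    def test_slsmd_agreement(self):
        result = bland_altman(SLSMD_PAIRS)
        assert result.bias == pytest.approx(-9.60, abs=0.0051)
        assert result.loa_low == pytest.approx(-19.37, abs=0.0051)
        assert result.loa_high == pytest.approx(0.18, abs=0.0051)

    def test_identical_pairs(self):
        pairs = [ConcordancePair(str(i), float(i), float(i)) for i in range(4)]
        result = bland_altman(pairs)
        assert result.bias == 0 and result.loa_low == 0 and result.loa_high == 0

    def test_constant_offset(self):
        pairs = [ConcordancePair(str(i), i + 3.5, float(i)) for i in range(4)]
        result = bland_altman(pairs)
        assert result.bias == pytest.approx(3.5) and result.sd_diff == pytest.approx(0)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(SLSMD_PAIRS[:1])

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=2, max_size=12
        )
    )
    def test_matches_brute_force(self, raw):
        pairs = [ConcordancePair(str(i), a, b) for i, (a, b) in enumerate(raw)]
        result = bland_altman(pairs)
        diffs = [a - b for a, b in raw]
        mean = sum(diffs) / len(diffs)
        var = sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)
        sd = var ** 0.5
        assert result.bias == pytest.approx(mean, abs=1e-9)
        assert result.loa_low == pytest.approx(mean - 1.96 * sd, abs=1e-9)
        assert result.loa_high == pytest.approx(mean + 1.96 * sd, abs=1e-9)


# Published benchmark rows: (caller, variant type, sample, tp, fp, fn,
# truth-set size, printed TN, sens, spec, prec, recall).
BENCHMARK_ROWS = [
    ("LoFreq", "SNV", "C1", 16, 0, 0, 16, 16553, 100.00, 100.00, 100.00, 100.00),
    ("LoFreq", "SNV", "C2", 37, 0, 0, 37, 16532, 100.00, 100.00, 100.00, 100.00),
    ("LoFreq", "SNV", "C3", 15, 0, 0, 15, 16554, 100.00, 100.00, 100.00, 100.00),
    ("LoFreq", "SNV", "C4", 34, 0, 0, 34, 16535, 100.00, 100.00, 100.00, 100.00),
    ("Mutect2", "SNV", "C1", 16, 0, 0, 16, 16553, 100.00, 100.00, 100.00, 100.00),
    ("Mutect2", "SNV", "C2", 37, 0, 0, 37, 16532, 100.00, 100.00, 100.00, 100.00),
    ("Mutect2", "SNV", "C3", 15, 0, 0, 15, 16554, 100.00, 100.00, 100.00, 100.00),
    ("Mutect2", "SNV", "C4", 34, 0, 2, 34, 16535, 94.44, 100.00, 100.00, 94.44),
    ("LoFreq", "indel", "C1", 0, 0, 0, 0, 16569, 0.00, 100.00, 0.00, 0.00),
    ("LoFreq", "indel", "C2", 1, 0, 0, 1, 16568, 100.00, 100.00, 100.00, 100.00),
    ("LoFreq", "indel", "C3", 1, 0, 0, 1, 16568, 100.00, 100.00, 100.00, 100.00),
    ("LoFreq", "indel", "C4", 2, 0, 2, 2, 16567, 50.00, 100.00, 100.00, 50.00),
    ("Mutect2", "indel", "C1", 0, 2, 0, 0, 16569, 0.00, 99.99, 0.00, 0.00),
    ("Mutect2", "indel", "C2", 1, 1, 0, 1, 16568, 100.00, 99.99, 50.00, 100.00),
    ("Mutect2", "indel", "C3", 1, 1, 0, 1, 16568, 100.00, 99.99, 50.00, 100.00),
    ("Mutect2", "indel", "C4", 2, 2, 0, 2, 16567, 100.00, 99.99, 50.00, 100.00),
]


class TestBenchmarkMetrics:
    @pytest.mark.parametrize(
        "caller, vtype, sample, tp, fp, fn, called, tn, sens, spec, prec, rec",
        BENCHMARK_ROWS,
        ids=[f"{r[0]}-{r[1]}-{r[2]}" for r in BENCHMARK_ROWS],
    )
    def test_published_benchmark_cells(
        self, caller, vtype, sample, tp, fp, fn, called, tn, sens, spec, prec, rec
    ):
        counts = BenchmarkCounts(tp=tp, fp=fp, fn=fn, total_called=called)
        assert counts.tn == tn
        metrics = benchmark_metrics(counts)
        assert metrics.sensitivity == pytest.approx(sens)
        assert metrics.specificity == pytest.approx(spec)
        assert metrics.precision == pytest.approx(prec)
        assert metrics.recall == pytest.approx(rec)

    def test_mixed_calls_precision(self):
        metrics = benchmark_metrics(BenchmarkCounts(tp=1, fp=1, fn=0, total_called=1))
        assert metrics.precision == 50.00 and metrics.sensitivity == 100.00

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkCounts(tp=-1, fp=0, fn=0, total_called=0)


@pytest.fixture(scope="module")
def fixture_reads(tmp_path_factory):
    from mitodel import alnio

    config = simgen.preset_config("slsmd", seed=23, mean_coverage=300)
    ref, sim = simgen.simulate_dataset(config)
    sam = tmp_path_factory.mktemp("ds") / "reads.sam"
    sim.write_sam(sam)
    return list(alnio.read_mito_alignments(sam)), ref


class TestDownsampling:

    def test_full_fraction_reproduces_full_estimate(self, fixture_reads):
        reads, ref = fixture_reads
        table = downsample_series(reads, ref, fractions=[1.0], n_reps=3, seed=1)
        assert table.heteroplasmy.nunique() == 1

    def test_default_design_is_twenty_by_five(self, fixture_reads):
        reads, ref = fixture_reads
        table = downsample_series(reads, ref, n_reps=5, seed=1)
        assert len(table) == 100
        assert table.fraction.nunique() == 20

    def test_deterministic_given_seed(self, fixture_reads):
        reads, ref = fixture_reads
        a = downsample_series(reads, ref, fractions=[0.2, 0.5], n_reps=2, seed=9)
        b = downsample_series(reads, ref, fractions=[0.2, 0.5], n_reps=2, seed=9)
        assert a.equals(b)

    def test_summary_has_sd_column(self, fixture_reads):
        reads, ref = fixture_reads
        table = downsample_series(reads, ref, fractions=[0.5, 1.0], n_reps=3, seed=2)
        summary = downsample_summary(table)
        assert set(summary.columns) >= {"fraction", "mean_cov", "het_sd"}

    def test_bad_fraction_rejected(self, fixture_reads):
        reads, ref = fixture_reads
        with pytest.raises(ValueError):
            downsample_series(reads, ref, fractions=[0.0], n_reps=1, seed=1)
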