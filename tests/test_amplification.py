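"""Density scan, region quantification, fold computation, classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lowmeth.amplification import (
    classify_sample,
    count_region_reads,
    density_scan,
    fold_amplification,
    quantify_cohort,
    region_methylation,
    region_read_fraction,
)
from lowmeth.genome import generate_genome, generate_methylome
from lowmeth.simulate import SampleSpec, simulate_sample
from lowmeth.types import CALL_COLUMNS, Region, SampleMethylome


def _sample(rows, **kw):
    return SampleMethylome(sample_id=kw.pop("sample_id", "s"),
                           calls=pd.DataFrame(rows, columns=CALL_COLUMNS), **kw)


class TestDensityScan:
    def test_uniform_calls_give_unit_ratios(self):
        rows = [("c", p, "+", "CG", 1, 0) for p in range(1, 100_000, 100)]
        df = density_scan([_sample(rows)], window_size=10_000)
        assert df["density_ratio"].mean() == pytest.approx(1.0)
        assert (abs(df["density_ratio"] - 1.0) < 0.01).all()

    def test_tenfold_window_renormalisation(self):
        # 99 windows with 100 calls, one with 1000: ratio 1000/109 ~ 9.17
        rows = []
        for w in range(100):
            n = 1000 if w == 0 else 100
            rows += [("c", w * 1000 + 1 + i, "+", "CG", 1, 0) for i in range(n)]
        df = density_scan([_sample(rows)], window_size=1000)
        top = df.iloc[0]
        assert top["start"] == 1
        assert top["density_ratio"] == pytest.approx(1000 / 109, rel=1e-6)

    def test_single_covered_window_ratio_is_window_count(self):
        rows = [("c", 5, "+", "CG", 1, 0) for _ in range(50)]
        df = density_scan([_sample(rows)], window_size=1000, contig_sizes={"c": 10_000})
        assert len(df) == 10
        assert df.iloc[0]["density_ratio"] == pytest.approx(10.0)

    def test_replicates_pooled_before_counting(self):
        a = _sample([("c", 10, "+", "CG", 1, 0)])
        b = _sample([("c", 1010, "+", "CG", 3, 0)])
        df = density_scan([a, b], window_size=1000)
        assert set(df["n_cg_calls"]) == {1, 3}
        assert df["density_ratio"].mean() == pytest.approx(1.0)


class TestRegionQuant:
    region = Region("c", 1000, 2000)

    def test_no_overlap_gives_zero_fraction(self):
        s = _sample([("c", 5000, "+", "CG", 1, 0)], total_mapped_reads=100)
        frac, source = region_read_fraction(s, self.region, region_reads=0)
        assert frac == 0.0 and source == "reads"

    def test_call_fraction_fallback_flagged(self):
        rows = [("c", 1500, "+", "CG", 1, 0)] + [("c", 9000 + i, "+", "CG", 1, 0) for i in range(9)]
        frac, source = region_read_fraction(_sample(rows), self.region)
        assert source == "calls"
        assert frac == pytest.approx(10.0)

    def test_methylation_undefined_below_ten_calls(self):
        rows = [("c", 1500 + i, "+", "CG", 1, 0) for i in range(9)]
        assert region_methylation(_sample(rows), self.region) is None

    def test_fully_methylated_region(self):
        rows = [("c", 1500 + i, "+", "CG", 2, 0) for i in range(10)]
        assert region_methylation(_sample(rows), self.region) == 100.0

    def test_overlap_rule_one_base(self):
        from lowmeth.bisulfite import Alignment

        alns = [
            Alignment("a", "c", 901, "CTOT", 0, 100),  # ends at 1000: overlaps
            Alignment("b", "c", 900, "CTOT", 0, 100),  # ends at 999: no
            Alignment("d", "c", 2000, "CTOT", 0, 100),  # starts at end: overlaps
            Alignment("e", "c", 2001, "CTOT", 0, 100),
        ]
        assert count_region_reads(alns, self.region) == 2


class TestFold:
    def test_printed_cohort_values_give_170fold_claim(self):
        fold = fold_amplification(20.75, 0.032)
        assert fold == pytest.approx(648.4, abs=0.1)
        assert fold >= 170

    def test_equal_fractions_fold_one(self):
        assert fold_amplification(0.5, 0.5) == 1.0

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            fold_amplification(1.0, 0.0)

    @pytest.mark.parametrize("k", [20.0, 100.0])
    def test_planted_factor_recovered_small_unit(self, k):
        # unit is a tiny genome share, so the fraction ratio stays close to k
        g = generate_genome(
            {"chr1": 1_000_000, "chr2": 1_000_000}, seed=21, repeat_density=0.0,
            rdna_contig="chr2", rdna_start=500_001, rdna_unit_length=400,
            rdna_gc=0.40, rdna_cg_every=60,
        )
        m = generate_methylome(g, seed=22)
        spec = SampleSpec(sample_id="s", n_reads=150_000, read_length=150,
                          rdna_copy_factor=k, seed=int(k))
        res = simulate_sample(g, m, spec, mode="calls")
        background = simulate_sample(
            g, m, SampleSpec(sample_id="b", n_reads=150_000, read_length=150, seed=99),
            mode="calls",
        ).truth.expected_region_read_fraction
        fold = fold_amplification(res.truth.realized_region_read_fraction, background)
        assert fold == pytest.approx(k, rel=0.10)


class TestClassify:
    def test_three_printed_archetypes(self):
        kw = dict(background_fraction=0.032)
        assert classify_sample(20.75, 1.7, **kw)[0] == "amplified"
        assert classify_sample(0.03, 73.0, **kw)[0] == "background"
        assert classify_sample(0.3, 10.0, **kw)[0] == "intermediate"

    def test_undefined_methylation_low_fraction_flagged_background(self):
        label, low_evidence = classify_sample(0.05, None, background_fraction=0.032)
        assert label == "background" and low_evidence

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        frac=st.floats(0, 30, allow_nan=False),
        bump=st.floats(0, 30, allow_nan=False),
        meth=st.one_of(st.none(), st.floats(0, 100, allow_nan=False)),
    )
    def test_monotone_in_fraction(self, frac, bump, meth):
        order = {"background": 0, "intermediate": 1, "amplified": 2}
        kw = dict(background_fraction=0.05)
        lo = classify_sample(frac, meth, **kw)[0]
        hi = classify_sample(frac + bump, meth, **kw)[0]
        assert order[hi] >= order[lo]


class TestCohortQuantification:
    def test_background_set_is_non_germline(self):
        region = Region("c", 1000, 2000)
        rows_bg = [("c", 1500 + i, "+", "CG", 8, 2) for i in range(10)]
        rows_out = [("c", 50_000 + 37 * i, "+", "CG", 8, 2) for i in range(490)]
        samples = [
            _sample(rows_bg + rows_out, sample_id="ctrl1", germline=False),
            _sample(rows_bg + rows_out, sample_id="ctrl2", germline=False),
            _sample(rows_bg * 30 + rows_out, sample_id="germ", germline=True),
        ]
        quants = quantify_cohort(samples, region)
        by_id = {q.sample_id: q for q in quants}
        assert by_id["ctrl1"].fold_vs_background == pytest.approx(1.0)
        assert by_id["germ"].fold_vs_background > 10
        assert by_id["germ"].label == "amplified"

    def test_no_controls_rejected(self):
        s = _sample([("c", 1500, "+", "CG", 1, 0)], germline=True)
        with pytest.raises(ValueError):
            quantify_cohort([s], Region("c", 1000, 2000))
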