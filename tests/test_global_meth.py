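"""Windowed/pooled global methylation and repeat partitioning."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lowmeth.globalmeth import (
    global_estimate,
    paired_partition_test,
    partition_by_annotation,
    window_methylation,
)
from lowmeth.simulate import SampleSpec, simulate_sample
from lowmeth.types import CALL_COLUMNS, SampleMethylome


def _sample(rows):
    return SampleMethylome(sample_id="s", calls=pd.DataFrame(rows, columns=CALL_COLUMNS))


class TestWindowMethylation:
    def test_all_methylated_windows_are_one(self):
        s = _sample([("c", p, "+", "CG", 3, 0) for p in (5, 15_000_000, 25_000_000)])
        win = window_methylation(s)
        assert (win["meth_fraction"] == 1.0).all()

    def test_counts_in_one_window(self):
        s = _sample([("c", 100, "+", "CG", 8, 2)])
        win = window_methylation(s)
        assert len(win) == 1
        assert win.loc[0, "n_cg_calls"] == 10
        assert win.loc[0, "meth_fraction"] == pytest.approx(0.8)

    def test_boundary_position_falls_in_second_window(self):
        s = _sample([("c", 10_000_000, "+", "CG", 1, 0), ("c", 10_000_001, "+", "CG", 0, 1)])
        win = window_methylation(s, window_size=10_000_000)
        assert list(win["start"]) == [1, 10_000_001]
        assert win.loc[0, "meth_fraction"] == 1.0
        assert win.loc[1, "meth_fraction"] == 0.0

    def test_rejects_nonpositive_window(self):
        with pytest.raises(ValueError):
            window_methylation(_sample([("c", 1, "+", "CG", 1, 0)]), window_size=0)


class TestGlobalEstimate:
    def test_uniform_simulation_recovered_by_both_modes(self, plain_genome):
        from lowmeth.genome import generate_methylome

        m = generate_methylome(plain_genome, seed=1, background_mean=0.8, repeat_mean=0.8,
                               rdna_mean=0.8, concentration=np.inf)
        spec = SampleSpec(sample_id="s", n_reads=10_000, read_length=100,
                          conversion_efficiency=1.0, seed=2)
        res = simulate_sample(plain_genome, m, spec, mode="calls")
        for mode in ("windowed", "pooled"):
            est = global_estimate(res.sample, mode, window_size=10_000)
            assert est.value == pytest.approx(80.0, abs=1.0)

    def test_overrepresented_demethylated_region_depresses_pooled(self):
        rows = [("c", p, "+", "CG", 8, 2) for p in range(1000, 60_000, 200)]
        rows += [("c", p, "+", "CG", 0, 30) for p in range(70_000, 72_000, 10)]  # hot region
        s = _sample(rows)
        pooled = global_estimate(s, "pooled", min_calls=1).value
        windowed = global_estimate(s, "windowed", window_size=10_000, min_calls=1).value
        assert pooled < windowed

    def test_single_window_modes_agree(self):
        s = _sample([("c", p, "+", "CG", 4, 1) for p in range(1, 500, 7)])
        pooled = global_estimate(s, "pooled", min_calls=1).value
        windowed = global_estimate(s, "windowed", window_size=10_000_000, min_calls=1).value
        assert pooled == pytest.approx(windowed)

    def test_pooled_equals_call_weighted_window_mean(self, toy_genome, toy_methylome):
        spec = SampleSpec(sample_id="s", n_reads=3_000, read_length=100, seed=3)
        res = simulate_sample(toy_genome, toy_methylome, spec, mode="calls")
        win = window_methylation(res.sample, window_size=5_000)
        weighted = (win["meth_fraction"] * win["n_cg_calls"]).sum() / win["n_cg_calls"].sum()
        pooled = global_estimate(res.sample, "pooled", min_calls=1).value
        assert pooled == pytest.approx(100 * weighted, abs=1e-9)

    def test_windowed_invariant_to_call_order(self, toy_genome, toy_methylome):
        spec = SampleSpec(sample_id="s", n_reads=2_000, read_length=100, seed=4)
        res = simulate_sample(toy_genome, toy_methylome, spec, mode="calls")
        shuffled = SampleMethylome(
            sample_id="s",
            calls=res.sample.calls.sample(frac=1.0, random_state=0).reset_index(drop=True),
        )
        a = global_estimate(res.sample, "windowed", window_size=5_000, min_calls=1).value
        b = global_estimate(shuffled, "windowed", window_size=5_000, min_calls=1).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_low_coverage_flag_below_floor(self):
        s = _sample([("c", 1, "+", "CG", 1, 0)])
        est = global_estimate(s, "pooled", min_calls=10_000)
        assert est.low_coverage
        assert est.value == 100.0


class TestPartition:
    def test_no_intervals_everything_nonrepeat(self):
        s = _sample([("c", p, "+", "CG", 1, 1) for p in range(1, 100, 7)])
        rep, nonrep, frac = partition_by_annotation(s, [])
        assert np.isnan(rep)
        assert nonrep == pytest.approx(50.0)
        assert frac == 0.0

    def test_whole_genome_interval_is_all_repeat(self):
        s = _sample([("c", p, "+", "CG", 1, 0) for p in range(1, 100, 7)])
        rep, nonrep, frac = partition_by_annotation(s, [("c", 1, 1000)])
        assert frac == 100.0
        assert rep == 100.0
        assert np.isnan(nonrep)

    def test_simulated_compartments_recovered(self, toy_genome, toy_methylome):
        spec = SampleSpec(sample_id="s", n_reads=20_000, read_length=100,
                          conversion_efficiency=1.0, seed=5)
        res = simulate_sample(toy_genome, toy_methylome, spec, mode="calls")
        rep, nonrep, frac = partition_by_annotation(res.sample, toy_genome.repeat_intervals)
        assert rep == pytest.approx(87.0, abs=2.0)
        # non-repeat pool includes the 75%-methylated rDNA unit plus 68% bg
        assert nonrep == pytest.approx(68.0, abs=2.5)
        assert 5 < frac < 50


class TestPairedTest:
    def test_consistent_direction_is_significant(self):
        rng = np.random.default_rng(0)
        pairs = [(87 + rng.normal(0, 1), 68 + rng.normal(0, 2)) for _ in range(20)]
        res = paired_partition_test(pairs)
        assert res.pvalue < 0.01

    def test_identical_pairs_degenerate(self):
        res = paired_partition_test([(70.0, 70.0)] * 8)
        assert res.degenerate

    def test_sign_symmetry(self):
        rng = np.random.default_rng(1)
        pairs = [(80 + rng.normal(0, 3), 70 + rng.normal(0, 3)) for _ in range(12)]
        flipped = [(b, a) for a, b in pairs]
        assert paired_partition_test(pairs).pvalue == pytest.approx(
            paired_partition_test(flipped).pvalue
        )

    def test_requires_six_samples(self):
        with pytest.raises(ValueError):
            paired_partition_test([(1.0, 2.0)] * 5)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    meth=st.lists(st.integers(0, 20), min_size=3, max_size=30),
    unmeth=st.lists(st.integers(0, 20), min_size=3, max_size=30),
    window=st.sampled_from([1_000, 10_000, 1_000_000]),
)
def test_pooled_is_call_weighted_window_mean_property(meth, unmeth, window):
    n = min(len(meth), len(unmeth))
    rows = [
        ("c", 997 * (i + 1), "+", "CG", meth[i], unmeth[i])
        for i in range(n)
        if meth[i] + unmeth[i] > 0
    ]
    if not rows:
        return
    s = _sample(rows)
    win = window_methylation(s, window_size=window)
    weighted = (win["meth_fraction"] * win["n_cg_calls"]).sum() / win["n_cg_calls"].sum()
    pooled = global_estimate(s, "pooled", min_calls=1).value
    assert pooled == pytest.approx(100 * weighted, abs=1e-9)
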