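"""Generator contracts: determinism, compartment means, sampling algebra."""
import numpy as np
import pytest

from lowmeth.genome import ConfigurationError, generate_genome, generate_methylome
from lowmeth.simulate import SampleSpec, simulate_sample


def _genome_kwargs(**over):
    kw = dict(
        contig_sizes={"chr1": 200_000},
        seed=1,
        repeat_density=0.1,
        rdna_contig="chr1",
        rdna_start=150_001,
        rdna_unit_length=11_500,
    )
    kw.update(over)
    return kw


class TestGenerateGenome:
    def test_unit_span_arithmetic(self):
        g = generate_genome(**_genome_kwargs())
        assert (g.rdna_unit.contig, g.rdna_unit.start, g.rdna_unit.end) == ("chr1", 150_001, 161_500)
        assert g.rdna_unit.length == 11_500

    def test_deterministic_for_fixed_seed(self, tmp_path):
        a = generate_genome(**_genome_kwargs())
        b = generate_genome(**_genome_kwargs())
        assert a.contigs == b.contigs
        assert a.repeat_intervals == b.repeat_intervals
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        a.write_fasta(pa)
        b.write_fasta(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_zero_repeat_density_gives_no_intervals(self):
        g = generate_genome(**_genome_kwargs(repeat_density=0.0))
        assert g.repeat_intervals == []

    def test_tandem_copies_written_exactly(self):
        g = generate_genome(**_genome_kwargs(rdna_unit_length=2000, rdna_reference_copies=3))
        r = g.rdna_unit
        seq = g.contigs["chr1"][r.start - 1 : r.end]
        assert len(seq) == 6000
        assert seq[:2000] == seq[2000:4000] == seq[4000:6000]

    def test_unit_exceeding_contig_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_genome(**_genome_kwargs(rdna_start=195_001))

    def test_gc_content_near_configured(self):
        g = generate_genome(**_genome_kwargs(repeat_density=0.0, rdna_contig=None, gc_content=0.40))
        seq = g.contigs["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.40) < 0.01


class TestGenerateMethylome:
    def test_compartment_means_recovered(self):
        g = generate_genome(**_genome_kwargs(repeat_density=0.3))
        m = generate_methylome(g, seed=5, background_mean=0.68, repeat_mean=0.87, rdna_mean=0.75)
        pos = m.positions["chr1"]
        rep = np.zeros(len(pos), dtype=bool)
        for _, s, e in g.repeat_intervals:
            rep |= (pos >= s) & (pos <= e)
        r = g.rdna_unit
        rd = (pos >= r.start) & (pos <= r.end)
        bg = ~rep & ~rd
        assert bg.sum() > 1000 and rep.sum() > 1000
        assert abs(m.probs["chr1"][bg].mean() - 0.68) < 0.02
        assert abs(m.probs["chr1"][rep].mean() - 0.87) < 0.02

    def test_rdna_mean_zero_gives_all_zero(self):
        g = generate_genome(**_genome_kwargs())
        m = generate_methylome(g, seed=5, rdna_mean=0.0)
        pos = m.positions["chr1"]
        r = g.rdna_unit
        rd = (pos >= r.start) & (pos <= r.end)
        assert rd.sum() > 0
        assert (m.probs["chr1"][rd] == 0.0).all()

    def test_infinite_concentration_collapses_to_means(self):
        g = generate_genome(**_genome_kwargs(repeat_density=0.0, rdna_contig=None))
        m = generate_methylome(g, seed=5, background_mean=0.7, concentration=np.inf)
        assert (m.probs["chr1"] == 0.7).all()

    def test_every_cg_has_one_probability(self, toy_genome, toy_methylome):
        for contig in toy_genome.contigs:
            pos = toy_genome.cg_positions(contig)
            assert np.array_equal(pos, toy_methylome.positions[contig])
            assert len(toy_methylome.probs[contig]) == len(pos)
            assert ((toy_methylome.probs[contig] >= 0) & (toy_methylome.probs[contig] <= 1)).all()


class TestSimulateSample:
    def test_fixed_seed_bitwise_identical(self, toy_genome, toy_methylome, tmp_path):
        spec = SampleSpec(sample_id="s", n_reads=300, read_length=100, seed=9)
        r1 = simulate_sample(toy_genome, toy_methylome, spec, mode="reads")
        r2 = simulate_sample(toy_genome, toy_methylome, spec, mode="reads")
        assert r1.reads == r2.reads
        assert r1.truth == r2.truth
        p1, p2 = tmp_path / "a.fq", tmp_path / "b.fq"
        r1.write_fastq(p1)
        r2.write_fastq(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unamplified_read_fraction_matches_unit_share(self, toy_genome, toy_methylome):
        spec = SampleSpec(sample_id="s", n_reads=50_000, read_length=100, seed=2)
        res = simulate_sample(toy_genome, toy_methylome, spec, mode="calls")
        u = res.truth.expected_region_read_fraction
        # close to unit_length / genome_length, edge-corrected
        assert u == pytest.approx(600 / 60_000, rel=0.25)
        sd = np.sqrt(u * (1 - u) / spec.n_reads)
        assert abs(res.truth.realized_region_read_fraction - u) < 4 * sd

    def test_amplified_fraction_weighted_sampling_algebra(self):
        # x100 weight on an 11.5-kb unit in a 1.15-Mb genome -> ~50.3% of reads
        g = generate_genome(
            {"chr1": 1_150_000}, seed=3, repeat_density=0.0,
            rdna_contig="chr1", rdna_start=500_001, rdna_unit_length=11_500,
        )
        m = generate_methylome(g, seed=4)
        spec = SampleSpec(sample_id="s", n_reads=20_000, read_length=150,
                          rdna_copy_factor=100.0, seed=5)
        res = simulate_sample(g, m, spec, mode="calls")
        assert res.truth.expected_region_read_fraction == pytest.approx(0.503, abs=0.01)
        assert res.truth.realized_region_read_fraction == pytest.approx(0.503, abs=0.02)

    def test_full_methylation_and_conversion_keeps_every_c(self, plain_genome):
        m = generate_methylome(plain_genome, seed=6, background_mean=1.0, repeat_mean=1.0,
                               rdna_mean=1.0, non_cg_level=1.0)
        spec = SampleSpec(sample_id="s", n_reads=200, read_length=100,
                          conversion_efficiency=1.0, seed=7)
        res = simulate_sample(plain_genome, m, spec, mode="reads")
        assert (res.realized_calls["unmeth"] == 0).all()
        for rid, seq in res.reads:  # no conversion happened anywhere
            _, contig, start, strand = rid.split("|")
            start = int(start)
            ref = plain_genome.contigs[contig][start - 1 : start - 1 + 100]
            if strand == "CTOT":
                frag = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            else:
                frag = seq.translate(str.maketrans("ACGT", "TGCA"))
            assert frag == ref or frag == ref.translate(str.maketrans("ACGT", "TGCA"))

    def test_zero_reads_flagged_undefined(self, toy_genome, toy_methylome):
        spec = SampleSpec(sample_id="s", n_reads=0, seed=1)
        res = simulate_sample(toy_genome, toy_methylome, spec, mode="reads")
        assert res.truth.undefined
        assert res.reads == []
        assert np.isnan(res.truth.realized_global_cg)

    def test_realized_global_converges_to_model(self, toy_genome, toy_methylome):
        spec = SampleSpec(sample_id="s", n_reads=30_000, read_length=100,
                          conversion_efficiency=0.98, seed=8)
        res = simulate_sample(toy_genome, toy_methylome, spec, mode="calls")
        assert res.sample.n_cg_calls > 100_000
        # call-weighted realized vs site-weighted model differ by density
        # weighting; both must agree within a percentage point at this depth
        assert abs(100 * res.truth.realized_global_cg - 100 * res.truth.model_global_observed) < 1.0

    def test_region_fraction_within_binomial_bounds_across_seeds(self, toy_genome, toy_methylome):
        spec0 = SampleSpec(sample_id="s", n_reads=2_000, read_length=100,
                           rdna_copy_factor=5.0, seed=0)
        u = simulate_sample(toy_genome, toy_methylome, spec0, mode="calls").truth.expected_region_read_fraction
        sd = np.sqrt(u * (1 - u) / 2_000)
        bad = 0
        for seed in range(60):
            spec = SampleSpec(sample_id="s", n_reads=2_000, read_length=100,
                              rdna_copy_factor=5.0, seed=seed)
            res = simulate_sample(toy_genome, toy_methylome, spec, mode="calls")
            if abs(res.truth.realized_region_read_fraction - u) > 3 * sd:
                bad += 1
        assert bad <= 2  # 3-sigma exceedances should be rare

    def test_calls_and_reads_modes_agree_statistically(self, plain_genome, plain_methylome):
        spec = SampleSpec(sample_id="s", n_reads=4_000, read_length=100,
                          conversion_efficiency=0.97, seed=11)
        rc = simulate_sample(plain_genome, plain_methylome, spec, mode="calls")
        rr = simulate_sample(plain_genome, plain_methylome, spec, mode="reads")
        assert abs(rc.truth.realized_global_cg - rr.truth.realized_global_cg) < 0.01
        assert abs(
            rc.truth.realized_conversion_efficiency - rr.truth.realized_conversion_efficiency
        ) < 0.005
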