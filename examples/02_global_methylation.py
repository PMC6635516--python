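"""Global CG methylation: windowed vs pooled estimates and the
repeat/non-repeat partition, on a sample with a known methylation landscape
(repeats at 87%, background at 68%, plus a 75%-methylated rDNA-like unit).

The windowed estimate (unweighted mean over genome windows) and the pooled
estimate (all calls lumped) agree on this unamplified sample; the repeat
partition recovers the planted compartment means.
"""
from lowmeth import (
    SampleSpec,
    generate_genome,
    generate_methylome,
    global_estimate,
    partition_by_annotation,
    simulate_sample,
)

genome = generate_genome(
    {"chr1": 200_000}, seed=1, repeat_density=0.3, rdna_contig="chr1",
    rdna_start=150_001, rdna_unit_length=2_000,
)
methylome = generate_methylome(genome, seed=2, background_mean=0.68,
                               repeat_mean=0.87, rdna_mean=0.75)
spec = SampleSpec(sample_id="demo", n_reads=30_000, read_length=150,
                  conversion_efficiency=1.0, seed=3)
sample = simulate_sample(genome, methylome, spec, mode="calls").sample

windowed = global_estimate(sample, "windowed", window_size=10_000)
pooled = global_estimate(sample, "pooled")
rep, nonrep, frac = partition_by_annotation(sample, genome.repeat_intervals)

print(f"CG calls                 : {windowed.n_calls}")
print(f"windowed global CG meth  : {windowed.value:.2f}%")
print(f"pooled   global CG meth  : {pooled.value:.2f}%")
print(f"repeat methylation       : {rep:.2f}%  (planted 87%)")
print(f"non-repeat methylation   : {nonrep:.2f}%  (planted ~68% + unit)")
print(f"calls in repeats         : {frac:.1f}%")
print()
print("Windowed and pooled estimates agree when no region is amplified;")
print("repeats are more methylated than the non-repeat background.")
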