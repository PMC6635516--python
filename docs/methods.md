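# Methods

This note documents the models, parameter choices and numerical decisions
behind `lowmeth`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Scope and coordinate conventions

All public coordinates are 1-based inclusive (`contig:start-end`), the
convention of genome browsers and Bismark coverage files. BED output is
converted to 0-based half-open at the file boundary only. Windows tile
contigs half-open on 1-based positions: position *p* belongs to window
⌊(p−1)/size⌋, so a position exactly at `size+1` opens the second window.

## Bisulfite model

Bisulfite treatment converts unmethylated cytosine to uracil (read as T);
methylated cytosine is protected. A PBAT (post-bisulfite adaptor tagging)
library sequences the strands *complementary* to the two converted
genomic strands, CTOT and CTOB. The reference converter produces all four
alignable strands — OT (top, every C→T), OB (converted reverse
complement), and their complements — and the mapper restricts candidates
to CTOT/CTOB in PBAT mode.

The mapper is deliberately simple: exact 20-mer seed at the read start,
full-length mismatch count (default maximum 5), unique best hit required,
ties reported unmapped. Reads are made methylation-insensitive before
comparison (C→T for OT/OB candidates, G→A for CTOT/CTOB). The contract
is correctness on clean simulated data, not sensitivity on real reads;
indel-aware alignment and base-quality weighting are out of scope. On
repeat-free simulations 100% of error-free reads map to their true locus;
reads from diverged repeat copies tie and are correctly rejected, which
is why the mapping-rate guarantee is stated for *uniquely placeable*
reads.

Call extraction assigns context (CG/CHG/CHH) from the reference
trinucleotide, never from the read, and keeps calls per strand (a CpG's
bottom-strand cytosine is reported at the G's coordinate with strand
"−"). Calls are pooled across strands only at aggregation time. No
deduplication is performed: the target regime is low-coverage data.

Conversion efficiency is estimated as 100 − non-CG methylation %. The
simulator's `non_cg_level` knob pools true non-CG methylation with
conversion failure, because the two are indistinguishable to this proxy;
the estimator is unbiased exactly when `non_cg_level = 0` (verified to
within 0.2 pp over 50 seeds).

## Synthetic-data generator

The generator emulates, at reduced scale, the genomic situation the
pipeline targets:

* **Genome** — a few contigs (default cohort: 1.6 + 1.6 + 0.8 Mb) of iid
  sequence at 40% GC, ~30% covered by copies of four repeat families
  (2 kb, ~1% divergence between copies), plus one tandem rDNA-like unit
  (default cohort: 1.9 kb, one reference copy) that is modestly GC- and
  CpG-enriched, as ribosomal DNA is.
* **Methylome** — every top-strand CG receives a probability drawn from a
  compartment Beta distribution (concentration 20; ∞ collapses to the
  mean): background, repeat and rDNA compartments. Methylation is treated
  as symmetric across strands. Defaults mirror a vertebrate somatic
  methylome: repeats more methylated (≈87%) than background, global mean
  planted per sample in 78–84%.
* **Samples** — reads are single-end, adapter-free, error-free by
  default, 150 bp, drawn uniformly over read-start positions except that
  starts whose read overlaps the rDNA unit carry the sample's
  `rdna_copy_factor` weight. This models extrachromosomal rolling-circle
  amplification whose products all map back to one collapsed reference
  unit; it deliberately does **not** add reference copies. A per-sample
  `rdna_methylation_override` decouples region methylation from the
  genome landscape (amplified copies are demethylated). Conversion is
  applied per cytosine: methylated state ~ Bernoulli(p), unmethylated
  cytosines convert with probability `conversion_efficiency`.

Two output paths share this sampling model. The FASTQ path builds actual
read sequences plus the per-site call table an error-free extractor
should recover (the oracle for mapper/caller tests). The call-table path
draws per-site methylation counts directly from the realized read
coverage — statistically identical to simulating, mapping and extracting
error-free reads, but vectorised, so cohorts with ~10⁶ reads per sample
are cheap. Non-CG observations are aggregated rather than stored per
site on this path, mirroring a conversion report accompanying a CG-only
coverage file.

The truth table records both realized draws (call-weighted global
methylation, region read fraction, conversion events) and analytic
planted values. Because amplification is a sampling *weight*, the
expected region fraction is k·u/(1−u+k·u) for unit mass fraction *u*,
and the expected fold over an unamplified background is k/(1−u+k·u) —
equal to k only as u→0. The generator therefore reports this expected
fold (`planted_fold`) computed exactly from the coverage-mass integral;
recovery tests compare the estimator against it, while the "fold ≈ k"
simplification is asserted only for small units (u ≤ ~3·10⁻⁴) and
k ≤ 100, where the distortion is within a few percent. This mirrors the
saturation seen in real data, where a library can be "at least" some
fold amplified once the region consumes a large share of all reads.

What the generator does **not** model: paired ends, base-quality
realism, indels, adapters, PCR duplicates, chimeras, incomplete repeat
assembly, or CpG-island structure. Passing tests therefore demonstrate
the correctness of the statistics under the stated sampling model, not
robustness to artefacts of real libraries.

## Global methylation

Pooled estimate: Σ meth / Σ calls. Windowed estimate: unweighted mean of
per-window fractions over windows with ≥10 calls. The pooled estimate
equals the call-weighted mean of window fractions exactly (asserted as an
algebraic identity), which is why amplification of a demethylated region
depresses pooled but barely moves windowed values. Samples below 10,000
total CG calls are flagged low-coverage rather than refused. The default
window is 10 Mb; toy genomes pass `--window` (the cohort tests use
20 kb, giving ~200 windows — the same windows-per-genome regime as 10-Mb
windows on a 1.4-Gb genome). Whether the windowed mean should be
call-weighted is genuinely open; both modes are computed and reported.

The repeat/non-repeat partition assigns a call to "repeat" iff its
position lies in any annotated interval (merged, sorted-interval lookup),
and the per-sample pairs feed a two-sided Wilcoxon signed-rank test
(≥6 pairs required; all-zero differences return a degenerate flag).

## Calibration

For each n in a regular grid (default 100 to 30,000 in 30 steps, B =
1000, CI 99%), subsamples of n calls are drawn with replacement and the
margin is half the central percentile interval of their methylation
fractions — the reading of "margin of error" consistent with a ± form.
Percentiles use linear interpolation between order statistics. For a 0/1
call pool the subsample total is exactly Binomial(n, pool mean) and is
drawn directly; an optional by-site mode resamples whole loci with their
call counts, capturing the inflation produced by locus-clustered
sampling (a bimodal methylome sampled by locus yields a visibly larger
coefficient than the iid value). One seed governs the curve; per-n
streams derive from it deterministically.

The fit `margin = c/√n` uses the closed-form least-squares solution on
the fractional scale. Note two small-B biases pull the fitted c a few
percent below the asymptotic normal value 2.576·√(p(1−p)): empirical
extreme quantiles at B = 1000 sit slightly inside the true quantiles, and
small-n binomial discreteness adds noise. Accuracy claims are therefore
stated for the mean over 10 seeds (within 5% of the closed form), which
holds comfortably.

`predict_margin(c, n) = 100·c/√n` percentage points; it is exactly
scale-consistent (quadrupling n halves the margin).

## Amplification and classification

Density scan: CG calls per window (default 1 Mb, scaled for toy genomes)
divided by the mean over all windows; replicates are pooled before
counting, and when contig sizes are supplied the windows tile the whole
genome with empty windows counting zero, so the ratios average to exactly
one. Region quantification reports the read fraction (alignment overlap
≥1 bp) when alignments are available and falls back to the CG-call
fraction, labelled with its source, when only call tables exist. Region
methylation requires ≥10 calls, else it is undefined and flagged.

Classification thresholds (exposed as configuration): amplified iff the
region fraction exceeds 1% of the library; else intermediate iff region
methylation is defined, below 30%, and the fraction exceeds the control
background mean; else background (flagged low-evidence when methylation
was unquantifiable). The background level is the mean region fraction
over non-germline control samples. The intermediate/background boundary
is genuinely underdetermined by the observed clusters (their fraction
ranges overlap); the methylation cut at 30% plus the above-background
requirement separates a 10%-methylated intermediate state from
~75%-methylated background cleanly and is monotone in the fraction.

## qPCR

Classic ΔΔCt with amplification efficiency fixed at 2.0 per cycle;
replicate Cts are averaged; the baseline is the mean ΔCt of non-germline
controls; fold = 2^−ΔΔCt with >5-fold called amplified. Ct determination
from raw fluorescence is out of scope — Ct values are inputs. The
synthetic Ct generator (Ct = a − log₂(copies) + noise) exists to verify
fold recovery against planted copy numbers.

## Reference cohort and problem sizes

The acceptance-level checks run on a 20-sample cohort over a 4-Mb
genome: five amplified samples (weights ×100–×650, region methylation
2%), three intermediates (×3–×10 at 10%), twelve background samples
(eight of them non-germline controls), global methylation planted in
78–84%, conversion efficiency in 96–100%, 10⁶ read positions per sample
(~6·10⁶ CG calls) via the vectorised call path. These sizes keep all
region-read counts high enough that fold recovery at 10% tolerance is a
>3σ event while the whole cohort simulates in well under a minute.
"Within the calibrated margin" for global estimates means the margin the
cohort's own calibration predicts at the 10,000-call sequencing floor
(±~1 pp), the depth at which the pipeline's quality guarantee is stated;
at the cohort's actual depth the windowed estimator's residual bias
(≈0.3–0.5 pp, from the amplified unit's own window entering the
unweighted mean) would dominate a per-depth margin on a toy genome with
only ~200 windows.

## Known limitations

* The mapper has no indel handling and requires an exact seed; it is a
  correctness oracle for clean data, not a production aligner.
* Fold estimates from fractions saturate for large amplification weights
  on units that are a non-negligible genome share (see above).
* Low-coverage data cannot quantify methylation at single-copy loci;
  all statistics here are global, windowed, or multi-copy-region level.
* The conversion-efficiency proxy cannot separate true non-CG
  methylation from conversion failure.
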