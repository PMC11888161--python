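# chipms

Two statistical procedures used to characterize a chromatin-binding factor
whose ChIP-seq signal concentrates at pericentromeric satellite repeats:

1. **Chromosome-stratified shuffle enrichment** of a ChIP-seq peak set
   against annotation catalogs (RepeatMasker repeat families, or one file
   per track in a directory-of-narrowPeak screen). For each annotation
   family, every element is relocated to a uniformly random position on its
   own chromosome, independently of all other elements; the test statistic
   is the base-pair overlap `O = |union(annotation) ∩ union(peaks)|`. The
   shuffle is repeated *n* times (default 20) and the enrichment score is

   ```
   z = (O_observed − mean(O_null)) / sd(O_null)
   ```

2. **IP-MS differential statistics** for label-free proteomics intensity
   matrices: missing log2 intensities are imputed by sampling
   `N(μ − 1.8σ, (0.8σ)²)` with μ, σ the observed per-sample moments
   (down-shifted Gaussian, modeling limit-of-detection dropout), followed by
   a moderated two-group t-test (empirical-Bayes variance shrinkage),
   Benjamini–Hochberg correction, and hit filtering at `log2FC > 2` and
   `p < 0.05` (both strict).

The package is aimed at epigenomics/proteomics analysts who need these
stages as reproducible, seeded, tested components rather than one-off
scripts. A synthetic-data module generates genomes with clustered
pericentromeric satellite arrays and dispersed LINEs, peak sets with a known
placement bias ρ toward a chosen family, and intensity matrices with planted
effects under intensity-dependent (MNAR) missingness — so every stage is
testable against known ground truth without any download.

## Worked example

Generate the synthetic study inputs, then run the analysis drivers:

```bash
python analysis/01_simulate_fixtures.py   # writes results/fixtures/
python analysis/02_repeat_enrichment.py
python analysis/03_track_screen.py
python analysis/04_ipms_differential.py
```

`02_repeat_enrichment.py` screens the planted-bias peak set (200 × 200 bp
peaks, placement biased 10× toward the 5% satellite fraction of a 1 Mb
genome) against the repeat catalog and prints:

```
  Satellite  observed= 13,145 bp  null=   2183.2 +/- 1464.9  z=+7.48
  LINE       observed=  9,217 bp  null=  10726.5 +/- 2068.0  z=-0.73
top family: Satellite (z=7.48) — the planted satellite bias is recovered
```

The satellite family, toward which peak placement was biased, stands out at
z ≈ +7.5 while the unbiased LINE family sits near the null. The IP-MS driver
imputes the ~10% MNAR-missing cells and recovers the planted protein hits:

```
hits called: 46 / 50 planted; recall 0.88, false positives 2
```

The same stages are available as a CLI for real inputs (UCSC rmsk dumps,
BED/narrowPeak, chrom.sizes, intensity TSVs):

```bash
chipms enrich-batch --peaks peaks.narrowPeak --rmsk rmsk.tsv \
    --chrom-sizes genome.chrom.sizes --n-shuffles 20 --seed 1 --out enrich.tsv
chipms ipms --matrix intensities.tsv --groups groups.tsv --out diff.tsv
```

Each run writes a `.manifest` file recording input checksums, parameters,
and the seed; reruns with the same inputs and seed are byte-identical.

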