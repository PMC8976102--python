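# genomesurvey

A toolkit for short-read **genome surveys** of the kind used to
characterize non-model fish (and other vertebrate) genomes before any
chromosome-level assembly exists: estimate genome size, heterozygosity and
repeat content from a k-mer spectrum, call the sex-determination system
(ZZ/ZW vs XX/XY) from male/female asymmetries, discover
W-chromosome-specific PCR markers by subtractive mapping, scan for
microsatellites (SSRs), and compare mitogenomes with ANI and
neighbor-joining trees. Every analysis can be exercised end to end on
synthetic diploid ZW/ZZ genomes generated — with full planted ground truth
— by the package itself, which is how the test suite validates each
estimator as a recovery problem.

It is aimed at people who run genome surveys (or teach/review them) and
want the whole pipeline as inspectable, seeded, pure-Python/NumPy code
rather than a chain of black-box binaries.

## The model in brief

For reads at homozygous k-mer depth λ, the depth histogram of canonical
k-mers is a mixture: errors at low depth, haplotype-specific (heterozygous)
k-mers at λ/2, single-copy homozygous k-mers at λ, and m-copy repeats at
mλ. From the fitted weights:

    genome size   G = (total k-mer mass) / λ
    revised size  G · (1 − e)                e = error-mass fraction
    heterozygosity r = 1 − (1 − α)^(1/k)     α = haplotype-specific share
    repeat fraction  Σ_{m≥2} m·w_m / L̂      (length-based)

A ZW system is called when the female shows higher r **and** a smaller
revised genome size than the male (degenerated W); the mirrored pattern
gives XY. The subtractive marker pipeline maps female reads onto the male
assembly, assembles the unmapped remainder into contigs (De Bruijn
unitigs), discards contigs < 200 bp or matching the male assembly, keeps
those matching the female assembly, then designs primer pairs and
classifies them by in-silico PCR against both assemblies. Details and all
numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

Profile a simulated diploid genome planted at 0.39% heterozygosity and
32.6% repeats, sequenced error-free at 60× k-mer depth:

```python
from genomesurvey import (SimulationParams, simulate_diploid_genome,
                          simulate_reads, count_kmers, SpectrumModel)

params = SimulationParams(genome_length=500_000, heterozygosity=0.0039,
                          repeat_fraction=0.326, ssr_density=0,
                          sex_system="ZZ_male", coverage=60*150/134, seed=5)
genome = simulate_diploid_genome(params)
reads = simulate_reads(genome, params)          # 111,940 pairs of 2x150 bp
fit = SpectrumModel(count_kmers(reads, k=17)).fit()
print(fit.summary())
```

prints

```
Spectrum fit
======================================
k                         17
K-mer depth (peak)        59
Refined depth             60.00
Genome size (Mb)          0.50
Error k-mer rate          0.0000
Revised genome size (Mb)  0.50
Heterozygous ratio (%)    0.33
Repeat (%)                30.9
Fit residual (rel.)       0.0354
```

Reading it: the modal 17-mer depth lands on the simulated coverage (59–60);
the genome size estimate recovers the true 0.5 Mb; the fitted heterozygous
ratio 0.33% is within 15% of the planted 0.39%; and the repeat fraction
30.9% is within 2 points of the planted 32.6% (each repeat copy loses its
k−1 boundary k-mers, a known small downward bias). Error-free reads give an
error rate of 0, so revised size equals genome size.

The same objects drive the full survey from a shell:

```bash
survey run --outdir out --seed 7        # male+female 2-Mb survey, ~10 min
survey profile --reads R1.fq R2.fq -k 17 --out fit.json
survey ssr --fasta genome.fasta
survey sexmarker --female-reads R1.fq R2.fq --male-ref male.fa \
                 --female-ref female.fa --outdir markers
survey mito --fasta mitos.fasta --bootstrap 1000
```

`survey run` writes `survey_report.json` containing both specimens'
spectrum fits, the sex-system call (`"ZW"` on the default configuration),
the SSR summary tables, the marker classification counts (with at least
one `FEMALE_SPECIFIC` pair whose amplicon lies inside planted W material),
and the bootstrap-annotated mitogenome tree in Newick.

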