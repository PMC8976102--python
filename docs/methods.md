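# Methods

This note documents the models, numerical choices and limitations behind
`genomesurvey`. It is written for a reader who wants to know *why* the
package computes what it computes, and what passing its test suite does and
does not demonstrate about real data.

## The survey model

A short-read genome survey estimates genome-scale quantities without an
assembly, from the depth histogram of k-mers in the reads. Let λ be the
modal depth of homozygous single-copy k-mers ("k-mer depth"). For a diploid
genome the histogram decomposes into:

* an **error component** at very low depth (k-mers created by miscalls are
  nearly unique);
* a **heterozygous component** near λ/2 — a k-mer overlapping a
  haplotype-specific variant is sampled from one haplotype only;
* the **homozygous single-copy component** at λ;
* **repeat components** at integer multiples mλ for m-copy families.

The headline estimators:

* **Genome size** `G = total k-mer mass / λ_peak` where mass is the number
  of k-length windows counted. With the integer modal depth this is exactly
  the survey's printed formula and reproduces its worked examples
  (`estimate_genome_size`).
* **Revised genome size** `G × (1 − e)`, where `e` is the fraction of
  k-mer mass below the error cutoff.
* **Heterozygosity** from the mixture weights. If `w_het` is the count of
  distinct k-mers in the λ/2 component and `w_hom` the single-copy count
  (with repeats weighted by copy number), then the fraction of positions
  whose k-mer is haplotype-specific is `α = w_het / (w_het + 2·w_hom_eq)`
  (each het position contributes two distinct k-mers, one per haplotype),
  and the per-site rate is `r = 1 − (1 − α)^{1/k}` — the standard relation
  between a SNP and the k overlapping k-mers it disrupts.
* **Repeat fraction**, length-based: `Σ_{m≥2} m·w_m / L̂` with
  `L̂ = w_het/2 + w_hom + Σ m·w_m` the haploid length in k-mer terms.
  Whether a survey's printed "Repeat (%)" is mass- or length-based is
  generally tool-dependent; this package defines it length-based and tests
  it against planted truth.

### Fitting

`SpectrumModel(spectrum).fit()` returns a `SpectrumFit` results object
(`summary()` prints a survey-style table). The fit is deliberately simple
and fully deterministic:

1. The peak is the argmax of the 3-point-smoothed histogram over occupied
   depths ≥ `min_depth` (default 5), ties toward smaller depth. Restricting
   to occupied depths matters: degenerate comb-shaped histograms (e.g.
   exactly duplicated read sets) otherwise place the smoothed mode on an
   empty bin.
2. The error cutoff is the valley of the smoothed histogram below λ/2
   (floor 2). `e` = mass strictly below it over total mass. The survey
   literature never prints its error definition; this valley heuristic is
   this package's stated choice.
3. Component weights are fitted by non-negative least squares on the
   histogram over depths above the cutoff, with Poisson component shapes at
   means λ/2, λ, 2λ … 8λ (a negative-binomial switch `shape="nb"` exists
   for over-dispersed data). Components whose probability mass lies outside
   the fitted depth range are excluded (they are unidentifiable and NNLS
   would otherwise assign them arbitrary weight). λ is refined on a 0.1-step
   grid within ±1 of the integer peak by residual norm.
4. Mass beyond 8.5λ is pooled into the repeat length at its implied copy
   number.

The `SpectrumFit` genome size uses the *refined* λ rather than the integer
peak: at desk scale (peaks of 25–60) integer rounding alone moves the
estimate by up to ±2%, which would drown the ~1.5% male/female size
asymmetry the sex-system call rests on. The printed-formula operation is
kept separately and byte-exactly for the worked examples.

### Sex-system inference

For a heterogametic female (ZW): the female shows the higher heterozygosity
(hemizygous W material and Z/W divergence inflate the λ/2 component) and
the *smaller* revised genome size (the W is a degenerated Z). `infer_sex_system`
requires both asymmetries, each beyond a relative margin (defaults 5% for
heterozygosity, 0.3% for size); the mirrored pattern yields XY, anything
else "inconclusive". Margins are configurable; the defaults accept the
survey pattern (0.34% vs 0.39%; 1671.5 vs 1645.7 Mb) with room to spare.

## Synthetic data: what it emulates, what it does not

The generator (`simulate` module) is first-class, tested code; every
pipeline claim in the test suite is a recovery claim against its planted
truth.

* **Background sequence** is a permutation of an exact base multiset at the
  target GC (36.95% by default, the male assembly's value), so realized GC
  matches the target to rounding — the GC invariant holds by construction,
  not by luck.
* **Repeats** are exact copies of family unit sequences (default units 300,
  700, 1500 bp; 2–8 copies per family) interleaved into the background to
  the requested fraction (33% default). Exact copies make the mλ components
  clean; real repeat families diverge, which smears those components — the
  recovery tolerances (±5 points) leave room for that but the tests do not
  exercise it.
* **Heterozygosity** is substitution-only, applied outside planted SSR loci
  (default 0.39%, the female specimen's printed ratio). No heterozygous
  indels, consistent with the SNP-type signal the spectrum model reads.
* **SSR loci** (default 50/Mb) are planted in the unique background with
  motifs guaranteed non-periodic, repeat counts at or above the MISA-style
  thresholds, flanks adjusted so each run is maximal, and ≥150 bp spacing
  so planted loci never merge into compounds.
* **W-specific segments** (ZW females only; each ≥400 bp, default 1–2 kb)
  come from a separate random stream and are rejected and redrawn until
  they share no exact 31-mer with either haplotype — recoverability of the
  subtractive pipeline's ground truth is enforced, not assumed.
* **W degeneration** is modeled as `z_loss_bases` deleted from the
  W-bearing haplotype in feature-free zones. The survey pipeline's default
  (77 kb on a 2-Mb genome) makes the female haploid genome ~1.5% smaller
  than the male's, the proportional gap reported for the real specimens.
  How much of a real size gap is loss versus repeat-content difference is
  unknown; the parameter is exposed rather than asserted.
* **Reads** are uniform 2×150 bp pairs with Gaussian insert (350 ± 30 bp),
  drawn evenly from both haplotypes, constant Q37 qualities, and optional
  uniform miscalls. No quality ramps, adapter read-through, PCR duplicates,
  GC-coverage bias or structural variants — so passing recovery tests here
  says the *estimators* are correct, not that they are robust to platform
  artifacts.
* **Mitogenomes** carry the canonical vertebrate complement (13 CDS,
  22 tRNA, 2 rRNA, 1 D-loop; ~16.5 kb with the D-loop length jittered) and
  evolve along a guide tree by per-branch substitutions
  (`P(sub) = branch length × subs_rate`); no indels, rearrangements or
  rate heterogeneity among sites.

## Alignment machinery

The mapper indexes every canonical s-mer (default s = 15) of the reference
as a sorted code array; queries collect seeds at s-spaced offsets, cluster
them by diagonal, and extend the best clusters. Extension prefers a gapless
placement check (optimal for substitution-only differences) and falls back
to semi-global affine alignment via Biopython's `PairwiseAligner` (match
+1, mismatch −2; a gap of length g costs 4 + (g−1)). "Mapped" means
identity ≥ 0.90 over the aligned region and ≥ 80% of the query aligned —
declared configuration, not a claim about any particular external mapper's
thresholds. Identity is matches / alignment columns; hits re-align to the
same identity with `global_align` by construction.

Primer placement is stricter, reflecting PCR chemistry: full-length,
indel-free, ≤1 mismatch, 3'-terminal 5 bases exact.

## Subtractive sex-marker discovery

Stages, in order: map female reads to the male assembly → assemble the
unmapped remainder (De Bruijn unitigs, k = 55, singleton k-mers dropped,
tips < 2k clipped) → discard contigs < 200 bp → discard contigs with any
mapped hit on the male assembly → keep contigs with a mapped hit on the
female assembly. Candidates are sampled (uniform, seeded, default 50),
primers designed (length 18–27, GC 40–60%, Tm 57–63 °C by SantaLucia
nearest-neighbor at 50 mM Na⁺ / 250 nM oligo, homopolymers ≤ 4, 3'-GC run
≤ 3, |ΔTm| ≤ 3 °C, product 150–700 bp, ranked by deviation from Tm 60 °C
and length 20), and each pair classified by in-silico PCR (convergent
placements within 2 kb) against both assemblies.

`FEMALE_SPECIFIC` demands a female product and *zero* placements of either
primer on the male assembly. A known, reproducible failure mode: contigs
assembled from reads straddling a W boundary carry up to ~120 bp of shared
flank (a read becomes mappable once ≥80% of it is shared sequence), so
primers landing in that flank amplify both sexes. This mirrors the false
positives real subtractive studies report from fragmented references; the
soundness guarantee — tested by exhaustive 31-mer containment — is that
female-specific *amplicons* contain no male-genome sequence.

## Trees and alignment of mitogenomes

* **ANI**: full-length affine global alignment; identity counts gap columns
  in the denominator; reported as percent.
* **MSA**: progressive profile alignment along an NJ guide tree built from
  8-mer Jaccard distances. Profile pairs align under banded linear-gap DP
  (band ≥ 60 columns, widened by the length difference; column score is the
  profile-weighted +2/−1 substitution expectation, gap −3, gap characters
  score 0). Adequate for the >90%-identity, few-indel regime of congeneric
  mitogenomes; it is validated by invariants (degap round trip, planted
  indel placement, gapless on identical inputs), not by equivalence to any
  production aligner. Circular sequences are linearized at the first CDS
  before alignment.
* **Distances**: p-distance = mismatches / shared ungapped columns; an
  optional Jukes–Cantor correction.
* **NJ**: Saitou–Nei Q-criterion with the standard branch-length formulas;
  a negative branch is clamped to zero and its excess moved to the sibling
  edge; the unrooted tree is serialized with a trifurcating root. On
  additive matrices the output path metric reproduces the input within
  1e-9 and the generating topology is recovered (tested to 8 taxa).
* **Bootstrap**: alignment columns resampled with replacement; support of
  each internal edge of the full-data tree is the percentage of replicate
  NJ trees containing the same unrooted bipartition. Per-pair mismatch and
  shared-column masks are precomputed so each replicate costs one matrix
  slice plus an NJ run.

## Orchestration

`run_survey` chains: simulate a conspecific ZZ male and ZW female sharing
one autosomal background → profile both read sets (k = 17) → infer the sex
system → SSR-scan both genomes → run the subtractive marker workflow →
simulate and analyze a mitogenome set. A single root seed expands into
fixed per-stage seeds (recorded in the report); the report's content hash
excludes timestamps, so identical configs hash identically. The default
profile is a 2-Mb genome at 60× with 10 W segments; the test suite runs
reduced profiles (150–500 kb, 25–40×) chosen so the full suite completes
in minutes while every recovery margin stays comfortably wider than the
sampling noise at that scale — the margins, not the scale, carry the
scientific claims.

## Known limitations

* The spectrum model is a single-peak diploid mixture: no four-peak
  duplication terms, no GC-bias correction, no k-mer multiplicity sweep.
  Genomes with very high heterozygosity (λ/2 component dominating) would
  need the peak finder pointed at the homozygous peak explicitly.
* The error-rate definition (valley heuristic) is a declared choice; tools
  differ here, and revised sizes inherit that choice.
* The DBG assembler is unitig-only (single k, no bubble popping beyond tip
  clipping); heterozygous bubbles yield two contigs. Acceptable for the
  haploid W material it is pointed at, wrong tool for whole genomes.
* In-silico PCR ignores secondary structure, dimers and thermodynamic
  mispriming beyond the mismatch rule.
* All coordinates are 0-based half-open internally; GFF3 and the
  MISA-style table are emitted 1-based per their dialects.
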