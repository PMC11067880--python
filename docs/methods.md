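# Methods

## The admixture model and the f4-ratio estimator

East Asian house-mouse genomes are modeled as two-way mixtures of a
*musculus*-like source (sharing ancestry with the Korean panel, KOR) and a
*castaneus*-like source (sharing ancestry with the Indian panel, IND), with
the Kazakh *musculus* panel (KAZ) and the *M. spretus* outgroup (SPR)
closing the quartet. Because the drift on the branch shared by KAZ and KOR
is the only term that survives in both f4 values, the ratio

α̂ = f4(KAZ, SPR; X, IND) / f4(KAZ, SPR; KOR, IND)

estimates the fraction of X's genome drawn from the *musculus* side.
Implementation choices:

* **Frequencies.** Per-site alternate-allele frequencies over non-missing
  calls; a site enters an f4 sum only when all panels involved are defined
  (pairwise-complete deletion). A single focal sample is treated as a
  one-member panel with frequencies in {0, ½, 1}; no pseudo-haploidization.
* **Windows.** Non-overlapping, anchored at position 0 of each chromosome,
  0-based half-open, 20 kb by default; the final partial window is kept and
  subject to the same filters. Windows with fewer than 100 usable SNVs are
  flagged `too_few_snvs`; windows where either f4 term is ≤ 0 (statistical
  noise, unmodeled introgression or ancestral polymorphism) are flagged
  `nonpositive_term`. Flagged windows are retained in output with NaN α̂ so
  filtering is auditable downstream. α̂ > 1 is capped at 1.
* **Denominator.** Both f4 terms are computed from the same window by
  default; a `global_denominator` switch uses the genome-wide denominator
  instead. The per-window choice makes a window's α̂ self-contained at the
  cost of a noisier denominator.
* **Hudson FST** uses the standard unbiased per-site numerator
  (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) and denominator
  p1(1−p2) + p2(1−p1), aggregated per window as a ratio of sums
  (variance-stabilized); windows without usable sites are NaN, never 0.
* **LD pruning** follows the greedy sliding-window rule (window 50 SNVs,
  step 5, r² > 0.5): within each window the later member of any
  still-kept pair exceeding the threshold is removed; removal is global and
  windows never span chromosomes. r² is the squared dosage correlation over
  pairwise-complete samples.

## The synthetic cohort generator

The generator is the package's stand-in for the study cohort: it must
reproduce the *statistical structure* the estimators assume, not sequence
realism.

* **Allele frequencies** follow hierarchical Balding–Nichols drift along
  the population tree (outgroup; a shared ingroup branch; *musculus* and
  *castaneus* ancestors; panel branches). Each branch of length t
  generations and diploid size N contributes F = 1 − exp(−t/2N); the
  ancestral frequency is Uniform(0.05, 0.95). Defaults (Ne = 25,000
  everywhere; splits at 50k / 18k / 5k generations) put ~0.30 of
  heterozygosity-scaled drift on each source lineage, giving Hudson FST
  ≈ 0.30 between the KOR-like and IND-like sources — a realistic level of
  *castaneus*–*musculus* autosomal differentiation — and a comfortably
  positive f4 denominator. The fitted demographic parameters behind the
  original study are not published in the main text, so these defaults are
  a calibrated reconstruction, not the study's estimates.
* **Admixed genomes** are two-state mosaics per haplotype: switch events
  are Poisson with rate 5×10⁻⁶ per bp and the state is redrawn
  Bernoulli(a) at each event (a = 0.878 by default, the mean Japanese
  *musculus* fraction used as the generator's set-point). The redraw
  construction keeps the marginal law exactly Bernoulli(a) — a symmetric
  two-state chain would force the marginal to ½ — while leaving block
  lengths tunable: mean *musculus* segment 1/(r(1−a)) ≈ 1.6 Mb, mean
  *castaneus* segment ≈ 0.23 Mb, consistent with admixture a few hundred
  generations old. Truth tracks record the exact bp fraction of
  *musculus* state per window and genome-wide.
* **Planted blocks** override the mosaic inside an interval with a single
  constant state per haplotype, assigned deterministically by haplotype
  rank so the cohort-level block ancestry equals the requested fraction
  exactly — this is the fixture for outlier-recovery tests (emulating the
  ~2-Mb *castaneus*-enriched receptor cluster).
* **Sites** are uniformly placed, all biallelic, with SNV density 0.05/bp
  by default — the study-scale density (≈134M autosomal SNVs over the
  ~2.5-Gb mouse autosomes), which gives ~1000 SNVs per 20-kb window.
  Genotypes are Binomial(2, p) per panel member; missingness is off by
  default and available as a rate. Fixed seed ⇒ byte-identical outputs.
* **What is not emulated:** linkage within windows apart from the shared
  ancestry state (panel sites drift independently), mutation/ascertainment
  processes, indels/SVs, and read-level error. Null α distributions here
  are therefore somewhat narrower than a fully genealogical null at equal
  SNV counts; passing calibration tests shows the threshold machinery is
  correct under the generating model, not that real-data thresholds are
  transferable.

The amplicon-depth generator draws diagnostic-allele depths
Poisson(CN × depth / 2) per tag site, with optional outlier sites
(multiplied ×10 by default) and sub-1 mappability flags, emulating exactly
the artifacts the copy-number filters remove.

## The drive-introgression simulator

Non-overlapping Wright–Fisher generations at constant diploid N. Each
offspring samples a mother and father within sex (probability ∝ a
viability-equivalent weight), inherits sex chromosomes Mendelianly,
mitochondria maternally, and autosomal donor ancestry as the parental mean
(an infinitesimal/blending background — ancestry is only needed as the
substrate for incompatibility selection, so explicit loci would add
arbitrary detail without changing the dynamics). Distortion acts in the
male germline: a father carrying the long (donor, high-copy *Sly*-like) Y
and a short X sires males with probability (1+d)/(2+d); a long (high-copy
*Slx*-like) X fully suppresses the drive. Migration replaces Poisson(Nm)
random residents per generation with donor individuals (long-Y males,
long-X, ancestry 1, donor mitochondria), keeping N fixed. Hybrid
incompatibility weights are w = (1 − s_xhi·h_X)(1 − s_mito·h_M) with h the
X/ancestry and mito/ancestry mismatches. Replicates use counter-based
per-replicate streams from one master seed, so paired-seed comparisons
across parameter values are possible and every run is reproducible.

**Fixation speed and N.** The long-Y transmission advantage per generation
is s = d/(2+d) (≈ 0.091 at d = 0.2). A sweep through the ~N/2 Y copies
therefore takes ≈ 2·ln(N/2)/s generations plus an establishment wait of
~1/(0.5·2s) generations for a successful migrant lineage. In units of N
generations this *shrinks* as N grows (logarithmic numerator, linear
unit): measured medians are ≈ 0.122·N at N = 1000, 0.069·N at N = 2000 and
0.038·N at N = 4000 (d = 0.2, Nm = 1). The qualitative claims — drive makes
donor-Y fixation fast, no drive makes it rare within 0.1N generations, Y
fixes much faster than X, and strong X-autosome incompatibility suppresses
long-X introgression entirely while leaving the Y sweep intact — hold
throughout; the specific "within 0.1N" bound holds for N ≳ 1500 and is
reported honestly at whatever N is requested.

## Copy number from tag SNVs

Tag SNVs are alignment columns (gap-free in every sequence) where one
cluster is monomorphic for an allele absent from all other clusters;
coordinates map to the designated reference sequence, and diagnostic
alleles claimed at the same coordinate by two clusters are dropped as
ambiguous. Filtering keeps sites with mappability exactly 1, then — per
cluster, per sample — sites whose diagnostic-allele depth lies in
[median/3, 3×median] inclusive, the median being computed over
mappability-passing sites before the depth filter (the order is fixed here
because it was not specified upstream; this choice is deterministic and
testable). The estimate is CN = mean depth / (genome depth / 2). The
filter column defaults to diagnostic-allele depth with a switch for total
site depth. A minimal samtools-mpileup parser (read starts/ends, indels,
deletion placeholders, ref shorthand) turns pileup text into the site-depth
table; read mapping itself is out of scope.

## Neutral thresholds and outlier calling

The null distribution of window α is built from n independent neutral
20-kb windows simulated under the cohort's demography with the same
estimator and filters (window failures are logged; > 50% failures aborts —
that indicates an inconsistent configuration, e.g. SNV density below the
min-SNV filter). The threshold is the empirical 5% quantile (configurable);
outliers are pass-status windows strictly below it (one-sided low-α, the
*castaneus*-enrichment direction; a `direction="high"` option scans the
other tail). Windows simulate independently rather than as whole
chromosomes — the statistic is window-level and the study's null was built
from per-window simulations at scale. Tests and examples run the null at
1,000–10,000 simulations; the study-scale 200,000 is a parameter choice.

Annotation is any-bp overlap between half-open window and gene intervals
(interval-tree backed), deduplicated over outlier windows. Contrasts:
2×2 chi-square without continuity correction (outlier × gene-containing)
and a two-sided Mann–Whitney U on length-weighted mean window
recombination rates; degenerate tables are reported untestable rather than
raising.

## Numerical and interface conventions

* Coordinates: VCF 1-based; windows/BED 0-based half-open. Window grids
  anchored at 0; partial final windows kept.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; derived streams use list-seeding
  (`default_rng([master, k])`).
* Dosages are int8 with −1 as missing; frequencies NaN where undefined —
  never silently 0.
* Output TSVs carry a provenance header line (version, seed, parameters);
  no timestamps, so fixed-seed reruns are byte-identical.
* Problem sizes in the test suite are desk-scale by design: cohorts of
  1–3 chromosomes × 2–10 Mb at study-scale SNV density, nulls of
  1,000–10,000 windows, 100–20,000 simulator replicates; the methods above
  are size-independent and the sizes used are stated in each test.
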