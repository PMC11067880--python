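# musadmix

Population-genetic tools for studying secondary contact between house-mouse
subspecies (*Mus musculus castaneus* × *M. m. musculus*), built around four
capabilities:

1. **f4-ratio admixture mapping** — estimate the *musculus* ancestry
   proportion α of a sample or population X from four reference panels
   (Kazakh *musculus* = KAZ, *M. spretus* outgroup = SPR, Korean
   *musculus* = KOR, Indian *castaneus* = IND):

   α̂ = f4(KAZ, SPR; X, IND) / f4(KAZ, SPR; KOR, IND),

   where f4(A,B;C,D) is the mean over sites of (p_A − p_B)(p_C − p_D).
   α̂ is computed genome-wide and in non-overlapping 20-kb windows with the
   standard filters (≥100 SNVs per window, both f4 terms positive, values
   above 1 capped at 1). Hudson FST (ratio-of-sums per window) and
   PLINK-style greedy LD pruning (`--indep-pairwise 50 5 0.5` semantics)
   round out the scan toolkit.

2. **Wright–Fisher drive simulation** — forward simulation of the
   introgression of "long" (high-copy, *musculus*-type *Sly*/*Slx*-like)
   segregation-distorter haplotypes on the X and Y chromosomes into a
   recipient population: one-way migration at rate Nm, male-germline
   distortion (a long-Y/short-X father sires males:females at (1+d):1,
   i.e. P(male) = (1+d)/(2+d); a long X restores 1:1), and optional
   X–autosome and mito–autosome hybrid incompatibilities.

3. **Ampliconic copy-number estimation** — tag SNVs (cluster-diagnostic
   alignment columns) are extracted from a paralog multiple alignment, and
   per-cluster copy number is estimated as the mean diagnostic-allele depth
   over filtered sites divided by half the genome-wide mean depth, after
   keeping only mappability-1 sites with depth in [median/3, 3×median].

4. **Simulation-based outlier scanning** — a neutral null distribution of
   window α is built from independent window simulations; windows below
   the empirical 5% quantile are ancestry-enriched outliers, which are then
   annotated against gene intervals and contrasted with the genomic
   background for gene density (chi-square) and recombination rate
   (Mann–Whitney U).

A synthetic-data module generates reference-panel cohorts with admixed
focal genomes and known per-window ancestry truth (hierarchical
Balding–Nichols drift + two-state ancestry mosaics), plus Poisson depth
profiles for the copy-number stage, so the whole pipeline is testable
without any data download.

## Worked example

```python
import musadmix as mx

spec = mx.DemographicSpec(
    seed=7, n_chromosomes=1, chrom_length=4_000_000,
    planted_blocks=(mx.PlantedBlock("chr1", 1_000_000, 3_000_000, 0.3),),
)
cohort = mx.simulate_cohort(spec)
alpha = mx.f4_ratio_alpha(cohort.geno, "FOCAL")
tab = mx.windowed_alpha(cohort.geno, "FOCAL",
                        chrom_lengths={"chr1": spec.chrom_length})
blk = tab[(tab.start >= 1_000_000) & (tab.end <= 3_000_000)]
print(alpha, blk.loc[blk.status == "pass", "alpha"].mean())
```

Running `python examples/02_alpha_scan.py` (this same analysis) prints:

```
genome-wide alpha = 0.586 (truth 0.582)
{'pass': 199, 'nonpositive_term': 1}
planted 2-Mb block (true musculus fraction 0.3): mean window alpha = 0.284
```

The genome-wide α̂ matches the generator's truth to ~0.004, and the 2-Mb
block planted at 30% *musculus* ancestry (emulating a *castaneus*-enriched
receptor-gene cluster) is recovered at a mean window α̂ of 0.28. The other
`examples/` scripts demonstrate cohort simulation, the drive simulator, the
copy-number estimator and the outlier scan in the same style.

A thin CLI mirrors the library: `musadmix simulate-cohort | alpha-scan |
fst-scan | ld-prune | sd-sim | copy-number | outlier-scan | demo`
(see `musadmix --help`).

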