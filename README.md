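# rohscan

Runs-of-homozygosity (ROH) detection, genomic inbreeding coefficients and
population-structure statistics for SNP-array genotype cohorts, plus a
synthetic-genotype generator with known ground truth for validating every
stage at desk scale.

The package is aimed at livestock and conservation geneticists comparing
selected (e.g. commercial hybrid) and unselected (autochthonous, free-range)
populations from medium-density array data in PLINK text format.

## What it computes

**ROH, consecutive method.** For each sample and chromosome, markers are
scanned in map order; a run is a maximal stretch of consecutive markers with
at most `max_het` heterozygous and `max_missing` missing calls and no
adjacent-marker gap above `max_gap_bp`, reported when it contains at least
`min_snps` homozygous SNPs and spans at least `min_length_bp`. Defaults:
150 SNPs, 1 Mb, 1 Mb gap, no heterozygote, no missing call. ROH length is
`end − start` (positions of the last and first SNP of the run). A brute-force
window-enumeration oracle (`detect_roh_oracle`) ships with the package and
the test suite proves scan/oracle equivalence on hundreds of randomized
instances.

**Genomic inbreeding.** Two coefficients per sample:

- excess homozygosity
  `F = (O_hom − E_hom) / (L − E_hom)` with
  `E_hom = Σᵢ (1 − 2 pᵢ(1 − pᵢ))` from Hardy–Weinberg proportions at cohort
  allele frequencies — negative values flag heterozygote excess;
- `F_ROH = Σ ROH length / genome length covered by SNPs`, total, per length
  class (`[0,2)`, `[2,4)`, `[4,8)`, `[8,∞)` Mb) and per chromosome. The
  denominator derives from the marker map, or can be fixed to a published
  assembly constant.

**ROH islands.** Per group, the fraction of samples whose ROH cover each
marker; maximal stretches with incidence ≥ 0.70 ("at least 70% of the
birds") become islands and can be annotated with gene intervals from BED or
GFF3 (closed-coordinate overlap, ≥ 1 bp).

**Population structure.** Weir–Cockerham (1984) pairwise F\_ST
(ratio-of-sums across markers; Hudson estimator available), PCA of centered
genotypes (deterministic up to a fixed sign convention), per-group
monomorphic-marker counts.

**Simulation.** Balding–Nichols drifted populations, tract-based
autozygosity (tracts placed to hit a target genome fraction α exactly — the
quantity F\_ROH estimates), and a four-way hybrid cross (A×B)×(C×D) of
near-fixed inbred lines with one generation of Poisson recombination, which
reproduces the negative-F / no-ROH signature of commercial hybrids.

## Worked example

```python
import rohscan as r
from rohscan.inbreeding import excess_hom_f, f_roh, regress_f_froh
from rohscan.popgen import pairwise_fst

cfg = r.SimConfig(
    n_chromosomes=10, chrom_length_bp=20_000_000, n_markers_per_chrom=2_000,
    pop_specs=(
        r.PopSpec("FREE", 20, drift_f=0.10, autozygosity_law=r.Law.uniform(0.02, 0.30)),
        r.PopSpec("HYB", 20, hybrid=True),
    ),
)
gm, mmap, groups, truth = r.simulate_cohort(cfg, seed=7)
records = r.detect_roh(gm, mmap)                     # 150 SNPs / 1 Mb / 1 Mb gap
froh = f_roh(records, mmap, gm.sample_ids)
fdf = excess_hom_f(gm)
fst = pairwise_fst(gm, groups)
reg = regress_f_froh(fdf["F"], froh.total, groups)

print(f"ROH detected: {len(records)}")
for g in groups.labels:
    m = groups.samples_in(g)
    print(f"{g:5s} mean F = {fdf.loc[m,'F'].mean():+.3f}   "
          f"mean F_ROH = {froh.total.loc[m].mean():.3f}   "
          f"R2(F~F_ROH) = {reg.loc[g,'r_squared']:.2f}")
print(f"F_ST(FREE, HYB) = {fst.get('FREE','HYB'):.3f}")
```

prints

```
ROH detected: 142
FREE  mean F = +0.153   mean F_ROH = 0.136   R2(F~F_ROH) = 0.98
HYB   mean F = -0.099   mean F_ROH = 0.000   R2(F~F_ROH) = 0.00
F_ST(FREE, HYB) = 0.171
```

The free-range group carries tract-based autozygosity: its mean F\_ROH
tracks the simulated autozygous fraction (slightly below the mean target
because tracts under ~1.5 Mb fall below the 150-SNP detection limit at this
marker density), F is positive, and F and F\_ROH are tightly coupled
(R² = 0.98). The hybrid cross shows the opposite signature: heterozygote
excess (F < 0), no ROH at all — its homozygosity is not organized in runs —
and consequently no F–F\_ROH relation. The F\_ST of 0.17 reflects the strong
divergence between drifted line frequencies and the free-range population.

## Command line

```sh
rohscan simulate --study --seed 1 --out-prefix scratch/study     # PED/MAP/groups/truth
rohscan roh --ped scratch/study.ped --map scratch/study.map --out scratch/roh.tsv
rohscan run --config pipeline.yaml                               # full pipeline
```

`rohscan run` executes filter → ROH → summaries → incidence → islands →
annotation → inbreeding → F\_ST → PCA and writes every table plus a
`manifest.json` (input hashes, parameter echo); reruns are byte-identical.
Exit codes: 0 success, 2 configuration error, 3 data error.

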