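# Methods

## Scope and data model

The package analyzes diploid SNP-array genotypes stored as allele counts
{0, 1, 2} of a per-marker *counted* allele, with −1 for missing calls, aligned
to a marker map of (id, chromosome, 1-based bp position) sorted by natural
chromosome order and position. The counted allele is the lexicographically
larger of the observed allele symbols — a reference-free, deterministic
convention. Every statistic in the package is symmetric under swapping allele
labels, so the polarity is immaterial; the one visible consequence is that a
marker whose calls are all 0 (the counted allele never observed) re-reads
from a written PED file as all 2. Round-trip identity therefore holds
exactly for every marker at which the counted allele is observed at least
once, and up to polarity otherwise.

Coordinates follow PLINK conventions: 1-based, closed intervals. All BED
exports convert to 0-based half-open. Interval length is `end − start`
throughout (ROH and islands alike); this matches how array studies print ROH
lengths from SNP edge positions.

## ROH detection (consecutive method)

Per sample and chromosome, markers are scanned in map order without sliding
windows. The constraint set is:

| parameter | default | meaning |
|---|---|---|
| `min_snps` | 150 | minimum *homozygous* markers in the run |
| `min_length_bp` | 1,000,000 | minimum span, `end − start` |
| `max_gap_bp` | 1,000,000 | maximum adjacent-marker gap inside a run |
| `max_het` | 0 | heterozygous calls tolerated |
| `max_missing` | 0 | missing calls tolerated |

A gap above `max_gap_bp` always terminates a candidate, so locally sparse
marker coverage cannot fake a long homozygous stretch. With the default zero
tolerances, maximal runs are unique and disjoint, and the implementation
uses a vectorized segment scan. With positive tolerances maximal windows can
overlap; the scan emits maximal windows left-to-right and drops windows
contained in an emitted one. This dialect is pinned by an exhaustive oracle
(`detect_roh_oracle`): enumerate all windows, keep those satisfying every
constraint, discard windows contained in a larger valid window. Because the
reporting thresholds (`min_snps`, `min_length_bp`) are monotone under window
extension while the tolerance constraints are monotone under shrinking, the
two formulations coincide; the test suite checks equality on 200+ randomized
instances across a parameter grid, plus maximality and constraint assertions
on every emitted run.

Runs never span chromosomes. Raising `min_snps` or `min_length_bp` can only
remove runs; raising `max_gap_bp` can only grow total covered length — both
monotonicity properties are tested.

## Inbreeding coefficients

**Excess homozygosity.** For sample *j* over its non-missing markers with
defined frequency, `F_j = (O − E) / (L − E)` where `O` counts homozygous
genotypes, `E = Σᵢ (1 − 2pᵢ(1−pᵢ))`, and `L` is the marker count.
Frequencies default to the full cohort: this choice is what produces the
negative-F signature of hybrids, whose heterozygosity exceeds the
Hardy–Weinberg expectation at pooled frequencies. Monomorphic markers
contribute 1 to `O`, `E` and `L` and cancel; if all markers are monomorphic
the denominator vanishes and F is NA (warned). An optional finite-sample
correction (`2pq·n/(n−1)`) is available but off by default; with the
uncorrected estimator the null expectation of F carries a small negative
O(1/n) bias (about −0.02 at n = 30, −0.007 at n = 100), which the null test
accounts for by using a 100-sample cohort.

**F_ROH.** Total ROH length over the genome length covered by SNPs. The
default denominator is Σ over chromosomes of (max − min marker position),
fully determined by the map; a constant override is provided for matching a
published assembly span (e.g. 901,342,009 bp for 30 turkey autosomes).
Per-class values use the same total denominator, so they sum exactly to the
total (the integer numerators partition the total ROH length — asserted in
tests). Per-chromosome values use per-chromosome spans and recombine to the
total under the map-derived denominator.

**Regression of F on F_ROH.** Ordinary least squares per group. When F_ROH
has zero variance the slope is undefined (NA); R² is then reported as 0 when
F still varies — a constant predictor explains nothing — and NA when both
are constant. This case is not academic: hybrid-cross cohorts simulated
under marker independence have no ROH at all (below).

## Length classes, incidence and islands

Length classes are half-open `[a, b)` in Mb, defaults `[0,2)`, `[2,4)`,
`[4,8)` plus an overflow class `[8, ∞)` so the classes partition (0, ∞); a
run of exactly 2.000 Mb belongs to 2–4. Report percentages are rounded to
integers (they sum to 100 ± 1).

The incidence profile gives, per group and marker, the fraction of the
group's samples (including zero-ROH samples) with a ROH covering the marker
position. Islands are maximal stretches of consecutive markers with
incidence ≥ threshold (default 0.70, inclusive — "at least 70%"), evaluated
on integer counts (`count ≥ threshold·size − 1e-9`) to avoid float boundary
artifacts, spanning first to last qualifying SNP, and requiring at least 2
SNPs (a single-marker island has zero length). Gene annotation reports any
gene interval overlapping the island by ≥ 1 bp on closed coordinates; genes
are read from BED (converted from 0-based half-open) or GFF3 via gffutils.

## Population structure

Pairwise F_ST uses the Weir–Cockerham (1984) two-population variance
components a (among populations), b (among individuals) and c (within
individuals), aggregated across markers as Σa / Σ(a+b+c) (ratio of sums, the
standard multi-locus form). Markers monomorphic across the pair or observed
in fewer than two samples of either group are skipped. Raw estimates (which
can be slightly negative for undifferentiated groups) are kept in the audit
output; the summary matrix truncates at 0 and prints 3 decimals. A
Hudson-type estimator is available as a sensitivity option.

PCA centers genotype columns on 2p (optionally scales by √(2p(1−p))),
mean-imputes missing calls per marker, and takes the SVD; eigenvalues are
singular values squared over (n−1). The sign of each component is fixed by
making its largest-magnitude loading positive, so results are fully
deterministic and invariant (up to that convention) to marker permutation.

Monomorphic-marker counts report, per group and chromosome, markers whose
within-group frequency is exactly 0 or 1, ignoring missing calls.

## Synthetic cohorts

The generator emulates a small livestock array cohort; all randomness flows
from one seed and outputs are bit-reproducible.

- **Markers**: positions uniform without replacement per chromosome;
  default 10 chromosomes × 20 Mb with 2,000 markers each (1 per 10 kb).
  The study-scale configuration (`study_config`) uses 30 autosomes.
- **Ancestral frequencies**: Uniform(0.05, 0.95) by default.
- **Population drift**: Balding–Nichols,
  `p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, so the drift parameter F equals
  the expected F_ST; two populations drifted by F sit near pairwise
  Weir–Cockerham F_ST ≈ F (recovered within ±0.03 at 10,000 markers,
  n = 25 + 25).
- **Autozygosity**: per sample, a target fraction α is drawn from the
  population's law and identical-by-descent tracts (lengths from a
  configurable law, default Exp(mean 3 Mb)) are placed without overlap
  until Σ lengths = α·genome exactly, the last tract truncated. Starts are
  drawn uniform over positions where the tract fits, so chromosome ends do
  not distort the length law. Inside a tract one allele is drawn from the
  population frequency and doubled; outside, genotypes are Hardy–Weinberg
  draws. Tract-level ground truth is returned for parameter-recovery tests.
- **Hybrid cross**: four inbred lines with independently drifted near-fixed
  frequencies (line drift 0.95 by default); each offspring receives one
  gamete from an (A×B) parent and one from a (C×D) parent, each gamete a
  mosaic with Poisson crossovers (default 10⁻⁸ per bp ≈ 1 cM/Mb). Offspring
  show heterozygosity above the pooled Hardy–Weinberg expectation (mean
  excess-homozygosity F ≈ −0.1 to −0.33 depending on the frequency
  reference), and — because line frequencies are independent across
  markers — per-marker allele agreement between gametes is ≈ 0.64, making a
  150-marker run astronomically unlikely: hybrid cohorts have no ROH.
- **Missing calls**: sprinkled independently at a configurable rate,
  default 0 (array studies filter to ≥ 0.99 call rate before ROH analysis,
  and the default detector forbids missing calls inside runs).

**What the simulator does not model.** Markers are independent given
population frequencies: there is no linkage disequilibrium, no haplotype
sharing between lines, and no shared selection. Consequences worth knowing:
(i) the short-ROH background that LD creates in real arrays is absent, so
simulated cohorts have relatively fewer sub-2 Mb runs than real data;
(ii) ROH islands essentially never arise (tracts are placed independently
across samples), so island calling is validated on constructed incidence
profiles rather than on simulated cohorts; (iii) hybrid F_ROH is exactly 0
rather than small-but-positive. Passing recovery tests therefore validate
the estimators' arithmetic and calibration, not robustness to LD structure.

**Detection bias on F_ROH.** At 1 marker / 10 kb, the 150-SNP rule implies
an effective detectability limit near 1.5 Mb, so tracts below it — about
10% of the tract mass under Exp(3 Mb), plus the target-truncated final
tract — are invisible. Mean recovered F_ROH at α = 0.15 is ≈ 0.134
(5 seeds), a real, explained −0.016 bias that still sits inside the ±0.02
recovery band used in the acceptance suite.

## Numerical and degenerate-case choices

- Call-rate comparison uses `rate ≥ min_rate − 1e-12` so 0.99 behaves as
  printed; the filter is idempotent and may (with a warning) empty the map.
- The brute-force ROH oracle refuses instances above 10⁴ sample×marker
  cells; acceptance equivalence runs use 2 samples × 120 markers × 200
  instances plus one 5 × 600 instance.
- A single-marker "run" is rejected because its span is 0 < `min_length_bp`.
- F_ST of a group with itself is defined as 0; groups need ≥ 2 samples.
- PCA truncates (with a warning) when more components are requested than
  the matrix rank; a single sample yields zero scores.
- Pipeline tables are written with fixed float formatting; reruns with the
  same config are byte-identical (the manifest records input SHA-256 hashes
  and the parameter echo, and contains no timestamps).

## Problem sizes

Test-suite and acceptance computations are desk-scale by design: the
study-scale cohort is 68 samples × 60,000 markers; recovery experiments use
30 samples × 20,000 markers × 5 seeds (F_ROH) and 50 samples × 10,000
markers (F_ST). The full suite runs in a few seconds on one CPU.

## Known limitations

- No PLINK binary (BED/BIM/FAM) or VCF ingestion; PED/MAP text only.
- No LD-aware or pedigree-based simulation; no selection sweeps.
- The consecutive-method dialect for positive heterozygote/missing
  tolerances (left-to-right maximal windows, containment dropped) is one of
  several reasonable conventions; it is documented and oracle-pinned rather
  than matched bit-for-bit to any external tool.
- Enrichment analyses (GO/KEGG, QTL databases) are out of scope; export the
  island gene lists instead.
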