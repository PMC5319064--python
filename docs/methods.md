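# Methods

This note records the models the package implements, the default parameters
and their rationale, what the simulators do and do not emulate, the numerical
choices, and known limitations. Every number quoted here is computed by the
test suite or by `scripts/acceptance.py`.

## Tamura–Nei (TN93) distance with gamma rate heterogeneity

For an aligned sequence pair, sites where either sequence is not an
unambiguous base (A/C/G/T) are removed for that pair (pairwise deletion).
Base frequencies `g_A..g_T` are estimated empirically from the pair itself
(averaging the two sequences), matching the convention of standard
phylogenetics software. With `g_R = g_A + g_G`, `g_Y = g_C + g_T`,
purine-transition proportion `P1`, pyrimidine-transition proportion `P2` and
transversion proportion `Q`:

```
k1 = 2 g_A g_G / g_R
k2 = 2 g_C g_T / g_Y
k3 = 2 (g_R g_Y − g_A g_G g_Y / g_R − g_C g_T g_R / g_Y)
w1 = 1 − P1/k1 − Q/(2 g_R)
w2 = 1 − P2/k2 − Q/(2 g_Y)
w3 = 1 − Q/(2 g_R g_Y)
```

Without rate heterogeneity the distance is
`d = −(k1 ln w1 + k2 ln w2 + k3 ln w3)`; with gamma-distributed site rates of
shape `α` it is `d = α [k1 (w1^(−1/α) − 1) + k2 (w2^(−1/α) − 1) +
k3 (w3^(−1/α) − 1)]`. When any `w` term is non-positive the distance is
undefined (saturation) and reported as NaN. Negative estimates from sampling
noise are clamped to zero.

**Defaults.** `gamma_shape = 0.33` (the shape commonly used for mammalian
D-loop data and the package's default throughout); `bootstrap_reps = 500`
column-resampling replicates for group-mean standard errors. The gamma form
converges to the log form as `α → ∞`; the test suite checks agreement at
`α = 10^9` to 1e-6 and agreement with an independently coded closed form to
1e-10. Parameter recovery on simulated pairs (true distance 0.01/0.05/0.1,
10 kb, 100 replicates) is within 1% relative error.

**Group distances** average the pairwise distances over all pairs between (or
within) groups, excluding undefined pairs with a warning; a single-member
group has no within-group distance. Bootstrap SEs resample alignment columns
with replacement and take the standard deviation (ddof 1) of the replicate
means.

## Haplotype collapsing and clade assignment

Sequences are grouped into haplotypes by exact identity after primer
trimming; under the default "lenient" policy IUPAC ambiguity codes match any
of their expansions and the least-ambiguous member represents the haplotype.
Haplotype ids are assigned by descending carrier count. Clade assignment is
nearest-mean TN93 distance to a labelled reference panel; ties give
"unassigned" with margin 0. The margin (distance gap between the two nearest
clades) is reported so low-confidence calls are visible.

## MC1R allele typing and coat colour

Variants are called by global alignment (free end gaps) of each allele
sequence against a reference CDS; substitutions are annotated with their
amino-acid consequence and indels with position and inserted bases. Allele
classification follows a fixed decision order on the variant set: the 2-bp
CC insertion near nt 67 → E^P (0501); Asp124Asn alone → E^D2 (0301);
Leu102Pro (with or without Val95Met) → E^D1 (0201); Ala164Val + Ala243Thr →
e (0401); no defining variant → wild-type (0101). Variant sets that match no
definition are "novel" with a warning. Sequences that do not cover all
defining positions are classified from the covered sites and flagged
"partial". Coat colour follows the dominance cascade black (any 0201/0301) >
wild-type (any 0101/0102) > spotted (any 0501) > red (0401/0401); any novel
allele that would be decisive yields "indeterminate".

The bundled reference CDS is **synthetic**: a random 963-bp (321-codon) open
reading frame with the defining codons pinned so that each documented variant
has its documented amino-acid consequence, and with the insertion
neighbourhood chosen so alignment cannot slide the insertion. It is a test
harness, not the real porcine gene; real analyses should pass the real CDS
via `reference_cds`.

## Genotype QC, merging, sex inference, PCA

QC removes, in order: SNPs with missingness > 10%, SNPs with minor-allele
frequency < 5% (computed on remaining calls), then samples with missingness
> 10% over the surviving SNPs. The order matters and is fixed; thresholds
are strict inequalities. Dataset merging harmonises swapped allele order by
flipping dosages and drops SNPs with irreconcilable alleles; A/T and C/G
SNPs (strand-ambiguous) are dropped when the frequency difference between
datasets exceeds 0.4. Sex inference calls a sample male when X
heterozygosity ≤ 0.05 and Y call rate ≥ 0.5, female when the converse holds,
otherwise ambiguous. PCA mean-imputes missing calls, centres, scales by
`sqrt(p(1−p))` (the smartpca convention; sample-SD scaling is available),
and takes the SVD; component signs are fixed by making the
largest-magnitude loading positive, so results are reproducible up to
machine precision.

## Weir & Cockerham FST and the selection scan

Per SNP, the two-population variance components a (among populations), b
(among individuals) and c (within individuals) are computed from sample
sizes, allele frequencies and observed heterozygosity exactly as in Weir &
Cockerham (1984); the per-SNP estimate is `a/(a+b+c)` and the genome
summaries are the weighted ratio of sums `Σa/Σ(a+b+c)` (the standard
genome-wide estimator) and the mean of per-SNP ratios. SNPs where either
population has fewer than two genotyped samples, or with no variation in the
combined sample, are NaN. The implementation is verified against an
independently coded scalar transcription on 1,000 random instances to 1e-12,
and the weighted estimator recovers the Balding–Nichols simulation's true
FST within 0.01 at F ∈ {0, 0.15, 0.33} (100 per population, 5,000 SNPs).

The scan smooths raw per-SNP FST in centred windows of ±50 kb (100 kb
total), excluding NaNs; an isolated SNP's smoothed value is its own raw
value. A SNP qualifies as a candidate when its raw FST strictly exceeds the
genome-wide 99th percentile **and** its smoothed FST strictly exceeds the
95th percentile (numpy linear-interpolation quantiles). Each qualifying SNP
contributes a ±50 kb window; windows that overlap or touch are merged and
each merged interval reports the SNP with the highest raw FST as its peak.
Sex-chromosome SNPs and SNPs fixed within either population are excluded
before estimation. Across multiple pairwise comparisons, candidate coverage
is intersected per base; shared intervals carry the best overlapping peak.

**Scan validation scale.** Because both thresholds are genome-relative
quantiles, a spiked region can only be recovered *cleanly* (no candidate
elsewhere) when it holds more than 1% of the genome's SNPs (raw threshold)
and, with its flanks, more than 5% (smoothed threshold). The package's scan
validation therefore uses a deliberately scaled genome: 2 chromosomes × 3 Mb
at 10 kb SNP spacing (600 SNPs), background FST 0.02, one 200 kb spike with
delta 0.3 at chr1:1.5–1.7 Mb, 100 samples per population. Under these
conditions the spike occupies ~3.3% of SNPs and is recovered with no false
interval in 10/10 seeds. On paper-scale genomes the same thresholds always
flag ~1% of SNPs somewhere, so "no interval elsewhere" is not a meaningful
expectation at that scale; this is a property of percentile-based outlier
scans generally, not of this implementation.

## Simulators: what they emulate and what they do not

- **D-loop simulator.** Two clade root sequences diverge from a random
  ancestor (half the clade divergence each), then haplotypes evolve from
  their clade root at the within-clade divergence. Mutations are Poisson per
  site with gamma-distributed site rates and transition:transversion bias
  (kappa = 4). It emulates the haplotype structure and rate heterogeneity of
  control-region data; it does **not** emulate indels, recombination (absent
  in mtDNA anyway), heteroplasmy, or sequencing error.
- **Genotype simulator.** Balding–Nichols: ancestral frequencies uniform on
  the configured MAF range, population frequencies Beta-distributed with
  variance `F·p(1−p)`, genotypes Binomial(2, p_pop) — i.e.
  Hardy–Weinberg within populations, no linkage disequilibrium, no
  inbreeding, independent missingness. Spiked regions add `delta` to F for
  SNPs inside. X/Y markers follow assigned sexes deterministically (males: X
  homozygous, Y called; females: no Y calls). It validates estimators and
  the scan; it does not emulate LD decay, ascertainment bias of SNP chips,
  or genotype-calling error structure.
- **TN93 pair simulator.** Exact: builds the TN93 rate matrix (mean rate 1),
  draws gamma site rates, and samples the second sequence from the matrix
  exponential at the requested distance — so estimator recovery checks are
  against an exactly known truth.
- **MC1R simulator.** Applies defined variant sets to the reference CDS; no
  sequencing noise.

## Numerical choices

- Distances and FST are computed in float64 throughout; genotypes are stored
  as int8 dosages with −1 as the missing code.
- Quantile thresholds use `numpy.nanquantile` (linear interpolation) with
  strict inequality, so a constant FST vector yields no candidates.
- Window smoothing uses per-chromosome cumulative sums with binary search,
  O(n log n), identical (to 1e-12) to the brute-force window mean.
- Bootstrap and all simulations take explicit integer seeds (< 2^31) and are
  bit-reproducible for a given seed.

## Limitations

- The two-population Weir–Cockerham form is implemented (r = 2); multi-
  population FST is out of scope.
- Clade assignment uses nearest mean distance to a panel, not phylogenetic
  placement; a Bayesian tree (as used in full analyses of such data) is out
  of scope.
- PED/MAP text I/O covers the standard whitespace dialect only (no binary
  BED, no compound fields).
- The MC1R reference CDS is synthetic (see above); allele definitions cover
  the six documented alleles, and anything else is reported as "novel"
  rather than interpreted.
- The QC example fixture is 20 samples × 10 SNPs, constructed so the three
  removal stages each fire a known number of times (2 SNPs for missingness,
  3 for MAF, 1 sample); smaller sample counts cannot realise those counts at
  the default thresholds because per-call missingness granularity exceeds
  the 10% threshold.
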