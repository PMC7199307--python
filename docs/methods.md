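# Methods

## The analysis model

`rohmap` implements homozygosity mapping of a quantitative phenotype in five
stages, each exposed as a library function and a CLI subcommand.

### Marker quality control

Markers are removed when they map off autosomes 1–29, have call rate ≤ 0.95,
or minor allele frequency ≤ 0.05. Removal **at** the threshold is
deliberate, and the comparisons are done in integer count space
(`minor_count > maf * 2 * n_obs`) so that an exactly-boundary marker is
never mis-kept through floating-point rounding. A marker with no non-missing
calls falls under the call-rate rule. There is no sample-level QC. When a
bull carries several phenotype records, the one with most breedings is kept
(ties: larger |SCR|, then input order).

### ROH detection

The scanner reproduces the PLINK `--homozyg` window logic with
oracle-defined semantics (the test suite pins it, segment for segment, to a
brute-force enumeration of every window and run):

1. every span of `window_snp` consecutive markers fully inside a chromosome
   is *homozygous* when it has ≤ `window_max_het` hets and
   ≤ `window_max_miss` missing calls;
2. each marker's hit fraction is homozygous-covering-windows /
   covering-windows (chromosomes shorter than one window yield nothing);
3. a marker is marked when its hit fraction ≥ `hit_threshold` **and** its
   own call is homozygous non-missing — so a heterozygous call splits runs;
4. maximal marked runs are split at inter-marker gaps > `max_gap_kb` and
   kept when they satisfy `min_snp`, `min_kb` and the `max_kb_per_snp`
   density bound.

The hit-fraction threshold is compared as
`hits >= threshold * n_windows - 1e-9` (integer hit counts, one shared
comparison rule) so vectorized and enumerated computations can never
disagree at the boundary.

Defaults (100-SNP window, 1 het, 1 miss, threshold 0.05, min 100 SNP /
1,000 kb, 1,000 kb gap, 50 kb/SNP) are the PLINK 1.9 defaults for a ~270k
bovine array. For the simulated desk panel (1,000 markers/chromosome at
~10 kb spacing, i.e. the real array's density but a 29-times smaller panel)
the window and minimum-run sizes are scaled to `window_snp=50`,
`min_snp=50`, `min_kb=500`, keeping the het/miss allowances; the final
segments carry no het/miss limit beyond what the windows allowed.

Coordinates are 1-based inclusive bp (PLINK `.hom` convention);
`length_kb = (end − start + 1)/1000`. BED3 export is 0-based half-open.

### Burden association

OLS of the phenotype on the per-animal sum/mean/max of ROH length, slope
standardized to SCR % per **Mb** (a slope on kb is exactly 1000× smaller;
unit consistency is property-tested). Extreme groups are the top and bottom
`n_per_group` animals by SCR; at a tied cutoff the record with more
breedings is admitted, and the low group is drawn from the complement of the
high group so the two can never share an animal. Group differences use
Welch's t-test by default (`test="ranksum"` for the Mann–Whitney
alternative). Pedigree inbreeding (for burden–F comparisons) uses the
tabular additive-relationship recursion; any animal with an unknown parent
gets F = 0.

### Consensus regions and enrichment

Segment boundaries partition each chromosome into atomic intervals with
constant carrier sets (carrier = animal whose single ROH covers the whole
interval); adjacent intervals with identical carrier sets are merged, and
regions with ≥ `min_snp` (default 5) markers and ≥ `min_carriers`
(default 2) carriers are kept. The sweep removes a segment's carrier before
adding at a shared boundary, so back-to-back segments of one animal stay
active. The 5-SNP filter is applied *before* testing (the stricter reading
of the source protocol); Bonferroni m is the number of regions actually
tested. The Fisher test is one-sided for carrier excess in the low group via
the exact hypergeometric tail; the odds ratio adds 0.5 to every cell only
when some cell is zero, and that correction never enters the p-value.

### GBLUP validation

One model per significant region (a joint fit is available behind
`joint=True`): y = Xb + Zu + e with X = [intercept, carrier indicator],
u ~ N(0, Gσ²g), e ~ N(0, Iσ²e), G the VanRaden method-1 GRM from observed
allele frequencies with per-marker mean imputation of missing calls.
Because each animal has one record, ZGZ' is a sub-matrix of G and V is a
single-kernel covariance; REML therefore reduces, after one
eigendecomposition of ZGZ', to a 1-D profile likelihood in
λ = σ²g/σ²e, maximized by bounded scalar search on log λ
(tolerance 1e-8, ≤ 200 evaluations, bounds e±12, with an explicit
boundary check for σ²g → 0). This replaces the usual AI/EM iteration: it
cannot diverge, needs no step-size control, and each evaluation is O(np²).
With fixed variances the solver is algebraically the GLS closed form
(property-tested to 1e-8 against a direct (X'V⁻¹X)⁻¹X'V⁻¹y). A region is
validated when the carrier |t| ≥ 2. G gets a 1e-6 ridge only where a
Cholesky of a simulated G is needed (duplicated genotypes occur in
simulation).

## The simulator

Gene dropping over an explicit pedigree rather than coalescent simulation,
because it yields exact IBD truth (founder-haplotype labels inherited
through the same crossovers as the alleles) and a pedigree for inbreeding-F
cross-checks. Defaults emulate the study system at desk scale:

| parameter | default | rationale |
|---|---|---|
| chromosomes × markers | 29 × 1,000 | bovine autosomes; panel shrunk ~29× |
| marker spacing | exp(mean 10 kb) | real ~270k array density (~9.7 kb/SNP) |
| founder allele freq | U(0.05, 0.5) | post-QC spectrum |
| map length | 1 Morgan/chromosome | cattle chromosomes ≈ 1 M |
| population | 40 founders, 5 generations of 600 | few elite sires, strong drift |
| loop rate | 0.2 | sib/half-sib matings → recent autozygosity |
| mu, beta_sum | 0, −0.002 %/Mb | slope consistent with r ≈ −0.09 at SCR sd ≈ 2 |
| σ²g, σ²e | 0.4, 3.6 | h² = 0.1; male fertility is lowly heritable; SCR sd ≈ 2 |
| n_breedings | log-uniform [300, 136,001] | observed range; exercises de-duplication |

A planted region makes a chosen fraction of animals homozygous by descent
across a marker span (haplotype 0 copied over haplotype 1, labels included)
and shifts their phenotype by `effect` (the recessive δ). Genotyping error
replaces a call with one of the other two codes uniformly; missingness is
applied last. HBD truth is the set of marker spans where the two labels
agree; per-animal burden is total HBD Mb.

What the simulator does **not** model: background linkage disequilibrium
(LD exists only through co-inherited founder haplotypes), mutation,
selection, realistic cattle demography, or sex chromosomes. Passing tests
therefore demonstrate the pipeline's correctness and power on
pedigree-driven autozygosity, not calibration to any real population's ROH
abundance (the real-data segment counts and ~10% autozygosity depend on the
access-restricted genotypes and are out of scope).

## Verification experiments and problem sizes

The acceptance tests fix these conditions (chosen once, for statistical
adequacy at workstation scale):

- **Detector equivalence**: 50 random panels (≤ 30 × ≤ 3,000 markers,
  random parameters with windows ≤ 25) against an oracle that enumerates
  every window directly.
- **Tract recovery**: desk profile; per-tract boundary-accurate recovery
  (both boundaries within one window of truth) with clean genotypes, and
  per-marker coverage of qualifying tracts (≥ 2·min_snp markers) under 1%
  genotyping error — split runs are designed behaviour under the own-call
  rule, so coverage is the honest error-case metric.
- **Fisher exactness**: exhaustive sweep of every 2×2 table with both group
  sizes ≤ 60 against exact integer enumeration (1e-12).
- **Slope recovery**: 50 replicates, n = 2,000, 12 chromosomes × 400
  markers (the larger genome gives the burden enough variance that the
  GRM-correlated polygenic term does not distort OLS coverage),
  GRM thinned 4× for the phenotype draw.
- **REML recovery**: 20 replicates, n = 500, true h² = 0.3.
- **End-to-end power**: 20 desk replicates with the planted δ = −3 region,
  groups of 100 of 600; plus label-permutation null scans for family-wise
  error control. The GRM uses every 3rd marker here (n ≫ effective marker
  dimension; the thinning is immaterial and cuts the dominant cost).

## Known limitations

- The scanner is the window heuristic, not an HMM; short IBD tracts
  (< min_snp markers) are invisible by design.
- Heterozygous genotyping errors split runs (see above); with error rates
  well above ~1% the `min_snp` threshold should be lowered or an
  HMM-based method preferred.
- REML with a single genetic kernel only; no multi-trait or single-step
  (pedigree + genomic) relationship matrices.
- Consensus regions are defined by exact whole-region coverage; an animal
  whose ROH covers 99% of a region is a non-carrier of that region.
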