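# Methods

This document records the model, the numerical conventions, every default
parameter with its rationale, and the known limitations of `connekt`.

## 1. Model and assumptions

All statistics are computed under the single-trait animal model

```
y = X b + Z u + e,    u ~ N(0, K σ²ᵤ),    e ~ N(0, I σ²ₑ)
```

with one phenotype record per individual. `X = [X₁ X₂]` where `X₁` is the
one-hot incidence of the management unit (no intercept — the unit effects are
directly identifiable) and `X₂` holds optional extra categorical fixed effects,
coded with the first level dropped so the combined design has full column rank.
A rank check rejects confounded designs and names the aliased columns. `Z`
maps records to the individuals indexed by `K`; individuals present in `K` but
without a record get a zero column, so their breeding values are still
predicted and their PEVs contribute to unit summaries.

Variance components are taken as known and supplied either as a heritability
`h²` (with phenotypic variance fixed at 1, so `σ²ᵤ = h²`, `σ²ₑ = 1 − h²`) or
directly as the ratio `λ = σ²ₑ/σ²ᵤ`. No variance-component estimation is
performed.

### Relationship matrices

- **Pedigree**: numerator relationship matrix `A` by the tabular method after
  a topological sort of the pedigree (parents before offspring; cycles and
  unknown-parent codes are validated first). Results are returned in the
  caller's original order.
- **Genomic**: VanRaden method 1, `G = W W′ / (2 Σ pⱼ(1−pⱼ))` with `W` the
  column-centered 0/1/2 genotype matrix and `pⱼ` the observed allele
  frequencies. Monomorphic markers carry no information and are dropped with a
  warning; an all-monomorphic panel is an error. *Open question resolved:*
  the method-1 form (observed-frequency centering and scaling) is assumed
  throughout; no weighting or blending with `A` is implemented.

### Inversion and regularization

`K` is inverted via Cholesky factorization. If the factorization fails
(singular or indefinite `K`, common for `G` when individuals outnumber
effective markers), a ridge `ε = 1e-8` is added to the diagonal and
the factorization retried, with a warning. `ε` is small enough to leave CD/r
unchanged at the reported precision and large enough to lift `G`'s null
directions; the value actually used is returned to the caller and logged by
the pipeline.

## 2. Prediction error variance

The coefficient matrix

```
C = [ X'X      X'Z          ]
    [ Z'X      Z'Z + K⁻¹ λ  ]
```

is inverted densely (Cholesky). `PEV = C²² σ²ₑ` and `Var(b̂) = C¹¹ σ²ₑ`.
An equivalent *absorbed* route computes `PEV = (Z'MZ + K⁻¹λ)⁻¹ σ²ₑ` with
`M = I − X(X'X)⁻X'`; the generalized inverse is used for `(X'X)⁻` so the
absorption also covers rank-deficient fixed-effect blocks. *Open question
resolved:* the projector uses the pseudo-inverse rather than assuming the
full-rank normal equations. The two routes agree to ~1e-16 on all tested
systems (an acceptance test). Dense inversion is exact but O(n³); a
warning is emitted above 10,000 equations.

## 3. Connectedness statistics

For units `i, j` with PEV block means `v_ij` (see convention below):

- **PEVD** `= v_ii + v_jj − 2 v_ij` — prediction error variance of the unit
  difference; small is good.
- **CD** `= 1 − PEVD / (σ²ᵤ (k_ii + k_jj − 2 k_ij))` where `k` are the
  matching block means of `K` — PEVD scaled by the genetic variability of the
  contrast; large is good.
- **r** `= v_ij / √(v_ii v_jj)` — prediction error correlation; large is good.

Summaries:

- **IdAve**: pairwise statistics between individuals, averaged over all
  cross-unit pairs. For CD the individual-average form is the
  *ratio of sums* — the average PEVD divided by the average scaled genetic
  distance — not the average of pairwise CD values. The two differ whenever
  the denominator varies across pairs; the ratio-of-sums form is the one whose
  algebra extends consistently to the group-average and contrast forms.
- **GrpAve**: statistics computed from unit-block means of PEV (and of `K`
  for CD).
- **Contrast**: `x'PEVx` (and relatives) for a zero-sum contrast vector `x`;
  the unit-pair contrast puts `1/nᵢ` on unit `i` and `−1/nⱼ` on unit `j`.
  *Open question resolved:* the contrast form of r is evaluated literally as
  `x'PEVx` quantities (the printed algebra), not re-normalized per individual.

**Block-mean convention.** All block means are *diagonal-inclusive*: the
within-unit mean `v_ii` averages all `nᵢ²` entries of the block, diagonal
included. Under this convention the unit-pair contrast and the group average
are *identical by algebra* (`x'PEVx` expands to exactly
`v_ii + v_jj − 2 v_ij`), which the tests verify to 1e-16 across seeds. The
same convention makes the exactly corrected VE statistics equal the PEV group
averages (§4). Excluding the diagonal would break both identities.

**Overall summary.** The overall connectedness of a design is the unweighted
mean of the off-diagonal upper triangle of the unit-pair matrix. *Open
question resolved:* no weighting by unit size is applied — each unit pair
counts once regardless of how many animals it contains.

**Undefined pairs.** When a denominator falls below `DENOM_TOL = 1e-10`
(e.g. r between units with zero prediction error covariance structure, or CD
when the genetic distance between units vanishes), the pair is reported as
NaN — never silently as 0, since 0 is a meaningful value ("fully
disconnected") for r. Overall summaries use NaN-aware means. Diagonals are 1
for CD and r, 0 for PEVD and VED.

## 4. Variance-of-unit-effects (VE) statistics

VE statistics approximate PEV-based ones using only the fixed-effect block
`Var(b̂)`, at three correction levels:

- **Correction 0**: the unit block of `Var(b̂)` as-is. Overstates PEV block
  means by exactly `σ²ₑ/nᵢ` on the diagonal (the record-noise term).
- **Correction 1**: subtracts `σ²ₑ (X₁'X₁)⁻¹`. For *unit-only* models this
  equals the diagonal-inclusive PEV block means exactly; it is rejected with
  `CorrectionLevelError` when other fixed effects are present (it would be
  silently wrong there).
- **Correction 2**: the four-term correction that additionally accounts for
  the covariance between unit estimates and the other fixed effects:
  `VE₂ = V₁₁ − σ²ₑ diag(1/nᵢ) + N V₂₂ N' + N V₂₁ + V₁₂ N'` with
  `N = (X₁'X₁)⁻¹ X₁'X₂`. This equals the PEV block means exactly whenever
  extra fixed effects are present, and is rejected for unit-only models
  (where it degenerates). The identity was verified algebraically
  (partitioned-inverse expansion shows VE₂ = Q·PEV·Q′ with Q the unit-wise
  averaging map) before implementation and is checked numerically to 1e-16 in
  the acceptance tests.

`VED`, `CDVED`, `CR` then apply the PEVD/CD/r formulas to the corrected VE
matrix; with the exact correction they reproduce `pevd_grpave`, `cd_grpave`
and `r_grpave` to machine precision (the "bridge" acceptance test).

## 5. Data simulator

The simulator exists to generate data with realistic connectedness structure
for testing and demonstration; it emulates the scale of a typical simulated
livestock example but is not a full breeding-program simulator.

Pipeline: non-overlapping generational pedigree (sires drawn from previous
generation's males, dams from its females) → gene dropping of founder
haplotypes through the pedigree with Haldane recombination (Poisson crossover
counts per chromosome, uniform positions) → management units assigned by
k-medoids clustering of the relationship matrix with dissimilarity
`D = 1 − K/max(K)`, so units align with family structure → phenotypes
`y = sex_effect·1[male] + u + e` with `u ~ N(0, K h²)` drawn via Cholesky and
`e ~ N(0, I(1−h²))`.

k-medoids uses a compact PAM (greedy BUILD initialization plus alternating
swap refinement) implemented in `simdata.py`; no suitable pre-installed
library provides it.

### Defaults and rationale

| parameter | default | rationale |
|---|---|---|
| `n_founders` | 100 | founder pool for a 2,500-animal example |
| `generations` | 5 | 100 founders + 4 × 600 offspring = 2,500 individuals |
| `offspring_per_generation` | 600 | as above |
| `n_markers` | 10,000 | dense enough that `G` ≈ pedigree expectations |
| `n_chromosomes` | 29 | cattle-like karyotype |
| `chrom_length_cm` | 100 | ~1 Morgan per chromosome, typical for livestock |
| `h2` | 0.6 | moderately high heritability; phenotypic variance 1 |
| `sex_effect` | 0.5 | a half-phenotypic-SD fixed effect — large enough that ignoring it visibly biases results, small enough not to dominate (chosen once, not stated by any source) |
| `founder_freq_range` | U(0.05, 0.95) | segregating founders while avoiding near-fixed markers that would be dropped (chosen once) |
| `n_units` | 5 | enough unit pairs (10) for meaningful overall summaries (chosen once) |
| `seed` | 42 | arbitrary fixed default for reproducibility |

The two-unit linked design (`two_unit_design`) builds two families of
4 sires × 8 dams × 2 offspring each and then grafts `n_links` across-unit
sire matings; `n_links = 0` yields an exactly block-diagonal `A`, for which
the prediction errors of the two units are exactly uncorrelated (r = 0 to
machine precision, since the mixed model equations decouple).

### Simulator validation

- Gene dropping is validated against the tabular `A`: twice the
  marker/allele-IBD kinship from 20,000 dropping replicates matches `A`
  within 0.02 (an acceptance test), and on a zero-length chromosome the
  transmitted alleles at different markers are perfectly correlated.
- Phenotypes: `Var(u)` lands in a sampling band around `h²`; the regression
  of `y` on `u` has unit slope across replicates; the across-replicate
  covariance of `u` matches `K σ²ᵤ`.

## 6. Numerical conventions (summary)

| constant | value | used for |
|---|---|---|
| `DEFAULT_EPSILON` | 1e-8 | ridge added to `K` when Cholesky fails |
| `DENOM_TOL` | 1e-10 | below this, a statistic's denominator is treated as zero → NaN |
| contrast zero-sum tolerance | 1e-12 | `ContrastVector` validation |
| missing-parent code | `"0"` (or empty) | pedigree files |

Undefined values propagate as NaN (written as `NA` in CSV output), never as 0.

## 7. Problem sizes and runtime

Dense MME inversion is O((p+n)³). Sizes used in tests and acceptance runs:
identity checks at ~60 individuals (milliseconds), Monte-Carlo calibration at
40 individuals × 2,000 replicates (~1 s), the default 2,500-animal /
10,000-marker example builds and solves in ~5 s per kernel. The full test
suite runs in well under five minutes; `scripts/acceptance.py` in ~10 s.

## 8. Known limitations

- **Single trait, one record per individual, known variance components.**
  Repeated records, multiple traits, and REML estimation are out of scope.
- **Dense algebra throughout.** Practical to roughly 10,000 individuals;
  no sparse-inverse or iterative approximations are implemented.
- **CD is not monotone in link density everywhere.** CD penalizes genetic
  similarity between units in its denominator, so at high across-unit link
  density CD can *decrease* while r and PEVD keep improving. The
  design-response acceptance test uses the sparse-link regime (0–8 links)
  where all three statistics move monotonically; interpret CD accordingly.
- **With unit as a fixed effect, CD saturates below 1.** Each breeding value
  is confounded with its unit mean, so even with abundant data and λ → 0,
  within-unit CD tends to `1 − 1/nᵢ`, not 1.
- **Monte-Carlo calibration at 2,000 replicates is noisy by construction.**
  The MC standard error of a 2,000-replicate variance estimate is
  `√(2/1999) ≈ 3.2%`, so the maximum relative deviation over 40 individuals
  is ~7% in expectation and a 5% cap on it fails for most seeds (measured
  pass rate ≈ 3%). The estimator is unbiased: the same maximum deviation
  falls to ~2.9% at 20,000 replicates and ~1.0% at 200,000. The acceptance
  test keeps the stated 2,000-replicate setting (and is expected to be red);
  the property test in `tests/test_mme.py` uses 20,000 replicates, where the
  5% band has adequate statistical power.
- **Simulator scope.** Non-overlapping generations, random mating within the
  allowed parent pools, no selection, no mutation, Haldane (no interference)
  recombination, biallelic markers only.
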