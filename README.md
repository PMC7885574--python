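# connekt

Genetic connectedness analysis for livestock genetic evaluation.

When animals are raised in separate management units (herds, flocks, stations),
comparing their estimated breeding values across units is only reliable if the
units are *genetically connected* — linked through common ancestors or shared
genotyped relatives. `connekt` quantifies that connectedness. It builds a
pedigree or genomic relationship matrix, solves Henderson's mixed model
equations, and reports prediction-error–based and variance-of-estimates–based
connectedness statistics between every pair of units, so that breeders and
analysts can judge whether across-unit comparisons of breeding values are
trustworthy.

## The model

The linear mixed model is

```
y = Xb + Zu + e,    u ~ N(0, K σ²ᵤ),    e ~ N(0, I σ²ₑ)
```

where `b` holds fixed effects (management unit, plus optional covariates such
as sex), `u` the additive genetic values, and `K` is either the numerator
relationship matrix `A` (from pedigree, tabular method) or the genomic
relationship matrix `G` (VanRaden method 1). The coefficient matrix of the
mixed model equations is

```
C = [ X'X      X'Z          ]        λ = σ²ₑ / σ²ᵤ
    [ Z'X      Z'Z + K⁻¹ λ  ]
```

and its inverse blocks give the prediction error variance `PEV = C²² σ²ₑ` and
the variance of estimated unit effects `Var(b̂) = C¹¹ σ²ₑ`.

Connectedness statistics:

| family | statistic | meaning |
|---|---|---|
| PEV-based | **PEVD** | prediction error variance of the difference between units (smaller = better connected) |
| PEV-based | **CD** | coefficient of determination — PEVD scaled by the genetic variability of the contrast |
| PEV-based | **r** | prediction error correlation ("flock connectedness") |
| VE-based | **VED**, **CDVED**, **CR** | approximations using only `Var(b̂)`, with fixed-effect correction levels 0, 1, 2 |

PEV-based statistics come in three summaries — individual average (`IdAve`),
group average (`GrpAve`), and unit contrasts (`Contrast`). With the
diagonal-inclusive block-mean convention used here, `GrpAve` and `Contrast`
coincide exactly, and the exactly corrected VE statistics (correction 1 for
unit-only models, correction 2 with extra fixed effects) reproduce the PEV
group averages to machine precision. See [docs/methods.md](docs/methods.md)
for derivations, conventions, and defaults.

## Worked example

### Command line

Simulate a data set (20 founders, 2 further generations of 40, 3 units):

```sh
$ cat config.json
{"n_founders": 20, "generations": 3, "offspring_per_generation": 40,
 "n_markers": 500, "n_chromosomes": 5, "n_units": 3}
$ connekt simulate --config config.json --seed 7 --out data
wrote 100 individuals, 500 markers to data
```

Compute group-average CD between units from the pedigree:

```sh
$ connekt compute --ped data/pedigree.csv --pheno data/phenotypes.csv \
    --h2 0.6 --metric CD --summary GrpAve --out out/demo
CD_GrpAve: overall = 0.414296
$ cat out/demo_CD_GrpAve.csv
unit,u1,u2,u3
u1,1.0,0.43067946569302906,0.42375358757380455
u2,0.43067946569302906,1.0,0.3884552008828863
u3,0.42375358757380455,0.3884552008828863,1.0
```

Swap `--ped` for `--geno data/genotypes.txt` to use the genomic relationship
matrix instead; pass `--all` to emit every valid metric/summary/correction
combination at once, or `--contrast my_contrast.csv` for a custom zero-sum
contrast across units. A `.log` file next to the outputs records the defaults
in effect for the run.

### Python API

```python
import connekt as ck

cfg = ck.SimConfig(n_founders=20, generations=3, offspring_per_generation=40,
                   n_markers=500, n_chromosomes=5, n_units=3, seed=7)
data = ck.make_example(cfg)

vc = ck.VarianceComponents.from_h2(0.6)
Kinv, _ = ck.regularize_and_invert(data.A)
design = ck.build_design(data.phenotype_table(), data.A.individual_ids, ["sex"])
system = ck.build_mme(design, Kinv, vc)
store = ck.pev(system)

cd = ck.cd_grpave(store, data.A, vc)
print(cd.matrix.round(4))
print("overall CD:", round(cd.overall, 4))
print("r(u1, u2): ", round(ck.r_grpave(store).pair("u1", "u2"), 4))

ve = ck.ve2(system)              # exact fixed-effect correction
print("CDVED(2) == CD_GrpAve:",
      bool(abs(ck.cdved(ve, data.A, vc, store.unit_index).matrix
               - cd.matrix).max() < 1e-12))
```

Output:

```
[[1.     0.4286 0.4234]
 [0.4286 1.     0.3879]
 [0.4234 0.3879 1.    ]]
overall CD: 0.4133
r(u1, u2):  0.3927
CDVED(2) == CD_GrpAve: True
```

(The API example differs slightly from the CLI run above because it includes a
sex fixed effect.)

## Package layout

- `connekt.relmat` — pedigree validation, numerator relationship matrix `A`
  (tabular method), genomic relationship matrix `G` (VanRaden method 1),
  regularized inversion.
- `connekt.mme` — design matrices with identifiability checks, mixed model
  equations, PEV via the full inverse or the absorbed (fixed-effects-projected)
  system.
- `connekt.vestat` — variance of estimated unit effects with correction
  levels 0/1/2, PEV block means.
- `connekt.connect` — PEVD / CD / r with IdAve / GrpAve / Contrast summaries;
  VED / CDVED / CR; overall summaries.
- `connekt.simdata` — pedigree simulator, gene-dropping genotype simulator
  with recombination, k-medoids unit assignment, phenotype simulator.
- `connekt.io` / `connekt.cli` — file formats, pipeline runner, `connekt`
  command line.

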