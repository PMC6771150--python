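# arowana

Simulation-based demographic inference for two-basin SNP datasets,
built around the silver arowana (*Osteoglossum bicirrhosum*) study
system: did the Tocantins-Araguaia (TAb) population originate by
vicariance, by colonization from the Amazon basin (AMb), or is the
species panmictic across basins?

The package is aimed at population geneticists working with
reduced-representation SNP matrices (DArTseq and similar) from two
demes. It provides:

- **`arowana.simulate`** — a Hudson-style coalescent simulator for four
  demographic scenarios (panmixia; vicariance; colonization in either
  direction with a founder bottleneck of relative size θrF-A growing
  exponentially to θrC-A), under uniform priors on Ne, divergence time
  DT, generation time G and the two size ratios, with θ = 4·Ne·μ·G and
  CT = DT/(4·Ne·G). By default every SNP rides its own genealogy (one
  SNP per locus, as in DArT data); a linked single-genealogy mode and
  ms-style text I/O are included.
- **`arowana.encode`** — deterministic image encoding of haplotype or
  diploid genotype matrices (deme-blocked, lexicographically sorted
  rows, zero-padding, {0, ½, 1} diploid code).
- **`arowana.netinfer`** — a compact convolutional network implemented
  directly on NumPy (1-D convolutions along the SNP axis with
  individuals as channels, Adam, dropout, seeded and reproducible) for
  4-way scenario classification and 4-parameter regression, plus
  RMSE/Spearman scoring and bootstrap parameter intervals.
- **`arowana.popstats`** — diversity table (A, H_O, unbiased H_E,
  G_IS), pairwise Weir–Cockerham F_ST, PCoA on 1−IBS distances, and
  readers for VCF, DArT two-row CSV and plain 0/1/2 matrix CSV.
- **`arowana.synthdata`** — synthetic stand-ins for the undeposited
  empirical data (hierarchical Balding–Nichols generator with F_ST
  targets, and a coalescent-to-genotype bridge for pseudo-empirical
  self-consistency experiments).
- **`arowana.cli` / `arowana.pipeline`** — a `click` command line
  (`arowana all|simulate|encode|train|select|estimate|stats|synth`)
  orchestrating simulate → encode → train → select → estimate with full
  seed provenance.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

Run the pipeline on a pseudo-empirical dataset — simulated under the
AMb→TAb colonization scenario at mid-prior parameter values (Ne =
505,000; DT = 1,000,000 yr; founder ratio 0.055; growth ratio 0.55) —
at a quick demonstration scale (800 training simulations per scenario,
10 epochs; a full run uses the `desk` or `paper` preset defaults):

```bash
cat > demo.yaml <<'YAML'
n_per_model: 800
test_n: 100
estimation_train_n: 6000
estimation_test_n: 1000
n_bootstrap: 100
YAML
arowana all --config demo.yaml --seed 7 --scale desk --out report.json
```

which logs the stages to stderr and prints:

```
selected model: 3 (posteriors ['0.005', '0.283', '0.478', '0.235'])
report written to report.json
```

Model 3 — colonization of TAb from AMb, the scenario that generated the
data — gets the highest posterior even at this small training scale.
The report JSON carries the rest: the held-out confusion matrix of the
scenario classifier, parameter medians with 95% column-bootstrap
intervals in natural units, and the diversity/F_ST summary of the input
matrix. From this run:

| parameter | truth | median | 95% interval |
|---|---|---|---|
| Ne (diploids) | 505,000 | 516,839 | 453,627 – 566,808 |
| DT (years) | 1,000,000 | 1,003,455 | 862,318 – 1,095,179 |
| founder ratio | 0.055 | 0.051 | 0.0499 – 0.0539 |
| growth ratio | 0.55 | 0.58 | 0.525 – 0.619 |

Ne, DT and the growth ratio are recovered well, with intervals covering
the generating values; the founder ratio — the hardest parameter — has
a point estimate close to truth but an overconfident interval that
narrowly misses it (see the limitations section of `docs/methods.md`).

The statistics suite alone, on a synthetic silver-arowana-like dataset:

```bash
arowana synth --preset bicirrhosum-like --seed 1 --out-dir data/
arowana stats data/genotypes.csv --format matrix-csv \
        --popmap data/popmap.tsv --out-dir stats/
```

writes `diversity.csv` (per-locality A, Ho, He, Gis), `fst.csv`
(pairwise Weir–Cockerham θ; strong between-basin, weak within-basin
differentiation) and `pcoa.csv` (coordinates separating the basins
along axis 1).

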