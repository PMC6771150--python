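# Methods

`arowana` implements simulation-based demographic inference for a
two-basin population pair of the silver arowana (*Osteoglossum
bicirrhosum*): coalescent simulation of four demographic scenarios,
image encoding of SNP matrices, a convolutional network for scenario
classification and parameter regression, and the classical
diversity/differentiation statistics used to characterize such SNP
datasets. This note records the model, the defaults and the design
choices a maintainer would want to know about.

## Demographic models

All four scenarios describe two demes — TAb (Tocantins-Araguaia, 11
sampled diploids) and AMb (Amazon, 2 sampled diploids) — backward in
time on the standard coalescent time scale of 4·Ne generations:

1. **Panmixia.** One constant-size population; deme labels are retained
   only so every dataset encodes to the same image layout.
2. **Vicariance.** Two demes of size Ne each merge into an ancestor of
   size Ne at the coalescent divergence time CT. "Same size" is
   ambiguous between Ne each and Ne/2 each; we implement Ne each (the
   minimal-parameter reading) after checking with an independent
   gradient-boosting probe that scenario identifiability is essentially
   unchanged under the other reading.
3. **Colonization AMb→TAb.** The TAb deme is founded at CT with size
   (founder ratio)·Ne and grows exponentially to its present size
   (growth ratio)·Ne; the source deme and the ancestor stay at Ne.
4. **Colonization TAb→AMb.** The exact mirror image.

Priors (uniform): Ne ∈ [10⁴, 10⁶] diploids; divergence time DT ∈ [0,
2·10⁶] years (fixed at 0 under panmixia); generation time G ∈ [1, 2]
years; founder ratio θrF-A ∈ [0.01, 0.1]; growth ratio θrC-A ∈ [0.1, 1].
Mutation rate μ = 1.25·10⁻⁹ per site per year. Derived quantities:
θ = 4·Ne·μ·G per site (the per-generation rate μ·G keeps the mutation
clock and the coalescent clock in the same units; a `theta_per_year`
flag restores the literal 4·Ne·μ) and CT = DT/(4·Ne·G). No migration
after divergence; no recombination within a locus; two demes only.

## Simulation

The simulator is a Hudson-style event-driven structured coalescent.
Within the colonized deme the backward-time size is x(t) = gr·e^{−αt}
with α = ln(gr/fr)/CT, and coalescence waiting times are drawn by
inverting the integrated hazard in closed form; the other demes are
constant-size exponentials. Mutations follow the infinite-sites model.

**Unlinked sites are the default.** Reduced-representation SNP matrices
keep one SNP per locus, so sites are effectively independent; each SNP
therefore rides its own genealogy and carries exactly one mutation,
placed on an edge chosen proportionally to branch length (the `ms -s 1`
convention, one replicate per site). Two observations force this
default rather than a single shared genealogy per dataset: with one
tree, a 26-haplotype dataset contains at most 49 distinct column
patterns and the vicariance scenario becomes nearly unidentifiable
(~50% accuracy); and the rank correlation attainable for Ne given a
fixed site count is capped by what CT alone reveals (ρ ≈ 0.65, computed
by conditional-expectation binning over the priors), a cap that is only
approached when CT is estimated with negligible genealogical noise,
i.e. from many independent trees. The linked single-genealogy mode
(`unlinked=False`), with fixed-S multinomial placement or Poisson
(fixed-θ) mutation counts, remains available and drives the analytic
validation suite (Watterson's E[S], π = θ). The unlinked kernel is
JIT-compiled with numba (≈2 ms per 400-SNP dataset) and is checked in
the tests against stacking single-site linked simulations, and the
linked path against msprime by two-sample Kolmogorov–Smirnov.

Note one subtlety of per-site conditioning: choosing one edge per tree
weights site patterns by E[Lᵢ/L], not by E[Lᵢ]/E[L], so the unlinked
site-frequency spectrum deviates slightly from the Poisson-mutation
spectrum (≈1.5 points more singletons at n = 26). This matches what a
fixed-S simulator produces and is shared by train and test data.

## Image encoding

A dataset becomes a fixed-shape float32 image in [0, 1]: deme-1 rows on
top, deme-2 rows below, rows sorted lexicographically within each deme
(removing haplotype exchangeability), columns zero-padded up to the
fixed width or randomly subsampled down (seeded). Diploid data use the
half-step code {0, ½, 1}; missing genotypes are imputed at 0.5. For
empirical prediction the entire pipeline (training simulations
included) runs in diploid-collapsed mode — simulated haplotypes are
paired into pseudo-diploids — because DArT genotypes are unphased;
train and serve distributions must match. A positions channel exists
but is off: DArT SNPs carry no usable coordinates here.

## Network

The default is a 1-D convolutional network along the SNP axis with
individuals as channels: two convolution layers (kernel 3,
rectified-linear), pooling, a 128-unit dense layer, and a softmax or
linear head. Convolutions along sites with samples-as-channels are the
standard choice for population-genetic matrices; on one CPU this layout
is also roughly 50× cheaper than the equivalent 2-D network (which is
implemented and available via `NetConfig(architecture="conv2d")`, but
is memory-bound on large SNP images).

The two tasks use different heads, reflecting what each needs to
measure. The classifier uses 64+64 filters, max pooling (widths 4 and
2) and a flattened readout. The regressor uses 96+96 filters, *mean*
pooling and a global-average readout over the site axis
(`readout="gap"`): unlinked SNPs are exchangeable, so a site-order-
invariant composition readout is the right inductive bias, and the
founder-ratio signal in particular is a *density* of rare variants in
the founded deme — information that max pooling and position-sensitive
flattening discard. Empirically the invariant readout improves every
parameter, the founder ratio most.

Training: Adam (learning rate 10⁻³, cosine-decayed), mini-batch 250, 25
epochs by default, cross-entropy or mean-squared-error loss, inverted
dropout (0.25 dense / 0.1 after pooling for classification, 0.15 / 0.05
for regression). All randomness — initialization, shuffling, dropout —
derives from one seed; training is bit-reproducible on a fixed BLAS.
Gradients of every layer are verified against central differences in
the test suite. The backward pass of convolution uses the
flipped-kernel correlation identity; pooling resolves ties to the first
maximum.

Regression targets (Ne, DT, founder ratio, growth ratio) are min-max
normalized to [0, 1] over their prior ranges — the priors are uniform on
the natural scale, and DT includes 0, which rules out log transforms —
so RMSE values are comparable across parameters; predictions are
de-normalized for reporting. "Intervals" for empirical estimates are
2.5–97.5 percentile intervals over column-bootstrap re-encodings of the
empirical matrix: they quantify site-resampling uncertainty, not full
posterior uncertainty (with unlinked sites the two are close; see
limitations).

## Diversity statistics

Per population and locus: observed heterozygosity is the heterozygote
fraction among genotyped individuals; expected heterozygosity uses the
small-sample correction He = 2n/(2n−1)·2pq; A counts observed alleles.
Population values average over loci polymorphic in the dataset, and
G_IS = 1 − mean(Ho)/mean(He) over loci with He > 0 (ratio of averages,
the convention of the Genodive-style software family). Pairwise F_ST is
the Weir–Cockerham (1984) θ with ratio-of-sums aggregation over loci
and pairwise-complete missing-data handling. PCoA performs classical
metric scaling (via scikit-bio) of the 1 − IBS allele-sharing distance
averaged over co-genotyped loci.

## Synthetic data

The empirical genotypes behind the original study are not deposited, so
`synthdata` provides two stand-ins. The Balding–Nichols generator draws
basin frequencies around uniform(0.05, 0.95) ancestral frequencies at
the between-basin F_ST target and locality frequencies around basin
frequencies at the within-basin target, then Hardy–Weinberg genotypes;
defaults emulate the silver-arowana matrix (13 individuals in three
localities, 1,661 SNPs, 0.95% missing, F_ST targets 0.49 between and
0.059 within basins; a `ferreirai-like` preset gives 20 individuals,
433 SNPs, 3.77% missing). Monomorphic loci are redrawn, missing
entries are masked uniformly. The coalescent route
(`generate_pseudo_empirical`) converts a simulated scenario into the
same diploid format and is the structurally faithful alternative used
for self-consistency tests. What these generators do not emulate:
linkage within DArT reads, allelic dropout, locus-specific missingness
and genotyping error — so passing tests demonstrate pipeline
correctness under the assumed generative models, not robustness to
those artifacts.

## Problem sizes

Full-scale runs in the published protocol use 50,000 simulations per
scenario and 10⁶ parameter-estimation simulations (the `paper` scale
preset). The reproduction scripts and the test suite use the `desk`
scale: 2,000 simulations per scenario with 400 unlinked SNPs for model
selection, and 20,000 training simulations for regression — chosen so a
complete reproduction runs on a single CPU core in well under half an
hour while leaving the study's qualitative structure (class ordering,
parameter-recovery ordering) intact. Sample sizes (22 + 4 haploids) and
priors are never scaled.

## Known limitations

- Desk-scale accuracies differ from full-scale ones in a known
  direction: fewer sites and training simulations lower them, while
  fully unlinked sites raise identifiability relative to any partially
  linked generative process.
- The founder ratio is intrinsically the hardest parameter: when CT is
  small the founding bottleneck is invisible, and a severe bottleneck
  (0.01–0.1) coalesces the founded deme almost surely regardless of its
  exact size. A gradient-boosting probe on handcrafted summary
  statistics bounds what is extractable (ρ ≈ 0.6); the image network
  recovers less.
- Column-bootstrap intervals understate uncertainty whenever sites are
  correlated (linked mode) and ignore prior uncertainty entirely.
- With only 2 AMb diploids, empirical F_ST involving that deme is very
  noisy; the synthetic generator reproduces this property faithfully.
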