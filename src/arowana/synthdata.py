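"""Synthetic stand-ins for the (undeposited) empirical SNP datasets.

Two generators are provided.  ``generate_dataset`` draws structured
genotypes from a hierarchical Balding-Nichols model: locus frequencies
diverge from a shared ancestral frequency at the between-basin F_ST
target, and locality frequencies diverge from their basin frequency at
the within-basin target, with Hardy-Weinberg genotypes inside each
locality.  Defaults emulate the silver-arowana dataset: 13 individuals
in three localities (Luciara 6 + Loroti 5 in the Tocantins-Araguaia
basin, Catalao 2 in the Amazon basin), 1661 biallelic SNPs, 0.95%
missing entries, between-basin F_ST ~ 0.49 and within-basin ~ 0.059.

``generate_pseudo_empirical`` instead converts a coalescent simulation
into empirical-format diploid genotypes, which is the structurally
faithful route used for end-to-end self-consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .popstats import MISSING, GenotypeMatrix
from .simulate import DatasetShape, HaplotypeDataset, ScenarioParams, simulate_dataset

__all__ = [
    "SynthConfig",
    "generate_dataset",
    "generate_pseudo_empirical",
    "PRESETS",
    "generate_preset",
    "write_vcf",
    "write_dart_two_row",
    "write_popmap",
]


@dataclass(frozen=True)
class SynthConfig:
    """Targets for the Balding-Nichols genotype generator."""

    n_per_pop: dict[str, int] = field(
        default_factory=lambda: {"TAb-Luciara": 6, "TAb-Loroti": 5, "AMb-Catalao": 2}
    )
    basin_of: dict[str, str] = field(
        default_factory=lambda: {"TAb-Luciara": "TAb", "TAb-Loroti": "TAb", "AMb-Catalao": "AMb"}
    )
    n_loci: int = 1661
    fst_between_basins: float = 0.49
    fst_within_basin: float = 0.059
    missing_rate: float = 0.0095
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_pop or any(n < 1 for n in self.n_per_pop.values()):
            raise ValueError("every population needs at least one diploid")
        if set(self.n_per_pop) != set(self.basin_of):
            raise ValueError("basin_of must cover exactly the populations of n_per_pop")
        for name in ("fst_between_basins", "fst_within_basin"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


def _balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Daughter frequencies around ``p`` with divergence ``fst``."""
    if fst == 0.0:
        return p.copy()
    lam = (1.0 - fst) / fst
    return rng.beta(np.maximum(p * lam, 1e-12), np.maximum((1.0 - p) * lam, 1e-12))


def generate_dataset(config: SynthConfig) -> GenotypeMatrix:
    """Draw one empirical-like genotype matrix; deterministic per seed.

    Loci monomorphic across the whole sample are redrawn so the output
    contains ``n_loci`` polymorphic SNPs, as in a filtered SNP matrix.
    """
    rng = np.random.default_rng(config.rng_seed)
    pops = list(config.n_per_pop)
    basins = sorted({config.basin_of[p] for p in pops})
    counts = [config.n_per_pop[p] for p in pops]
    n_ind = sum(counts)

    filled = 0
    geno = np.empty((n_ind, config.n_loci), dtype=np.int8)
    while filled < config.n_loci:
        m = max(config.n_loci - filled, 64)
        p0 = rng.uniform(*config.ancestral_freq_range, size=m)
        p_basin = {b: _balding_nichols(p0, config.fst_between_basins, rng) for b in basins}
        block = []
        for pop, n in zip(pops, counts):
            p_loc = _balding_nichols(p_basin[config.basin_of[pop]],
                                     config.fst_within_basin, rng)
            block.append(rng.binomial(2, p_loc, size=(n, m)).astype(np.int8))
        block = np.concatenate(block, axis=0)
        alt = block.sum(axis=0)
        keep = (alt > 0) & (alt < 2 * n_ind)
        k = min(int(keep.sum()), config.n_loci - filled)
        geno[:, filled: filled + k] = block[:, keep][:, :k]
        filled += k

    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    individuals = [f"{pop}_{i + 1}" for pop, n in zip(pops, counts) for i in range(n)]
    populations = [pop for pop, n in zip(pops, counts) for _ in range(n)]
    return GenotypeMatrix(geno, individuals, populations)


def generate_pseudo_empirical(
    scenario: ScenarioParams,
    shape: DatasetShape,
    missing_rate: float = 0.0095,
    rng_seed: int | np.random.Generator = 0,
    **simulate_kwargs,
) -> GenotypeMatrix:
    """Coalescent-simulated data recoded into the empirical diploid format.

    Haplotypes are paired within each deme into unphased 0/1/2 diploids
    and missing entries are masked uniformly; the result passes through
    the same readers/encoders as real data.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    ds = simulate_dataset(scenario, shape, rng, **simulate_kwargs)
    return haplotypes_to_genotypes(ds, missing_rate, rng)


def haplotypes_to_genotypes(
    ds: HaplotypeDataset,
    missing_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> GenotypeMatrix:
    """Pair consecutive within-deme haplotypes into diploid genotypes."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    genos, individuals, populations = [], [], []
    for deme, name in ((0, "TAb"), (1, "AMb")):
        block = ds.matrix[ds.deme_labels == deme]
        if block.shape[0] % 2:
            raise ValueError(f"deme {name}: odd haploid count cannot be paired into diploids")
        dip = block[0::2] + block[1::2]
        genos.append(dip.astype(np.int8))
        individuals.extend(f"{name}_{i + 1}" for i in range(dip.shape[0]))
        populations.extend([name] * dip.shape[0])
    geno = np.concatenate(genos, axis=0)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING
    return GenotypeMatrix(geno, individuals, populations)


# ---------------------------------------------------------------------------
# named presets and format writers
# ---------------------------------------------------------------------------

PRESETS: dict[str, SynthConfig] = {
    # silver arowana: 13 diploids, 1661 SNPs, 0.95% missing, strong
    # between-basin and weak within-basin differentiation
    "bicirrhosum-like": SynthConfig(),
    # black arowana: one locality, 20 diploids, 433 SNPs, 3.77% missing
    "ferreirai-like": SynthConfig(
        n_per_pop={"AMb-Taruma": 20},
        basin_of={"AMb-Taruma": "AMb"},
        n_loci=433,
        fst_between_basins=0.0,
        fst_within_basin=0.0,
        missing_rate=0.0377,
    ),
}


def generate_preset(name: str, rng_seed: int = 0) -> GenotypeMatrix:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return generate_dataset(SynthConfig(**{**cfg.__dict__, "rng_seed": rng_seed}))


def write_popmap(gm: GenotypeMatrix, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{i}\t{p}\n" for i, p in zip(gm.individuals, gm.populations))
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal biallelic VCF v4.2 with GT-only genotypes."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.individuals),
    ]
    for j in range(gm.n_loci):
        gts = "\t".join(code[int(g)] for g in gm.genotypes[:, j])
        lines.append(f"1\t{j + 1}\tL{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dart_two_row(gm: GenotypeMatrix, path: str | Path) -> None:
    """DArT two-row CSV: per locus one row per allele, 1/0 presence."""
    lines = ["locus,allele," + ",".join(gm.individuals)]
    for j in range(gm.n_loci):
        g = gm.genotypes[:, j]
        ref = ["-" if v == MISSING else str(int(v < 2)) for v in g]
        alt = ["-" if v == MISSING else str(int(v > 0)) for v in g]
        lines.append(f"L{j},ref," + ",".join(ref))
        lines.append(f"L{j},alt," + ",".join(alt))
    Path(path).write_text("\n".join(lines) + "\n")
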