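"""Hudson-style coalescent simulation of two-basin demographic scenarios.

Four demographic models for a pair of river-basin demes (TAb =
Tocantins-Araguaia, AMb = Amazon):

1. panmixia — a single constant-size population;
2. vicariance — the population splits into two equal-size demes at a
   divergence time DT, with no founder bottleneck;
3. colonization of TAb from AMb — the TAb deme is founded at DT with a
   reduced size (founder ratio x Ne) and grows exponentially to its
   contemporary size (growth ratio x Ne);
4. the mirror image, colonization of AMb from TAb.

Parameters are drawn from uniform priors (effective size Ne, divergence
time DT in years, generation time G in years, founder and growth size
ratios) with a fixed per-site mutation rate mu per year.  Derived
quantities follow the standard coalescent scalings: the population
mutation rate theta = 4*Ne*mu_gen per site and the coalescent divergence
time CT = DT / (4*Ne*G) in units of 4*Ne generations.

Simulation is backward in time on a single non-recombining genealogy per
dataset; mutations are placed under the infinite-sites model, either with
a fixed number of segregating sites (multinomial placement proportional
to branch length, as with ``ms -s``) or with a Poisson-distributed count
at a given per-locus theta (as with ``ms -t``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import numpy as np

__all__ = [
    "PriorConfig",
    "ScenarioParams",
    "DatasetShape",
    "HaplotypeDataset",
    "MODEL_IDS",
    "draw_priors",
    "simulate_dataset",
    "simulate_batch",
    "write_ms_text",
    "read_ms_text",
]

MODEL_IDS = (1, 2, 3, 4)

MODEL_NAMES = {
    1: "panmixia",
    2: "vicariance",
    3: "colonization AMb->TAb",
    4: "colonization TAb->AMb",
}


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PriorConfig:
    """Uniform prior ranges for the demographic parameters.

    Units: ``ne_range`` in diploid individuals, ``dt_range`` in years,
    ``g_range`` in years per generation, ``mu`` in mutations per site per
    year; the two ratio ranges are dimensionless.

    ``theta_per_year`` switches theta to the literal 4*Ne*mu (per year)
    reading instead of the generation-consistent 4*Ne*mu*G.
    """

    ne_range: tuple[float, float] = (10_000.0, 1_000_000.0)
    dt_range: tuple[float, float] = (0.0, 2_000_000.0)
    g_range: tuple[float, float] = (1.0, 2.0)
    mu: float = 1.25e-9
    founder_ratio_range: tuple[float, float] = (0.01, 0.1)
    growth_ratio_range: tuple[float, float] = (0.1, 1.0)
    theta_per_year: bool = False

    def __post_init__(self) -> None:
        for name in ("ne_range", "dt_range", "g_range",
                     "founder_ratio_range", "growth_ratio_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} > upper bound {hi}")
        if self.ne_range[0] <= 0:
            raise ValueError("ne lower bound must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.founder_ratio_range[0] <= 0 or self.growth_ratio_range[0] <= 0:
            raise ValueError("ratio lower bounds must be positive")


@dataclass(frozen=True)
class ScenarioParams:
    """One draw from the priors plus the derived coalescent quantities."""

    model_id: int
    ne: float
    dt: float
    g: float
    theta: float            # per-site 4*Ne*mu_gen
    ct: float               # DT / (4*Ne*G), units of 4*Ne generations
    founder_ratio: float | None = None   # theta-rF-A, models 3/4 only
    growth_ratio: float | None = None    # theta-rC-A, models 3/4 only

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}")
        if self.ct < 0:
            raise ValueError("ct must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.model_id in (3, 4):
            if self.founder_ratio is None or self.growth_ratio is None:
                raise ValueError("models 3 and 4 require founder_ratio and growth_ratio")
        elif self.founder_ratio is not None or self.growth_ratio is not None:
            raise ValueError("founder/growth ratios only apply to models 3 and 4")


@dataclass(frozen=True)
class DatasetShape:
    """Sample sizes and site count matching the empirical SNP matrix."""

    n_dip_deme1: int = 11   # TAb diploids
    n_dip_deme2: int = 2    # AMb diploids
    n_sites: int = 1661

    def __post_init__(self) -> None:
        if self.n_dip_deme1 < 1 or self.n_dip_deme2 < 1:
            raise ValueError("each deme needs at least one diploid")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def n_hap_deme1(self) -> int:
        return 2 * self.n_dip_deme1

    @property
    def n_hap_deme2(self) -> int:
        return 2 * self.n_dip_deme2

    @property
    def n_haploids(self) -> int:
        return self.n_hap_deme1 + self.n_hap_deme2


@dataclass
class HaplotypeDataset:
    """Binary haplotype matrix with deme labels and relative positions.

    Rows are haploid sequences, columns segregating sites; every column is
    polymorphic.  ``deme_labels`` holds 0 (deme 1, TAb) or 1 (deme 2, AMb)
    per row; ``positions`` are sorted relative positions in [0, 1).
    """

    matrix: np.ndarray
    deme_labels: np.ndarray
    positions: np.ndarray
    params: ScenarioParams | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.deme_labels = np.asarray(self.deme_labels, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.deme_labels.shape[0] != self.matrix.shape[0]:
            raise ValueError("one deme label per haplotype row required")
        if self.positions.shape[0] != self.matrix.shape[1]:
            raise ValueError("one position per site required")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def nucleotide_diversity(self) -> float:
        """Mean pairwise difference summed over sites (per-locus pi)."""
        n = self.n_haplotypes
        if n < 2 or self.n_sites == 0:
            return 0.0
        p = self.matrix.mean(axis=0)
        return float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))

    def swap_demes(self) -> "HaplotypeDataset":
        """Return the dataset with deme identities exchanged (deme-2 rows first)."""
        order = np.argsort(self.deme_labels == 0, kind="stable")
        return HaplotypeDataset(
            matrix=self.matrix[order],
            deme_labels=1 - self.deme_labels[order],
            positions=self.positions.copy(),
            params=self.params,
        )


def derived_quantities(config: PriorConfig, ne: float, dt: float, g: float) -> tuple[float, float]:
    """Return (theta per site, ct) for a parameter draw.

    theta = 4*Ne*mu*G by default so that the mutation clock and the
    coalescent time scale both run in generations; ``theta_per_year``
    restores the literal 4*Ne*mu reading.  ct = DT / (4*Ne*G).
    """
    mu_gen = config.mu if config.theta_per_year else config.mu * g
    theta = 4.0 * ne * mu_gen
    ct = dt / (4.0 * ne * g)
    return theta, ct


def draw_priors(
    config: PriorConfig,
    model_id: int,
    rng_seed: int | np.random.Generator,
) -> ScenarioParams:
    """Draw one parameter set from the uniform priors for ``model_id``.

    Model 1 has no divergence, so DT (and hence CT) is fixed at zero;
    founder and growth ratios are drawn only for models 3 and 4.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    rng = _as_rng(rng_seed)
    ne = rng.uniform(*config.ne_range)
    g = rng.uniform(*config.g_range)
    dt = 0.0 if model_id == 1 else rng.uniform(*config.dt_range)
    theta, ct = derived_quantities(config, ne, dt, g)
    founder = growth = None
    if model_id in (3, 4):
        founder = rng.uniform(*config.founder_ratio_range)
        growth = rng.uniform(*config.growth_ratio_range)
    return ScenarioParams(
        model_id=model_id, ne=ne, dt=dt, g=g, theta=theta, ct=ct,
        founder_ratio=founder, growth_ratio=growth,
    )


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

def _exp_deme_waiting_time(
    k: int, t0: float, x_present: float, alpha: float, rng: np.random.Generator
) -> float:
    """Waiting time to the next coalescence among ``k`` lineages in a deme
    whose relative size is x(t) = x_present * exp(-alpha * t) backward in
    time.  Returns inf if no event occurs in finite time (possible when
    alpha < 0, i.e. the deme grows backward in time).
    """
    if k < 2:
        return math.inf
    rate0 = k * (k - 1) / x_present  # pair rate 2*C(k,2)/x at t=0
    e = rng.exponential()
    if alpha == 0.0:
        return e / rate0
    # cumulative hazard from t0 to t0+w: (rate0/alpha) * (exp(a(t0+w)) - exp(a t0))
    arg = math.exp(alpha * t0) + e * alpha / rate0
    if arg <= 0.0:
        return math.inf
    return math.log(arg) / alpha - t0


def _coalesce_pair(
    pool: list[int], t: float, times: list[float], parent: np.ndarray,
    rng: np.random.Generator,
) -> None:
    i, j = rng.choice(len(pool), size=2, replace=False)
    a, b = pool[i], pool[j]
    new = len(times)
    times.append(t)
    parent[a] = new
    parent[b] = new
    # remove the higher index first
    for idx in sorted((i, j), reverse=True):
        pool.pop(idx)
    pool.append(new)


def _deme_schedule(params: ScenarioParams) -> tuple[float, float, float, float]:
    """Backward-time relative deme sizes (x1, alpha1, x2, alpha2).

    Each deme's size is x * exp(-alpha * t) backward in time on [0, ct):
    constant 1 for the source/vicariance demes, and shrinking from the
    growth ratio at present to the founder ratio at ct for the colonized
    deme of models 3 and 4.
    """
    x = [1.0, 1.0]
    alpha = [0.0, 0.0]
    if params.model_id in (3, 4) and params.ct > 0.0:
        founded = 0 if params.model_id == 3 else 1
        fr, gr = params.founder_ratio, params.growth_ratio
        x[founded] = gr
        alpha[founded] = math.log(gr / fr) / params.ct
    return x[0], alpha[0], x[1], alpha[1]


def _simulate_genealogy(
    params: ScenarioParams, n1: int, n2: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one genealogy; return (parent, node_times).

    Leaves 0..n1-1 belong to deme 1 (TAb), n1..n1+n2-1 to deme 2 (AMb).
    Internal nodes are appended in coalescence order; the root's parent
    is -1.  Time is measured backward in units of 4*Ne generations.
    """
    n = n1 + n2
    if n < 2:
        raise ValueError("need at least 2 haploid samples in total")
    max_nodes = 2 * n - 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    times: list[float] = [0.0] * n
    pools: list[list[int]] = [list(range(n1)), list(range(n1, n))]

    model = params.model_id
    ct = params.ct if model != 1 else 0.0
    t = 0.0

    if model != 1 and ct > 0.0:
        x1, a1, x2, a2 = _deme_schedule(params)
        size_present = [x1, x2]
        alpha = [a1, a2]
        while t < ct and len(pools[0]) + len(pools[1]) > 1:
            waits = [
                _exp_deme_waiting_time(len(pools[d]), t, size_present[d], alpha[d], rng)
                for d in (0, 1)
            ]
            d = 0 if waits[0] <= waits[1] else 1
            if not math.isfinite(waits[d]) or t + waits[d] >= ct:
                break
            t += waits[d]
            _coalesce_pair(pools[d], t, times, parent, rng)
        t = ct

    # ancestral / panmictic phase: one pool of constant relative size 1
    pool = pools[0] + pools[1]
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(1.0 / (k * (k - 1)))
        _coalesce_pair(pool, t, times, parent, rng)

    return parent[: len(times)], np.asarray(times, dtype=np.float64)


def _descendant_masks(parent: np.ndarray, n_leaves: int) -> np.ndarray:
    """Boolean (n_nodes, n_leaves) matrix of leaves below each node."""
    n_nodes = parent.shape[0]
    masks = np.zeros((n_nodes, n_leaves), dtype=bool)
    masks[np.arange(n_leaves), np.arange(n_leaves)] = True
    # internal nodes are created in increasing time order, so a single
    # ascending pass accumulates children before parents
    for node in range(n_nodes - 1):
        masks[parent[node]] |= masks[node]
    return masks


def simulate_dataset(
    params: ScenarioParams,
    shape: DatasetShape,
    rng_seed: int | np.random.Generator,
    *,
    mode: str = "fixed_s",
    locus_theta: float | None = None,
    unlinked: bool = True,
) -> HaplotypeDataset:
    """Simulate one haplotype dataset under ``params``.

    By default each of the ``shape.n_sites`` SNPs rides its own
    independent genealogy with exactly one mutation (``unlinked=True``),
    matching the one-SNP-per-locus structure of a reduced-representation
    dataset.  With ``unlinked=False`` a single non-recombining genealogy
    carries all sites: ``mode='fixed_s'`` places exactly
    ``shape.n_sites`` segregating sites multinomially by branch length
    (as with ``ms -s``), while ``mode='fixed_theta'`` draws the site
    count as Poisson(locus_theta * total branch length);
    ``locus_theta`` defaults to theta_per_site * n_sites.
    """
    if mode not in ("fixed_s", "fixed_theta"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = _as_rng(rng_seed)
    n1, n2 = shape.n_hap_deme1, shape.n_hap_deme2
    deme_labels = np.repeat([0, 1], [n1, n2])

    if unlinked and mode == "fixed_s":
        # fixed_theta implies a shared genealogy, so it always takes the
        # linked path below
        from ._fastsim import unlinked_matrix

        x1, a1, x2, a2 = _deme_schedule(params)
        seed = int(rng.integers(0, 2 ** 31 - 1))
        matrix = unlinked_matrix(params.model_id, params.ct if params.model_id != 1 else 0.0,
                                 x1, a1, x2, a2, n1, n2, shape.n_sites, seed)
        positions = np.sort(rng.uniform(size=shape.n_sites))
        return HaplotypeDataset(matrix, deme_labels, positions, params)

    parent, times = _simulate_genealogy(params, n1, n2, rng)
    lengths = times[parent[:-1]] - times[:-1]  # per non-root edge
    total_length = float(lengths.sum())
    if mode == "fixed_s":
        s = shape.n_sites
    else:
        lt = locus_theta if locus_theta is not None else params.theta * shape.n_sites
        s = int(rng.poisson(lt * total_length))
    if s == 0:
        return HaplotypeDataset(
            np.empty((n1 + n2, 0), dtype=np.int8), deme_labels,
            np.empty(0, dtype=np.float64), params,
        )
    counts = rng.multinomial(s, lengths / total_length)
    masks = _descendant_masks(parent, n1 + n2)
    edge_per_site = np.repeat(np.arange(lengths.shape[0]), counts)
    rng.shuffle(edge_per_site)
    matrix = masks[edge_per_site].T.astype(np.int8)
    positions = np.sort(rng.uniform(size=s))
    return HaplotypeDataset(matrix, deme_labels, positions, params)


def simulate_batch(
    config: PriorConfig,
    shape: DatasetShape,
    n_per_model: int,
    models: Iterable[int],
    rng_seed: int,
    **dataset_kwargs,
) -> Iterator[tuple[HaplotypeDataset, int]]:
    """Yield ``n_per_model`` labeled datasets per requested model.

    Datasets are produced lazily (never all held in memory).  Each dataset
    gets an independent RNG substream spawned from ``rng_seed``, so the
    batch is reproducible and order-independent per (model, replicate).
    """
    models = sorted(set(models))
    if not models:
        raise ValueError("empty model set")
    unknown = [m for m in models if m not in MODEL_IDS]
    if unknown:
        raise ValueError(f"unknown model ids {unknown}")
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    root = np.random.SeedSequence(rng_seed)
    children = root.spawn(len(models) * n_per_model)
    idx = 0
    for model_id in models:
        for _ in range(n_per_model):
            rng = np.random.default_rng(children[idx])
            idx += 1
            params = draw_priors(config, model_id, rng)
            yield simulate_dataset(params, shape, rng, **dataset_kwargs), model_id


# ---------------------------------------------------------------------------
# ms-style text interchange
# ---------------------------------------------------------------------------

def write_ms_text(dataset: HaplotypeDataset, sink: IO[str]) -> None:
    """Write one dataset as an ms-style block (``//`` / segsites / positions /
    one 0-1 row per haplotype)."""
    if dataset.n_sites == 0 or dataset.n_haplotypes == 0:
        raise ValueError("cannot serialize an empty dataset")
    sink.write("//\n")
    sink.write(f"segsites: {dataset.n_sites}\n")
    sink.write("positions: " + " ".join(f"{p:.6f}" for p in dataset.positions) + "\n")
    for row in dataset.matrix:
        sink.write("".join("1" if v else "0" for v in row) + "\n")
    sink.write("\n")


def read_ms_text(source: IO[str], deme_labels: np.ndarray | None = None) -> list[HaplotypeDataset]:
    """Read ms-style blocks back into datasets (inverse of write_ms_text)."""
    datasets: list[HaplotypeDataset] = []
    lines = source.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("//"):
            i += 1
            continue
        seg_line = lines[i + 1]
        if not seg_line.startswith("segsites:"):
            raise ValueError(f"malformed block: expected 'segsites:', got {seg_line!r}")
        s = int(seg_line.split(":")[1])
        pos_line = lines[i + 2]
        if not pos_line.startswith("positions:"):
            raise ValueError(f"malformed block: expected 'positions:', got {pos_line!r}")
        positions = np.array([float(x) for x in pos_line.split()[1:]], dtype=np.float64)
        i += 3
        rows = []
        while i < len(lines) and lines[i].strip() and not lines[i].startswith("//"):
            rows.append([int(c) for c in lines[i].strip()])
            i += 1
        matrix = np.asarray(rows, dtype=np.int8)
        if matrix.shape[1] != s:
            raise ValueError("segsites does not match row width")
        labels = deme_labels if deme_labels is not None else np.zeros(matrix.shape[0], dtype=np.int64)
        datasets.append(HaplotypeDataset(matrix, labels, positions))
    return datasets
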