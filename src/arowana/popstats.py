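"""Diversity and differentiation statistics for biallelic SNP matrices.

Genotypes are coded 0/1/2 (count of the alternate allele) with -1 for
missing; individuals carry a population label.  The module computes the
per-population diversity table (mean allele count A, observed and
unbiased expected heterozygosity, inbreeding coefficient G_IS), pairwise
Weir & Cockerham (1984) F_ST, and a principal coordinates analysis of
the allele-sharing (1 - IBS) distance; readers accept VCF, DArT two-row
CSV and plain 0/1/2 matrix CSV with a separate population map.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "DiversityTable",
    "FstMatrix",
    "read_genotypes",
    "read_popmap",
    "write_matrix_csv",
    "diversity",
    "pairwise_fst",
    "weir_cockerham_fst",
    "pcoa",
    "summarize_dataset",
]


@dataclass
class GenotypeMatrix:
    """Diploid 0/1/2 genotype matrix with a population map.

    ``genotypes``: (n_individuals, n_loci) int8, -1 = missing;
    ``individuals``: ids, one per row; ``populations``: label per row.
    """

    genotypes: np.ndarray
    individuals: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        if len(self.individuals) != self.genotypes.shape[0]:
            raise ValueError("one individual id per genotype row required")
        if len(self.populations) != self.genotypes.shape[0]:
            raise ValueError("one population label per genotype row required")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes at {np.argwhere(bad)[0]}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def subset_populations(self, pops: list[str]) -> "GenotypeMatrix":
        keep = [i for i, p in enumerate(self.populations) if p in pops]
        return GenotypeMatrix(
            self.genotypes[keep],
            [self.individuals[i] for i in keep],
            [self.populations[i] for i in keep],
        )

    def as_float_matrix(self) -> np.ndarray:
        """Float copy with missing as NaN (encoder-ready)."""
        out = self.genotypes.astype(np.float64)
        out[self.genotypes == MISSING] = np.nan
        return out


@dataclass
class DiversityTable:
    """Per-population diversity summary (Table-2-style layout)."""

    table: pd.DataFrame  # index = population; columns A, Ho, He, Gis

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="population")


@dataclass
class FstMatrix:
    """Symmetric pairwise Weir-Cockerham theta with zero diagonal."""

    values: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="population")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> dict[str, str]:
    """Two-column (individual, population) TSV/CSV."""
    popmap: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split("\t")
        if len(parts) < 2:
            raise ValueError(f"popmap line {ln}: expected two columns")
        popmap[parts[0].strip()] = parts[1].strip()
    return popmap


def _apply_popmap(ids: list[str], popmap: dict[str, str]) -> list[str]:
    missing = [i for i in ids if i not in popmap]
    if missing:
        raise ValueError(f"individuals absent from popmap: {missing}")
    return [popmap[i] for i in ids]


def _read_vcf(path: str | Path) -> tuple[np.ndarray, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    cols = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS}; "
                "only biallelic SNPs are supported"
            )
        gt = variant.gt_types.astype(np.int8)  # 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        cols.append(gt)
    vcf.close()
    if not cols:
        raise ValueError(f"no variant records in {path}")
    return np.stack(cols, axis=1), ids


def _read_dart_two_row(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """DArT two-row format: two consecutive rows per locus (one per
    allele), entries 1/0 for allele presence, '-' for missing."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    header = rows[0]
    if len(header) < 3:
        raise ValueError("DArT two-row header needs locus, allele and sample columns")
    ids = [h.strip() for h in header[2:]]
    body = rows[1:]
    if len(body) % 2:
        raise ValueError("DArT two-row body must have an even number of rows")
    loci = []
    for ln in range(0, len(body), 2):
        ref_row, alt_row = body[ln], body[ln + 1]
        if ref_row[0] != alt_row[0]:
            raise ValueError(
                f"rows {ln + 2}/{ln + 3}: allele rows of one locus must share the locus id"
            )
        geno = np.full(len(ids), MISSING, dtype=np.int8)
        for j, (ref, alt) in enumerate(zip(ref_row[2:], alt_row[2:])):
            ref, alt = ref.strip(), alt.strip()
            if ref in ("-", "") or alt in ("-", ""):
                continue
            ref_present, alt_present = int(ref), int(alt)
            if ref_present and alt_present:
                geno[j] = 1
            elif ref_present:
                geno[j] = 0
            elif alt_present:
                geno[j] = 2
        loci.append(geno)
    return np.stack(loci, axis=1), ids


def _read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    geno = df.to_numpy(dtype=np.float64)
    geno = np.where(np.isnan(geno), MISSING, geno)
    if not np.isin(geno, (0, 1, 2, MISSING)).all():
        raise ValueError("matrix CSV entries must be 0/1/2 or missing")
    return geno.astype(np.int8), [str(i) for i in df.index]


def read_genotypes(
    source: str | Path,
    format: str,
    popmap: dict[str, str] | str | Path,
) -> GenotypeMatrix:
    """Read a genotype file (``vcf``, ``dart-two-row`` or ``matrix-csv``)
    and attach populations from the popmap (dict or file path)."""
    readers = {
        "vcf": _read_vcf,
        "dart-two-row": _read_dart_two_row,
        "matrix-csv": _read_matrix_csv,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    genotypes, ids = readers[format](source)
    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)
    return GenotypeMatrix(genotypes, ids, _apply_popmap(ids, popmap))


def write_matrix_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    geno = gm.genotypes.astype(object)
    df = pd.DataFrame(geno, index=gm.individuals,
                      columns=[f"L{j}" for j in range(gm.n_loci)])
    df = df.where(gm.genotypes != MISSING, other="")
    df.to_csv(path, index_label="id")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _pop_locus_stats(geno: np.ndarray):
    """Per-locus (n genotyped, alt freq, observed het) for one population."""
    ok = geno != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(ok, geno, 0).sum(axis=0) / np.maximum(2 * n, 1)
        ho = np.where(ok, geno == 1, False).sum(axis=0) / np.maximum(n, 1)
    return n, p, ho


def diversity(gm: GenotypeMatrix) -> DiversityTable:
    """Per-population A, Ho, He (unbiased) and Gis.

    Per locus within a population: Ho is the heterozygote fraction among
    genotyped individuals and He = 2n/(2n-1) * 2pq with n the genotyped
    diploid count.  A, Ho and He are averaged over loci polymorphic in
    the dataset and genotyped in the population; Gis = 1 - mean(Ho)/mean(He)
    over the loci with He > 0 (ratio of averages).
    """
    overall_ok = gm.genotypes != MISSING
    overall_n = overall_ok.sum(axis=0)
    overall_alt = np.where(overall_ok, gm.genotypes, 0).sum(axis=0)
    polymorphic = (overall_alt > 0) & (overall_alt < 2 * overall_n)

    rows = {}
    for pop in gm.population_ids:
        sel = np.asarray([p == pop for p in gm.populations])
        geno = gm.genotypes[sel]
        if (np.sum(geno != MISSING, axis=0) >= 2).sum() == 0:
            raise ValueError(f"population {pop!r} has <2 genotyped individuals at every locus")
        n, p, ho = _pop_locus_stats(geno)
        use = polymorphic & (n >= 1)
        n_u, p_u, ho_u = n[use], p[use], ho[use]
        with np.errstate(invalid="ignore", divide="ignore"):
            he = 2.0 * n_u / (2.0 * n_u - 1.0) * 2.0 * p_u * (1.0 - p_u)
        a = np.where((p_u > 0) & (p_u < 1), 2.0, 1.0)
        seg = he > 0
        gis = 1.0 - ho_u[seg].mean() / he[seg].mean() if seg.any() else float("nan")
        rows[pop] = {
            "A": float(a.mean()),
            "Ho": float(ho_u.mean()),
            "He": float(he.mean()),
            "Gis": float(gis),
        }
    return DiversityTable(pd.DataFrame.from_dict(rows, orient="index"))


def weir_cockerham_fst(
    genos: list[np.ndarray],
) -> float:
    """Multi-locus Weir & Cockerham (1984) theta for r populations.

    ``genos``: one (individuals x loci) 0/1/2/-1 matrix per population.
    Ratio-of-sums across loci; loci genotyped in fewer than two
    populations (or monomorphic overall) contribute nothing.  Returns NaN
    when no locus is informative.
    """
    r_stats = [_pop_locus_stats(g) for g in genos]
    n = np.stack([s[0] for s in r_stats]).astype(np.float64)   # (r, loci)
    p = np.stack([s[1] for s in r_stats])
    h = np.stack([s[2] for s in r_stats])

    informative = (n >= 1).sum(axis=0) >= 2
    n, p, h = n[:, informative], p[:, informative], h[:, informative]
    if n.size == 0:
        return float("nan")
    present = n >= 1
    r = present.sum(axis=0).astype(np.float64)
    n_sum = n.sum(axis=0)
    nbar = n_sum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - (n ** 2).sum(axis=0) / n_sum) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / n_sum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / n_sum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (pbar > 0) & (pbar < 1)
    denom = (a + b + c)[ok].sum()
    if denom == 0 or not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom)


def pairwise_fst(gm: GenotypeMatrix) -> FstMatrix:
    """Pairwise Weir-Cockerham theta between all declared populations."""
    pops = gm.population_ids
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs at least two populations")
    sel = {p: np.asarray([q == p for q in gm.populations]) for p in pops}
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            theta = weir_cockerham_fst([gm.genotypes[sel[pa]], gm.genotypes[sel[pb]]])
            out.loc[pa, pb] = out.loc[pb, pa] = theta
    return FstMatrix(out)


def ibs_distance(gm: GenotypeMatrix) -> np.ndarray:
    """1 - identity-by-state averaged over co-genotyped loci."""
    g = gm.genotypes.astype(np.float64)
    g[gm.genotypes == MISSING] = np.nan
    n = gm.n_individuals
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g - g[i]) / 2.0          # (n, loci), NaN where missing
        dist[i] = np.nanmean(diff, axis=1)
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


def pcoa(gm: GenotypeMatrix, n_axes: int = 2):
    """Classical metric scaling of the 1 - IBS distance.

    Returns (coordinates DataFrame, eigenvalues array); eigenvalues are
    non-increasing and ``n_axes`` is truncated to the positive rank with
    a warning when it exceeds it.
    """
    if gm.n_individuals < 3:
        raise ValueError("PCoA needs at least 3 individuals")
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa as skbio_pcoa

    dm = DistanceMatrix(ibs_distance(gm), ids=gm.individuals)
    res = skbio_pcoa(dm, number_of_dimensions=0)
    eigvals = res.eigvals.to_numpy()
    pos = int((eigvals > 1e-12).sum())
    if n_axes > pos:
        import warnings
        warnings.warn(f"n_axes={n_axes} exceeds positive rank {pos}; truncating")
        n_axes = pos
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = gm.individuals
    return coords, eigvals[:n_axes]


def summarize_dataset(gm: GenotypeMatrix) -> dict:
    """Counts of individuals, loci and the missing-entry fraction."""
    n_missing = int((gm.genotypes == MISSING).sum())
    return {
        "n_individuals": gm.n_individuals,
        "n_loci": gm.n_loci,
        "n_missing": n_missing,
        "missing_fraction": n_missing / gm.genotypes.size,
        "populations": {p: gm.populations.count(p) for p in gm.population_ids},
    }
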