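"""Sequence and microsatellite diversity summaries.

Sequence side: segregating sites S, haplotype count and diversity
(h = n/(n-1) * (1 - sum p_i^2)), nucleotide diversity pi (mean pairwise
differences per site), and Watterson's theta (S / (a_n * L)) — all computed
over the columns with no gap or N in any pool member (complete deletion),
whose count is the effective length L.  Approximate standard deviations use
the classical Nei (1987) and Watterson formulas.

Microsatellite side: Nei's unbiased expected heterozygosity HE, observed
heterozygosity HO, mean allele number NA, rarefaction-standardized allelic
richness AR(g), the within-population inbreeding coefficient FIS, and the
between-habitat heterozygosity-loss coefficient
F = (HE_source - HE_derived) / HE_source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .mito_io import AnnotatedAlignment

MISSING_ALLELE = "."


@dataclass(frozen=True)
class DiversitySummary:
    pool: str
    n: int
    S: int
    Nh: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    thetaW: float
    thetaW_sd: float
    L: int


# -- sequence statistics ----------------------------------------------------


def _pool_matrix(aln: AnnotatedAlignment, pool: str) -> tuple[np.ndarray, int]:
    """(samples x usable-columns nucleotide matrix, effective length L)."""
    samples = aln.pool_samples(pool)
    if len(samples) < 2:
        raise ValueError(f"pool {pool!r} needs >= 2 samples")
    mask = aln.usable_columns(samples)
    L = int(mask.sum())
    if L == 0:
        raise ValueError(f"pool {pool!r} has no usable columns (L = 0)")
    mat = np.array(
        [np.frombuffer(aln.sequences[s].encode(), dtype="S1")[mask] for s in samples]
    )
    return mat, L


def segregating_sites(aln: AnnotatedAlignment, pool: str) -> int:
    mat, _ = _pool_matrix(aln, pool)
    return int(((mat != mat[0]).any(axis=0)).sum())


def haplotype_stats(aln: AnnotatedAlignment, pool: str) -> tuple[int, float]:
    """(number of haplotypes Nh, unbiased haplotype diversity h).

    Haplotypes are distinct sequences over the pool's usable columns.
    """
    mat, _ = _pool_matrix(aln, pool)
    n = mat.shape[0]
    _, counts = np.unique(mat.view(f"S{mat.shape[1]}").ravel(), return_counts=True)
    freqs = counts / n
    h = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
    return len(counts), h


def haplotype_diversity_sd(counts: Sequence[int]) -> float:
    """Nei (1987) sampling SD of haplotype diversity from haplotype counts."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2
    )
    return math.sqrt(max(var, 0.0))


def nucleotide_diversity(aln: AnnotatedAlignment, pool: str) -> float:
    """pi: mean pairwise differences per usable site."""
    mat, L = _pool_matrix(aln, pool)
    n = mat.shape[0]
    total = 0
    for i, j in combinations(range(n), 2):
        total += int((mat[i] != mat[j]).sum())
    return total / (n * (n - 1) / 2) / L


def watterson_theta(aln: AnnotatedAlignment, pool: str) -> float:
    """Watterson's theta per site: S / (a_n * L)."""
    mat, L = _pool_matrix(aln, pool)
    n = mat.shape[0]
    S = int(((mat != mat[0]).any(axis=0)).sum())
    a_n = sum(1.0 / i for i in range(1, n))
    return S / (a_n * L)


def pi_sd(pi: float, n: int, L: int) -> float:
    """Nei (1987) stochastic SD of pi per site."""
    var = ((n + 1) / (3.0 * (n - 1))) * pi / L + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return math.sqrt(max(var, 0.0))


def watterson_theta_sd(theta: float, n: int, L: int) -> float:
    """Watterson SD of theta per site from Var(S) = a_n*theta*L + b_n*(theta*L)^2."""
    a_n = sum(1.0 / i for i in range(1, n))
    b_n = sum(1.0 / i**2 for i in range(1, n))
    var_S = a_n * theta * L + b_n * (theta * L) ** 2
    return math.sqrt(max(var_S, 0.0)) / (a_n * L)


def diversity_summary(aln: AnnotatedAlignment, pool: str) -> DiversitySummary:
    """All sequence diversity statistics for one pool (SDs are approximate)."""
    mat, L = _pool_matrix(aln, pool)
    n = mat.shape[0]
    S = int(((mat != mat[0]).any(axis=0)).sum())
    _, counts = np.unique(mat.view(f"S{mat.shape[1]}").ravel(), return_counts=True)
    freqs = counts / n
    Nh = len(counts)
    h = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
    pi = nucleotide_diversity(aln, pool)
    theta = S / (sum(1.0 / i for i in range(1, n)) * L)
    return DiversitySummary(
        pool=pool,
        n=n,
        S=S,
        Nh=Nh,
        h=h,
        h_sd=haplotype_diversity_sd(counts),
        pi=pi,
        pi_sd=pi_sd(pi, n, L),
        thetaW=theta,
        thetaW_sd=watterson_theta_sd(theta, n, L),
        L=L,
    )


# -- microsatellites --------------------------------------------------------


@dataclass
class MicrosatDataset:
    """Diploid genotypes: long-format frame (sample, population, locus, allele1, allele2).

    Missing alleles are encoded as ``'.'``; allele pairs are unordered.
    """

    df: pd.DataFrame

    COLUMNS = ("sample", "population", "locus", "allele1", "allele2")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"microsat table missing columns: {sorted(missing)}")
        self.df = self.df.astype(
            {"sample": str, "population": str, "locus": str, "allele1": str, "allele2": str}
        )

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())

    @property
    def loci(self) -> list[str]:
        return sorted(self.df["locus"].unique())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MicrosatDataset":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def _locus_genotypes(data: MicrosatDataset, pop: str, locus: str) -> pd.DataFrame:
    df = data.df
    sub = df[(df["population"] == pop) & (df["locus"] == locus)]
    return sub[(sub["allele1"] != MISSING_ALLELE) & (sub["allele2"] != MISSING_ALLELE)]


def allelic_richness(allele_counts: Sequence[int], g: int) -> float:
    """Rarefaction-expected number of alleles in a subsample of g genes.

    AR(g) = sum_a [1 - C(N - N_a, g) / C(N, g)] over alleles a, with N the
    total sampled genes and N_a the count of allele a.
    """
    counts = np.asarray(allele_counts, int)
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds sampled genes N={N}")
    denom = math.comb(N, g)
    return float(sum(1.0 - math.comb(N - c, g) / denom for c in counts))


def microsat_summary(
    data: MicrosatDataset, pop: str, rarefaction_g: int | None = None
) -> dict:
    """Per-population multilocus summary: HE, HO, NA, AR(g), FIS.

    HE is Nei's unbiased expected heterozygosity, averaged over loci; FIS is
    1 - HO/HE averaged over the loci where HE > 0.  ``rarefaction_g``
    defaults to twice the smallest complete per-locus sample size across the
    whole dataset (so AR is comparable across populations).
    """
    if pop not in data.populations:
        raise ValueError(f"unknown population {pop!r}")
    if rarefaction_g is None:
        min_n = min(
            len(_locus_genotypes(data, p, loc))
            for p in data.populations
            for loc in data.loci
            if len(_locus_genotypes(data, p, loc)) > 0
        )
        rarefaction_g = 2 * min_n
    he_vals, ho_vals, na_vals, ar_vals, fis_vals = [], [], [], [], []
    for locus in data.loci:
        geno = _locus_genotypes(data, pop, locus)
        n = len(geno)
        if n < 2:
            continue
        alleles = pd.concat([geno["allele1"], geno["allele2"]])
        counts = alleles.value_counts().to_numpy()
        freqs = counts / counts.sum()
        he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(freqs**2)))
        ho = float((geno["allele1"] != geno["allele2"]).mean())
        he_vals.append(he)
        ho_vals.append(ho)
        na_vals.append(len(counts))
        ar_vals.append(allelic_richness(counts, min(rarefaction_g, int(counts.sum()))))
        if he > 0:
            fis_vals.append(1.0 - ho / he)
    if not he_vals:
        raise ValueError(f"population {pop!r} has no usable loci")
    return {
        "population": pop,
        "n_loci": len(he_vals),
        "HE": float(np.mean(he_vals)),
        "HO": float(np.mean(ho_vals)),
        "NA": float(np.mean(na_vals)),
        "AR": float(np.mean(ar_vals)),
        "FIS": float(np.mean(fis_vals)) if fis_vals else float("nan"),
        "rarefaction_g": rarefaction_g,
    }


def inbreeding_loss(he_source: float, he_derived: float) -> float:
    """F = (HE_source - HE_derived) / HE_source; negative if diversity grew."""
    if he_source <= 0:
        raise ValueError("source expected heterozygosity must be positive")
    return (he_source - he_derived) / he_source
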