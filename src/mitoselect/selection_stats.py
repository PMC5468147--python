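"""Selection-efficacy statistics in the McDonald-Kreitman framework.

Given the within-species polymorphism counts (Pn, Ps) and between-species
fixed-substitution counts (Dn, Ds), the fraction of nonsynonymous
polymorphisms that are weakly or moderately deleterious is

    delta = 1 - (Dn * Ps) / (Ds * Pn)

Under strict neutrality Pn/Ps = Dn/Ds and delta = 0; an excess of
nonsynonymous polymorphism relative to divergence pushes delta toward 1.
Confidence intervals come from a percentile bootstrap that resamples the
class labels of the polymorphism and substitution lists (binomially
equivalent).  This module also provides the habitat-contrast tests: Fisher's
exact test on the 2x2 class table, a one-sided downsampling permutation test
for the Pn/Ps difference, Nei-Gojobori (1986) dN/dS with Jukes-Cantor
correction, and the rank/correlation tests used on functional-score vectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .mito_io import AnnotatedAlignment, codon_usable, translate
from .variant_classify import (
    ClassCounts,
    CodingVariant,
    classify_codon_pair,
    effect_is_nonsynonymous,
    find_polymorphisms,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaEstimate:
    delta: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    method: str = "percentile"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str  # "one" | "two"
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# -- Pn/Ps and delta -------------------------------------------------------


def pnps_ratio(counts: ClassCounts) -> float | None:
    """Pn/Ps; ``None`` (reported n/a) when Ps = 0."""
    if counts.Ps == 0:
        return None
    return counts.Pn / counts.Ps


def mk_delta(counts: ClassCounts) -> float:
    """delta = 1 - (Dn*Ps)/(Ds*Pn); requires Pn > 0 and Ds > 0."""
    if counts.Pn == 0 or counts.Ds == 0:
        raise ValueError("delta undefined: requires Pn > 0 and Ds > 0")
    return 1.0 - (counts.Dn * counts.Ps) / (counts.Ds * counts.Pn)


def delta_bootstrap(
    counts: ClassCounts, n_boot: int = 10_000, seed: int = 0
) -> DeltaEstimate:
    """Percentile bootstrap CI for delta (class-label resampling).

    Each replicate redraws Pn* ~ Binomial(Pn+Ps, Pn/(Pn+Ps)) and
    Dn* ~ Binomial(Dn+Ds, Dn/(Dn+Ds)) — exactly equivalent to resampling
    the labelled polymorphism and substitution lists with replacement —
    and recomputes delta.  Replicates with Pn* = 0 (or Ds* = 0) are kept
    in the ranking as -inf, so the lower percentile is never optimistic.
    """
    point = mk_delta(counts)
    rng = np.random.default_rng(seed)
    p_total, d_total = counts.Pn + counts.Ps, counts.Dn + counts.Ds
    pn = rng.binomial(p_total, counts.Pn / p_total, size=n_boot).astype(float)
    dn = rng.binomial(d_total, counts.Dn / d_total, size=n_boot).astype(float)
    ps, ds = p_total - pn, d_total - dn
    with np.errstate(divide="ignore", invalid="ignore"):
        deltas = 1.0 - (dn * ps) / (ds * pn)
    deltas = np.where((pn == 0) | (ds == 0), -np.inf, deltas)
    lo, hi = np.quantile(deltas, [0.025, 0.975], method="closest_observation")
    return DeltaEstimate(
        delta=point, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, seed=seed
    )


def mutation_load(delta: float, mean_nonsyn_per_genome: float) -> float:
    """Deleterious mutations per genome: delta x mean derived nonsynonymous alleles."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1] for a load estimate")
    return delta * mean_nonsyn_per_genome


# -- contingency and resampling tests --------------------------------------


def fisher_exact_2x2(table: Sequence[Sequence[int]], sidedness: str = "two") -> TestResult:
    """Conditional (hypergeometric) Fisher exact test on a 2x2 table.

    The two-sided p-value sums, over all tables with the observed margins,
    the probabilities no larger than that of the observed table (the
    point-probability criterion).  A zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative entries")
    alternative = "two-sided" if sidedness == "two" else "greater"
    odds, p = stats.fisher_exact(t, alternative=alternative)
    return TestResult(
        statistic=float(odds), p_value=float(p), sidedness=sidedness, method="fisher_exact"
    )


def pnps_downsampling_test(
    variants: Sequence[CodingVariant] | Sequence[str],
    n_target: int,
    observed_ratio: float,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """One-sided downsampling permutation test for an elevated Pn/Ps.

    Draws ``n_target`` polymorphisms without replacement from the source
    (brackish) list and asks how often the downsampled Pn*/Ps* is at least
    the observed (freshwater) ratio.  Because only the class labels matter,
    Pn* follows a hypergeometric distribution, sampled directly.  Replicates
    with Ps* = 0 count as exceeding (conservative).  p uses the add-one
    correction (#exceeding + 1)/(n_perm + 1).
    """
    labels = [v.effect if isinstance(v, CodingVariant) else v for v in variants]
    n_nonsyn = sum(
        lab in ("nonsyn", "nonsynonymous", "pathway-ambiguous") for lab in labels
    )
    n_total = len(labels)
    if n_target > n_total:
        raise ValueError("n_target exceeds the number of source polymorphisms")
    rng = np.random.default_rng(seed)
    pn_star = rng.hypergeometric(n_nonsyn, n_total - n_nonsyn, n_target, size=n_perm)
    ps_star = n_target - pn_star
    with np.errstate(divide="ignore"):
        ratio = np.where(ps_star > 0, pn_star / np.maximum(ps_star, 1), np.inf)
    exceed = int((ratio >= observed_ratio).sum())
    p = (exceed + 1) / (n_perm + 1)
    return TestResult(
        statistic=float(observed_ratio),
        p_value=p,
        sidedness="one",
        method="pnps_downsampling",
    )


def pnps_genome_subsampling_test(
    aln: AnnotatedAlignment,
    pool: str,
    n_genomes: int,
    observed_ratio: float,
    n_perm: int = 1_000,
    seed: int = 0,
) -> TestResult:
    """Alternative reading of the downsampling test: subsample genomes.

    Each replicate draws ``n_genomes`` samples from ``pool`` without
    replacement, recounts which of the pool's polymorphic sites still
    segregate in the subsample, and recomputes Pn*/Ps*.  One-sided p as in
    :func:`pnps_downsampling_test`.
    """
    samples = aln.pool_samples(pool)
    if n_genomes > len(samples):
        raise ValueError("n_genomes exceeds pool size")
    variants = find_polymorphisms(aln, pool)
    # site x sample matrix of minor-allele carriage (deduplicated sites)
    seen: set[int] = set()
    carrier_rows, is_nonsyn = [], []
    for v in variants:
        if v.aln_position in seen:
            continue
        seen.add(v.aln_position)
        minor = v.minor_allele
        gene = aln.gene(v.gene)
        idx = v.aln_position - 1
        row = np.array(
            [
                (aln.sequences[s][idx] if gene.strand == "+" else aln.sequences[s][idx])
                == (minor if gene.strand == "+" else _complement(minor))
                for s in samples
            ],
            dtype=bool,
        )
        carrier_rows.append(row)
        is_nonsyn.append(effect_is_nonsynonymous(v.effect))
    if not carrier_rows:
        raise ValueError(f"pool {pool!r} has no polymorphisms")
    carriers = np.array(carrier_rows)
    nonsyn = np.array(is_nonsyn)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.choice(len(samples), size=n_genomes, replace=False)
        counts = carriers[:, idx].sum(axis=1)
        seg = (counts > 0) & (counts < n_genomes)
        pn_star = int((seg & nonsyn).sum())
        ps_star = int((seg & ~nonsyn).sum())
        if ps_star == 0 or pn_star / ps_star >= observed_ratio:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return TestResult(
        statistic=float(observed_ratio),
        p_value=p,
        sidedness="one",
        method="pnps_genome_subsampling",
    )


def _complement(nuc: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[nuc]


# -- Nei-Gojobori dN/dS ----------------------------------------------------


def _ng86_site_counts(codon: str, code) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon (NG86).

    Each position contributes the fraction of its three one-step changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = translate(codon, code)
    syn = 0.0
    for i in range(3):
        for nuc in "ACGT":
            if nuc == codon[i]:
                continue
            mutant = codon[:i] + nuc + codon[i + 1 :]
            if translate(mutant, code) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _ng86_diff_counts(codon_a: str, codon_b: str, code) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts with pathway averaging."""
    if codon_a == codon_b:
        return 0.0, 0.0
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if len(diffs) == 1:
        (_, effect), = classify_codon_pair(codon_a, codon_b, code)
        return (1.0, 0.0) if effect == "synonymous" else (0.0, 1.0)
    # average per-step classes over all stop-avoiding pathways
    from itertools import permutations

    syn_total, n_paths = 0.0, 0
    for order in permutations(diffs):
        current, syn_steps, blocked = codon_a, 0, False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if translate(nxt, code) == "*" and nxt != codon_b:
                blocked = True
                break
            if translate(current, code) == translate(nxt, code):
                syn_steps += 1
            current = nxt
        if not blocked:
            syn_total += syn_steps
            n_paths += 1
    if n_paths == 0:  # all paths pass through stops; use them anyway
        for order in permutations(diffs):
            current, syn_steps = codon_a, 0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if translate(current, code) == translate(nxt, code):
                    syn_steps += 1
                current = nxt
            syn_total += syn_steps
            n_paths += 1
    mean_syn = syn_total / n_paths
    return mean_syn, len(diffs) - mean_syn


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -3/4 ln(1 - 4p/3)."""
    if p >= 0.75:
        raise ValueError("proportion >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(
    seqs_a: Sequence[Sequence[str]],
    seqs_b: Sequence[Sequence[str]],
    code=None,
) -> tuple[float, float, float | None]:
    """Nei-Gojobori (1986) dN and dS averaged over all cross pairs.

    ``seqs_a`` and ``seqs_b`` are lists of codon lists of equal length
    (e.g. from :func:`mitoselect.mito_io.extract_codons`).  Codons unusable
    in either member of a pair are skipped for that pair.  Returns
    (dN, dS, dN/dS) with the ratio ``None`` when dS = 0.  If a pairwise
    proportion reaches the Jukes-Cantor ceiling the uncorrected proportion
    is used for that pair, with a warning.
    """
    if code is None:
        from .mito_io import vertebrate_mito_code

        code = vertebrate_mito_code()
    dn_vals, ds_vals = [], []
    for ca in seqs_a:
        for cb in seqs_b:
            if len(ca) != len(cb):
                raise ValueError("codon sequences must have equal length")
            S = N = sd = nd = 0.0
            for x, y in zip(ca, cb):
                if not (codon_usable(x) and codon_usable(y)):
                    continue
                if translate(x, code) == "*" or translate(y, code) == "*":
                    continue
                sx, nx = _ng86_site_counts(x, code)
                sy, ny = _ng86_site_counts(y, code)
                S += (sx + sy) / 2.0
                N += (nx + ny) / 2.0
                s_diff, n_diff = _ng86_diff_counts(x, y, code)
                sd += s_diff
                nd += n_diff
            if S == 0 or N == 0:
                continue
            ps, pn = sd / S, nd / N
            try:
                ds = jukes_cantor(ps)
            except ValueError:
                log.warning("pS = %.3f >= 3/4; using uncorrected proportion", ps)
                ds = ps
            try:
                dn = jukes_cantor(pn)
            except ValueError:
                log.warning("pN = %.3f >= 3/4; using uncorrected proportion", pn)
                dn = pn
            dn_vals.append(dn)
            ds_vals.append(ds)
    if not dn_vals:
        return 0.0, 0.0, None
    dN, dS = float(np.mean(dn_vals)), float(np.mean(ds_vals))
    return dN, dS, (dN / dS if dS > 0 else None)


# -- generic two-sample / correlation tests --------------------------------


def mannwhitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        sidedness="two",
        method="mannwhitney_u",
    )


def variance_f_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided F test on the ratio of sample variances."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    f = np.var(x, ddof=1) / np.var(y, ddof=1)
    dfx, dfy = len(x) - 1, len(y) - 1
    cdf = stats.f.cdf(f, dfx, dfy)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return TestResult(
        statistic=float(f), p_value=float(min(p, 1.0)), sidedness="two", method="variance_f"
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with tie-corrected ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for constant input")
    res = stats.spearmanr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness="two",
        method="spearman",
    )
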