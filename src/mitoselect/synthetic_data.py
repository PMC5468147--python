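"""Synthetic inputs with known ground truth.

The generator emulates the study design the pipeline targets: a two-habitat
sample of complete mitogenomes (26 freshwater + 31 brackish by default, 13
protein-coding genes laid out like the vertebrate mitochondrial OXPHOS
complement, one divergent outgroup genome), functional-score tables whose
observed-variant distribution sits below the all-potential distribution,
and microsatellite genotypes drifted through a freshwater bottleneck.

Variants are *planted*, not evolved: each requested synonymous or
nonsynonymous polymorphism (or fixed difference) occupies its own codon,
chosen so that a single-nucleotide change has exactly the required effect
under translation table 2.  Class counts recovered by the classifier are
therefore exact, and every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mito_io import (
    OUTGROUP_POOL,
    STOP,
    AnnotatedAlignment,
    GeneModel,
    ScoreTable,
    reverse_complement,
    translate,
    vertebrate_mito_code,
)
from .score_selection import AminoAcidVariant

log = logging.getLogger(__name__)

# 13 OXPHOS genes with lengths close to the vertebrate mitogenome layout
# (nt, multiples of 3 including a terminal stop codon); ND6 on the minus strand.
DEFAULT_GENE_LAYOUT: tuple[tuple[str, int, str], ...] = (
    ("ND1", 975, "+"),
    ("ND2", 1047, "+"),
    ("COX1", 1551, "+"),
    ("COX2", 690, "+"),
    ("ATP8", 168, "+"),
    ("ATP6", 684, "+"),
    ("COX3", 786, "+"),
    ("ND3", 348, "+"),
    ("ND4L", 297, "+"),
    ("ND4", 1380, "+"),
    ("ND5", 1839, "+"),
    ("ND6", 522, "-"),
    ("CYTB", 1140, "+"),
)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the alignment simulator.

    Defaults mirror the emulated design: pooled freshwater n=26 and
    brackish n=31 mitogenomes, one outgroup genome, per-pool polymorphism
    targets (Pn, Ps) = (28, 51) freshwater and (41, 145) brackish, and
    (Dn, Ds) = (141, 1565) fixed differences on the outgroup branch.
    ``singleton_prob`` = 0.7 makes most planted variants singletons, giving
    the singleton-rich site frequency spectrum of a recently expanded
    population; non-singleton counts are drawn uniformly up to
    ``max_maf`` (0.108), the upper end of realistic minor allele
    frequencies for such data.
    """

    seed: int = 0
    n_fw: int = 26
    n_bw: int = 31
    n_outgroup: int = 1
    gene_layout: Sequence[tuple[str, int, str]] = DEFAULT_GENE_LAYOUT
    fw_targets: tuple[int, int] = (28, 51)  # (Pn, Ps)
    bw_targets: tuple[int, int] = (41, 145)
    fixed_targets: tuple[int, int] = (141, 1565)  # (Dn, Ds)
    singleton_prob: float = 0.7
    max_maf: float = 0.108
    spacer: int = 12  # non-coding nt between genes

    def __post_init__(self) -> None:
        for pair in (self.fw_targets, self.bw_targets, self.fixed_targets):
            if min(pair) < 0:
                raise ValueError("variant targets must be nonnegative")
        if self.n_fw < 2 or self.n_bw < 2:
            raise ValueError("in-group pools need >= 2 samples")
        if self.n_outgroup < 1:
            raise ValueError("need at least one outgroup genome")


_NON_STOP_CODONS: list[str] = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if vertebrate_mito_code()[a + b + c] != STOP
]


def _one_step_mutants(codon: str, code) -> list[tuple[int, str, str]]:
    """(position 0-based, new nucleotide, effect) for the 9 one-step mutants."""
    aa = translate(codon, code)
    out = []
    for i in range(3):
        for nuc in "ACGT":
            if nuc == codon[i]:
                continue
            mutant = codon[:i] + nuc + codon[i + 1 :]
            maa = translate(mutant, code)
            if maa == STOP:
                continue
            out.append((i, nuc, "synonymous" if maa == aa else "nonsynonymous"))
    return out


def simulate_alignment(
    cfg: SimulationConfig,
) -> tuple[AnnotatedAlignment, dict[str, pd.DataFrame]]:
    """Build an annotated alignment with exactly the planted variant counts.

    Returns the alignment plus truth tables: ``polymorphisms`` (one row per
    planted within-pool variant with its carrier count) and ``fixed`` (one
    row per planted outgroup difference).
    """
    rng = np.random.default_rng(cfg.seed)
    code = vertebrate_mito_code()

    # reference genome: spacer + genes (coding strand generated, minus-strand
    # genes inserted as the reverse complement) + spacer
    genes: list[GeneModel] = []
    parts: list[str] = []
    pos = 1
    non_stop = np.array(_NON_STOP_CODONS)
    for name, length, strand in cfg.gene_layout:
        if length % 3:
            raise ValueError(f"gene {name}: length must be a multiple of 3")
        spacer = "".join(rng.choice(list("ACGT"), size=cfg.spacer))
        parts.append(spacer)
        pos += cfg.spacer
        n_codons = length // 3
        body = "".join(rng.choice(non_stop, size=n_codons - 2))
        coding = "ATG" + body + "TAA"
        parts.append(coding if strand == "+" else reverse_complement(coding))
        genes.append(GeneModel(name=name, start=pos, end=pos + length - 1, strand=strand))
        pos += length
    parts.append("".join(rng.choice(list("ACGT"), size=cfg.spacer)))
    reference = "".join(parts)

    # candidate slots: one per internal codon, shuffled; each planted variant
    # consumes one slot so no two variants share a codon
    slots: list[tuple[GeneModel, int]] = []
    for g in genes:
        slots.extend((g, ci) for ci in range(1, g.n_codons - 1))  # skip start + stop
    order = rng.permutation(len(slots))
    slot_iter = iter(order)

    def genome_edit(gene: GeneModel, codon_index: int, offset: int, nuc: str):
        """(0-based genome position, genome-strand allele) for a coding change."""
        p = gene.codon_positions(codon_index)[offset]
        allele = nuc if gene.strand == "+" else {"A": "T", "T": "A", "C": "G", "G": "C"}[nuc]
        return p - 1, allele

    def ref_codon(gene: GeneModel, codon_index: int) -> str:
        chars = [reference[p - 1] for p in gene.codon_positions(codon_index)]
        if gene.strand == "-":
            chars = [{"A": "T", "T": "A", "C": "G", "G": "C"}[c] for c in chars]
        return "".join(chars)

    def take_slot(effect: str):
        """Next unused codon offering a one-step mutant of the given effect."""
        for idx in slot_iter:
            gene, ci = slots[idx]
            codon = ref_codon(gene, ci + 1)
            options = [m for m in _one_step_mutants(codon, code) if m[2] == effect]
            if options:
                offset, nuc, _ = options[rng.integers(len(options))]
                return gene, ci + 1, codon, offset, nuc
        raise ValueError(
            f"infeasible targets: ran out of codons able to host a {effect} variant"
        )

    fw = [f"fw_{i:02d}" for i in range(1, cfg.n_fw + 1)]
    bw = [f"bw_{i:02d}" for i in range(1, cfg.n_bw + 1)]
    og = [f"out_{i:02d}" for i in range(1, cfg.n_outgroup + 1)]
    edits: dict[str, list[tuple[int, str]]] = {s: [] for s in fw + bw + og}

    poly_rows = []
    for pool_name, members, (pn, ps) in (
        ("freshwater", fw, cfg.fw_targets),
        ("brackish", bw, cfg.bw_targets),
    ):
        n = len(members)
        max_count = max(2, int(round(cfg.max_maf * n)))
        for effect, target in (("nonsynonymous", pn), ("synonymous", ps)):
            for _ in range(target):
                gene, ci, codon, offset, nuc = take_slot(effect)
                if rng.random() < cfg.singleton_prob:
                    count = 1
                else:
                    count = int(rng.integers(2, max_count + 1))
                carriers = rng.choice(n, size=count, replace=False)
                gpos, allele = genome_edit(gene, ci, offset, nuc)
                for k in carriers:
                    edits[members[k]].append((gpos, allele))
                poly_rows.append(
                    {
                        "pool": pool_name,
                        "gene": gene.name,
                        "codon_index": ci,
                        "aln_position": gpos + 1,
                        "ref_codon": codon,
                        "alt_codon": codon[:offset] + nuc + codon[offset + 1 :],
                        "effect": effect,
                        "derived_count": count,
                        "n_pool": n,
                    }
                )

    fixed_rows = []
    for effect, target in (
        ("nonsynonymous", cfg.fixed_targets[0]),
        ("synonymous", cfg.fixed_targets[1]),
    ):
        for _ in range(target):
            gene, ci, codon, offset, nuc = take_slot(effect)
            gpos, allele = genome_edit(gene, ci, offset, nuc)
            for s in og:
                edits[s].append((gpos, allele))
            fixed_rows.append(
                {
                    "gene": gene.name,
                    "codon_index": ci,
                    "aln_position": gpos + 1,
                    "ingroup_codon": codon,
                    "outgroup_codon": codon[:offset] + nuc + codon[offset + 1 :],
                    "effect": effect,
                }
            )

    sequences = {}
    base = np.frombuffer(reference.encode(), dtype="S1").copy()
    for sample, sample_edits in edits.items():
        arr = base.copy()
        for gpos, allele in sample_edits:
            arr[gpos] = allele.encode()
        sequences[sample] = arr.tobytes().decode()

    pools = {s: "freshwater" for s in fw}
    pools.update({s: "brackish" for s in bw})
    pools.update({s: OUTGROUP_POOL for s in og})
    aln = AnnotatedAlignment(sequences=sequences, pools=pools, genes=genes)
    truth = {
        "polymorphisms": pd.DataFrame(poly_rows),
        "fixed": pd.DataFrame(fixed_rows),
    }
    return aln, truth


# -- functional scores -------------------------------------------------------


@dataclass
class ScoreModel:
    """Distributional model for simulated pathogenicity scores.

    ``beta_shift`` (default): observed variants draw their unit score from
    Beta(1.2, 4) (mass near benign) and potential-only variants from
    Beta(4, 1.5) (mass near damaging) — the qualitative contrast seen when
    purifying selection removes damaging variants before they are observed.
    ``exponential``: potential scores are uniform and observed scores are
    acceptance-sampled with weight exp(-decay_b * x), planting a known
    selection-gradient parameter.  ``equal``: no shift (null model).
    """

    mode: str = "beta_shift"
    observed_beta: tuple[float, float] = (1.2, 4.0)
    potential_beta: tuple[float, float] = (4.0, 1.5)
    decay_b: float = 3.0
    scorer_noise: float = 0.12  # sd of the SNAP2 deviation from the shared latent score

    def __post_init__(self) -> None:
        if self.mode not in ("beta_shift", "exponential", "equal"):
            raise ValueError(f"unknown score model mode {self.mode!r}")


def _draw_unit_scores(rng, model: ScoreModel, n: int, observed: bool) -> np.ndarray:
    if model.mode == "equal":
        a, b = model.potential_beta
        return rng.beta(a, b, size=n)
    if model.mode == "beta_shift":
        a, b = model.observed_beta if observed else model.potential_beta
        return rng.beta(a, b, size=n)
    # exponential: uniform potential; observed accepted with weight exp(-b x)
    if not observed:
        return rng.uniform(0.0, 1.0, size=n)
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, 1.0, size=4 * (n - filled))
        keep = cand[rng.uniform(size=len(cand)) < np.exp(-model.decay_b * cand)]
        take = keep[: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def simulate_scores(
    observed: Sequence[AminoAcidVariant],
    potential: Sequence[AminoAcidVariant],
    model: ScoreModel | None = None,
    seed: int = 0,
) -> tuple[ScoreTable, ScoreTable]:
    """MutPred-style and SNAP2-style score tables covering all given variants.

    Each unique variant key receives one latent unit score; variants in the
    ``observed`` set draw from the observed distribution, the rest from the
    potential distribution.  The MutPred-dialect score is the latent value;
    the SNAP2-dialect score adds scorer noise before mapping to [-100, 100],
    so the two scorers are positively but imperfectly correlated.
    """
    model = model or ScoreModel()
    rng = np.random.default_rng(seed)
    observed_keys = {v.key for v in observed}
    keys: list[tuple[str, int, str, str]] = []
    seen = set()
    for v in list(observed) + list(potential):
        if v.key not in seen:
            seen.add(v.key)
            keys.append(v.key)
    is_obs = np.array([k in observed_keys for k in keys])
    latent = np.empty(len(keys))
    latent[is_obs] = _draw_unit_scores(rng, model, int(is_obs.sum()), observed=True)
    latent[~is_obs] = _draw_unit_scores(rng, model, int((~is_obs).sum()), observed=False)
    snap_latent = np.clip(latent + rng.normal(0.0, model.scorer_noise, len(keys)), 0.0, 1.0)
    frame = pd.DataFrame(keys, columns=["gene", "pos", "ref_aa", "alt_aa"])
    mutpred = frame.copy()
    mutpred["score"] = np.round(latent, 6)
    snap2 = frame.copy()
    snap2["score"] = np.round(200.0 * snap_latent - 100.0, 4)
    return (
        ScoreTable(df=mutpred, dialect="mutpred01"),
        ScoreTable(df=snap2, dialect="snap2_100"),
    )


# -- microsatellites ----------------------------------------------------------


@dataclass
class MicrosatConfig:
    """Wright-Fisher drift design for the microsatellite generator.

    Source (brackish-like) populations sample genotypes directly from the
    shared ancestral allele frequencies; derived (freshwater-like)
    populations first drift those frequencies through ``generations``
    rounds of a bottleneck of ``bottleneck_n`` diploids, so their expected
    heterozygosity decays by the factor (1 - 1/(2*bottleneck_n))^generations.
    Defaults (Nb = 25, t = 18) give an expected heterozygosity loss near
    0.30, the scale of a post-glacial freshwater colonization.
    """

    seed: int = 0
    n_loci: int = 9
    n_alleles: int = 8
    n_source_pops: int = 5
    n_derived_pops: int = 5
    n_per_pop: int = 48
    bottleneck_n: int = 25
    generations: int = 18
    missing_rate: float = 0.0


def simulate_microsats(cfg: MicrosatConfig):
    """Genotype table with source and bottleneck-drifted derived populations."""
    from .diversity_stats import MicrosatDataset

    if cfg.generations < 0:
        raise ValueError("generations must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    base_freqs = [
        rng.dirichlet(np.full(cfg.n_alleles, 2.0)) for _ in range(cfg.n_loci)
    ]
    rows = []

    def sample_pop(pop_name: str, freqs_per_locus) -> None:
        for li, freqs in enumerate(freqs_per_locus):
            alleles = [str(100 + 2 * a) for a in range(len(freqs))]
            for ind in range(cfg.n_per_pop):
                pair = rng.choice(len(freqs), size=2, p=freqs)
                a1, a2 = alleles[pair[0]], alleles[pair[1]]
                if cfg.missing_rate and rng.random() < cfg.missing_rate:
                    a1 = a2 = "."
                rows.append(
                    {
                        "sample": f"{pop_name}_{ind:03d}",
                        "population": pop_name,
                        "locus": f"L{li + 1:02d}",
                        "allele1": a1,
                        "allele2": a2,
                    }
                )

    for p in range(cfg.n_source_pops):
        sample_pop(f"src_{p + 1}", base_freqs)
    two_n = 2 * cfg.bottleneck_n
    for p in range(cfg.n_derived_pops):
        drifted = []
        for freqs in base_freqs:
            f = freqs.copy()
            for _ in range(cfg.generations):
                f = rng.multinomial(two_n, f) / two_n
            drifted.append(f)
        sample_pop(f"der_{p + 1}", drifted)
    return MicrosatDataset(pd.DataFrame(rows))
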