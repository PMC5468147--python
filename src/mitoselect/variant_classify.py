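"""Detection and classification of coding variants.

Segregating sites within a pool become :class:`CodingVariant` records;
sites monomorphic within the ingroup but differing from a monomorphic
outgroup become :class:`FixedDifference` records.  Each is labelled
synonymous or nonsynonymous under the vertebrate mitochondrial code, and
the per-pool totals (Pn, Ps) together with the interspecific totals
(Dn, Ds) form the :class:`ClassCounts` quadruple that feeds the
McDonald-Kreitman-style statistics in :mod:`mitoselect.selection_stats`.

Multi-difference codon pairs are classified per site by enumerating all
minimal mutational pathways that avoid stop codons (the Nei-Gojobori
convention); a site whose pathway votes tie is labelled pathway-ambiguous
and counted as nonsynonymous in the totals, which is conservative for a
deleterious-load question.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mito_io import (
    OUTGROUP_POOL,
    STOP,
    AnnotatedAlignment,
    codon_usable,
    extract_codons,
    translate,
)

log = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
AMBIGUOUS = "pathway-ambiguous"


@dataclass(frozen=True)
class CodingVariant:
    """One segregating coding site (one minor allele vs the major allele)."""

    gene: str
    aln_position: int  # 1-based alignment coordinate
    codon_index: int  # 1-based within gene
    codon_position: int  # 1, 2 or 3 within the codon
    ref_codon: str  # major-allele codon context
    alt_codon: str
    effect: str  # synonymous | nonsynonymous | pathway-ambiguous
    allele_counts: tuple[tuple[str, int], ...]  # in-pool (nucleotide, count), desc
    pool: str
    maf: float
    is_singleton: bool
    derived_allele: str | None = None
    site_multiallelic: bool = False

    @property
    def major_allele(self) -> str:
        return self.allele_counts[0][0]

    @property
    def minor_allele(self) -> str:
        # the allele this record contrasts against the major context
        if self.codon_position:
            return self.alt_codon[self.codon_position - 1]
        return self.allele_counts[-1][0]

    @property
    def minor_count(self) -> int:
        counts = dict(self.allele_counts)
        return counts[self.minor_allele]


@dataclass(frozen=True)
class FixedDifference:
    """A site fixed within the ingroup and differing from the outgroup."""

    gene: str
    aln_position: int
    codon_index: int
    ingroup_codon: str
    outgroup_codon: str
    effect: str


@dataclass(frozen=True)
class ClassCounts:
    """The (Pn, Ps, Dn, Ds) quadruple behind the MK-style statistics."""

    Pn: int
    Ps: int
    Dn: int = 0
    Ds: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.Pn, self.Ps, self.Dn, self.Ds) < 0:
            raise ValueError("class counts must be nonnegative")


# -- codon-pair classification -------------------------------------------


def classify_codon_pair(
    ref_codon: str, alt_codon: str, code: Mapping[str, str] | None = None
) -> list[tuple[int, str]]:
    """Classify each differing site of a codon pair.

    Returns ``[(codon_position_1based, effect), ...]`` for every position at
    which the codons differ.  Single-difference pairs are classified
    directly; multi-difference pairs by majority vote over all minimal
    stop-avoiding mutational pathways, falling back to all pathways when
    every path passes through a stop codon.
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    diffs = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
    if not diffs:
        raise ValueError("codons are identical")
    aa_ref = translate(ref_codon, code)
    aa_alt = translate(alt_codon, code)
    if "X" in (aa_ref, aa_alt):
        raise ValueError("codons must be fully determined (no N or gaps)")

    if len(diffs) == 1:
        effect = SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS
        return [(diffs[0] + 1, effect)]

    def walk(order: tuple[int, ...]) -> list[tuple[int, str]] | None:
        current = ref_codon
        steps = []
        for pos in order:
            nxt = current[:pos] + alt_codon[pos] + current[pos + 1 :]
            aa_from, aa_to = translate(current, code), translate(nxt, code)
            if aa_to == STOP and nxt != alt_codon:
                return None  # intermediate stop: pathway disallowed
            steps.append((pos, SYNONYMOUS if aa_from == aa_to else NONSYNONYMOUS))
            current = nxt
        return steps

    votes: dict[int, Counter] = {i: Counter() for i in diffs}
    orders = list(permutations(diffs))
    pathways = [w for w in (walk(o) for o in orders) if w is not None]
    if not pathways:  # all paths blocked by stops: fall back to unrestricted
        pathways = [
            [
                (pos, SYNONYMOUS if a == b else NONSYNONYMOUS)
                for pos, a, b in _steps_unrestricted(ref_codon, alt_codon, order, code)
            ]
            for order in orders
        ]
    for steps in pathways:
        for pos, effect in steps:
            votes[pos][effect] += 1
    out = []
    for pos in diffs:
        syn, nonsyn = votes[pos][SYNONYMOUS], votes[pos][NONSYNONYMOUS]
        if syn > nonsyn:
            out.append((pos + 1, SYNONYMOUS))
        elif nonsyn > syn:
            out.append((pos + 1, NONSYNONYMOUS))
        else:
            out.append((pos + 1, AMBIGUOUS))
    return out


def _steps_unrestricted(ref, alt, order, code):
    current = ref
    for pos in order:
        nxt = current[:pos] + alt[pos] + current[pos + 1 :]
        yield pos, translate(current, code), translate(nxt, code)
        current = nxt


def effect_is_nonsynonymous(effect: str) -> bool:
    """Totals count pathway-ambiguous sites as nonsynonymous."""
    return effect in (NONSYNONYMOUS, AMBIGUOUS)


# -- polymorphism detection ----------------------------------------------


def find_polymorphisms(aln: AnnotatedAlignment, pool: str) -> list[CodingVariant]:
    """One :class:`CodingVariant` per (minor allele, coding site) in a pool.

    Codons containing a gap or N in any pool member are excluded entirely
    (complete deletion).  Triallelic sites yield one record per minor
    allele, flagged ``site_multiallelic``; totals deduplicate them.
    """
    samples = aln.pool_samples(pool)
    if len(samples) < 2:
        raise ValueError(f"pool {pool!r} needs >= 2 samples")
    code = aln.genetic_code
    variants: list[CodingVariant] = []
    for gene in aln.genes:
        codons = extract_codons(aln, gene.name)
        pool_codons = [codons[s] for s in samples]
        for ci in range(gene.n_codons):
            column = [row[ci] for row in pool_codons]
            if not all(codon_usable(c) for c in column):
                continue
            if len(set(column)) == 1:
                continue
            # major codon context: per-position major allele
            positions = gene.codon_positions(ci + 1)
            major_codon = "".join(
                Counter(c[j] for c in column).most_common(1)[0][0] for j in range(3)
            )
            if translate(major_codon, code) == STOP:
                log.warning(
                    "gene %s codon %d: major-allele codon %s is a stop; site excluded",
                    gene.name, ci + 1, major_codon,
                )
                continue
            for j in range(3):
                counts = Counter(c[j] for c in column)
                if len(counts) == 1:
                    continue
                ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
                major = major_codon[j]
                multi = len(counts) > 2
                if multi:
                    log.info(
                        "gene %s position %d: %d alleles; splitting minor vs major",
                        gene.name, positions[j], len(counts),
                    )
                for allele, count in ranked:
                    if allele == major:
                        continue
                    alt_codon = major_codon[:j] + allele + major_codon[j + 1 :]
                    (_, effect), = classify_codon_pair(major_codon, alt_codon, code)
                    n = len(column)
                    variants.append(
                        CodingVariant(
                            gene=gene.name,
                            aln_position=positions[j],
                            codon_index=ci + 1,
                            codon_position=j + 1,
                            ref_codon=major_codon,
                            alt_codon=alt_codon,
                            effect=effect,
                            allele_counts=tuple(ranked),
                            pool=pool,
                            maf=min(count, n - count) / n,
                            is_singleton=count == 1,
                            site_multiallelic=multi,
                        )
                    )
    return variants


def find_fixed_differences(
    aln: AnnotatedAlignment,
    ingroup_pools: Iterable[str] | None = None,
    outgroup_pool: str = OUTGROUP_POOL,
) -> list[FixedDifference]:
    """Sites monomorphic in the ingroup and in the outgroup, with states differing.

    Returns one record per differing site; the effect of each site in a
    multi-difference codon comes from stop-avoiding pathway averaging.
    Codons polymorphic within the ingroup are polymorphisms, not fixed
    differences, and contribute nothing here.
    """
    if ingroup_pools is None:
        ingroup = aln.ingroup_samples()
    else:
        wanted = set(ingroup_pools)
        ingroup = [s for s in aln.samples if aln.pools[s] in wanted]
    outgroup = [s for s in aln.samples if aln.pools[s] == outgroup_pool]
    if not outgroup:
        raise ValueError(f"outgroup pool {outgroup_pool!r} is empty")
    code = aln.genetic_code
    fixed: list[FixedDifference] = []
    for gene in aln.genes:
        codons = extract_codons(aln, gene.name)
        for ci in range(gene.n_codons):
            in_col = {codons[s][ci] for s in ingroup}
            out_col = {codons[s][ci] for s in outgroup}
            if len(in_col) != 1 or len(out_col) != 1:
                continue
            in_codon, out_codon = in_col.pop(), out_col.pop()
            if in_codon == out_codon:
                continue
            if not (codon_usable(in_codon) and codon_usable(out_codon)):
                continue
            if translate(in_codon, code) == STOP:
                log.warning(
                    "gene %s codon %d: ingroup codon %s is a stop; excluded",
                    gene.name, ci + 1, in_codon,
                )
                continue
            positions = gene.codon_positions(ci + 1)
            for codon_pos, effect in classify_codon_pair(in_codon, out_codon, code):
                fixed.append(
                    FixedDifference(
                        gene=gene.name,
                        aln_position=positions[codon_pos - 1],
                        codon_index=ci + 1,
                        ingroup_codon=in_codon,
                        outgroup_codon=out_codon,
                        effect=effect,
                    )
                )
    return fixed


# -- polarization ---------------------------------------------------------


def outgroup_states(
    aln: AnnotatedAlignment, outgroup_pool: str = OUTGROUP_POOL
) -> dict[int, str]:
    """Map 1-based alignment position -> outgroup nucleotide where monomorphic."""
    outgroup = [s for s in aln.samples if aln.pools[s] == outgroup_pool]
    if not outgroup:
        return {}
    states: dict[int, str] = {}
    seqs = [aln.sequences[s] for s in outgroup]
    for i in range(aln.length):
        col = {seq[i] for seq in seqs}
        if len(col) == 1:
            nuc = col.pop()
            if nuc in "ACGT":
                states[i + 1] = nuc
    return states


def polarize(
    variant: CodingVariant, outgroup_states: Mapping[int, str]
) -> CodingVariant:
    """Set the derived allele: the minor allele, with outgroup tie-breaking.

    The lower-frequency allele is taken as derived.  At an exact frequency
    tie (MAF = 0.5) the outgroup state, where informative, is ancestral and
    the other allele derived; otherwise the call is left undetermined.
    """
    counts = list(variant.allele_counts)
    alleles = [a for a, _ in counts]
    if variant.maf < 0.5:
        minor = variant.minor_allele
        return replace(variant, derived_allele=minor)
    anc = outgroup_states.get(variant.aln_position)
    major, minor = variant.major_allele, variant.minor_allele
    if anc == major:
        return replace(variant, derived_allele=minor)
    if anc == minor:
        return replace(variant, derived_allele=major)
    return replace(variant, derived_allele=None)


# -- tabulation -----------------------------------------------------------


def _dedupe_sites(records, key=lambda r: r.aln_position):
    """Keep the first record per alignment site (gene-annotation order)."""
    seen: set[int] = set()
    out = []
    for r in records:
        k = key(r)
        if k in seen:
            continue
        seen.add(k)
        out.append(r)
    return out


def tabulate_counts(
    variants: Sequence[CodingVariant],
    fixed: Sequence[FixedDifference] = (),
    label: str = "",
) -> ClassCounts:
    """Genome-wide (Pn, Ps, Dn, Ds).

    Sites appearing in more than one record (overlapping genes, triallelic
    splits) are counted once, keeping the first record in annotation order.
    """
    uniq_vars = _dedupe_sites(variants)
    uniq_fixed = _dedupe_sites(fixed)
    pn = sum(effect_is_nonsynonymous(v.effect) for v in uniq_vars)
    dn = sum(effect_is_nonsynonymous(f.effect) for f in uniq_fixed)
    return ClassCounts(
        Pn=pn,
        Ps=len(uniq_vars) - pn,
        Dn=dn,
        Ds=len(uniq_fixed) - dn,
        label=label,
    )


def per_gene_counts(
    variants: Sequence[CodingVariant], fixed: Sequence[FixedDifference] = ()
) -> pd.DataFrame:
    """Per-gene (Pn, Ps, Dn, Ds) table; overlap sites count once per gene."""
    genes = sorted({v.gene for v in variants} | {f.gene for f in fixed})
    rows = []
    for gene in genes:
        gv = _dedupe_sites([v for v in variants if v.gene == gene])
        gf = _dedupe_sites([f for f in fixed if f.gene == gene])
        pn = sum(effect_is_nonsynonymous(v.effect) for v in gv)
        dn = sum(effect_is_nonsynonymous(f.effect) for f in gf)
        rows.append(
            {"gene": gene, "Pn": pn, "Ps": len(gv) - pn, "Dn": dn, "Ds": len(gf) - dn}
        )
    return pd.DataFrame(rows, columns=["gene", "Pn", "Ps", "Dn", "Ds"])


def mean_nonsyn_per_genome(
    variants: Sequence[CodingVariant], n_samples: int
) -> float:
    """Mean number of derived nonsynonymous alleles carried per genome.

    The derived allele is the minor allele (or the polarized call when set),
    so each nonsynonymous site contributes its derived-allele count / n.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    uniq = _dedupe_sites([v for v in variants if effect_is_nonsynonymous(v.effect)])
    total = 0
    for v in uniq:
        counts = dict(v.allele_counts)
        if v.derived_allele is not None and v.derived_allele in counts:
            total += counts[v.derived_allele]
        else:
            total += v.minor_count
    return total / n_samples


def variants_to_frame(variants: Sequence[CodingVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "gene": v.gene,
                "aln_position": v.aln_position,
                "codon_index": v.codon_index,
                "codon_position": v.codon_position,
                "ref_codon": v.ref_codon,
                "alt_codon": v.alt_codon,
                "effect": v.effect,
                "pool": v.pool,
                "maf": v.maf,
                "is_singleton": v.is_singleton,
                "derived_allele": v.derived_allele or ".",
                "allele_counts": ";".join(f"{a}:{c}" for a, c in v.allele_counts),
            }
        )
    return pd.DataFrame(rows)


def fixed_to_frame(fixed: Sequence[FixedDifference]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": f.gene,
                "aln_position": f.aln_position,
                "codon_index": f.codon_index,
                "ingroup_codon": f.ingroup_codon,
                "outgroup_codon": f.outgroup_codon,
                "effect": f.effect,
            }
            for f in fixed
        ]
    )
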