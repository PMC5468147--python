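"""Functional-score analysis of amino acid variants.

Externally computed pathogenicity predictions (MutPred-style scores on
[0, 1], SNAP2-style scores on [-100, 100]) are joined to the amino acid
variants actually observed (polymorphisms and fixed differences) and to the
set of all potential variants at the same genes.  Dividing the observed
score distribution by the all-potential distribution gives a relative
"selection function": under purifying selection it decays with predicted
severity, and an exponential y = a*exp(-b*x) fitted to the binned ratio
summarizes the selection gradient (larger b = steeper purifying selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mito_io import (
    STOP,
    AnnotatedAlignment,
    ScoreTable,
    codon_usable,
    extract_codons,
    translate,
)
from .selection_stats import TestResult, fisher_exact_2x2, mannwhitney_u, spearman
from .variant_classify import (
    CodingVariant,
    FixedDifference,
    effect_is_nonsynonymous,
)

log = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

ORIGIN_POLY = "observed_polymorphism"
ORIGIN_FIXED = "fixed_between_species"
ORIGIN_POTENTIAL = "potential"


@dataclass(frozen=True)
class AminoAcidVariant:
    gene: str
    residue_position: int  # 1-based within the protein
    ref_aa: str
    alt_aa: str
    origin: str  # observed_polymorphism | fixed_between_species | potential
    frequency_class: str = "n/a"  # singleton | frequent | fixed | n/a
    direction_note: str = ""  # set for dual-direction / unpolarized cases

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt amino acids must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene, self.residue_position, self.ref_aa, self.alt_aa)


@dataclass
class SelectionCurveFit:
    """Exponential fit y = a*exp(-b*x) to the binned observed/potential ratio."""

    bin_centers: np.ndarray
    ratio_values: np.ndarray
    a: float
    b: float
    adj_r2: float
    n_observed: int
    n_potential: int


# -- variant enumeration ----------------------------------------------------


def consensus_codons(
    aln: AnnotatedAlignment, gene_name: str, samples: Sequence[str] | None = None
) -> list[str]:
    """Majority-rule codon sequence of a gene over the given samples."""
    if samples is None:
        samples = aln.ingroup_samples()
    codons = extract_codons(aln, gene_name)
    out = []
    for ci in range(len(codons[samples[0]])):
        column = [codons[s][ci] for s in samples if codon_usable(codons[s][ci])]
        if not column:
            out.append("NNN")
            continue
        vals, counts = np.unique(column, return_counts=True)
        out.append(str(vals[np.argmax(counts)]))
    return out


def enumerate_potential_variants(
    aln: AnnotatedAlignment,
    gene_name: str,
    mode: str = "all19",
    samples: Sequence[str] | None = None,
) -> list[AminoAcidVariant]:
    """All potential amino acid variants of a gene's consensus protein.

    ``all19``: every other amino acid at every residue.  ``single_nt``: only
    amino acids reachable by a single nucleotide change of the consensus
    codon under the genetic code in force; stop-producing changes excluded.
    """
    if mode not in ("all19", "single_nt"):
        raise ValueError(f"unknown enumeration mode {mode!r}")
    code = aln.genetic_code
    out: list[AminoAcidVariant] = []
    for ci, codon in enumerate(consensus_codons(aln, gene_name, samples)):
        if not codon_usable(codon):
            continue
        ref_aa = translate(codon, code)
        if ref_aa in (STOP, "X"):
            continue
        if mode == "all19":
            alts: Sequence[str] = [a for a in AA_ALPHABET if a != ref_aa]
        else:
            reachable = set()
            for i in range(3):
                for nuc in "ACGT":
                    if nuc == codon[i]:
                        continue
                    aa = translate(codon[:i] + nuc + codon[i + 1 :], code)
                    if aa not in (STOP, ref_aa):
                        reachable.add(aa)
            alts = sorted(reachable)
        for alt in alts:
            out.append(
                AminoAcidVariant(
                    gene=gene_name,
                    residue_position=ci + 1,
                    ref_aa=ref_aa,
                    alt_aa=alt,
                    origin=ORIGIN_POTENTIAL,
                )
            )
    return out


def map_observed_to_protein(
    variants: Sequence[CodingVariant],
    fixed: Sequence[FixedDifference] = (),
    ancestral_aa: Mapping[tuple[str, int], str] | None = None,
    code=None,
) -> list[AminoAcidVariant]:
    """Amino acid records, ancestral -> derived, for nonsynonymous inputs.

    Polymorphisms: the major-allele codon is ancestral and the variant codon
    derived (minor-allele polarization); a variant whose polarization is
    undetermined is emitted with ``direction_note='unpolarized'`` so callers
    can exclude it from directional analyses.  Fixed differences: when an
    externally supplied ancestral amino acid (``ancestral_aa``, keyed by
    (gene, residue)) matches one species' state, a single record in the
    derived direction is emitted; when it differs from both states, two
    records are emitted (one per species) flagged ``dual_direction``; absent
    any ancestral call, the outgroup state is taken as ancestral.
    """
    out: list[AminoAcidVariant] = []
    for v in variants:
        if not effect_is_nonsynonymous(v.effect):
            continue
        ref_aa = translate(v.ref_codon, code)
        alt_aa = translate(v.alt_codon, code)
        if ref_aa == alt_aa:
            continue
        note = ""
        if v.maf == 0.5 and v.derived_allele is None:
            note = "unpolarized"
        elif v.derived_allele is not None and v.derived_allele == v.ref_codon[v.codon_position - 1]:
            # polarization says the major allele is derived: swap direction
            ref_aa, alt_aa = alt_aa, ref_aa
        out.append(
            AminoAcidVariant(
                gene=v.gene,
                residue_position=v.codon_index,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                origin=ORIGIN_POLY,
                frequency_class="singleton" if v.is_singleton else "frequent",
                direction_note=note,
            )
        )
    for f in fixed:
        if not effect_is_nonsynonymous(f.effect):
            continue
        in_aa = translate(f.ingroup_codon, code)
        out_aa = translate(f.outgroup_codon, code)
        if in_aa == out_aa:
            continue
        anc = (ancestral_aa or {}).get((f.gene, f.codon_index))
        if anc is None or anc == out_aa:
            out.append(
                AminoAcidVariant(
                    gene=f.gene,
                    residue_position=f.codon_index,
                    ref_aa=out_aa,
                    alt_aa=in_aa,
                    origin=ORIGIN_FIXED,
                    frequency_class="fixed",
                )
            )
        elif anc == in_aa:
            out.append(
                AminoAcidVariant(
                    gene=f.gene,
                    residue_position=f.codon_index,
                    ref_aa=in_aa,
                    alt_aa=out_aa,
                    origin=ORIGIN_FIXED,
                    frequency_class="fixed",
                )
            )
        else:
            # ancestral state differs from both species: score both directions
            for derived in (in_aa, out_aa):
                if derived == anc:
                    continue
                out.append(
                    AminoAcidVariant(
                        gene=f.gene,
                        residue_position=f.codon_index,
                        ref_aa=anc,
                        alt_aa=derived,
                        origin=ORIGIN_FIXED,
                        frequency_class="fixed",
                        direction_note="dual_direction",
                    )
                )
    return out


# -- score joining -----------------------------------------------------------


def join_scores(
    variants: Sequence[AminoAcidVariant], table: ScoreTable
) -> tuple[pd.DataFrame, list[AminoAcidVariant]]:
    """Inner join of variants with a score table on (gene, pos, ref, alt).

    Returns (scored DataFrame, unmatched variants).  Unmatched variants are
    reported, never silently dropped.
    """
    rows = [
        {
            "gene": v.gene,
            "pos": v.residue_position,
            "ref_aa": v.ref_aa,
            "alt_aa": v.alt_aa,
            "origin": v.origin,
            "frequency_class": v.frequency_class,
            "direction_note": v.direction_note,
        }
        for v in variants
    ]
    vdf = pd.DataFrame(
        rows,
        columns=["gene", "pos", "ref_aa", "alt_aa", "origin", "frequency_class", "direction_note"],
    )
    merged = vdf.merge(table.df, on=["gene", "pos", "ref_aa", "alt_aa"], how="left")
    unmatched_mask = merged["score"].isna()
    unmatched = [variants[i] for i in merged.index[unmatched_mask]]
    if unmatched:
        log.warning(
            "%d of %d variants had no score in the %s table",
            len(unmatched), len(variants), table.dialect,
        )
    scored = merged[~unmatched_mask].reset_index(drop=True)
    scored.attrs["dialect"] = table.dialect
    return scored, unmatched


# -- distributions and the selection function --------------------------------


def kde_density(scores: Sequence[float], grid: Sequence[float]) -> np.ndarray:
    """Gaussian kernel density estimate with Silverman's rule-of-thumb bandwidth."""
    scores = np.asarray(scores, float)
    if len(np.unique(scores)) < 2:
        raise ValueError("KDE requires >= 2 distinct values")
    kde = stats.gaussian_kde(scores, bw_method="silverman")
    return kde(np.asarray(grid, float))


def selection_function(
    observed_scores: Sequence[float],
    potential_scores: Sequence[float],
    n_bins: int = 10,
) -> SelectionCurveFit:
    """Relative selection intensity vs predicted severity, exponential fit.

    Both score samples must already be on the common [0, 1] scale
    (:meth:`ScoreTable.unit_scores`).  Scores are binned into ``n_bins``
    equal-width bins; the per-bin ratio of observed to potential proportions
    is fitted with y = a*exp(-b*x) by nonlinear least squares in linear
    space (zero-ratio bins retained; bins with zero potential mass dropped).
    """
    obs = np.asarray(observed_scores, float)
    pot = np.asarray(potential_scores, float)
    if len(obs) == 0 or len(pot) == 0:
        raise ValueError("both score samples must be non-empty")
    if obs.min() < 0 or obs.max() > 1 or pot.min() < 0 or pot.max() > 1:
        raise ValueError("scores must be normalized to [0, 1] before fitting")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    obs_prop = np.histogram(obs, bins=edges)[0] / len(obs)
    pot_prop = np.histogram(pot, bins=edges)[0] / len(pot)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = pot_prop > 0
    x, y = centers[keep], obs_prop[keep] / pot_prop[keep]
    if len(x) < 3:
        raise ValueError(f"only {len(x)} usable bins; need >= 3 for the fit")

    def model(x, a, b):
        return a * np.exp(-b * x)

    a0 = max(y[0], 1e-6)
    (a, b), _ = optimize.curve_fit(
        model, x, y, p0=(a0, 1.0), maxfev=20_000, bounds=((0, -50), (np.inf, 200))
    )
    resid = y - model(x, a, b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n, p = len(x), 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else r2
    return SelectionCurveFit(
        bin_centers=x,
        ratio_values=y,
        a=float(a),
        b=float(b),
        adj_r2=float(adj_r2),
        n_observed=len(obs),
        n_potential=len(pot),
    )


# -- categorical tests --------------------------------------------------------


DEFAULT_THRESHOLDS = {"mutpred01": ("ge", 0.6), "snap2_100": ("gt", 0.0)}


def categorize_and_test(
    scored: pd.DataFrame,
    dialect: str,
    threshold: tuple[str, float] | None = None,
) -> dict:
    """Singleton-vs-frequent contrast of predicted-harmful fractions.

    ``scored`` is a joined frame from :func:`join_scores` restricted to
    observed polymorphisms.  Builds the 2x2 table
    (singleton, frequent) x (harmful, benign) under the dialect's threshold
    (MutPred >= 0.6, SNAP2 > 0 by default), runs Fisher's exact test, and a
    Mann-Whitney U on the raw scores between the two frequency classes.
    """
    op, cut = threshold if threshold is not None else DEFAULT_THRESHOLDS[dialect]
    df = scored[scored["frequency_class"].isin(["singleton", "frequent"])]
    harmful = df["score"] >= cut if op == "ge" else df["score"] > cut
    singles = df["frequency_class"] == "singleton"
    table = [
        [int((singles & harmful).sum()), int((singles & ~harmful).sum())],
        [int((~singles & harmful).sum()), int((~singles & ~harmful).sum())],
    ]
    fisher = fisher_exact_2x2(table)
    result = {"table": table, "fisher": fisher, "dialect": dialect, "threshold": (op, cut)}
    x = df.loc[singles, "score"].to_numpy()
    y = df.loc[~singles, "score"].to_numpy()
    if len(x) >= 2 and len(y) >= 2:
        result["mannwhitney"] = mannwhitney_u(x, y)
    return result


def scorer_agreement(
    scored_a: pd.DataFrame, scored_b: pd.DataFrame
) -> TestResult:
    """Spearman correlation between two scorers on their shared variants."""
    merged = scored_a.merge(
        scored_b,
        on=["gene", "pos", "ref_aa", "alt_aa"],
        suffixes=("_a", "_b"),
    )
    return spearman(merged["score_a"].to_numpy(), merged["score_b"].to_numpy())
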