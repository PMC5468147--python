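"""Reading, writing and codon-level access for annotated mitogenome alignments.

The central container is :class:`AnnotatedAlignment`: a multiple alignment of
complete mitochondrial genomes together with protein-coding gene models,
per-sample pool (habitat) labels, and the genetic code in force.  All coding
analyses in this package run under the vertebrate mitochondrial code
(NCBI translation table 2: TGA=Trp, ATA=Met, AGA/AGG=stop).

Coordinates in annotation files are 1-based inclusive, following the GenBank
feature-table convention; internally everything is converted to 0-based
half-open offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STOP = "*"
UNKNOWN = "X"
VALID_CHARS = frozenset("ACGTN-")
NUCLEOTIDES = ("A", "C", "G", "T")
OUTGROUP_POOL = "outgroup"

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

SCORE_DIALECTS = {
    "mutpred01": (0.0, 1.0),
    "snap2_100": (-100.0, 100.0),
}


def vertebrate_mito_code() -> dict[str, str]:
    """Codon -> one-letter amino acid map for translation table 2 ('*' = stop)."""
    table = CodonTable.unambiguous_dna_by_id[2]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = STOP
    return code


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(codon: str, code: Mapping[str, str] | None = None) -> str:
    """Translate a single codon; N or gap characters yield ``UNKNOWN``.

    Raises ``ValueError`` for codons that are not exactly 3 characters.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if code is None:
        code = vertebrate_mito_code()
    codon = codon.upper()
    if any(c not in "ACGT" for c in codon):
        return UNKNOWN
    return code[codon]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene on the mitogenome alignment.

    ``start``/``end`` are 1-based inclusive alignment coordinates.  A trailing
    incomplete codon (1-2 nt, completed by polyadenylation in vivo) is allowed
    and dropped during codon extraction.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.name}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be '+' or '-'")
        if not 0 <= self.reading_frame_offset <= 2:
            raise ValueError(f"gene {self.name}: reading_frame_offset must be 0-2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        return (self.length - self.reading_frame_offset) // 3

    def codon_positions(self, codon_index: int) -> tuple[int, int, int]:
        """1-based alignment positions of the three bases of a codon.

        ``codon_index`` is 1-based.  For minus-strand genes the codon reads
        from ``end`` toward ``start``, so positions descend.
        """
        if not 1 <= codon_index <= self.n_codons:
            raise ValueError(f"codon index {codon_index} out of range for {self.name}")
        k = 3 * (codon_index - 1)
        if self.strand == "+":
            p = self.start + self.reading_frame_offset + k
            return (p, p + 1, p + 2)
        p = self.end - self.reading_frame_offset - k
        return (p, p - 1, p - 2)


@dataclass
class AnnotatedAlignment:
    """Aligned mitogenomes + gene models + pool labels + genetic code."""

    sequences: dict[str, str]
    pools: dict[str, str]
    genes: list[GeneModel]
    genetic_code: dict[str, str] = field(default_factory=vertebrate_mito_code)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.sequences:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        length = lengths.pop()
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene names in annotation")
        for g in self.genes:
            if g.start < 1 or g.end > length:
                raise ValueError(
                    f"gene {g.name} ({g.start}..{g.end}) outside alignment of length {length}"
                )
        for sample in self.sequences:
            if sample not in self.pools:
                raise ValueError(f"sample {sample!r} missing from pool map")
        if not any(p != OUTGROUP_POOL for s, p in self.pools.items() if s in self.sequences):
            raise ValueError("at least one non-outgroup pool must be non-empty")

    # -- sample access ----------------------------------------------------

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def samples(self) -> list[str]:
        return list(self.sequences)

    def pool_samples(self, pool: str) -> list[str]:
        out = [s for s in self.sequences if self.pools[s] == pool]
        if not out:
            raise ValueError(f"unknown or empty pool {pool!r}")
        return out

    @property
    def pool_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.sequences:
            p = self.pools[s]
            if p not in seen:
                seen.append(p)
        return seen

    def ingroup_samples(self) -> list[str]:
        return [s for s in self.sequences if self.pools[s] != OUTGROUP_POOL]

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"gene {name!r} not in annotation")

    def subset(self, samples: Sequence[str]) -> "AnnotatedAlignment":
        return AnnotatedAlignment(
            sequences={s: self.sequences[s] for s in samples},
            pools={s: self.pools[s] for s in samples},
            genes=list(self.genes),
            genetic_code=self.genetic_code,
        )

    def usable_columns(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask of columns where every given sample has A/C/G/T.

        Columns failing this (gap or N in any member: complete deletion) are
        excluded from variant counting and from the effective length L.
        """
        if samples is None:
            samples = self.ingroup_samples()
        mask = np.ones(self.length, dtype=bool)
        for s in samples:
            arr = np.frombuffer(self.sequences[s].encode(), dtype="S1")
            ok = (arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")
            mask &= ok
        return mask


def extract_codons(aln: AnnotatedAlignment, gene_name: str) -> dict[str, list[str]]:
    """Per-sample codon strings for one gene, in translation orientation.

    Minus-strand genes are reverse-complemented before slicing.  A trailing
    incomplete codon is dropped.  Codons containing N or '-' are retained in
    the list (so indices line up across samples) but are unusable for
    classification; callers test with :func:`codon_usable`.
    """
    gene = aln.gene(gene_name)
    out: dict[str, list[str]] = {}
    for sample, seq in aln.sequences.items():
        region = seq[gene.start - 1 : gene.end]
        if gene.strand == "-":
            region = reverse_complement(region)
        region = region[gene.reading_frame_offset :]
        n = len(region) - len(region) % 3
        out[sample] = [region[i : i + 3] for i in range(0, n, 3)]
    return out


def codon_usable(codon: str) -> bool:
    return all(c in "ACGT" for c in codon)


# -- readers -------------------------------------------------------------


def _clean_sequence(sample: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_CHARS
    if bad:
        log.warning(
            "sample %s: %d non-ACGTN- characters (%s) mapped to N",
            sample,
            sum(seq.count(c) for c in bad),
            "".join(sorted(bad)),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in bad}))
    return seq


def read_alignment(
    fasta_path: str | Path,
    annotation_path: str | Path,
    pools_path: str | Path,
) -> AnnotatedAlignment:
    """Read a FASTA alignment plus gene-annotation and pool-label TSVs.

    Annotation columns: name, start, end, strand (1-based inclusive
    coordinates, GenBank convention), optional reading_frame_offset.
    Pools columns: sample, pool.
    """
    sequences = {
        rec.id: _clean_sequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not sequences:
        raise ValueError(f"no sequences in {fasta_path}")
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"name": str})
    genes = [
        GeneModel(
            name=row["name"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            reading_frame_offset=int(row.get("reading_frame_offset", 0) or 0),
        )
        for _, row in ann.iterrows()
    ]
    pools_df = pd.read_csv(pools_path, sep="\t", dtype=str)
    pools = dict(zip(pools_df["sample"], pools_df["pool"]))
    for sample in sequences:
        if sample not in pools:
            raise ValueError(f"sample {sample!r} missing from pool map {pools_path}")
    return AnnotatedAlignment(sequences=sequences, pools=pools, genes=genes)


def write_alignment(
    aln: AnnotatedAlignment,
    fasta_path: str | Path,
    annotation_path: str | Path,
    pools_path: str | Path,
) -> None:
    records = [
        SeqRecord(Seq(seq), id=sample, description="") for sample, seq in aln.sequences.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "name": [g.name for g in aln.genes],
            "start": [g.start for g in aln.genes],
            "end": [g.end for g in aln.genes],
            "strand": [g.strand for g in aln.genes],
            "reading_frame_offset": [g.reading_frame_offset for g in aln.genes],
        }
    ).to_csv(annotation_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample": list(aln.sequences), "pool": [aln.pools[s] for s in aln.sequences]}
    ).to_csv(pools_path, sep="\t", index=False)


# -- functional score tables ----------------------------------------------


@dataclass
class ScoreTable:
    """Per-amino-acid-variant functional scores from one external predictor.

    ``dialect`` declares the score scale: ``mutpred01`` (pathogenicity
    probability on [0, 1]) or ``snap2_100`` (effect score on [-100, 100]).
    """

    df: pd.DataFrame  # columns: gene, pos, ref_aa, alt_aa, score
    dialect: str

    COLUMNS = ("gene", "pos", "ref_aa", "alt_aa", "score")

    def __post_init__(self) -> None:
        if self.dialect not in SCORE_DIALECTS:
            raise ValueError(f"unknown score dialect {self.dialect!r}")
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        lo, hi = SCORE_DIALECTS[self.dialect]
        bad = self.df[(self.df["score"] < lo) | (self.df["score"] > hi)]
        if len(bad):
            first = bad.index[0]
            raise ValueError(
                f"score {bad.loc[first, 'score']} out of [{lo}, {hi}] "
                f"for dialect {self.dialect} (row index {first})"
            )
        keys = self.df[["gene", "pos", "ref_aa", "alt_aa"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant key {tuple(dup)} in score table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)

    def unit_scores(self) -> np.ndarray:
        """Scores mapped to the common [0, 1] scale used for curve fitting."""
        s = self.scores
        if self.dialect == "snap2_100":
            return (s + 100.0) / 200.0
        return s


def read_scores(tsv_path: str | Path, dialect: str) -> ScoreTable:
    df = pd.read_csv(tsv_path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    try:
        return ScoreTable(df=df[list(ScoreTable.COLUMNS)].copy(), dialect=dialect)
    except ValueError as exc:
        raise ValueError(f"{tsv_path}: {exc}") from exc


def write_scores(table: ScoreTable, tsv_path: str | Path) -> None:
    table.df.to_csv(tsv_path, sep="\t", index=False)


def write_results(obj, path: str | Path) -> None:
    """Write a DataFrame as TSV, or a flat mapping as a key<TAB>value report."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, Mapping):
        with open(path, "w") as fh:
            for key, value in obj.items():
                fh.write(f"{key}\t{value}\n")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
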