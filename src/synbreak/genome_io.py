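"""Domain types and file I/O for the rearrangement pipeline.

Coordinates on sequences are 1-based inclusive (GFF convention)
throughout; permutation and window indices used internally by other
modules are 0-based.  Genes wrapping the circular origin (end < start)
are rejected: the synthetic generator never emits them and midpoint
arithmetic assumes start <= end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Gene",
    "GenomeRecord",
    "SpeciesSet",
    "Alignment",
    "FormatError",
    "ValidationError",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_phylip_square",
    "write_tsv_report",
]

GENE_TABLE_COLUMNS = [
    "genome_id",
    "species_id",
    "circular",
    "length_bp",
    "gene_id",
    "family_id",
    "strand",
    "start",
    "end",
    "cog_id",
    "cog_category",
    "is_transposase",
]


class FormatError(ValueError):
    """A file does not match the expected layout (missing columns, ragged alignment...)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (bad strand, end < start...)."""


@dataclass(frozen=True)
class Gene:
    """A gene annotation on a genome.

    ``family_id`` is the ortholog family assignment ('' if unassigned,
    i.e. a singleton/unclustered gene).  ``cog_id``/``cog_category``
    carry the COG functional annotation ('' when unannotated).
    """

    gene_id: str
    family_id: str
    strand: str
    start: int
    end: int
    cog_id: str = ""
    cog_category: str = ""
    is_transposase: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id!r}: start must be >= 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start}); "
                "origin-wrapping genes are not supported"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GenomeRecord:
    """One genome: ordered gene annotations plus optional nucleotide sequence."""

    genome_id: str
    species_id: str
    circular: bool
    length_bp: int
    genes: list[Gene] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValidationError(
                f"genome {self.genome_id!r}: sequence length {len(self.sequence)} "
                f"!= length_bp {self.length_bp}"
            )


@dataclass
class SpeciesSet:
    """All genomes of one species, plus an optional core-alignment handle."""

    species_id: str
    genomes: list[GenomeRecord]
    alignment: "Alignment | None" = None

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"species {self.species_id!r}: duplicate genome_ids")
        for g in self.genomes:
            if g.species_id != self.species_id:
                raise ValidationError(
                    f"genome {g.genome_id!r} has species_id {g.species_id!r}, "
                    f"expected {self.species_id!r}"
                )

    def genome(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


@dataclass
class Alignment:
    """A concatenated core-genome nucleotide alignment (gap character '-')."""

    rows: dict[str, str]
    length: int

    def __post_init__(self) -> None:
        for gid, seq in self.rows.items():
            if len(seq) != self.length:
                raise FormatError(
                    f"alignment row {gid!r} has length {len(seq)}, expected {self.length}"
                )

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.rows

    def __getitem__(self, genome_id: str) -> str:
        return self.rows[genome_id]


def _parse_bool(value: str, *, line: int, column: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise FormatError(f"line {line}: column {column!r}: cannot parse boolean {value!r}")


def read_gene_table(path) -> list[GenomeRecord]:
    """Read a gene table TSV into GenomeRecords (one per genome_id).

    The TSV must carry the columns in :data:`GENE_TABLE_COLUMNS`.
    Genes come back sorted by start coordinate.  Malformed rows are
    reported with their 1-based file line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: dict[str, GenomeRecord] = {}
    genes_by_genome: dict[str, list[Gene]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        gid = row.genome_id
        try:
            gene = Gene(
                gene_id=row.gene_id,
                family_id=row.family_id,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                cog_id=row.cog_id,
                cog_category=row.cog_category,
                is_transposase=_parse_bool(
                    row.is_transposase, line=line, column="is_transposase"
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {line}: {exc}") from exc
        except (TypeError, OverflowError) as exc:
            raise FormatError(f"{path} line {line}: {exc}") from exc
        if gid not in records:
            records[gid] = GenomeRecord(
                genome_id=gid,
                species_id=row.species_id,
                circular=_parse_bool(row.circular, line=line, column="circular"),
                length_bp=int(row.length_bp),
            )
        genes_by_genome.setdefault(gid, []).append(gene)

    out = []
    for gid, rec in records.items():
        out.append(
            GenomeRecord(
                genome_id=rec.genome_id,
                species_id=rec.species_id,
                circular=rec.circular,
                length_bp=rec.length_bp,
                genes=genes_by_genome[gid],
            )
        )
    return out


def write_gene_table(records: list[GenomeRecord], path) -> None:
    """Write GenomeRecords to the gene table TSV (round-trips through read_gene_table)."""
    rows = []
    for rec in records:
        for g in rec.genes:
            rows.append(
                {
                    "genome_id": rec.genome_id,
                    "species_id": rec.species_id,
                    "circular": rec.circular,
                    "length_bp": rec.length_bp,
                    "gene_id": g.gene_id,
                    "family_id": g.family_id,
                    "strand": g.strand,
                    "start": g.start,
                    "end": g.end,
                    "cog_id": g.cog_id,
                    "cog_category": g.cog_category,
                    "is_transposase": g.is_transposase,
                }
            )
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {genome_id: uppercase sequence}; id = first header token."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gid, seq in sequences.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA; all rows must have identical length."""
    rows = read_fasta(path)
    if not rows:
        raise FormatError(f"{path}: empty alignment")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    return Alignment(rows=rows, length=lengths.pop())


def read_phylip_square(path) -> tuple[list[str], np.ndarray]:
    """Read a square PHYLIP distance matrix -> (ids, n x n float array).

    Hook for plugging externally computed (e.g. maximum-likelihood)
    pairwise distances into the rate calculation in place of raw
    substitution counts.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(tokens[0])
    except ValueError as exc:
        raise FormatError(f"{path}: first token must be the taxon count") from exc
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise FormatError(
            f"{path}: expected {expected} whitespace tokens for a square "
            f"{n}-taxon matrix, found {len(tokens)}"
        )
    ids, mat = [], np.zeros((n, n))
    pos = 1
    for i in range(n):
        ids.append(tokens[pos])
        pos += 1
        mat[i] = [float(t) for t in tokens[pos : pos + n]]
        pos += n
    if not np.allclose(mat, mat.T):
        raise FormatError(f"{path}: matrix is not symmetric")
    return ids, mat


def write_tsv_report(records: list[dict], path, columns: list[str] | None = None) -> None:
    """Write a list of dict rows as a TSV with a deterministic column order."""
    if columns is None:
        columns = list(records[0].keys()) if records else []
    pd.DataFrame(records, columns=columns).to_csv(path, sep="\t", index=False)


def read_tsv_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
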