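"""Core-genome calling and projection of genomes to signed core-gene permutations.

The core genome of a species is the set of ortholog families present in
at least a threshold fraction of its genomes (default 90%) and strictly
single-copy: any family duplicated in any genome is excluded entirely,
since a paralogous copy would make gene order ambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome_io import GenomeRecord, SpeciesSet, ValidationError

__all__ = ["CoreGenome", "CoreOrder", "call_core_families", "project_core_order"]


class EmptyCoreError(ValueError):
    """No ortholog family satisfies the core criteria."""


@dataclass
class CoreGenome:
    species_id: str
    core_families: list[str]  # deterministic (sorted) order
    freq_threshold: float

    @property
    def C(self) -> int:
        """Number of core families (the C of the rate formula)."""
        return len(self.core_families)

    def __contains__(self, family_id: str) -> bool:
        return family_id in self._family_set

    def __post_init__(self) -> None:
        self._family_set = set(self.core_families)


@dataclass
class CoreOrder:
    """A genome reduced to its signed circular permutation of core families.

    ``perm[i]`` is (family_id, sign) with sign +1/-1 from the gene's
    annotated strand.  ``positions_bp[i]`` is the gene midpoint,
    ``gene_index[i]`` the index into the genome's full gene list, and
    ``accessory_after[i]`` the number of non-core genes between core
    gene i and core gene i+1 (circularly).
    """

    genome_id: str
    perm: list[tuple[str, int]]
    positions_bp: list[float]
    gene_index: list[int]
    accessory_after: list[int]
    circular: bool
    genome_length_bp: int

    def __len__(self) -> int:
        return len(self.perm)


def call_core_families(species: SpeciesSet, freq: float = 0.90) -> CoreGenome:
    """Call the species core gene set at the given frequency threshold.

    A family is core iff it occurs in >= freq * n_genomes genomes
    (inclusive threshold) and is single-copy in every genome where it
    occurs.  Families duplicated anywhere are excluded outright.
    """
    n = len(species.genomes)
    if n < 2:
        raise ValidationError("core calling needs at least 2 genomes")
    presence: Counter[str] = Counter()
    duplicated: set[str] = set()
    for genome in species.genomes:
        counts = Counter(g.family_id for g in genome.genes if g.family_id)
        for fam, c in counts.items():
            presence[fam] += 1
            if c > 1:
                duplicated.add(fam)
    core = sorted(
        fam
        for fam, npres in presence.items()
        if fam not in duplicated and npres >= freq * n
    )
    if not core:
        raise EmptyCoreError(
            f"species {species.species_id!r}: no family passes freq>={freq} single-copy"
        )
    return CoreGenome(species_id=species.species_id, core_families=core, freq_threshold=freq)


def project_core_order(genome: GenomeRecord, core: CoreGenome) -> CoreOrder:
    """Project a genome onto its core-gene permutation.

    Accessory genes are skipped, but the count per inter-core interval
    is retained so blocks can later report their total (core+accessory)
    gene content.
    """
    perm: list[tuple[str, int]] = []
    positions: list[float] = []
    gene_index: list[int] = []
    accessory_counts: list[int] = []
    acc_pending = 0
    leading_acc = 0
    seen_core = False
    for idx, gene in enumerate(genome.genes):
        if gene.family_id and gene.family_id in core:
            perm.append((gene.family_id, +1 if gene.strand == "+" else -1))
            positions.append(gene.midpoint)
            gene_index.append(idx)
            if seen_core:
                accessory_counts.append(acc_pending)
            else:
                leading_acc = acc_pending
                seen_core = True
            acc_pending = 0
        else:
            acc_pending += 1
    if len(perm) < 2:
        raise ValidationError(
            f"genome {genome.genome_id!r} carries {len(perm)} core families; need >= 2"
        )
    # interval after the last core gene wraps to before the first one
    accessory_counts.append(acc_pending + leading_acc)
    return CoreOrder(
        genome_id=genome.genome_id,
        perm=perm,
        positions_bp=positions,
        gene_index=gene_index,
        accessory_after=accessory_counts,
        circular=genome.circular,
        genome_length_bp=genome.length_bp,
    )
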