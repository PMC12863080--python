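"""COG functional enrichment of rearranged blocks.

Block gene content — core genes plus the accessory genes interleaved
between them — is compared against the gene content of all genomes of
the species with a per-COG chi-square test and Benjamini-Hochberg
correction.  As in the source contingency layout, the genome-wide
column counts every gene of every genome, including the genes inside
the rearranged blocks; the ``disjoint`` flag subtracts block genes from
the genome-wide side for the orthodox disjoint table.

Excluded from the block side: single-block genomes (no rearrangement),
backbone blocks (the unrearranged frame), and blocks whose identity
occurs more than twice across the pooled pairs (deduplication).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_kernel
from .block_finder import (
    INVERSION,
    TRANSLOCATION,
    Block,
    BlockPartition,
    classify_block,
    dedup_blocks,
    rearranged_blocks,
)
from .genome_io import Gene, GenomeRecord, SpeciesSet

__all__ = [
    "COGContingency",
    "EnrichmentResult",
    "block_gene_entries",
    "count_cogs",
    "chi2_enrichment",
    "functional_composition",
    "transposase_correlation",
]


@dataclass
class COGContingency:
    cog: str
    a: int  # this COG in rearranged blocks
    b: int  # other COGs in rearranged blocks
    c: int  # this COG genome-wide
    d: int  # other COGs genome-wide
    scope: str = "all"
    gene_class: str = "both"


@dataclass
class EnrichmentResult:
    cog: str
    chi2: float
    p: float
    q: float
    enriched: bool
    low_count: bool = False
    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0


def block_genes(block: Block, genome: GenomeRecord) -> list[Gene]:
    """All genes (core and accessory) in the circular genome slice a block spans."""
    if block.query_gene_range is None:
        raise ValueError("block carries no gene range (simulation-only partition)")
    first, last = block.query_gene_range
    n = len(genome.genes)
    span = (last - first) % n + 1
    return [genome.genes[(first + t) % n] for t in range(span)]


def block_gene_entries(
    species: SpeciesSet,
    partitions: dict[str, BlockPartition],
    dedup: bool = True,
) -> list[tuple[GenomeRecord, Block, str]]:
    """(genome, block, event class) for every retained rearranged block.

    Applies the analysis exclusions: single-block genomes, backbone
    blocks, and (optionally) block identities pooled more than twice.
    """
    candidates: list[tuple[str, Block, str]] = []
    for qid, part in partitions.items():
        if part.n_blocks <= 1:
            continue  # no rearrangement to attribute
        for blk in rearranged_blocks(part):
            candidates.append((qid, blk, classify_block(blk, part)))
    if dedup:
        kept = set(id(b) for b in dedup_blocks([b for _q, b, _c in candidates]))
        candidates = [(q, b, c) for q, b, c in candidates if id(b) in kept]
    return [(species.genome(qid), blk, cls) for qid, blk, cls in candidates]


def _gene_filter(gene_class: str, core_families: set[str] | None):
    if gene_class == "both":
        return lambda g: True
    if core_families is None:
        raise ValueError("core/accessory filtering needs the core family set")
    if gene_class == "core":
        return lambda g: g.family_id in core_families
    if gene_class == "accessory":
        return lambda g: g.family_id not in core_families
    raise ValueError(f"unknown gene_class {gene_class!r}")


def _cog_label(gene: Gene, level: str) -> str:
    return gene.cog_category if level == "category" else gene.cog_id


def count_cogs(
    species: SpeciesSet,
    partitions: dict[str, BlockPartition],
    scope: str = "all",
    gene_class: str = "both",
    level: str = "category",
    core_families: set[str] | None = None,
    disjoint: bool = False,
    dedup: bool = True,
) -> list[COGContingency]:
    """Build one 2x2 contingency table per COG (id or one-letter category).

    ``scope`` restricts the block side to {'translocation', 'inversion',
    'all'}.  Unannotated genes count toward the 'other' cells but are
    not themselves tested.
    """
    if scope not in ("translocation", "inversion", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    keep = _gene_filter(gene_class, core_families)
    entries = block_gene_entries(species, partitions, dedup=dedup)

    block_counts: dict[str, int] = {}
    block_total = 0
    for genome, blk, cls in entries:
        if scope != "all" and cls != scope:
            continue
        for g in block_genes(blk, genome):
            if not keep(g):
                continue
            block_total += 1
            label = _cog_label(g, level)
            if label:
                block_counts[label] = block_counts.get(label, 0) + 1

    if block_total == 0:
        import logging

        logging.getLogger(__name__).warning(
            "species %s: no non-backbone block genes in scope %r; nothing to test",
            species.species_id,
            scope,
        )
        return []

    genome_counts: dict[str, int] = {}
    genome_total = 0
    for genome in species.genomes:
        for g in genome.genes:
            if not keep(g):
                continue
            genome_total += 1
            label = _cog_label(g, level)
            if label:
                genome_counts[label] = genome_counts.get(label, 0) + 1

    if disjoint:
        genome_total -= block_total
        for label, cnt in block_counts.items():
            genome_counts[label] = genome_counts.get(label, 0) - cnt

    tables = []
    for label in sorted(set(block_counts) | set(genome_counts)):
        a = block_counts.get(label, 0)
        c = genome_counts.get(label, 0)
        tables.append(
            COGContingency(
                cog=label,
                a=a,
                b=block_total - a,
                c=c,
                d=genome_total - c,
                scope=scope,
                gene_class=gene_class,
            )
        )
    return tables


def chi2_enrichment(tables: list[COGContingency], alpha: float = 0.05) -> list[EnrichmentResult]:
    """Per-COG chi-square with BH correction across the supplied tables.

    A COG is enriched when its adjusted p falls below ``alpha`` and its
    frequency in blocks exceeds its genome-wide frequency.
    """
    if not tables:
        return []
    stats = [stats_kernel.chi2_2x2(t.a, t.b, t.c, t.d) for t in tables]
    qvals = stats_kernel.bh_adjust([s.p_value for s in stats])
    out = []
    for t, s, q in zip(tables, stats, qvals):
        freq_block = t.a / (t.a + t.b) if (t.a + t.b) else 0.0
        freq_genome = t.c / (t.c + t.d) if (t.c + t.d) else 0.0
        out.append(
            EnrichmentResult(
                cog=t.cog,
                chi2=s.statistic,
                p=s.p_value,
                q=float(q),
                enriched=bool(q < alpha and freq_block > freq_genome),
                low_count="low expected count" in s.note or "degenerate" in s.method,
                a=t.a, b=t.b, c=t.c, d=t.d,
            )
        )
    return out


UNANNOTATED = "unannotated"


def functional_composition(
    species: SpeciesSet,
    partitions: dict[str, BlockPartition],
    dedup: bool = True,
) -> pd.DataFrame:
    """Per-category gene frequencies for translocated blocks, inverted
    blocks, non-rearranged regions, and all genomes; columns sum to 1.
    Unannotated genes are reported as their own category."""
    entries = block_gene_entries(species, partitions, dedup=dedup)
    cols: dict[str, list[str]] = {
        TRANSLOCATION: [],
        INVERSION: [],
        "non_rearranged": [],
        "all_genomes": [],
    }
    in_block_ids: dict[str, set[int]] = {}
    for genome, blk, cls in entries:
        genes = block_genes(blk, genome)
        cols[cls].extend(g.cog_category or UNANNOTATED for g in genes)
        first, last = blk.query_gene_range
        n = len(genome.genes)
        span = (last - first) % n + 1
        in_block_ids.setdefault(genome.genome_id, set()).update(
            (first + t) % n for t in range(span)
        )
    for genome in species.genomes:
        blocked = in_block_ids.get(genome.genome_id, set())
        for i, g in enumerate(genome.genes):
            cols["all_genomes"].append(g.cog_category or UNANNOTATED)
            if i not in blocked:
                cols["non_rearranged"].append(g.cog_category or UNANNOTATED)
    frames = {}
    for name, labels in cols.items():
        if not labels:
            continue  # empty scope: column omitted
        counts = pd.Series(labels).value_counts()
        frames[name] = counts / counts.sum()
    return pd.DataFrame(frames).fillna(0.0).sort_index()


def transposase_correlation(summaries: list[dict]) -> stats_kernel.TestResult:
    """Spearman correlation between species-level mean block counts and
    mean length-normalized transposase counts.

    Each summary dict needs ``mean_blocks`` and
    ``mean_transposases_per_bp``.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 species for a correlation")
    x = np.array([s["mean_transposases_per_bp"] for s in summaries], dtype=float)
    y = np.array([s["mean_blocks"] for s in summaries], dtype=float)
    return stats_kernel.spearman(x, y)
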