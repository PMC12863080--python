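"""Syntenic core-gene block finding on signed circular permutations.

A block is a maximal run of core genes that are consecutive — in the
same order, or fully reversed with flipped strands — in both genomes of
a pair.  Block boundaries are breakpoints: adjacencies present in one
genome but not the other.  Circular adjacency (last element next to
first) is honored on both genomes, which is what makes one inversion
split a genome into 2 blocks and one interior translocation into 3.

Internally a query is reduced, against a reference, to arrays
``(pos, sign)``: ``pos[j]`` is the reference index of the j-th shared
core gene in query order and ``sign[j]`` its strand relative to the
reference copy.  The adjacency j -> j+1 is conserved iff
``sign[j] == sign[j+1]`` and ``pos[j+1] == (pos[j] + sign[j]) mod m``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_genome import CoreOrder
from .genome_io import ValidationError

__all__ = [
    "Block",
    "BlockPartition",
    "SpeciesBlockSummary",
    "find_blocks",
    "classify_block",
    "select_reference",
    "rearranged_blocks",
    "dedup_blocks",
    "summarize_species",
    "count_blocks_raw",
]

logger = logging.getLogger(__name__)

INVERSION = "inversion"
TRANSLOCATION = "translocation"


@dataclass
class Block:
    families: list[tuple[str, int]]  # (family_id, query strand sign), query order
    n_core: int
    n_total_genes: int
    ref_span: tuple[float, float]
    query_span: tuple[float, float]
    orientation: str  # "forward" | "reverted" (relative to the reference)
    is_backbone: bool
    midpoint_bp: float
    identity_key: tuple
    n_sign_flipped: int = 0
    query_gene_range: tuple[int, int] | None = None  # circular slice into genome.genes


@dataclass
class BlockPartition:
    ref_id: str
    query_id: str
    blocks: list[Block]
    n_singletons_discarded: int
    n_shared_core: int
    query_flipped: bool = False

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def classifications(self) -> dict[int, str]:
        return {
            i: classify_block(b, self)
            for i, b in enumerate(self.blocks)
            if not b.is_backbone
        }


@dataclass
class SpeciesBlockSummary:
    species_id: str
    reference_id: str
    n_blocks_per_genome: dict[str, int]
    mean_blocks: float
    block_lengths_genes: list[int] = field(default_factory=list)
    inversions_per_genome: dict[str, int] = field(default_factory=dict)
    translocations_per_genome: dict[str, int] = field(default_factory=dict)


def canonical_identity_key(families: list[tuple[str, int]]) -> tuple:
    """Orientation-normalized key: min of the forward tuple and the reversed
    sign-flipped tuple, so a block and its reverse-complement listing match."""
    fwd = tuple(families)
    rev = tuple((f, -s) for f, s in reversed(families))
    return min(fwd, rev)


def _relative_arrays(
    ref: CoreOrder, qry: CoreOrder
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Reduce query to (pos, sign) arrays relative to the reference.

    Returns reference positions and relative signs for the shared core
    families in query order, plus the query-perm indices they came from.
    """
    ref_pos = {fam: i for i, (fam, _s) in enumerate(ref.perm)}
    ref_sign = {fam: s for fam, s in ref.perm}
    shared = [
        (j, fam, s) for j, (fam, s) in enumerate(qry.perm) if fam in ref_pos
    ]
    # positions are re-indexed over shared families only, preserving ref order
    shared_fams = {fam for _j, fam, _s in shared}
    ref_rank = {}
    r = 0
    for fam, _s in ref.perm:
        if fam in shared_fams:
            ref_rank[fam] = r
            r += 1
    pos = np.array([ref_rank[fam] for _j, fam, _s in shared], dtype=np.int64)
    sign = np.array([s * ref_sign[fam] for _j, fam, s in shared], dtype=np.int64)
    qidx = [j for j, _fam, _s in shared]
    return pos, sign, qidx


def _conserved_adjacencies(pos: np.ndarray, sign: np.ndarray, circular: bool) -> np.ndarray:
    """Boolean array: adjacency j -> j+1 conserved (length m if circular, m-1 if not)."""
    m = len(pos)
    if circular:
        nxt_pos = np.roll(pos, -1)
        nxt_sign = np.roll(sign, -1)
        return (sign == nxt_sign) & (nxt_pos == (pos + sign) % m)
    return (sign[:-1] == sign[1:]) & (pos[1:] == pos[:-1] + sign[:-1])


def _runs(conserved: np.ndarray, m: int, circular: bool) -> list[list[int]]:
    """Maximal runs of elements joined by conserved adjacencies, as index lists."""
    if m == 0:
        return []
    if circular:
        bps = np.nonzero(~conserved)[0]  # breakpoint after element j
        if len(bps) == 0:
            return [list(range(m))]
        runs = []
        for i, b in enumerate(bps):
            start = (b + 1) % m
            nxt = bps[(i + 1) % len(bps)]
            length = (nxt - start) % m + 1
            runs.append([(start + t) % m for t in range(length)])
        return runs
    runs, cur = [], [0]
    for j in range(m - 1):
        if conserved[j]:
            cur.append(j + 1)
        else:
            runs.append(cur)
            cur = [j + 1]
    runs.append(cur)
    return runs


def count_blocks_raw(perm: np.ndarray, circular: bool = True) -> tuple[int, int]:
    """Retained-block and discarded-singleton counts of a signed permutation
    against the identity reference (+1..+C).

    ``perm`` holds signed integers with absolute values 1..C.  This is
    the fast path used by the rearrangement simulations; `find_blocks`
    produces the same counts on full CoreOrder inputs.
    """
    perm = np.asarray(perm, dtype=np.int64)
    m = len(perm)
    pos = np.abs(perm) - 1
    sign = np.sign(perm)
    conserved = _conserved_adjacencies(pos, sign, circular)
    if circular and bool(conserved.all()):
        return 1, 0
    runs = _runs(conserved, m, circular)
    retained = sum(1 for r in runs if len(r) >= 2)
    singletons = sum(1 for r in runs if len(r) == 1)
    return retained, singletons


def _flip_order(order: CoreOrder) -> CoreOrder:
    """The same genome read on the opposite strand (reverse order, flip signs)."""
    n = len(order.perm)
    idx = list(range(n - 1, -1, -1))
    acc = [order.accessory_after[(i - 1) % n] for i in idx]
    return CoreOrder(
        genome_id=order.genome_id,
        perm=[(f, -s) for f, s in (order.perm[i] for i in idx)],
        positions_bp=[order.positions_bp[i] for i in idx],
        gene_index=[order.gene_index[i] for i in idx],
        accessory_after=acc,
        circular=order.circular,
        genome_length_bp=order.genome_length_bp,
    )


def _circular_midpoint(p1: float, p2: float, length: float) -> float:
    return (p1 + ((p2 - p1) % length) / 2.0) % length


def _build_partition(ref: CoreOrder, qry: CoreOrder, flipped: bool) -> BlockPartition:
    pos, sign, qidx = _relative_arrays(ref, qry)
    m = len(pos)
    if m < 2:
        raise ValidationError(
            f"pair ({ref.genome_id}, {qry.genome_id}): fewer than 2 shared core families"
        )
    circular = ref.circular and qry.circular
    conserved = _conserved_adjacencies(pos, sign, circular)
    if circular and bool(conserved.all()):
        runs = [list(range(m))]
    else:
        runs = _runs(conserved, m, circular)

    n_genes_total = len(qry.perm) + sum(qry.accessory_after)
    ref_posbp = {fam: p for (fam, _s), p in zip(ref.perm, ref.positions_bp)}
    blocks: list[Block] = []
    singletons = 0
    for run in runs:
        if len(run) < 2:
            singletons += 1
            continue
        # in a flipped query view, runs traverse the genome in decreasing
        # gene index: physical span endpoints swap
        if flipped:
            q_first, q_last = qidx[run[-1]], qidx[run[0]]
        else:
            q_first, q_last = qidx[run[0]], qidx[run[-1]]
        fams = [qry.perm[qidx[j]] for j in run]
        gi_first, gi_last = qry.gene_index[q_first], qry.gene_index[q_last]
        span_genes = (gi_last - gi_first) % n_genes_total + 1
        ref_bps = [ref_posbp[f] for f, _s in fams]
        q_start, q_end = qry.positions_bp[q_first], qry.positions_bp[q_last]
        orientation = "forward" if sign[run[0]] > 0 else "reverted"
        n_flipped = int(np.count_nonzero(sign[run] < 0))
        blocks.append(
            Block(
                families=fams,
                n_core=len(run),
                n_total_genes=max(span_genes, len(run)),
                ref_span=(min(ref_bps), max(ref_bps)),
                query_span=(q_start, q_end),
                orientation=orientation,
                is_backbone=False,
                midpoint_bp=_circular_midpoint(q_start, q_end, qry.genome_length_bp)
                if circular
                else (q_start + q_end) / 2.0,
                identity_key=canonical_identity_key(fams),
                n_sign_flipped=n_flipped,
                query_gene_range=(gi_first, gi_last),
            )
        )
    part = BlockPartition(
        ref_id=ref.genome_id,
        query_id=qry.genome_id,
        blocks=blocks,
        n_singletons_discarded=singletons,
        n_shared_core=m,
        query_flipped=flipped,
    )
    if blocks:
        _mark_backbone(part)
    return part


def _mark_backbone(part: BlockPartition) -> None:
    """Largest block by core genes; ties by total genes, then smallest ref start."""
    best = min(
        range(len(part.blocks)),
        key=lambda i: (
            -part.blocks[i].n_core,
            -part.blocks[i].n_total_genes,
            part.blocks[i].ref_span[0],
        ),
    )
    for i, b in enumerate(part.blocks):
        b.is_backbone = i == best


def find_blocks(ref: CoreOrder, qry: CoreOrder, canonicalize: bool = True) -> BlockPartition:
    """Partition the shared core genes of a pair into maximal syntenic blocks.

    Runs of a single core gene are discarded (possible orthology
    mis-assignment) but counted.  With ``canonicalize`` the query's
    global strand is chosen so the backbone block reads forward —
    a genome deposited as the reverse complement of the reference is
    not one giant inversion; on linear genomes the orientation with
    fewer breakpoints is additionally preferred.
    """
    part = _build_partition(ref, qry, flipped=False)
    if not canonicalize:
        return part
    if not (ref.circular and qry.circular):
        alt = _build_partition(ref, _flip_order(qry), flipped=True)
        n_bp = part.n_blocks + part.n_singletons_discarded
        n_bp_alt = alt.n_blocks + alt.n_singletons_discarded
        if n_bp_alt < n_bp:
            part = alt
    backbone = next((b for b in part.blocks if b.is_backbone), None)
    if backbone is not None and backbone.orientation == "reverted":
        flip_src = _flip_order(qry) if not part.query_flipped else qry
        part = _build_partition(ref, flip_src, flipped=not part.query_flipped)
    return part


def classify_block(block: Block, partition: BlockPartition) -> str:
    """Inversion if the block's order is reversed relative to the reference
    (order is primary; a reversal without strand flips is logged), else
    translocation."""
    if block.is_backbone:
        raise ValueError("the backbone block is the unrearranged frame; not classifiable")
    if block.orientation == "reverted":
        if block.n_sign_flipped * 2 < block.n_core:
            logger.warning(
                "pair (%s, %s): reversed block with only %d/%d strand flips; "
                "classifying as inversion on order",
                partition.ref_id,
                partition.query_id,
                block.n_sign_flipped,
                block.n_core,
            )
        return INVERSION
    return TRANSLOCATION


def select_reference(orders: list[CoreOrder]) -> str:
    """Reference = genome minimizing the average retained-block count against
    all other genomes; ties broken by lexicographically smallest id."""
    if len(orders) < 2:
        raise ValidationError("reference selection needs >= 2 genomes")
    best_id, best_avg = None, None
    for cand in orders:
        total = 0
        for other in orders:
            if other.genome_id == cand.genome_id:
                continue
            total += find_blocks(cand, other).n_blocks
        avg = total / (len(orders) - 1)
        if best_avg is None or avg < best_avg or (avg == best_avg and cand.genome_id < best_id):
            best_id, best_avg = cand.genome_id, avg
    return best_id


def rearranged_blocks(partition: BlockPartition) -> list[Block]:
    """The n-1 non-backbone blocks, i.e. those reorganized relative to the
    largest block.  A single-block genome has no rearrangements."""
    if partition.n_blocks < 1:
        raise ValidationError("partition has no retained blocks")
    return [b for b in partition.blocks if not b.is_backbone]


def dedup_blocks(blocks: list[Block]) -> list[Block]:
    """Drop every copy of a block whose identity occurs more than twice
    across the pooled pairs, to avoid recounting one event many times."""
    from collections import Counter

    counts = Counter(b.identity_key for b in blocks)
    return [b for b in blocks if counts[b.identity_key] <= 2]


def summarize_species(
    species_id: str,
    reference_id: str,
    partitions: dict[str, BlockPartition],
) -> SpeciesBlockSummary:
    """Per-genome block counts and event tallies against the species reference.

    ``partitions`` maps query genome_id -> partition vs the reference;
    the reference's trivial self-comparison must not be included.
    """
    if reference_id in partitions:
        raise ValidationError("reference self-comparison must be excluded from the summary")
    n_blocks = {qid: p.n_blocks for qid, p in partitions.items()}
    inv: dict[str, int] = {}
    tra: dict[str, int] = {}
    lengths: list[int] = []
    for qid, part in partitions.items():
        classes = list(part.classifications.values())
        inv[qid] = classes.count(INVERSION)
        tra[qid] = classes.count(TRANSLOCATION)
        lengths.extend(b.n_total_genes for b in rearranged_blocks(part))
    mean_blocks = float(np.mean(list(n_blocks.values()))) if n_blocks else 0.0
    return SpeciesBlockSummary(
        species_id=species_id,
        reference_id=reference_id,
        n_blocks_per_genome=n_blocks,
        mean_blocks=mean_blocks,
        block_lengths_genes=lengths,
        inversions_per_genome=inv,
        translocations_per_genome=tra,
    )
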