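"""Synthetic species generator with planted ground truth.

Emulates the inputs of the rearrangement analysis: a clonal set of
circular genomes sharing a single-copy core gene set, accessory genes
interleaved between core genes, planted inversions and translocations
on a star genealogy (each genome rearranged independently from a common
ancestor), nucleotide substitutions on a concatenated core alignment,
GC-skewed replichores around planted Ori/Ter, and COG labels with a
mobilome category enriched inside rearranged spans.

A star genealogy keeps per-branch truth independent: every planted
event belongs to exactly one genome.  The truth log stores each
genome's explicit event list, the final unit order, the substitution
positions, and the planted Ori/Ter, so every downstream inference can
be checked against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import rates
from .core_genome import CoreOrder
from .genome_io import (
    Alignment,
    Gene,
    GenomeRecord,
    SpeciesSet,
    write_fasta,
    write_gene_table,
)

__all__ = [
    "SynthParams",
    "SpeciesBundle",
    "make_species",
    "make_skewed_sequence",
    "plant_rearrangements",
]

MOBILOME = "X"  # COG category "Mobilome: prophages, transposons"

DEFAULT_COG_FREQS = {
    "J": 0.07,  # translation, ribosomal structure
    "K": 0.06,  # transcription
    "L": 0.05,  # replication, recombination and repair
    "C": 0.06,  # energy production
    "E": 0.07,  # amino acid metabolism
    "G": 0.06,  # carbohydrate metabolism
    "M": 0.05,  # cell wall/membrane
    "P": 0.05,  # inorganic ion transport
    "T": 0.04,  # signal transduction
    MOBILOME: 0.03,
    "": 0.46,   # unannotated
}


@dataclass
class SynthParams:
    """Study conditions of the synthetic species.

    Defaults describe a small but realistic clonal species: 8 complete
    circular genomes (the analysis requires more than five per
    species), 100 single-copy core families, about one accessory gene
    per inter-core interval, roughly one to two rearrangements per
    genome, a 0.2 %/site substitution load on the core alignment, a
    leading-strand G excess of 0.2, and a five-fold mobilome excess in
    rearranged spans.
    """

    n_genomes: int = 8
    C: int = 100
    accessory_per_interval: float = 1.0
    genome_length_bp: int = 1_000_000
    gene_length_bp: int = 900
    aln_sites_per_core_gene: int = 300
    sub_rate: float = 0.002
    rearr_per_branch: float = 1.5
    p_inversion: float = 0.5
    seg_len_dist: tuple = ("uniform", 2, 8)
    skew_delta: float = 0.2
    ori_frac: float = 0.0
    ter_frac: float = 0.5
    transposase_boost: float = 5.0
    cog_freqs: dict = field(default_factory=lambda: dict(DEFAULT_COG_FREQS))
    seed: int = 0
    species_id: str = "synthspec"
    with_sequences: bool = True

    def __post_init__(self) -> None:
        if self.C < 10:
            raise ValueError("need C >= 10 core families")
        if not 0.0 < self.skew_delta < 1.0:
            raise ValueError("skew_delta must be in (0, 1)")
        if abs(sum(self.cog_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("COG base frequencies must sum to 1")
        if self.ori_frac == self.ter_frac:
            raise ValueError("planted Ori and Ter must differ")

    @property
    def alignment_length(self) -> int:
        return self.C * self.aln_sites_per_core_gene


@dataclass
class SpeciesBundle:
    species: SpeciesSet
    alignment: Alignment
    truth: dict
    params: SynthParams

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(self.species.genomes, outdir / "gene_table.tsv")
        seqs = {
            g.genome_id: g.sequence
            for g in self.species.genomes
            if g.sequence is not None
        }
        if seqs:
            write_fasta(seqs, outdir / "genomes.fasta")
        write_fasta(self.alignment.rows, outdir / "core_aln.fasta")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def make_skewed_sequence(
    length_bp: int,
    ori_bp: int,
    ter_bp: int,
    delta: float,
    seed_or_rng,
) -> str:
    """A circular sequence whose windowed GC skew switches sign at the
    planted Ori and Ter.

    Each position is a G/C with probability 1/2; on the leading arc
    (Ori -> Ter in increasing coordinates, wrapping) a G is chosen over
    a C with probability (1+delta)/2, on the other arc (1-delta)/2.
    The A/T filler is balanced.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    if ori_bp == ter_bp:
        raise ValueError("Ori and Ter must differ")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    pos = np.arange(length_bp)
    leading = ((pos - ori_bp) % length_bp) < ((ter_bp - ori_bp) % length_bp)
    is_gc = rng.random(length_bp) < 0.5
    p_g = np.where(leading, (1 + delta) / 2.0, (1 - delta) / 2.0)
    g_pick = rng.random(length_bp) < p_g
    at_pick = rng.random(length_bp) < 0.5
    chars = np.where(is_gc, np.where(g_pick, "G", "C"), np.where(at_pick, "A", "T"))
    return "".join(chars.tolist())


def plant_rearrangements(
    order: CoreOrder, events: list[tuple]
) -> tuple[CoreOrder, list[dict]]:
    """Apply an explicit list of events to a core order (for worked examples).

    Events are ``("inversion", start, length)`` or ``("translocation",
    start, length, gap)`` with 0-based circular indices into the
    current permutation; events are applied sequentially.  The genomic
    coordinate slots stay fixed — rearrangement moves gene content, not
    positions.
    """
    n = len(order.perm)
    idx = np.arange(1, n + 1, dtype=np.int64)  # signed slots over current perm
    truth = []
    for ev in events:
        kind = ev[0]
        if kind == "inversion":
            _, start, length = ev
            idx = rates.apply_inversion(idx, start, length)
        elif kind == "translocation":
            _, start, length, gap = ev
            idx = rates.apply_translocation(idx, start, length, gap)
        else:
            raise ValueError(f"unknown event {kind!r}")
        truth.append({"type": kind, "args": list(ev[1:])})
    perm = []
    for signed in idx:
        src = int(abs(signed)) - 1
        fam, s = order.perm[src]
        perm.append((fam, s if signed > 0 else -s))
    return (
        CoreOrder(
            genome_id=order.genome_id,
            perm=perm,
            positions_bp=list(order.positions_bp),
            gene_index=list(order.gene_index),
            accessory_after=list(order.accessory_after),
            circular=order.circular,
            genome_length_bp=order.genome_length_bp,
        ),
        truth,
    )


def _draw_category(rng: np.random.Generator, freqs: dict) -> str:
    cats = list(freqs.keys())
    p = np.array([freqs[c] for c in cats], dtype=float)
    return cats[int(rng.choice(len(cats), p=p / p.sum()))]


def _boosted_freqs(freqs: dict, boost: float) -> dict:
    out = dict(freqs)
    out[MOBILOME] = out.get(MOBILOME, 0.0) * boost
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def _non_backbone_units(signed_units: np.ndarray) -> set[int]:
    """0-based ancestral unit indices outside the largest syntenic run
    relative to the ancestor (empty for an unrearranged genome)."""
    from .block_finder import _conserved_adjacencies, _runs

    m = len(signed_units)
    pos = np.abs(signed_units) - 1
    sign = np.sign(signed_units)
    conserved = _conserved_adjacencies(pos, sign, circular=True)
    if bool(conserved.all()):
        return set()
    runs = _runs(conserved, m, circular=True)
    backbone = max(range(len(runs)), key=lambda i: len(runs[i]))
    out: set[int] = set()
    for i, run in enumerate(runs):
        if i == backbone:
            continue
        out.update(int(abs(signed_units[j])) - 1 for j in run)
    return out


def _random_events(
    params: SynthParams, rng: np.random.Generator
) -> list[tuple]:
    k = int(rng.poisson(params.rearr_per_branch))
    sim = rates.SimParams(
        C=params.C, p_inversion=params.p_inversion, seg_len_dist=params.seg_len_dist
    )
    dist = sim.resolved_seg_len_dist()
    events = []
    for _ in range(k):
        length = rates._draw_segment_length(dist, params.C, rng)
        start = int(rng.integers(0, params.C))
        if rng.random() < params.p_inversion:
            events.append(("inversion", start, length))
        else:
            gap = int(rng.integers(1, params.C - length))
            events.append(("translocation", start, length, gap))
    return events


def make_species(
    params: SynthParams,
    events_per_genome: dict[str, list[tuple]] | None = None,
) -> SpeciesBundle:
    """Generate a synthetic species bundle under the given conditions.

    ``events_per_genome`` overrides the random Poisson event draw for
    the named genomes with explicit event lists (for planting worked
    examples).  Every source of randomness derives from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    C = params.C
    fam_ids = [f"fam{i:04d}" for i in range(1, C + 1)]
    fam_strand = ["+" if rng.random() < 0.5 else "-" for _ in range(C)]
    fam_cat = [_draw_category(rng, params.cog_freqs) for _ in range(C)]

    # ancestral accessory genes per inter-core interval (shared content)
    acc_per_interval: list[list[tuple[str, str, str]]] = []
    for i in range(C):
        n_acc = int(rng.poisson(params.accessory_per_interval))
        interval = []
        for j in range(n_acc):
            cat = _draw_category(rng, params.cog_freqs)
            interval.append(
                (f"acc{i:04d}_{j}", "+" if rng.random() < 0.5 else "-", cat)
            )
        acc_per_interval.append(interval)

    ori_bp = int(params.ori_frac * params.genome_length_bp)
    ter_bp = int(params.ter_frac * params.genome_length_bp)

    # ancestral core alignment and per-branch substitutions
    L = params.alignment_length
    bases = np.array(list("ACGT"))
    ancestor_aln = rng.integers(0, 4, size=L)

    genome_ids = [f"g{i:02d}" for i in range(1, params.n_genomes + 1)]
    genomes: list[GenomeRecord] = []
    aln_rows: dict[str, str] = {}
    truth: dict = {
        "species_id": params.species_id,
        "planted_ori_bp": ori_bp,
        "planted_ter_bp": ter_bp,
        "enriched_category": MOBILOME,
        "core_families": fam_ids,
        "genomes": {},
    }

    for gid in genome_ids:
        if events_per_genome and gid in events_per_genome:
            events = [tuple(e) for e in events_per_genome[gid]]
        else:
            events = _random_events(params, rng)
        signed_units = np.arange(1, C + 1, dtype=np.int64)
        event_units: set[int] = set()
        for ev in events:
            if ev[0] == "inversion":
                _, start, length = ev
                touched = [(int(abs(signed_units[(start + t) % C])) - 1) for t in range(length)]
                signed_units = rates.apply_inversion(signed_units, start, length)
            else:
                _, start, length, gap = ev
                touched = [(int(abs(signed_units[(start + t) % C])) - 1) for t in range(length)]
                signed_units = rates.apply_translocation(signed_units, start, length, gap)
            event_units.update(touched)
        # mobilome boost targets the rearranged spans: every unit outside
        # the largest (backbone) syntenic run relative to the ancestor
        rearranged_units = _non_backbone_units(signed_units)

        # flatten units to a gene list in the rearranged order
        gene_specs: list[tuple[str, str, str, str, bool]] = []
        for signed in signed_units:
            u = int(abs(signed)) - 1
            flipped = signed < 0
            core_strand = fam_strand[u]
            if flipped:
                core_strand = "+" if core_strand == "-" else "-"
            boosted = u in rearranged_units
            core_gene = (f"{gid}_{fam_ids[u]}", fam_ids[u], core_strand, fam_cat[u], False)
            acc_genes = []
            for aid, astrand, acat in acc_per_interval[u]:
                if boosted:
                    acat = _draw_category(
                        rng, _boosted_freqs(params.cog_freqs, params.transposase_boost)
                    )
                strand = astrand
                if flipped:
                    strand = "+" if strand == "-" else "-"
                acc_genes.append(
                    (f"{gid}_{aid}", "", strand, acat, acat == MOBILOME)
                )
            if flipped:
                gene_specs.extend(reversed(acc_genes))
                gene_specs.append(core_gene)
            else:
                gene_specs.append(core_gene)
                gene_specs.extend(acc_genes)

        n_genes = len(gene_specs)
        spacing = params.genome_length_bp // n_genes
        if spacing <= params.gene_length_bp:
            raise ValueError(
                f"genome too short for {n_genes} genes of {params.gene_length_bp} bp"
            )
        genes = []
        for j, (gene_id, fam, strand, cat, is_tn) in enumerate(gene_specs):
            start = j * spacing + 1
            genes.append(
                Gene(
                    gene_id=gene_id,
                    family_id=fam,
                    strand=strand,
                    start=start,
                    end=start + params.gene_length_bp - 1,
                    cog_id=f"COG{cat}{sum(map(ord, gene_id)) % 5:01d}" if cat else "",
                    cog_category=cat,
                    is_transposase=is_tn,
                )
            )
        sequence = (
            make_skewed_sequence(
                params.genome_length_bp, ori_bp, ter_bp, params.skew_delta, rng
            )
            if params.with_sequences
            else None
        )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                species_id=params.species_id,
                circular=True,
                length_bp=params.genome_length_bp,
                genes=genes,
                sequence=sequence,
            )
        )

        n_subs = int(rng.poisson(params.sub_rate * L))
        n_subs = min(n_subs, L)
        sub_pos = rng.choice(L, size=n_subs, replace=False)
        row = ancestor_aln.copy()
        row[sub_pos] = (row[sub_pos] + rng.integers(1, 4, size=n_subs)) % 4
        aln_rows[gid] = "".join(bases[row].tolist())
        truth["genomes"][gid] = {
            "events": [{"type": e[0], "args": list(e[1:])} for e in events],
            "n_events": len(events),
            "final_unit_order": signed_units.tolist(),
            "substitution_positions": sorted(int(p) for p in sub_pos),
            "event_units": sorted(event_units),
            "rearranged_units": sorted(rearranged_units),
        }

    alignment = Alignment(rows=aln_rows, length=L)
    species = SpeciesSet(species_id=params.species_id, genomes=genomes, alignment=alignment)

    pair_subs = {}
    ids = genome_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            p1 = set(truth["genomes"][ids[i]]["substitution_positions"])
            p2 = set(truth["genomes"][ids[j]]["substitution_positions"])
            a = np.frombuffer(aln_rows[ids[i]].encode(), dtype=np.uint8)
            b = np.frombuffer(aln_rows[ids[j]].encode(), dtype=np.uint8)
            observed = int(np.count_nonzero(a != b))
            pair_subs[f"{ids[i]}|{ids[j]}"] = {
                "planted_union": len(p1 | p2),
                "collisions": len(p1 & p2),
                "observed": observed,
            }
    truth["pairwise_substitutions"] = pair_subs

    return SpeciesBundle(species=species, alignment=alignment, truth=truth, params=params)
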