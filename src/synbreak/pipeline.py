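"""End-to-end orchestration of the rearrangement analysis.

Stages: core calling -> reference selection and block finding ->
event classification -> Ori/Ter localization and positional bias ->
rate estimation -> COG enrichment.  Every stage writes a TSV into the
report directory, and the exclusions applied along the way (discarded
singletons, ambiguous skew profiles, single-block genomes,
deduplicated blocks) are first-class output, since they materially
shape the results.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import block_finder, core_genome, enrichment, genome_io, rates, replichore

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "freq": 0.90,
    "window_bp": 1000,
    "reference": "auto",
    "seed": 0,
    "calibration": {
        "k_grid": list(range(0, 21)),
        "p_inversion": 0.5,
        "replicates": 100,
    },
    "stages": {
        "blocks": True,
        "oriter": True,
        "posbias": True,
        "rates": True,
        "enrich": True,
    },
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _merge_config(config: dict) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def load_species(config: dict) -> genome_io.SpeciesSet:
    records = genome_io.read_gene_table(config["gene_table"])
    if not records:
        raise ValueError("gene table holds no genomes")
    species_id = records[0].species_id
    if config.get("fasta"):
        seqs = genome_io.read_fasta(config["fasta"])
        for rec in records:
            if rec.genome_id in seqs:
                rec.sequence = seqs[rec.genome_id]
                if len(rec.sequence) != rec.length_bp:
                    raise genome_io.ValidationError(
                        f"genome {rec.genome_id!r}: FASTA length != gene-table length_bp"
                    )
    aln = genome_io.read_alignment(config["alignment"]) if config.get("alignment") else None
    return genome_io.SpeciesSet(species_id=species_id, genomes=records, alignment=aln)


def compute_partitions(
    species: genome_io.SpeciesSet,
    freq: float = 0.90,
    reference: str = "auto",
) -> tuple[core_genome.CoreGenome, str, dict[str, block_finder.BlockPartition]]:
    """Core calling, reference selection, and per-genome block partitions."""
    core = core_genome.call_core_families(species, freq=freq)
    orders = [core_genome.project_core_order(g, core) for g in species.genomes]
    ref_id = (
        block_finder.select_reference(orders) if reference == "auto" else reference
    )
    by_id = {o.genome_id: o for o in orders}
    if ref_id not in by_id:
        raise ValueError(f"reference genome {ref_id!r} not in species")
    partitions = {
        o.genome_id: block_finder.find_blocks(by_id[ref_id], o)
        for o in orders
        if o.genome_id != ref_id
    }
    return core, ref_id, partitions


def _blocks_rows(partitions: dict[str, block_finder.BlockPartition]) -> list[dict]:
    rows = []
    for qid, part in partitions.items():
        classes = part.classifications
        for i, blk in enumerate(part.blocks):
            rows.append(
                {
                    "ref_id": part.ref_id,
                    "query_id": qid,
                    "block_index": i,
                    "families": ",".join(f"{'+' if s > 0 else '-'}{f}" for f, s in blk.families),
                    "n_core": blk.n_core,
                    "n_total_genes": blk.n_total_genes,
                    "ref_start": blk.ref_span[0],
                    "ref_end": blk.ref_span[1],
                    "query_start": blk.query_span[0],
                    "query_end": blk.query_span[1],
                    "orientation": blk.orientation,
                    "is_backbone": blk.is_backbone,
                    "event_class": classes.get(i, ""),
                    "midpoint_bp": blk.midpoint_bp,
                    "identity_key": "|".join(
                        f"{'+' if s > 0 else '-'}{f}" for f, s in blk.identity_key
                    ),
                }
            )
    return rows


def positional_analysis(
    species: genome_io.SpeciesSet,
    partitions: dict[str, block_finder.BlockPartition],
    window_bp: int = 1000,
    event_class: str = "all",
) -> dict:
    """Skew profiles, exclusions, pooled replichore distances, and the bias test."""
    profiles: dict[str, replichore.SkewProfile] = {}
    excluded: dict[str, str] = {}
    for g in species.genomes:
        if g.sequence is None:
            excluded[g.genome_id] = "no sequence"
            continue
        if not g.circular:
            excluded[g.genome_id] = "linear chromosome"
            continue
        prof = replichore.gc_skew_profile(g.sequence, window_bp, genome_id=g.genome_id)
        if prof.ambiguous:
            excluded[g.genome_id] = f"ambiguous skew: {prof.ambiguity_reason}"
            continue
        profiles[g.genome_id] = prof

    entries = enrichment.block_gene_entries(species, partitions, dedup=True)
    distances, classes = [], []
    for genome, blk, cls in entries:
        if genome.genome_id not in profiles:
            continue
        if event_class != "all" and cls != event_class:
            continue
        distances.append(
            replichore.relative_position(
                max(1.0, blk.midpoint_bp), profiles[genome.genome_id]
            )
        )
        classes.append(cls)
    sample = replichore.PositionalSample(
        species_id=species.species_id, distances=distances, event_class=classes
    )
    test = replichore.test_positional_bias(sample) if distances else None
    return {
        "profiles": profiles,
        "excluded_genomes": excluded,
        "sample": sample,
        "test": test,
    }


def rate_analysis(
    species: genome_io.SpeciesSet,
    core: core_genome.CoreGenome,
    partitions: dict[str, block_finder.BlockPartition],
    calibration: dict,
    seed: int = 0,
    distances: tuple[list[str], "np.ndarray"] | None = None,
) -> tuple[rates.QuadraticModel, list[rates.RateEstimate]]:
    """Calibrate the blocks-to-events map at the species' C and estimate
    per-pair rates against the reference.

    ``distances`` optionally supplies an external per-site distance
    matrix (e.g. maximum-likelihood distances, PHYLIP square format);
    the substitution count then becomes distance * alignment length
    instead of the raw column-difference count.
    """
    if species.alignment is None:
        raise ValueError("rate estimation needs the core alignment")
    params = rates.SimParams(
        C=core.C,
        k_grid=list(calibration.get("k_grid", range(0, 21))),
        p_inversion=calibration.get("p_inversion", 0.5),
        seg_len_dist=tuple(calibration.get("seg_len_dist", ("uniform", 2, 0))),
        replicates=calibration.get("replicates", 100),
        seed=seed,
    )
    model = rates.calibrate_blocks_to_events(params)
    L = species.alignment.length
    estimates = []
    for qid, part in sorted(partitions.items()):
        B = part.n_blocks
        if B < 1:
            continue
        N = rates.predict_events(B, model)
        if distances is not None:
            ids, mat = distances
            S = float(mat[ids.index(part.ref_id), ids.index(qid)]) * L
        else:
            S, _l_eff = rates.pairwise_substitutions(species.alignment, part.ref_id, qid)
        if S == 0:
            logger.info("pair (%s, %s): identical core alignment; rate undefined", part.ref_id, qid)
            continue
        estimates.append(
            rates.RateEstimate(
                genome_1=part.ref_id,
                genome_2=qid,
                B=B,
                N=N,
                C=core.C,
                S=S,
                L=L,
                B_cs=rates.rearrangement_rate(N, core.C, S, L),
            )
        )
    return model, estimates


def run_all(config: dict, out_dir=None) -> Path:
    """Run every enabled stage and write the report directory."""
    cfg = _merge_config(config)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    exclusions: list[dict] = []

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise StageError(name, exc) from exc

        return _Timer()

    with stage("load"):
        species = load_species(cfg)

    with stage("core-blocks"):
        core, ref_id, partitions = compute_partitions(
            species, freq=cfg["freq"], reference=cfg["reference"]
        )
        genome_io.write_tsv_report(
            [{"family_id": f} for f in core.core_families], out / "core_families.tsv"
        )
        genome_io.write_tsv_report(_blocks_rows(partitions), out / "blocks.tsv")
        summary = block_finder.summarize_species(species.species_id, ref_id, partitions)
        genome_io.write_tsv_report(
            [
                {
                    "genome_id": qid,
                    "n_blocks": summary.n_blocks_per_genome[qid],
                    "n_inversions": summary.inversions_per_genome[qid],
                    "n_translocations": summary.translocations_per_genome[qid],
                    "n_singletons_discarded": partitions[qid].n_singletons_discarded,
                }
                for qid in sorted(partitions)
            ],
            out / "summary.tsv",
        )
        genome_io.write_tsv_report(
            [
                {
                    "species_id": species.species_id,
                    "reference_id": ref_id,
                    "core_size": core.C,
                    "mean_blocks": summary.mean_blocks,
                    "median_block_length_genes": (
                        float(np.median(summary.block_lengths_genes))
                        if summary.block_lengths_genes
                        else 0.0
                    ),
                }
            ],
            out / "species_summary.tsv",
        )
        for qid, part in partitions.items():
            if part.n_singletons_discarded:
                exclusions.append(
                    {
                        "stage": "blocks",
                        "item": qid,
                        "rule": "single-core-gene blocks discarded",
                        "count": part.n_singletons_discarded,
                    }
                )

    posres = None
    if cfg["stages"]["oriter"] or cfg["stages"]["posbias"]:
        with stage("oriter-posbias"):
            posres = positional_analysis(species, partitions, window_bp=cfg["window_bp"])
            genome_io.write_tsv_report(
                [
                    {
                        "genome_id": gid,
                        "ori_bp": p.ori_bp,
                        "ter_bp": p.ter_bp,
                        "ambiguous": p.ambiguous,
                        "reason": p.ambiguity_reason,
                    }
                    for gid, p in sorted(posres["profiles"].items())
                ],
                out / "oriter.tsv",
            )
            genome_io.write_tsv_report(
                [
                    {"distance": d, "event_class": c}
                    for d, c in zip(
                        posres["sample"].distances, posres["sample"].event_class
                    )
                ],
                out / "distances.tsv",
            )
            if posres["test"] is not None:
                genome_io.write_tsv_report([posres["test"]], out / "positional_test.tsv")
            for gid, why in posres["excluded_genomes"].items():
                exclusions.append(
                    {"stage": "oriter", "item": gid, "rule": why, "count": 1}
                )
    else:
        logger.info("stage oriter/posbias: skipped by config")

    if cfg["stages"]["rates"] and species.alignment is not None:
        with stage("rates"):
            model, estimates = rate_analysis(
                species, core, partitions, cfg["calibration"], seed=cfg["seed"]
            )
            genome_io.write_tsv_report(
                [
                    {
                        "genome_1": e.genome_1,
                        "genome_2": e.genome_2,
                        "B": e.B,
                        "N": e.N,
                        "C": e.C,
                        "S": e.S,
                        "L": e.L,
                        "B_cs": e.B_cs,
                    }
                    for e in estimates
                ],
                out / "rates.tsv",
            )
            genome_io.write_tsv_report(
                [
                    {
                        "a": model.a,
                        "b": model.b,
                        "c": model.c,
                        "rmse": model.rmse,
                        "C": model.C,
                    }
                ],
                out / "calibration.tsv",
            )
    else:
        logger.info("stage rates: skipped (disabled or no alignment)")

    if cfg["stages"]["enrich"]:
        with stage("enrich"):
            tables = enrichment.count_cogs(
                species,
                partitions,
                scope=cfg.get("scope", "all"),
                level=cfg.get("level", "category"),
                core_families=set(core.core_families),
                disjoint=bool(cfg.get("disjoint", False)),
            )
            results = enrichment.chi2_enrichment(tables)
            genome_io.write_tsv_report(
                [
                    {
                        "cog": r.cog,
                        "a": r.a,
                        "b": r.b,
                        "c": r.c,
                        "d": r.d,
                        "chi2": r.chi2,
                        "p": r.p,
                        "q": r.q,
                        "enriched": r.enriched,
                        "low_count": r.low_count,
                    }
                    for r in results
                ],
                out / "enrichment.tsv",
            )
    else:
        logger.info("stage enrich: skipped by config")

    genome_io.write_tsv_report(exclusions, out / "exclusions.tsv",
                               columns=["stage", "item", "rule", "count"])
    genome_io.write_tsv_report(
        [{"stage": k, "seconds": round(v, 3)} for k, v in timings.items()],
        out / "timings.tsv",
    )
    return out
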