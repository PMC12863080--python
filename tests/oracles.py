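"""Independent reference implementations used only to check the package.

These deliberately re-derive results from first principles (literal
definitions, enumeration) rather than sharing code with the library.
"""

from __future__ import annotations

import numpy as np

from synbreak.core_genome import CoreOrder


def signed_successor_map(perm: list[tuple[str, int]]) -> dict:
    """succ[(family, sign)] for a circular signed gene order: reading the
    genome forward, the signed gene after (f, s); reading it on the other
    strand, the successor of (g, -t) is (f, -s) for each adjacency
    (f,s) -> (g,t)."""
    succ = {}
    n = len(perm)
    for i in range(n):
        f, s = perm[i]
        g, t = perm[(i + 1) % n]
        succ[(f, s)] = (g, t)
        succ[(g, -t)] = (f, -s)
    return succ


def brute_force_block_counts(
    ref: list[tuple[str, int]], qry: list[tuple[str, int]]
) -> tuple[int, int]:
    """(retained blocks, discarded singletons) of qry against ref by the
    literal definition: split the circular query at every adjacency that is
    not an adjacency of the reference in the same relative orientation."""
    ref_fams = {f for f, _ in ref}
    qry_shared = [(f, s) for f, s in qry if f in ref_fams]
    qry_fams = {f for f, _ in qry_shared}
    ref_shared = [(f, s) for f, s in ref if f in qry_fams]
    m = len(qry_shared)
    succ = signed_successor_map(ref_shared)
    conserved = [
        succ.get(qry_shared[i]) == qry_shared[(i + 1) % m] for i in range(m)
    ]
    if all(conserved):
        return 1, 0
    # walk the circle, cutting at broken adjacencies
    run_lengths = []
    starts = [(i + 1) % m for i in range(m) if not conserved[i]]
    breaks = sorted(starts)
    for a, b in zip(breaks, breaks[1:] + [breaks[0] + m]):
        run_lengths.append(b - a)
    retained = sum(1 for ln in run_lengths if ln >= 2)
    singles = sum(1 for ln in run_lengths if ln == 1)
    return retained, singles


def random_signed_circular_perm(
    rng: np.random.Generator, size: int
) -> list[tuple[str, int]]:
    order = rng.permutation(size)
    signs = rng.choice([-1, 1], size=size)
    return [(f"f{order[i]}", int(signs[i])) for i in range(size)]


def as_core_order(perm: list[tuple[str, int]], genome_id: str = "g") -> CoreOrder:
    n = len(perm)
    return CoreOrder(
        genome_id=genome_id,
        perm=list(perm),
        positions_bp=[i * 1000.0 + 500.0 for i in range(n)],
        gene_index=list(range(n)),
        accessory_after=[0] * n,
        circular=True,
        genome_length_bp=n * 1000,
    )


def chi2_textbook(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square via the closed 2x2 formula N(ad-bc)^2 / products."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den if den else 0.0


def bh_stepup_reference(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q
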