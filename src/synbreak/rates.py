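"""Rearrangement-rate estimation.

Observed block counts are converted into rearrangement-event estimates
through a simulation-calibrated quadratic map: random inversions and
translocations are applied to an identity permutation of the species'
core size C, the mean resulting block count is recorded per event count
k, and a quadratic mean_blocks = a + b*k + c*k**2 is fitted.  Inverting
that map at an observed block count B gives the predicted event count
N, and the rate per substitution is

    B_cs = N / (C * S * L)

with S the pairwise substitution count on the concatenated core-genome
alignment and L the alignment length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .block_finder import count_blocks_raw
from .genome_io import Alignment

__all__ = [
    "SimParams",
    "QuadraticModel",
    "RateEstimate",
    "simulate_rearrangements",
    "calibrate_blocks_to_events",
    "predict_events",
    "pairwise_substitutions",
    "rearrangement_rate",
    "jukes_cantor",
]


@dataclass
class SimParams:
    """Settings of the block-count calibration simulations.

    ``seg_len_dist`` is ``("uniform", min, max)`` in genes or
    ``("geometric", mean)``; draws are truncated to [2, C-2] since a
    one-gene segment would be a discarded singleton.
    """

    C: int
    k_grid: list[int] = field(default_factory=lambda: list(range(0, 21)))
    p_inversion: float = 0.5
    seg_len_dist: tuple = ("uniform", 2, 0)  # max 0 -> default max(3, C // 10)
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 4:
            raise ValueError("core size C must be >= 4")
        if any(k < 0 for k in self.k_grid):
            raise ValueError("event counts must be >= 0")
        if not 0.0 <= self.p_inversion <= 1.0:
            raise ValueError("p_inversion must be in [0, 1]")

    def resolved_seg_len_dist(self) -> tuple:
        if self.seg_len_dist[0] == "uniform" and self.seg_len_dist[2] == 0:
            return ("uniform", 2, max(3, self.C // 10))
        return self.seg_len_dist


@dataclass
class QuadraticModel:
    """Calibrated blocks-to-events map: mean_blocks = a + b*k + c*k**2."""

    a: float
    b: float
    c: float
    rmse: float
    C: int
    k_grid: list[int] = field(default_factory=list)
    mean_blocks: list[float] = field(default_factory=list)

    def blocks_at(self, k: float) -> float:
        return self.a + self.b * k + self.c * k * k


@dataclass
class RateEstimate:
    genome_1: str
    genome_2: str
    B: int           # observed retained blocks
    N: float         # predicted rearrangement events
    C: int           # core genome size (genes)
    S: float         # substitutions between the pair
    L: int           # core alignment length (nt)
    B_cs: float

    def __post_init__(self) -> None:
        if self.N < 0 or self.B_cs < 0:
            raise ValueError("N and B_cs must be non-negative")


def _draw_segment_length(dist: tuple, C: int, rng: np.random.Generator) -> int:
    lo, hi = 2, C - 2
    if hi < lo:
        raise ValueError(f"C={C} too small for segments of >= 2 genes with >= 2 outside")
    kind = dist[0]
    if kind == "uniform":
        dmin, dmax = int(dist[1]), int(dist[2])
        dmin, dmax = max(lo, dmin), min(hi, dmax)
        if dmax < dmin:
            raise ValueError(f"uniform segment-length range empty after truncation to [{lo},{hi}]")
        return int(rng.integers(dmin, dmax + 1))
    if kind == "geometric":
        mean = float(dist[1])
        if mean <= 1:
            raise ValueError("geometric mean segment length must exceed 1")
        while True:
            val = int(rng.geometric(1.0 / mean))
            if lo <= val <= hi:
                return val
    raise ValueError(f"unknown segment length distribution {kind!r}")


def apply_inversion(perm: np.ndarray, start: int, length: int) -> np.ndarray:
    """Reverse a circular arc of the signed permutation and flip its signs."""
    C = len(perm)
    idx = (start + np.arange(length)) % C
    out = perm.copy()
    out[idx] = -perm[idx[::-1]]
    return out


def apply_translocation(perm: np.ndarray, start: int, length: int, insert_gap: int) -> np.ndarray:
    """Excise a circular arc and reinsert it, orientation preserved, at the
    adjacency ``insert_gap`` steps (circularly) past the excision site
    (1 <= insert_gap <= C-length-1, so the original site is excluded).

    The array frame is preserved: elements outside the moved segment
    keep their original circular order starting from the lowest kept
    index, so the simulated coordinate frame does not rotate with every
    event.
    """
    C = len(perm)
    idx = (start + np.arange(length)) % C
    seg = perm[idx]
    if not 1 <= insert_gap <= C - length - 1:
        raise ValueError("insertion must target an adjacency other than the excision site")
    mask = np.ones(C, dtype=bool)
    mask[idx] = False
    kept = np.nonzero(mask)[0]
    rest = perm[kept]
    # adjacency just before the excised arc, located within the kept frame
    prev_orig = (start - 1) % C
    j_exc = int(np.searchsorted(kept, prev_orig))
    j_ins = (j_exc + insert_gap) % (C - length)
    return np.concatenate([rest[: j_ins + 1], seg, rest[j_ins + 1 :]])


def simulate_rearrangements(
    C: int,
    k: int,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply k random events to the identity signed permutation of size C.

    Each event is an inversion with probability ``p_inversion``, else a
    translocation to a uniformly chosen other adjacency.  Returns the
    signed permutation as integers with absolute values 1..C.
    """
    perm = np.arange(1, C + 1, dtype=np.int64)
    dist = params.resolved_seg_len_dist()
    for _ in range(k):
        length = _draw_segment_length(dist, C, rng)
        start = int(rng.integers(0, C))
        if rng.random() < params.p_inversion:
            perm = apply_inversion(perm, start, length)
        else:
            gap = int(rng.integers(1, C - length))
            perm = apply_translocation(perm, start, length, gap)
    return perm


def calibrate_blocks_to_events(params: SimParams) -> QuadraticModel:
    """Fit the quadratic mean-blocks-vs-events calibration curve by simulation."""
    from . import stats_kernel

    ks = sorted(set(params.k_grid))
    if len(ks) < 4 or 0 not in ks:
        raise ValueError("k_grid must span >= 4 distinct event counts including 0")
    rng = np.random.default_rng(params.seed)
    means = []
    for k in ks:
        if k == 0:
            means.append(1.0)  # identity genome: one block by definition
            continue
        counts = []
        for _ in range(params.replicates):
            perm = simulate_rearrangements(params.C, k, params, rng)
            retained, _singl = count_blocks_raw(perm)
            counts.append(retained)
        means.append(float(np.mean(counts)))
    a, b, c = stats_kernel.fit_quadratic(ks, means)
    fitted = np.array([a + b * k + c * k * k for k in ks])
    rmse = float(np.sqrt(np.mean((fitted - np.array(means)) ** 2)))
    return QuadraticModel(a=a, b=b, c=c, rmse=rmse, C=params.C,
                          k_grid=list(ks), mean_blocks=means)


def predict_events(B: float, model: QuadraticModel, c_tol: float = 1e-9) -> float:
    """Invert the calibration curve at an observed block count.

    Solves a + b*k + c*k**2 = B for k and returns the smallest
    non-negative real root (parsimony: fewest events explaining the
    blocks), clamped at 0.  One block means no rearrangement.
    """
    if B < 1:
        raise ValueError("block count must be >= 1")
    if B <= model.blocks_at(0.0) or B <= 1:
        return 0.0
    a, b, c = model.a - B, model.b, model.c
    if abs(c) < c_tol:
        if abs(b) < c_tol:
            raise ValueError("degenerate calibration: flat curve")
        return max(0.0, -a / b)
    disc = b * b - 4 * c * a
    if disc < 0:
        # beyond the fitted range (past the parabola's apex): extrapolate
        # linearly from the apex slope at the last calibrated point
        k_max = max(model.k_grid) if model.k_grid else 0.0
        slope = b + 2 * c * k_max
        if slope <= 0:
            slope = b
        import warnings

        warnings.warn(
            f"block count {B} exceeds the calibrated range; linear extrapolation",
            stacklevel=2,
        )
        return max(0.0, k_max + (B - model.blocks_at(k_max)) / max(slope, c_tol))
    roots = [(-b - math.sqrt(disc)) / (2 * c), (-b + math.sqrt(disc)) / (2 * c)]
    nonneg = sorted(r for r in roots if r >= 0)
    if nonneg:
        return nonneg[0]
    return 0.0


_ACGT = frozenset("ACGT")


def pairwise_substitutions(aln: Alignment, g1: str, g2: str) -> tuple[int, int]:
    """(S, L_eff): differing and total comparable (both unambiguous A/C/G/T)
    alignment columns between two genomes."""
    for g in (g1, g2):
        if g not in aln:
            raise KeyError(f"genome {g!r} not in alignment")
    a = np.frombuffer(aln[g1].upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(aln[g2].upper().encode("ascii"), dtype=np.uint8)
    valid = np.zeros(256, dtype=bool)
    for ch in "ACGT":
        valid[ord(ch)] = True
    comparable = valid[a] & valid[b]
    S = int(np.count_nonzero(comparable & (a != b)))
    L_eff = int(np.count_nonzero(comparable))
    return S, L_eff


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance from a proportion of differing sites."""
    if not 0 <= p < 0.75:
        raise ValueError("proportion of differences must be in [0, 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def rearrangement_rate(N: float, C: int, S: float, L: int) -> float:
    """B_cs = N / (C * S * L): predicted events per substitution, normalized
    by core genome size and alignment length."""
    if S == 0:
        raise ZeroDivisionError("S == 0: rate undefined for identical genomes")
    if C <= 0 or L <= 0 or S < 0:
        raise ValueError("C and L must be positive, S non-negative")
    return N / (C * S * L)
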